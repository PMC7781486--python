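import numpy as np
import pytest

from bladesim.model import ADDRESS_IDX, SPECIES, TABLE_OPTIMUM, ParameterSet, build_network
from bladesim.ssa import (
    EmptyPopulationError,
    SSAConfig,
    Trajectory,
    default_initial_state,
    final_occupancy,
    gillespie_final,
    gillespie_run,
    occupancy_from_state,
)

Z = {name: i for i, name in enumerate(SPECIES)}


def random_params(rng):
    vals = 10.0 ** rng.uniform(-5, 5, size=12)
    names = ("k1c", "k2c", "k1f", "k2f", "k_1c", "k_2c", "k_1f", "k_2f",
             "alpha", "beta_p", "delta_D", "delta_X")
    return ParameterSet(**dict(zip(names, vals)))


class TestDeterminism:
    def test_same_seed_same_trajectory(self):
        net = build_network(TABLE_OPTIMUM, (True, True))
        a = gillespie_run(net, SSAConfig(seed=11, max_reactions=2000))
        b = gillespie_run(net, SSAConfig(seed=11, max_reactions=2000))
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_distinct_seeds_distinct_trajectories(self):
        net = build_network(TABLE_OPTIMUM, (True, True))
        a = gillespie_run(net, SSAConfig(seed=1, max_reactions=2000))
        b = gillespie_run(net, SSAConfig(seed=2, max_reactions=2000))
        assert not np.array_equal(a.states, b.states)

    def test_final_matches_full_run(self):
        net = build_network(TABLE_OPTIMUM, (True, True))
        cfg = SSAConfig(seed=5, max_reactions=3000)
        traj = gillespie_run(net, cfg)
        final, t_end, n = gillespie_final(net, cfg)
        assert np.array_equal(final, traj.final_state)
        assert n == traj.n_events
        assert t_end == pytest.approx(traj.times[-1])


class TestLimitingBehaviours:
    def test_no_input_only_dilution(self):
        """Without recombinase input the only activity is Z00 dilution."""
        net = build_network(TABLE_OPTIMUM, (False, False))
        traj = gillespie_run(net, SSAConfig(seed=3))
        others = [i for i in range(len(SPECIES)) if i != Z["Z00"]]
        assert np.all(traj.states[:, others] == 0)
        z00 = traj.states[:, Z["Z00"]]
        assert np.all(np.diff(z00) == -1)
        # 1000 copies can sustain at most 1000 dilution events
        assert traj.n_events <= 1000

    def test_expression_only_growth(self):
        tiny = 1e-30  # parameters must be positive; effectively off
        p = ParameterSet(
            k1c=tiny, k2c=tiny, k1f=tiny, k2f=tiny, k_1c=tiny, k_2c=tiny,
            k_1f=tiny, k_2f=tiny, alpha=1.0, beta_p=tiny, delta_D=tiny,
            delta_X=tiny,
        )
        net = build_network(p, (True, True))
        traj = gillespie_run(net, SSAConfig(seed=4, max_reactions=500))
        assert np.all(np.diff(traj.states[:, Z["C"]]) >= 0)
        assert np.all(np.diff(traj.states[:, Z["F"]]) >= 0)
        assert np.all(traj.states[:, Z["Z00"]] == 1000)

    def test_max_time_guard_stops_early(self):
        net = build_network(TABLE_OPTIMUM, (True, True))
        traj = gillespie_run(net, SSAConfig(seed=6, max_time=100.0))
        assert traj.times[-1] <= 100.0
        assert traj.n_events < 10000


class TestConservation:
    @pytest.mark.parametrize("draw", range(12))
    def test_address_dna_only_lost_to_dilution(self, draw):
        """Across random rate constants spanning the full search box, total
        address DNA never increases, decreases only via Z00 dilution, and
        no count ever goes negative."""
        rng = np.random.default_rng(1000 + draw)
        params = random_params(rng)
        cond = (bool(rng.integers(2)), bool(rng.integers(2)))
        net = build_network(params, cond)
        traj = gillespie_run(net, SSAConfig(seed=int(rng.integers(2**31)), max_reactions=2000))
        assert np.all(traj.states >= 0)
        addr = traj.states[:, list(ADDRESS_IDX)].sum(axis=1)
        diffs = np.diff(addr)
        assert np.all(np.isin(diffs, [0, -1]))
        dilution_delta = np.zeros(len(SPECIES), dtype=np.int64)
        dilution_delta[Z["Z00"]] = -1
        for k in np.where(diffs == -1)[0]:
            assert np.array_equal(traj.states[k + 1] - traj.states[k], dilution_delta)

    def test_excision_pairs_circle_with_address(self):
        """Each excision event that creates a Z10 also creates one Z10X."""
        net = build_network(TABLE_OPTIMUM, (True, False))
        traj = gillespie_run(net, SSAConfig(seed=8, max_reactions=3000))
        d = np.diff(traj.states, axis=0)
        gained_z10 = d[:, Z["Z10"]] == 1
        came_from_z00 = d[:, Z["Z00"]] == -1
        forward = gained_z10 & came_from_z00
        assert forward.any()
        assert np.all(d[forward, Z["Z10X"]] == 1)


class TestOccupancy:
    def _traj(self, **counts):
        x = np.zeros(len(SPECIES), dtype=np.int64)
        for k, v in counts.items():
            x[Z[k]] = v
        return Trajectory(times=np.array([0.0]), states=x[None, :])

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (dict(Z00=1000), (1, 0, 0, 0)),
            (dict(Z00=250, Z10=250, Z01=250, Z11=250), (0.25, 0.25, 0.25, 0.25)),
            (dict(Z00=10, Z11=990), (0.01, 0, 0, 0.99)),
        ],
    )
    def test_fractions(self, counts, expected):
        assert final_occupancy(self._traj(**counts)) == pytest.approx(expected)

    def test_empty_population_rejected(self):
        with pytest.raises(EmptyPopulationError):
            final_occupancy(self._traj(C=5))

    def test_extinct_state_maps_to_pure_z00(self):
        # DNA can only leave via Z00 dilution, so extinction implies the
        # pre-extinction population was pure Z00
        assert occupancy_from_state(np.zeros(10, dtype=np.int64)) == pytest.approx(
            [1, 0, 0, 0]
        )


def test_config_validation():
    with pytest.raises(ValueError):
        SSAConfig(initial_state=np.array([-1] * 10))
    with pytest.raises(ValueError):
        SSAConfig(max_reactions=0)
    assert default_initial_state(500)[Z["Z00"]] == 500
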