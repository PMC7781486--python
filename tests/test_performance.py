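import numpy as np
import pytest

from bladesim.circuits import CircuitDesign, DATA_FIT_CIRCUITS, Gene, enumerate_circuits
from bladesim.model import TABLE_OPTIMUM, ParameterSet
from bladesim.performance import (
    cohort_scores,
    occupancy_to_output,
    ratio_scan,
    simulate_circuit,
)
from bladesim.ssa import SSAConfig

UNIFORM_GFP = CircuitDesign((Gene.GFP,) * 4)


class TestOutputMapping:
    def test_reporter_percentages_from_occupancy(self):
        circuit = CircuitDesign((Gene.GFP_MCHERRY, Gene.GFP, Gene.STOP, Gene.MCHERRY))
        occ = np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.2, 0.8, 0.0, 0.0],
            [0.5, 0.0, 0.5, 0.0],
            [0.0, 0.0, 0.1, 0.9],
        ])
        out = occupancy_to_output(occ, circuit)
        # input 00: all DNA at Z00 (GFPmCherry) -> both reporters 100
        # input 10: GFP from Z00+Z10 = 100, mCherry only from Z00 = 20
        # input 01: Z01 is STOP -> only the Z00 residue fluoresces
        # input 11: Z11 is mCherry-only
        assert out == pytest.approx([100, 100, 100, 20, 50, 50, 0, 90])

    def test_percentages_bounded_for_any_occupancy(self):
        rng = np.random.default_rng(0)
        for circuit in enumerate_circuits()[::31]:
            occ = rng.dirichlet(np.ones(4), size=4)
            out = occupancy_to_output(occ, circuit)
            assert np.all(out >= 0) and np.all(out <= 100 + 1e-9)


class TestSimulateCircuit:
    def test_uniform_circuit_is_perfect(self):
        """A circuit with the same single-reporter gene everywhere scores 0
        regardless of the dynamics: occupancies always sum to 1."""
        res = simulate_circuit(UNIFORM_GFP, TABLE_OPTIMUM, ensemble_size=4, seed=0)
        assert res.mean_theta_bar == pytest.approx(0.0, abs=1e-9)
        assert res.output_vector == pytest.approx([100, 0] * 4)

    def test_fast_kinetics_near_ideal(self):
        """With fast excision, negligible back-reaction and no dilution,
        every input drives its target address to occupancy ~1."""
        p = ParameterSet(
            k1c=1.0, k2c=1.0, k1f=1.0, k2f=1.0,
            k_1c=1e-9, k_2c=1e-9, k_1f=1e-9, k_2f=1e-9,
            alpha=10.0, beta_p=1e-9, delta_D=1e-12, delta_X=1.0,
        )
        res = simulate_circuit(
            DATA_FIT_CIRCUITS[0], p, ensemble_size=10, seed=1,
            ssa_config=SSAConfig(max_reactions=100000),
        )
        assert res.mean_theta_bar < 0.3

    def test_reproducible_under_seed(self):
        a = simulate_circuit(DATA_FIT_CIRCUITS[0], TABLE_OPTIMUM, ensemble_size=3, seed=9)
        b = simulate_circuit(DATA_FIT_CIRCUITS[0], TABLE_OPTIMUM, ensemble_size=3, seed=9)
        assert np.array_equal(a.theta_bar_runs, b.theta_bar_runs)

    def test_trivial_circuit_rejected(self):
        with pytest.raises(ValueError):
            simulate_circuit(CircuitDesign((Gene.STOP,) * 4), TABLE_OPTIMUM)


@pytest.fixture(scope="module")
def small_cohort():
    circuits = enumerate_circuits()[::16]  # 16 designs across the space
    return cohort_scores(circuits, TABLE_OPTIMUM, ensemble_size=4, seed=2)


class TestCohort:
    def test_partition_is_exhaustive(self, small_cohort):
        df = small_cohort.scores
        assert len(small_cohort.poor_ids) + (~df.is_poor).sum() == len(df)
        assert (df.loc[df.is_poor, "mean_theta_bar"]
                > small_cohort.mu + small_cohort.sigma).all()

    def test_compositions_sum_to_100(self, small_cohort):
        assert sum(small_cohort.poor_composition.values()) == pytest.approx(100.0)
        assert sum(small_cohort.nonpoor_composition.values()) == pytest.approx(100.0)

    def test_trivial_circuit_rejected(self):
        with pytest.raises(ValueError):
            cohort_scores(
                [CircuitDesign((Gene.STOP,) * 4)], TABLE_OPTIMUM, ensemble_size=1
            )

    def test_independent_master_seeds_agree_statistically(self):
        """Two cohort runs with different master seeds give means within
        twice the between-circuit spread over sqrt(n)."""
        circuits = enumerate_circuits()[::16]
        a = cohort_scores(circuits, TABLE_OPTIMUM, ensemble_size=4, seed=21)
        b = cohort_scores(circuits, TABLE_OPTIMUM, ensemble_size=4, seed=22)
        tol = 2 * max(a.sigma, b.sigma) / np.sqrt(len(circuits))
        assert abs(a.mu - b.mu) < max(tol, 0.05)


class TestRatioScan:
    def test_unit_scale_reproduces_base_ensemble(self):
        scan = ratio_scan([DATA_FIT_CIRCUITS[0]], TABLE_OPTIMUM, scales=(1.0,),
                          ensemble_size=4, seed=3)
        base = simulate_circuit(DATA_FIT_CIRCUITS[0], TABLE_OPTIMUM,
                                ensemble_size=4, seed=3)
        assert scan.mean_theta_bar.iloc[0] == pytest.approx(base.mean_theta_bar)

    def test_scan_shape_and_columns(self):
        scan = ratio_scan(list(DATA_FIT_CIRCUITS), TABLE_OPTIMUM,
                          scales=(1.0, 0.5), ensemble_size=2, seed=4)
        assert len(scan) == 4
        assert set(scan.columns) >= {"circuit_id", "alpha_scale", "mean_theta_bar"}

    def test_bad_scales_rejected(self):
        with pytest.raises(ValueError):
            ratio_scan([DATA_FIT_CIRCUITS[0]], TABLE_OPTIMUM, scales=(0.0, 2.0))

    def test_fixed_time_horizon_scan_degrades_with_dose(self):
        """Comparing doses at a fixed simulated-time horizon (rather than a
        fixed event budget), lower recombinase expression leaves conversion
        less complete and the score degrades monotonically."""
        cfg = SSAConfig(max_reactions=10**6, max_time=1700.0)
        scan = ratio_scan(list(DATA_FIT_CIRCUITS), TABLE_OPTIMUM,
                          scales=(1.0, 0.5, 0.1, 0.05), ssa_config=cfg,
                          ensemble_size=10, seed=5)
        for _, grp in scan.groupby("circuit_id"):
            vals = grp.sort_values("alpha_scale", ascending=False).mean_theta_bar.to_numpy()
            assert np.all(np.diff(vals) >= -1e-9)
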