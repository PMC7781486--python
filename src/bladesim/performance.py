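"""Circuit performance from stochastic ensembles.

For one circuit, an ensemble run simulates the network under each of
the four input conditions, converts final address occupancies to an
8-dimensional "% cells ON" vector and scores each run with the adapted
angular metric; a cohort analysis aggregates those scores over many
circuits, flags poor performers (θ̄ > μ + σ) and compares the gene
composition of the poor and non-poor sets.

"% cells ON" convention: each of the 1000 initial DNA copies stands
for one cell.  The percentage of cells ON for a reporter under a given
input is 100 times the fraction of surviving platform copies residing
in addresses whose gene expresses that reporter.  A run whose DNA pool
goes extinct (possible only under the no-input condition, where Z00
dilution is the sole active reaction) is scored with the composition
immediately before extinction, which is pure Z00.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import ADDRESS_NAMES, CircuitDesign, Gene, ideal_vector
from .metrics import adapted_metric, angular_metric
from .model import ParameterSet, build_network
from .ssa import SSAConfig, gillespie_final, occupancy_from_state

__all__ = [
    "EnsembleResult",
    "CohortSummary",
    "INPUT_CONDITIONS",
    "simulate_circuit",
    "cohort_scores",
    "ratio_scan",
]

#: (Cre, Flp) input conditions in truth-table order, matching the
#: address order Z00, Z10, Z01, Z11.
INPUT_CONDITIONS = ((False, False), (True, False), (False, True), (True, True))


@dataclass(frozen=True)
class EnsembleResult:
    """Scores of one circuit over an ensemble of stochastic runs."""

    circuit: CircuitDesign
    mean_occupancy: np.ndarray  # (4 inputs, 4 addresses) mean fractions
    output_vector: np.ndarray  # ensemble-mean 8-entry % cells ON
    theta_bar_runs: np.ndarray  # per-run adapted metric, degrees
    mean_theta_bar: float
    std_theta_bar: float

    @property
    def ensemble_size(self) -> int:
        return len(self.theta_bar_runs)


@dataclass(frozen=True)
class CohortSummary:
    """Population-level view of many circuits' ensemble scores."""

    scores: pd.DataFrame  # circuit_id, genes, mean/std theta_bar, is_poor
    mu: float  # cohort mean of per-circuit mean θ̄, degrees
    sigma: float  # cohort std, degrees
    poor_composition: dict[str, float]  # gene -> % of addresses, poor set
    nonpoor_composition: dict[str, float]

    @property
    def poor_ids(self) -> list[int]:
        return self.scores.loc[self.scores.is_poor, "circuit_id"].tolist()


def _run_seeds(master_seed: int, circuit_id: int, ensemble_size: int) -> np.ndarray:
    """Per-(input, run) child seeds, independent of everything but
    (master seed, circuit id), so dose scans reuse the same noise."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(circuit_id)))
    return ss.generate_state(4 * ensemble_size, dtype=np.uint32).reshape(4, ensemble_size)


def _ensemble_vectors(
    params: ParameterSet,
    seeds: np.ndarray,
    ssa_config: SSAConfig,
    double_cre: str,
) -> np.ndarray:
    """Per-run (ensemble, 4 inputs, 4 addresses) occupancy fractions."""
    n_runs = seeds.shape[1]
    occ = np.empty((n_runs, 4, 4))
    for j, cond in enumerate(INPUT_CONDITIONS):
        net = build_network(params, cond, double_cre=double_cre)
        for r in range(n_runs):
            cfg = SSAConfig(
                initial_state=ssa_config.initial_state,
                max_reactions=ssa_config.max_reactions,
                max_time=ssa_config.max_time,
                seed=int(seeds[j, r]),
            )
            state, _, _ = gillespie_final(net, cfg)
            occ[r, j] = occupancy_from_state(state)
    return occ


def occupancy_to_output(occ_one_run: np.ndarray, circuit: CircuitDesign) -> np.ndarray:
    """Map a (4 inputs, 4 addresses) occupancy block to the 8-entry % cells ON."""
    gfp = np.array([g.expresses_gfp for g in circuit.addresses], dtype=float)
    mch = np.array([g.expresses_mcherry for g in circuit.addresses], dtype=float)
    out = np.empty(8)
    for j in range(4):
        out[2 * j] = 100.0 * occ_one_run[j] @ gfp
        out[2 * j + 1] = 100.0 * occ_one_run[j] @ mch
    return out


def simulate_circuit(
    circuit: CircuitDesign,
    params: ParameterSet,
    ssa_config: SSAConfig | None = None,
    ensemble_size: int = 100,
    seed: int = 0,
    double_cre: str = "linear",
) -> EnsembleResult:
    """Run a stochastic ensemble of one circuit and score it.

    Each run is scored individually (θ̄ per run, then averaged) rather
    than scoring the ensemble-mean vector once.
    """
    if circuit.is_trivial:
        raise ValueError("the all-STOP circuit cannot be scored (division by zero)")
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if ssa_config is None:
        ssa_config = SSAConfig()
    iv = ideal_vector(circuit)
    seeds = _run_seeds(seed, circuit.circuit_id, ensemble_size)
    occ = _ensemble_vectors(params, seeds, ssa_config, double_cre)
    vectors = np.array([occupancy_to_output(occ[r], circuit) for r in range(len(occ))])
    theta_bars = np.array(
        [adapted_metric(angular_metric(v, iv), iv.n_fluorescent) for v in vectors]
    )
    return EnsembleResult(
        circuit=circuit,
        mean_occupancy=occ.mean(axis=0),
        output_vector=vectors.mean(axis=0),
        theta_bar_runs=theta_bars,
        mean_theta_bar=float(theta_bars.mean()),
        std_theta_bar=float(theta_bars.std(ddof=0)),
    )


def _composition(circuits: list[CircuitDesign]) -> dict[str, float]:
    counts = {g.value: 0 for g in Gene}
    for c in circuits:
        for g in c.addresses:
            counts[g.value] += 1
    total = max(sum(counts.values()), 1)
    return {k: 100.0 * v / total for k, v in counts.items()}


def cohort_scores(
    circuits: list[CircuitDesign],
    params: ParameterSet,
    ssa_config: SSAConfig | None = None,
    ensemble_size: int = 100,
    seed: int = 0,
    double_cre: str = "linear",
) -> CohortSummary:
    """Score a cohort of circuits and partition it at θ̄ > μ + σ."""
    if any(c.is_trivial for c in circuits):
        raise ValueError("exclude the all-STOP circuit from cohorts")
    rows = []
    by_id: dict[int, CircuitDesign] = {}
    for c in circuits:
        res = simulate_circuit(
            c, params, ssa_config, ensemble_size=ensemble_size, seed=seed,
            double_cre=double_cre,
        )
        by_id[c.circuit_id] = c
        row = {
            "circuit_id": c.circuit_id,
            "mean_theta_bar": res.mean_theta_bar,
            "std_theta_bar": res.std_theta_bar,
        }
        for name, gene in zip(ADDRESS_NAMES, c.addresses):
            row[f"gene_{name}"] = gene.value
        for j, name in enumerate(ADDRESS_NAMES):
            row[f"occ_{name}"] = res.mean_occupancy[j, j]
        rows.append(row)
    df = pd.DataFrame(rows)
    mu = float(df.mean_theta_bar.mean())
    sigma = float(df.mean_theta_bar.std(ddof=0))
    df["is_poor"] = df.mean_theta_bar > mu + sigma
    poor = [by_id[i] for i in df.loc[df.is_poor, "circuit_id"]]
    nonpoor = [by_id[i] for i in df.loc[~df.is_poor, "circuit_id"]]
    return CohortSummary(
        scores=df,
        mu=mu,
        sigma=sigma,
        poor_composition=_composition(poor),
        nonpoor_composition=_composition(nonpoor),
    )


def ratio_scan(
    circuits: list[CircuitDesign],
    params: ParameterSet,
    scales: tuple[float, ...] = (1.0, 0.5, 0.1, 0.05),
    ssa_config: SSAConfig | None = None,
    ensemble_size: int = 100,
    seed: int = 0,
    double_cre: str = "linear",
) -> pd.DataFrame:
    """Re-score circuits with recombinase expression α scaled down.

    Models reporter:recombinase transfection ratios (1:scale) by
    multiplying α by each scale.  Seeds depend only on (seed, circuit),
    so scale=1 reproduces the unscaled ensemble exactly.
    """
    if not all(0 < s <= 1 for s in scales):
        raise ValueError("scales must lie in (0, 1]")
    rows = []
    for scale in scales:
        p = params.with_alpha_scale(scale)
        for c in circuits:
            res = simulate_circuit(
                c, p, ssa_config, ensemble_size=ensemble_size, seed=seed,
                double_cre=double_cre,
            )
            rows.append(
                {
                    "circuit_id": c.circuit_id,
                    "alpha_scale": scale,
                    "mean_theta_bar": res.mean_theta_bar,
                    "std_theta_bar": res.std_theta_bar,
                }
            )
    return pd.DataFrame(rows)
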