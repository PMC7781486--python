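"""Circuit performance metrics.

An observed circuit output is an 8-dimensional vector of "% cells ON"
(one (GFP, mCherry) pair per input condition).  Performance against the
ideal truth-table vector is scored with:

* the angular metric θ = arccos(v_e·v_i / |v_e||v_i|) in degrees, which
  is 0° when the observed vector is proportional to the ideal one and
  90° when orthogonal to it;
* the adapted angular metric θ̄ = θ / n, where n is the number of
  truth-table entries expected to fluoresce (the count of 100s in the
  ideal vector) — this stops circuits with many expected-ON outputs
  being penalised for spreading the same relative error over more
  entries;
* L1 errors: total = Σ|v_e − v_i| and average = total / 8, in
  percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import CircuitDesign, IdealVector, ideal_vector

__all__ = [
    "ScoreRecord",
    "UndefinedAngleError",
    "angular_metric",
    "adapted_metric",
    "l1_errors",
    "score_circuit",
]


class UndefinedAngleError(ValueError):
    """The angle to or from an all-zero vector is undefined.

    Raised for the trivial all-STOP circuit (ideal vector is all zero)
    or for a dead circuit whose observed vector is all zero.
    """


@dataclass(frozen=True)
class ScoreRecord:
    """Full score of one circuit's observed-vs-ideal comparison."""

    theta: float  # angular metric, degrees
    theta_bar: float  # adapted angular metric, degrees
    n: int  # expected fluorescent outputs (100s in the ideal vector)
    total_error: float  # Σ|v_e - v_i|, percentage points
    average_error: float  # total_error / 8


def _as8(v) -> np.ndarray:
    if isinstance(v, IdealVector):
        v = v.values
    arr = np.asarray(v, dtype=float)
    if arr.shape != (8,):
        raise ValueError(f"output vectors have exactly 8 entries, got shape {arr.shape}")
    return arr


def angular_metric(v_e, v_i) -> float:
    """Angle in degrees between observed and ideal output vectors.

    The cosine is clamped to [-1, 1] before arccos to guard against
    floating-point overshoot for near-parallel vectors.
    """
    a, b = _as8(v_e), _as8(v_i)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedAngleError("angle with an all-zero vector is undefined")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def adapted_metric(theta: float, n: int) -> float:
    """θ̄ = θ / n for n ≥ 1 expected fluorescent outputs."""
    if n < 1:
        raise ZeroDivisionError(
            "adapted metric undefined for n = 0 (all-STOP circuit)"
        )
    return theta / n


def l1_errors(v_e, v_i) -> tuple[float, float]:
    """Total and per-output absolute error in percentage points."""
    a, b = _as8(v_e), _as8(v_i)
    total = float(np.abs(a - b).sum())
    return total, total / 8.0


def score_circuit(v_e, circuit: CircuitDesign) -> ScoreRecord:
    """Score one observed output vector against its circuit's truth table."""
    if circuit.is_trivial:
        raise UndefinedAngleError(
            "the all-STOP circuit has an all-zero truth table and cannot be scored"
        )
    iv = ideal_vector(circuit)
    theta = angular_metric(v_e, iv)
    total, avg = l1_errors(v_e, iv)
    return ScoreRecord(
        theta=theta,
        theta_bar=adapted_metric(theta, iv.n_fluorescent),
        n=iv.n_fluorescent,
        total_error=total,
        average_error=avg,
    )
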