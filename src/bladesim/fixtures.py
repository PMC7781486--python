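"""Synthetic observed-output datasets.

Generates "% cells ON" vectors with the statistical structure of the
experimental BLADE screen: outputs that are expected to fluoresce are
drawn from a truncated normal with mean 66.09% and sd 13.86%, and
expected-silent outputs from one with mean 1.83% and sd 4.38%, both
truncated to [0, 100].

The stated moments are moments of the *generated data*, not of the
untruncated parent normal: the parent location and scale are solved so
that the truncated distribution itself has the requested mean and, where
attainable, the requested standard deviation.  (For the silent outputs
no truncated normal on [0, 100] can have sd/mean = 4.38/1.83 ≈ 2.4, so
only the mean is matched there; the skewed, zero-bounded shape is an
acknowledged approximation of the empirical distribution.)  Truncation
is done through the distribution, not by clipping, so no point mass
accumulates at the bounds.

This lets the scoring and cohort machinery be exercised end-to-end
without access to the original per-circuit dataset, whose values are
not public; it does not reproduce any real circuit's measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .circuits import CircuitDesign, ideal_vector

__all__ = ["FixtureSpec", "generate_observed", "observed_table"]


@dataclass(frozen=True)
class FixtureSpec:
    """Distribution parameters for synthetic observed outputs."""

    fluorescent_mean: float = 66.09
    fluorescent_std: float = 13.86
    silent_mean: float = 1.83
    silent_std: float = 4.38
    lower: float = 0.0
    upper: float = 100.0
    seed: int = 0


def _truncated(loc: float, scale: float, lo: float, hi: float):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm(a, b, loc=loc, scale=scale)


def _match_moments(mean: float, std: float, lo: float, hi: float):
    """Parent (loc, scale) whose [lo, hi]-truncation has the given moments.

    Falls back to matching the mean alone (scale fixed at ``std``) when
    the two-moment system has no solution in this family.
    """
    from scipy.optimize import brentq, fsolve

    def resid(x):
        loc, log_scale = x
        d = _truncated(loc, np.exp(log_scale), lo, hi)
        return [d.mean() - mean, d.std() - std]

    sol, info, ok, _ = fsolve(resid, x0=[mean, np.log(std)], full_output=True)
    if ok and np.max(np.abs(info["fvec"])) < 1e-6:
        return sol[0], float(np.exp(sol[1]))
    # mean-only fallback: truncated mean is monotone increasing in loc
    f = lambda loc: _truncated(loc, std, lo, hi).mean() - mean
    loc = brentq(f, lo - 100 * std, hi + 100 * std)
    return loc, std


def _sampler(mean: float, std: float, lo: float, hi: float):
    if std == 0.0:
        return lambda size, rng: np.full(size, mean)
    loc, scale = _match_moments(mean, std, lo, hi)
    dist = _truncated(loc, scale, lo, hi)
    return lambda size, rng: dist.rvs(size=size, random_state=rng)


def generate_observed(
    circuits: list[CircuitDesign], spec: FixtureSpec | None = None
) -> np.ndarray:
    """Synthetic observed vectors, one row of 8 entries per circuit.

    Entries that are 100 in a circuit's truth table are drawn from the
    fluorescent-output distribution, zero entries from the silent one.
    Deterministic for a given spec (seed included).
    """
    if spec is None:
        spec = FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    fluor = _sampler(spec.fluorescent_mean, spec.fluorescent_std, spec.lower, spec.upper)
    silent = _sampler(spec.silent_mean, spec.silent_std, spec.lower, spec.upper)
    out = np.empty((len(circuits), 8))
    for i, c in enumerate(circuits):
        mask = ideal_vector(c).as_array() == 100.0
        out[i, mask] = fluor(int(mask.sum()), rng)
        out[i, ~mask] = silent(int((~mask).sum()), rng)
    return out


def observed_table(
    circuits: list[CircuitDesign], spec: FixtureSpec | None = None
) -> pd.DataFrame:
    """Synthetic observations in the observed-table CSV schema."""
    obs = generate_observed(circuits, spec)
    df = pd.DataFrame({"circuit_id": [c.circuit_id for c in circuits]})
    for k in range(8):
        df[f"observed_v{k + 1}"] = obs[:, k]
    return df
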