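"""Deterministic rate equations of the simplified BLADE model.

Mass-action ODEs for the ten species, used as the mean-field reference
for the stochastic engine.  Note two deliberate asymmetries carried
over from the model definition: DNA dilution δ_D acts on Z00 only, and
the two-monomer Cre step enters the Cre balance with unit
stoichiometry (the rate equations are written per excision event, not
per monomer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import SPECIES, ParameterSet

__all__ = ["ode_rhs", "integrate", "ODESolution", "DEFAULT_HORIZON"]

#: Default horizon in seconds: the 48 h readout time of the experiments.
DEFAULT_HORIZON = 48 * 3600.0


def ode_rhs(
    state: np.ndarray,
    params: ParameterSet,
    input_condition: tuple[bool, bool],
) -> np.ndarray:
    """Time derivatives of (C, F, Z00, Z10, Z10X, Z01, Z01X, Z11, Z11Xc, Z11Xf).

    α is set to zero for any recombinase absent from the input condition.
    """
    C, F, Z00, Z10, Z10X, Z01, Z01X, Z11, Z11Xc, Z11Xf = state
    p = params
    a_c = p.alpha if input_condition[0] else 0.0
    a_f = p.alpha if input_condition[1] else 0.0

    dC = a_c - p.beta_p * C - p.k1c * Z00 * C + p.k_1c * Z10 * Z10X \
        - p.k2c * Z01 * C + p.k_2c * Z11 * Z11Xc
    dF = a_f - p.beta_p * F - p.k1f * Z00 * F + p.k_1f * Z01 * Z01X \
        - p.k2f * Z10 * F + p.k_2f * Z11 * Z11Xf
    dZ00 = p.k_1c * Z10 * Z10X - p.k1c * Z00 * C \
        + p.k_1f * Z01 * Z01X - p.k1f * Z00 * F - p.delta_D * Z00
    dZ10 = p.k1c * Z00 * C - p.k_1c * Z10 * Z10X \
        - p.k2f * Z10 * F + p.k_2f * Z11 * Z11Xf
    dZ10X = p.k1c * Z00 * C - p.k_1c * Z10 * Z10X - p.delta_X * Z10X
    dZ01 = p.k1f * Z00 * F - p.k_1f * Z01 * Z01X \
        - p.k2c * Z01 * C + p.k_2c * Z11 * Z11Xc
    dZ01X = p.k1f * Z00 * F - p.k_1f * Z01 * Z01X - p.delta_X * Z01X
    dZ11 = p.k2f * Z10 * F - p.k_2f * Z11 * Z11Xf \
        + p.k2c * Z01 * C - p.k_2c * Z11 * Z11Xc
    dZ11Xc = p.k2c * Z01 * C - p.k_2c * Z11 * Z11Xc - p.delta_X * Z11Xc
    dZ11Xf = p.k2f * Z10 * F - p.k_2f * Z11 * Z11Xf - p.delta_X * Z11Xf

    return np.array([dC, dF, dZ00, dZ10, dZ10X, dZ01, dZ01X, dZ11, dZ11Xc, dZ11Xf])


@dataclass(frozen=True)
class ODESolution:
    """Sampled deterministic trajectory."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 10)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]


class IntegrationError(RuntimeError):
    pass


def integrate(
    initial: np.ndarray,
    params: ParameterSet,
    input_condition: tuple[bool, bool],
    horizon: float = DEFAULT_HORIZON,
    n_samples: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> ODESolution:
    """Integrate the rate equations with a stiff-capable solver (LSODA).

    Tiny negative excursions within solver tolerance are clipped to
    zero with a warning; anything larger raises.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (len(SPECIES),):
        raise ValueError("initial state must have 10 entries")
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, params, input_condition),
        (0.0, horizon),
        y0,
        method="LSODA",
        t_eval=np.linspace(0.0, horizon, n_samples),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = sol.y.T
    if (states < 0).any():
        worst = states.min()
        if worst < -1e-6:
            raise IntegrationError(f"negative concentration {worst} beyond tolerance")
        import warnings

        warnings.warn("clipping tiny negative concentrations to 0", RuntimeWarning)
        states = np.clip(states, 0.0, None)
    return ODESolution(times=sol.t, states=states)
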