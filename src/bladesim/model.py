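"""The simplified 2-input BLADE reaction network.

Ten molecular species: the recombinases Cre (C) and Flp (F), the four
DNA addresses (Z00, Z10, Z01, Z11) and four excised-DNA circles (Z10X,
Z01X, Z11Xc, Z11Xf — the suffix records which recombinase cut the
circle out of the Z11-bound intermediates).

Seventeen mass-action reactions:

* 2 constitutive expression reactions (∅ → C, ∅ → F at rate α; an
  input condition switches each on or off),
* 2 protein degradation reactions (rate β_p),
* 4 forward excisions (Z00+2C→Z10+Z10X, Z00+F→Z01+Z01X,
  Z10+F→Z11+Z11Xf, Z01+C→Z11+Z11Xc),
* 4 reverse insertions, bimolecular in the address and its matching
  excised circle (e.g. Z10+Z10X→Z00+C),
* 4 excised-circle dilutions (rate δ_X) and 1 DNA dilution on Z00
  (rate δ_D).

The Z00→Z10 step lumps two Cre-mediated excisions, so it consumes two
Cre monomers per event; its propensity is nevertheless linear in C
(k1c·Z00·C) so that the stochastic model's mean field matches the
deterministic rate equations, with an optional combinatorial form
k1c·Z00·C(C−1)/2 for users who prefer strict two-body counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "SPECIES",
    "ParameterSet",
    "TABLE_OPTIMUM",
    "ReactionNetwork",
    "build_network",
]

#: Species names in canonical order (state-vector index = position here).
SPECIES = ("C", "F", "Z00", "Z10", "Z10X", "Z01", "Z01X", "Z11", "Z11Xc", "Z11Xf")

_I = {name: i for i, name in enumerate(SPECIES)}

#: Indices of the four DNA addresses within the state vector.
ADDRESS_IDX = (_I["Z00"], _I["Z10"], _I["Z01"], _I["Z11"])


@dataclass(frozen=True)
class ParameterSet:
    """The 11 rate parameters of the simplified model.

    ``k1c``/``k2c`` and ``k1f``/``k2f`` are the forward excision rate
    constants of the first and second Cre- and Flp-mediated events;
    ``k_1c`` etc. are the corresponding reverse (insertion) constants.
    ``alpha`` is the constitutive expression rate of both recombinases,
    ``beta_p`` protein degradation, ``delta_D`` dilution of address DNA
    (acting on Z00) and ``delta_X`` dilution of excised circles.  Units
    follow mass-action kinetics with molecule counts: per-second for
    first-order constants, per-molecule per-second for second-order,
    molecules per second for ``alpha``.
    """

    k1c: float
    k2c: float
    k1f: float
    k2f: float
    k_1c: float
    k_2c: float
    k_1f: float
    k_2f: float
    alpha: float
    beta_p: float
    delta_D: float
    delta_X: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")

    def with_alpha_scale(self, scale: float) -> "ParameterSet":
        """Copy with α multiplied by ``scale`` (recombinase dose scan)."""
        return replace(self, alpha=self.alpha * scale)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Calibrated optimum of the genetic-algorithm fit.
TABLE_OPTIMUM = ParameterSet(
    k1c=4.20e-5,
    k2c=4.20e-5,
    k1f=2.64e-5,
    k2f=2.64e-5,
    k_1c=8.15e-5,
    k_2c=8.15e-5,
    k_1f=8.15e-5,
    k_2f=8.15e-5,
    alpha=6.29e-1,
    beta_p=1.69e-3,
    delta_D=1.66e-4,
    delta_X=3.31e-3,
)


@dataclass(frozen=True)
class ReactionNetwork:
    """Stoichiometry and propensity data for the 17-reaction system.

    Propensity of reaction j at state x:
    ``rate[j] * f(x[r1[j]]) * x[r2[j]]`` where f is the identity unless
    ``comb2[j]`` (then ``x*(x-1)/2``), with indices of -1 contributing a
    factor 1.  ``guard_sp[j]/guard_min[j]`` additionally zero the
    propensity unless species ``guard_sp`` has at least ``guard_min``
    copies (used by the two-monomer Cre excision).
    """

    names: tuple[str, ...]
    rates: np.ndarray  # float64[17]
    r1: np.ndarray  # int64[17], first propensity species (-1 = none)
    r2: np.ndarray  # int64[17], second propensity species (-1 = none)
    comb2: np.ndarray  # bool[17], use x*(x-1)/2 on r1
    guard_sp: np.ndarray  # int64[17], -1 = no guard
    guard_min: np.ndarray  # int64[17]
    stoich: np.ndarray  # int64[17, 10], net change per firing
    input_condition: tuple[bool, bool]

    @property
    def n_reactions(self) -> int:
        return len(self.names)

    @property
    def n_species(self) -> int:
        return len(SPECIES)


def build_network(
    params: ParameterSet,
    input_condition: tuple[bool, bool],
    double_cre: str = "linear",
) -> ReactionNetwork:
    """Assemble the 17-reaction network for one (Cre, Flp) input condition.

    ``double_cre`` selects the treatment of the two-monomer Z00→Z10
    excision: ``"linear"`` (propensity k1c·Z00·C, two monomers consumed,
    default), ``"combinatorial"`` (propensity k1c·Z00·C(C−1)/2, two
    consumed) or ``"single"`` (propensity k1c·Z00·C, one monomer
    consumed — the stoichiometry of the printed rate equations, used as
    the mean-field-exact reference in cross-validation against the ODE
    solver).
    """
    if double_cre not in ("linear", "combinatorial", "single"):
        raise ValueError("double_cre must be 'linear', 'combinatorial' or 'single'")
    cre_on, flp_on = input_condition
    p = params
    n = len(SPECIES)

    names: list[str] = []
    rates: list[float] = []
    r1: list[int] = []
    r2: list[int] = []
    comb2: list[bool] = []
    guard_sp: list[int] = []
    guard_min: list[int] = []
    stoich: list[np.ndarray] = []

    def rxn(name, rate, a=-1, b=-1, comb=False, gsp=-1, gmin=0, **delta):
        names.append(name)
        rates.append(rate)
        r1.append(a)
        r2.append(b)
        comb2.append(comb)
        guard_sp.append(gsp)
        guard_min.append(gmin)
        s = np.zeros(n, dtype=np.int64)
        for sp, d in delta.items():
            s[_I[sp]] += d
        stoich.append(s)

    # expression (zeroed when the recombinase is not supplied as input)
    rxn("expression_C", p.alpha if cre_on else 0.0, C=+1)
    rxn("expression_F", p.alpha if flp_on else 0.0, F=+1)
    # protein degradation
    rxn("degradation_C", p.beta_p, a=_I["C"], C=-1)
    rxn("degradation_F", p.beta_p, a=_I["F"], F=-1)
    # forward excisions; Z00->Z10 consumes two Cre monomers (one in
    # "single" reference mode)
    n_cre = 1 if double_cre == "single" else 2
    rxn(
        "excision_Z00_Z10",
        p.k1c,
        a=_I["C"],
        b=_I["Z00"],
        comb=(double_cre == "combinatorial"),
        gsp=_I["C"],
        gmin=n_cre,
        Z00=-1,
        C=-n_cre,
        Z10=+1,
        Z10X=+1,
    )
    rxn("excision_Z00_Z01", p.k1f, a=_I["F"], b=_I["Z00"], Z00=-1, F=-1, Z01=+1, Z01X=+1)
    rxn("excision_Z10_Z11", p.k2f, a=_I["F"], b=_I["Z10"], Z10=-1, F=-1, Z11=+1, Z11Xf=+1)
    rxn("excision_Z01_Z11", p.k2c, a=_I["C"], b=_I["Z01"], Z01=-1, C=-1, Z11=+1, Z11Xc=+1)
    # reverse insertions (one monomer released, mirroring the rate equations)
    rxn("insertion_Z10_Z00", p.k_1c, a=_I["Z10"], b=_I["Z10X"], Z10=-1, Z10X=-1, Z00=+1, C=+1)
    rxn("insertion_Z01_Z00", p.k_1f, a=_I["Z01"], b=_I["Z01X"], Z01=-1, Z01X=-1, Z00=+1, F=+1)
    rxn("insertion_Z11_Z10", p.k_2f, a=_I["Z11"], b=_I["Z11Xf"], Z11=-1, Z11Xf=-1, Z10=+1, F=+1)
    rxn("insertion_Z11_Z01", p.k_2c, a=_I["Z11"], b=_I["Z11Xc"], Z11=-1, Z11Xc=-1, Z01=+1, C=+1)
    # dilution of excised circles and of Z00 DNA
    rxn("dilution_Z10X", p.delta_X, a=_I["Z10X"], Z10X=-1)
    rxn("dilution_Z01X", p.delta_X, a=_I["Z01X"], Z01X=-1)
    rxn("dilution_Z11Xc", p.delta_X, a=_I["Z11Xc"], Z11Xc=-1)
    rxn("dilution_Z11Xf", p.delta_X, a=_I["Z11Xf"], Z11Xf=-1)
    rxn("dilution_Z00", p.delta_D, a=_I["Z00"], Z00=-1)

    assert len(names) == 17
    return ReactionNetwork(
        names=tuple(names),
        rates=np.asarray(rates, dtype=np.float64),
        r1=np.asarray(r1, dtype=np.int64),
        r2=np.asarray(r2, dtype=np.int64),
        comb2=np.asarray(comb2, dtype=np.bool_),
        guard_sp=np.asarray(guard_sp, dtype=np.int64),
        guard_min=np.asarray(guard_min, dtype=np.int64),
        stoich=np.vstack(stoich),
        input_condition=(bool(cre_on), bool(flp_on)),
    )
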