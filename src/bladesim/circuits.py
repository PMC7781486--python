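"""BLADE circuit designs and their ideal truth-table outputs.

A 2-input BLADE cassette has four DNA addresses (Z00, Z10, Z01, Z11),
one of which is transcriptionally active under each combination of the
Cre and Flp inputs: Z00 with no input, Z10 with Cre only, Z01 with Flp
only, Z11 with both.  Each address carries one of four genes — a STOP
sequence, GFP, mCherry, or a GFP-mCherry fusion cassette — so there are
4^4 = 256 possible circuits.

A circuit's ideal behaviour is its truth table expressed as an
8-dimensional "% cells ON" vector: for each input condition in the
order (no input, Cre, Flp, Cre+Flp), a (GFP, mCherry) percentage pair
that is 100 where the active address's gene expresses that reporter and
0 elsewhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "CircuitDesign",
    "IdealVector",
    "ADDRESS_NAMES",
    "ideal_vector",
    "enumerate_circuits",
    "circuit_table",
]

#: DNA address names in input order: (Cre, Flp) = (0,0), (1,0), (0,1), (1,1).
ADDRESS_NAMES = ("Z00", "Z10", "Z01", "Z11")


class Gene(Enum):
    """One of the four genes a BLADE address can carry."""

    STOP = "STOP"
    GFP = "GFP"
    MCHERRY = "mCherry"
    GFP_MCHERRY = "GFPmCherry"

    @property
    def expresses_gfp(self) -> bool:
        return self in (Gene.GFP, Gene.GFP_MCHERRY)

    @property
    def expresses_mcherry(self) -> bool:
        return self in (Gene.MCHERRY, Gene.GFP_MCHERRY)


#: Canonical gene ordering used for enumeration (base-4 digit values).
GENE_ORDER = (Gene.STOP, Gene.GFP, Gene.MCHERRY, Gene.GFP_MCHERRY)


@dataclass(frozen=True)
class CircuitDesign:
    """An ordered assignment of one gene to each of the four addresses.

    ``addresses`` is the 4-tuple of genes at (Z00, Z10, Z01, Z11).
    """

    addresses: tuple[Gene, Gene, Gene, Gene]

    def __post_init__(self) -> None:
        if len(self.addresses) != 4:
            raise ValueError("a circuit assigns genes to exactly 4 addresses")
        if not all(isinstance(g, Gene) for g in self.addresses):
            raise TypeError("addresses must be Gene members")

    @classmethod
    def from_labels(cls, labels) -> "CircuitDesign":
        """Build a design from 4 gene labels, e.g. ``["GFPmCherry","GFP","STOP","GFP"]``."""
        lut = {g.value.lower(): g for g in Gene}
        lut.update({g.name.lower(): g for g in Gene})
        return cls(tuple(lut[str(s).lower()] for s in labels))

    @property
    def is_trivial(self) -> bool:
        """True for the all-STOP circuit, which prescribes no function."""
        return all(g is Gene.STOP for g in self.addresses)

    @property
    def circuit_id(self) -> int:
        """Base-4 index with digit order (Z00, Z10, Z01, Z11), most significant first."""
        cid = 0
        for g in self.addresses:
            cid = cid * 4 + GENE_ORDER.index(g)
        return cid

    def labels(self) -> tuple[str, str, str, str]:
        return tuple(g.value for g in self.addresses)

    def __repr__(self) -> str:  # e.g. [GFPmCherry GFP STOP GFP]
        return "[" + " ".join(self.labels()) + "]"


@dataclass(frozen=True)
class IdealVector:
    """Truth-table output of a circuit as an 8-entry 0/100 vector.

    Entries are address-major with a (GFP, mCherry) pair per address:
    ``[GFP@Z00, mCh@Z00, GFP@Z10, mCh@Z10, GFP@Z01, mCh@Z01, GFP@Z11, mCh@Z11]``.
    ``n_fluorescent`` counts the 100-entries — the number of outputs
    expected to fluoresce, used by the adapted angular metric.
    """

    values: tuple[float, ...]
    n_fluorescent: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def ideal_vector(circuit: CircuitDesign) -> IdealVector:
    """Derive the ideal 8-dimensional "% cells ON" vector of a circuit.

    Under each input exactly one address is active; its gene determines
    which of the (GFP, mCherry) pair of entries are 100.
    """
    vals: list[float] = []
    for gene in circuit.addresses:
        vals.append(100.0 if gene.expresses_gfp else 0.0)
        vals.append(100.0 if gene.expresses_mcherry else 0.0)
    n = sum(1 for v in vals if v == 100.0)
    return IdealVector(tuple(vals), n)


def enumerate_circuits(include_trivial: bool = False) -> list[CircuitDesign]:
    """All 256 circuit designs (or 255 with the all-STOP circuit dropped).

    Enumeration is base-4 counting over (Z00, Z10, Z01, Z11) with gene
    digit order (STOP, GFP, mCherry, GFPmCherry), so IDs are stable.
    """
    designs = [
        CircuitDesign(combo) for combo in itertools.product(GENE_ORDER, repeat=4)
    ]
    if not include_trivial:
        designs = [d for d in designs if not d.is_trivial]
    return designs


#: The two circuits used to calibrate the model (full dynamic range in
#: equal measure): [GFPmCherry GFP STOP GFP] and [GFPmCherry STOP mCherry mCherry].
DATA_FIT_CIRCUITS = (
    CircuitDesign((Gene.GFP_MCHERRY, Gene.GFP, Gene.STOP, Gene.GFP)),
    CircuitDesign((Gene.GFP_MCHERRY, Gene.STOP, Gene.MCHERRY, Gene.MCHERRY)),
)


def circuit_table(circuits: list[CircuitDesign] | None = None) -> pd.DataFrame:
    """Tabulate designs with their ideal vectors (one column per entry)."""
    if circuits is None:
        circuits = enumerate_circuits()
    rows = []
    for c in circuits:
        iv = ideal_vector(c)
        row = {"circuit_id": c.circuit_id}
        for name, gene in zip(ADDRESS_NAMES, c.addresses):
            row[f"gene_{name}"] = gene.value
        for k, v in enumerate(iv.values, start=1):
            row[f"ideal_v{k}"] = v
        row["n_fluorescent"] = iv.n_fluorescent
        rows.append(row)
    return pd.DataFrame(rows)
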