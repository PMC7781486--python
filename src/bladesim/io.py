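"""Run configuration and tabular I/O.

CSV dialect everywhere: comma-separated, UTF-8, header row, ``.``
decimal; 8-entry vectors are stored one entry per column (``v1..v8``).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .circuits import CircuitDesign, enumerate_circuits
from .metrics import score_circuit
from .model import TABLE_OPTIMUM, ParameterSet

__all__ = ["RunConfig", "score_table", "setup_logging"]

logger = logging.getLogger("bladesim")


@dataclass(frozen=True)
class RunConfig:
    """Serializable settings for a simulation run."""

    params: dict = field(default_factory=lambda: TABLE_OPTIMUM.as_dict())
    max_reactions: int = 10000
    max_time: float | None = None
    initial_dna: int = 1000
    ensemble_size: int = 100
    circuits: str | list[int] = "nontrivial"  # "all" | "nontrivial" | explicit ids
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @property
    def parameter_set(self) -> ParameterSet:
        return ParameterSet(**self.params)

    def circuit_list(self) -> list[CircuitDesign]:
        if self.circuits == "all":
            return enumerate_circuits(include_trivial=True)
        if self.circuits == "nontrivial":
            return enumerate_circuits(include_trivial=False)
        by_id = {c.circuit_id: c for c in enumerate_circuits(include_trivial=True)}
        return [by_id[int(i)] for i in self.circuits]

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def score_table(observed: pd.DataFrame) -> pd.DataFrame:
    """Score observed vectors against each circuit's truth table.

    ``observed`` needs columns circuit_id, observed_v1..observed_v8.
    Raises ``ValueError`` naming the offending rows on malformed input.
    """
    cols = [f"observed_v{k}" for k in range(1, 9)]
    missing = [c for c in ["circuit_id", *cols] if c not in observed.columns]
    if missing:
        raise ValueError(f"observed table missing columns: {missing}")
    by_id = {c.circuit_id: c for c in enumerate_circuits(include_trivial=True)}
    bad = [
        int(row_idx)
        for row_idx, cid in observed.circuit_id.items()
        if int(cid) not in by_id
    ]
    if bad:
        raise ValueError(f"unknown circuit_id at rows {bad}")
    rows = []
    for _, row in observed.iterrows():
        circuit = by_id[int(row.circuit_id)]
        rec = score_circuit(row[cols].to_numpy(dtype=float), circuit)
        out = {"circuit_id": int(row.circuit_id)}
        out.update({c: float(row[c]) for c in cols})
        out.update(
            theta_deg=rec.theta,
            theta_bar_deg=rec.theta_bar,
            n=rec.n,
            total_error=rec.total_error,
            average_error=rec.average_error,
        )
        rows.append(out)
    return pd.DataFrame(rows)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
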