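"""Per-cell event tables for compensated donor / FRET / acceptor intensities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventTable", "EVENT_COLUMNS", "read_event_csv", "write_event_csv"]

EVENT_COLUMNS = [
    "sample_id",
    "mutant_id",
    "condition",
    "replicate",
    "donor_afu",
    "fret_afu",
    "acceptor_afu",
]


@dataclass
class EventTable:
    """Events of one acquired sample.

    donor/fret/acceptor are compensated intensities in AFU (donor = mTFP1,
    fret = sensitized emission, acceptor = Venus).  Debris, doublets and
    untransfected cells are assumed excluded upstream.  ``true_state`` is
    the generator's per-cell label ("soluble"/"aggregated"), present only
    for synthetic data.
    """

    sample_id: str
    mutant_id: str
    condition: str
    replicate: int
    donor: np.ndarray
    fret: np.ndarray
    acceptor: np.ndarray
    true_state: np.ndarray | None = None
    true_fraction_folded: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = self.donor.size
        if n == 0:
            raise ValueError(f"sample {self.sample_id!r}: empty event table")
        if self.fret.size != n or self.acceptor.size != n:
            raise ValueError("donor/fret/acceptor must have equal length")
        if np.any(self.donor <= 0):
            raise ValueError("donor intensities must be > 0")
        if np.any(self.fret < 0) or np.any(self.acceptor < 0):
            raise ValueError("fret and acceptor intensities must be >= 0")
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state)
            if self.true_state.size != n:
                raise ValueError("true_state length mismatch")

    def __len__(self) -> int:
        return self.donor.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "mutant_id": self.mutant_id,
                "condition": self.condition,
                "replicate": self.replicate,
                "donor_afu": self.donor,
                "fret_afu": self.fret,
                "acceptor_afu": self.acceptor,
            }
        )
        if self.true_state is not None:
            df["true_state"] = self.true_state
        return df


def _tables_from_frame(df: pd.DataFrame) -> list[EventTable]:
    tables = []
    for sid, g in df.groupby("sample_id", sort=True):
        tables.append(
            EventTable(
                sample_id=str(sid),
                mutant_id=str(g["mutant_id"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
                replicate=int(g["replicate"].iloc[0]),
                donor=g["donor_afu"].to_numpy(),
                fret=g["fret_afu"].to_numpy(),
                acceptor=g["acceptor_afu"].to_numpy(),
                true_state=g["true_state"].to_numpy() if "true_state" in g else None,
            )
        )
    return tables


def read_event_csv(path) -> list[EventTable]:
    """Read an event-table CSV (one row per cell) into per-sample tables."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV {path} missing columns: {missing}")
    return _tables_from_frame(df)


def write_event_csv(tables: list[EventTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )
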