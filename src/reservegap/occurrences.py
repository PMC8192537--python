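"""Occurrence point records and their CSV representation.

The on-disk format is a plain CSV with header ``species,x,y`` plus optional
``uncertainty_m`` and ``flags`` columns.  ``flags`` is a ``;``-separated set
of provenance markers (e.g. ``unidentified``); an empty ``uncertainty_m``
cell means the uncertainty is unknown, which is distinct from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

MANDATORY_COLUMNS = ("species", "x", "y")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced occurrence of one species."""

    species_id: str
    x: float
    y: float
    uncertainty_m: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"{self.species_id}: non-finite coordinates")
        if self.uncertainty_m is not None and self.uncertainty_m < 0:
            raise ValueError(f"{self.species_id}: negative coordinate uncertainty")
        object.__setattr__(self, "flags", frozenset(self.flags))


def read_occurrences(path: str) -> list[OccurrenceRecord]:
    """Read occurrence records from CSV.

    Raises ``ValueError`` on a missing mandatory column or an unparseable
    coordinate (the error names the offending row).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            x = float(getattr(row, "x"))
            y = float(getattr(row, "y"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 2}: unparseable coordinate") from exc
        unc_raw = getattr(row, "uncertainty_m", "") if "uncertainty_m" in df.columns else ""
        uncertainty = None
        if unc_raw not in ("", None):
            try:
                uncertainty = float(unc_raw)
            except ValueError as exc:
                raise ValueError(f"{path}: row {i + 2}: unparseable uncertainty_m") from exc
        flags_raw = getattr(row, "flags", "") if "flags" in df.columns else ""
        flags = frozenset(f for f in str(flags_raw).split(";") if f)
        records.append(
            OccurrenceRecord(
                species_id=str(getattr(row, "species")),
                x=x,
                y=y,
                uncertainty_m=uncertainty,
                flags=flags,
            )
        )
    return records


def write_occurrences(records: list[OccurrenceRecord], path: str) -> None:
    df = pd.DataFrame(
        {
            "species": [r.species_id for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "uncertainty_m": ["" if r.uncertainty_m is None else r.uncertainty_m for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
    df.to_csv(path, index=False)


def records_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    """Records as a DataFrame (uncertainty NaN when absent) for vector ops."""
    return pd.DataFrame(
        {
            "species": [r.species_id for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "uncertainty_m": [
                float("nan") if r.uncertainty_m is None else r.uncertainty_m for r in records
            ],
        }
    )
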