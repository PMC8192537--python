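"""Occurrence record cleaning and the minimum-occurrence species filter.

Filters mirror the standard coordinate-cleaning workflow for public
biodiversity databases and are applied in a fixed order so removal counts
are reproducible and attributable:

1. records unidentified at the species level (``unidentified`` flag);
2. records falling in the same grid cell as a known country centroid or a
   natural-history institution;
3. records with coordinate uncertainty above the threshold (default 1 km);
4. exact-coordinate duplicates within each species (first occurrence kept).

Records with *absent* uncertainty are retained: dropping them would empty
most real datasets, and unknown is not the same as too-coarse.

After cleaning, species are only modelled if they occupy at least
``min_unique`` distinct grid cells (default 15) — occurrence uniqueness is
counted at the pixel resolution, not at raw coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .grid import Grid
from .occurrences import OccurrenceRecord

logger = logging.getLogger(__name__)

UNIDENTIFIED_FLAG = "unidentified"

FILTER_ORDER = ("unidentified", "centroid_institution", "uncertainty", "duplicate")


@dataclass
class QCReport:
    """Bookkeeping for one QC pass: how many records each filter removed."""

    input_size: int = 0
    output_size: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    unique_cells_per_species: dict[str, int] = field(default_factory=dict)
    retained_species: list[str] = field(default_factory=list)

    def check(self) -> None:
        if sum(self.removed.values()) != self.input_size - self.output_size:
            raise AssertionError("QC removal counts do not sum to input - output")


def _cells_of_points(grid: Grid, points) -> set[tuple[int, int]]:
    cells = set()
    for x, y in points:
        c = grid.cell_of(x, y)
        if c is not None:
            cells.add(c)
    return cells


def clean_records(
    records: list[OccurrenceRecord],
    grid: Grid,
    known_centroids=(),
    known_institutions=(),
    uncertainty_max_m: float = 1000.0,
) -> tuple[list[OccurrenceRecord], QCReport]:
    """Apply the four record-level filters in order; returns cleaned records
    and an itemized :class:`QCReport`.

    "Located at" a centroid or institution means sharing its grid cell — the
    resolution-consistent reading of a point-radius match.  Duplicates are
    removed last so a duplicated erroneous record is counted under its error
    class, and within species only (the same coordinates for two different
    species is legitimate co-occurrence).
    """
    report = QCReport(input_size=len(records), removed={k: 0 for k in FILTER_ORDER})

    kept = []
    for r in records:
        if UNIDENTIFIED_FLAG in r.flags:
            report.removed["unidentified"] += 1
        else:
            kept.append(r)

    bad_cells = _cells_of_points(grid, known_centroids) | _cells_of_points(
        grid, known_institutions
    )
    kept2 = []
    for r in kept:
        if bad_cells and grid.cell_of(r.x, r.y) in bad_cells:
            report.removed["centroid_institution"] += 1
        else:
            kept2.append(r)

    kept3 = []
    for r in kept2:
        if r.uncertainty_m is not None and r.uncertainty_m > uncertainty_max_m:
            report.removed["uncertainty"] += 1
        else:
            kept3.append(r)

    seen: set[tuple[str, float, float]] = set()
    out = []
    for r in kept3:
        key = (r.species_id, r.x, r.y)
        if key in seen:
            report.removed["duplicate"] += 1
        else:
            seen.add(key)
            out.append(r)

    report.output_size = len(out)
    report.check()
    for name in FILTER_ORDER:
        logger.info("qc filter %-21s removed %d", name, report.removed[name])
    logger.info("qc: %d records in, %d out", report.input_size, report.output_size)
    return out, report


def filter_min_occurrences(
    records: list[OccurrenceRecord], grid: Grid, min_unique: int = 15
) -> tuple[list[str], QCReport]:
    """Species retained for modelling: those occupying >= ``min_unique``
    distinct grid cells.  A species with many records in one cell counts 1."""
    cells: dict[str, set[tuple[int, int]]] = {}
    for r in records:
        c = grid.cell_of(r.x, r.y)
        if c is not None:
            cells.setdefault(r.species_id, set()).add(c)
    counts = {sp: len(cc) for sp, cc in sorted(cells.items())}
    retained = [sp for sp, n in counts.items() if n >= min_unique]
    report = QCReport(
        input_size=len(counts),
        output_size=len(retained),
        removed={"below_min_unique": len(counts) - len(retained)},
        unique_cells_per_species=counts,
        retained_species=retained,
    )
    logger.info(
        "min-occurrence filter: %d of %d species retained (>= %d unique cells)",
        len(retained),
        len(counts),
        min_unique,
    )
    return retained, report


def subset_records(
    records: list[OccurrenceRecord], species: list[str]
) -> list[OccurrenceRecord]:
    keep = set(species)
    return [r for r in records if r.species_id in keep]
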