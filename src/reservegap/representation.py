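"""Range-size-scaled conservation targets, PA achievement and gap classes.

A species' conservation target is the fraction of its distribution area
that must fall inside the protected-area network for the species to count
as represented.  Targets scale inversely with range size: 80% for ranges at
or below 100 km² (the critically-endangered geographic-range threshold),
5% for ranges at or above 50,000 km², and loglinearly in between:

    target(A) = 0.80 - 0.75 * (log10 A - log10 100) / (log10 50000 - log10 100)

Achievement is the protected portion of the range divided by the target
area.  Species are classed as *represented* (achievement >= 1),
*underrepresented* (>= half the target but short of it) or *neglected*
(under half the target).  The percentage of species represented is the
network's extrinsic representativeness for the evaluated group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .grid import BinaryMask

CLASSES = ("represented", "underrepresented", "neglected")


@dataclass
class RepresentationRecord:
    species_id: str
    range_area: float  # km²
    target_fraction: float
    target_area: float  # km²
    protected_area_of_range: float  # km²
    achievement: float  # protected / target; may exceed 1
    achievement_class: str


def conservation_target(range_area_km2: float, config: RunConfig | None = None) -> float:
    """Target fraction of the range for a species with the given range area.

    Anchors are closed so the function is total: exactly 100 km² gives 0.80
    and exactly 50,000 km² gives 0.05.  The interpolation is linear in
    log10(area); the log base cancels.
    """
    cfg = config or RunConfig()
    if range_area_km2 <= 0:
        raise ValueError("range area must be positive")
    hi = cfg.target_pct_high / 100.0
    lo = cfg.target_pct_low / 100.0
    a0, a1 = cfg.target_area_low, cfg.target_area_high
    if range_area_km2 <= a0:
        return hi
    if range_area_km2 >= a1:
        return lo
    frac = (math.log10(range_area_km2) - math.log10(a0)) / (math.log10(a1) - math.log10(a0))
    return hi - (hi - lo) * frac


def classify(
    achievement: float, neglected_cut: float = 0.5, neglected_inclusive: bool = False
) -> str:
    """Achievement class.

    represented: achievement >= 1; neglected: achievement < cut (or <= cut
    when ``neglected_inclusive``, matching the alternative boundary
    convention); underrepresented otherwise.
    """
    if achievement < 0:
        raise ValueError("achievement must be non-negative")
    if achievement >= 1.0:
        return "represented"
    if achievement < neglected_cut or (neglected_inclusive and achievement == neglected_cut):
        return "neglected"
    return "underrepresented"


def achievement(
    species_id: str,
    species_range: BinaryMask,
    pa: BinaryMask,
    target_fraction: float,
    config: RunConfig | None = None,
) -> RepresentationRecord:
    """Evaluate one species' target achievement in the PA network."""
    cfg = config or RunConfig()
    species_range.grid.require_compatible(pa.grid)
    n_range = species_range.count()
    if n_range == 0:
        raise ValueError(f"{species_id}: empty range")
    cell_area = species_range.grid.cell_area
    range_area = n_range * cell_area
    protected = species_range.intersection_count(pa) * cell_area
    target_area = target_fraction * range_area
    ach = protected / target_area
    return RepresentationRecord(
        species_id=species_id,
        range_area=range_area,
        target_fraction=target_fraction,
        target_area=target_area,
        protected_area_of_range=protected,
        achievement=ach,
        achievement_class=classify(ach, cfg.neglected_cut, cfg.neglected_inclusive),
    )


def gap_analysis(
    ranges: dict[str, BinaryMask], pa: BinaryMask, config: RunConfig | None = None
) -> list[RepresentationRecord]:
    """Targets + achievement for every species range against one PA mask."""
    cfg = config or RunConfig()
    out = []
    for sp, rng in ranges.items():
        area = rng.count() * rng.grid.cell_area
        tf = conservation_target(area, cfg)
        out.append(achievement(sp, rng, pa, tf, cfg))
    return out


def extrinsic_representativeness(records: list[RepresentationRecord]) -> float:
    """Percent of species whose conservation target is fully achieved."""
    if not records:
        raise ValueError("no representation records")
    n_rep = sum(1 for r in records if r.achievement_class == "represented")
    return 100.0 * n_rep / len(records)


def class_fractions(records: list[RepresentationRecord]) -> dict[str, float]:
    """Percent of species per achievement class (sums to 100)."""
    if not records:
        raise ValueError("no representation records")
    return {
        c: 100.0 * sum(1 for r in records if r.achievement_class == c) / len(records)
        for c in CLASSES
    }


def records_to_frame(records: list[RepresentationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species_id for r in records],
            "range_area_km2": [r.range_area for r in records],
            "target_fraction": [r.target_fraction for r in records],
            "target_area_km2": [r.target_area for r in records],
            "protected_area_km2": [r.protected_area_of_range for r in records],
            "achievement": [r.achievement for r in records],
            "achievement_class": [r.achievement_class for r in records],
        }
    )
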