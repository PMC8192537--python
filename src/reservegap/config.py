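"""Run configuration: every tunable of the analysis with its default.

Defaults encode the standard workflow constants: species need >= 15 unique
occupied cells to be modelled; records with coordinate uncertainty above
1 km are dropped; predictors with VIF >= 10 are pruned; models are fitted
on a 70/30 presence split against 10,000 background points, 10 replicates
per technique, and ensembles with TSS <= 0.7 are discarded; conservation
targets scale loglinearly from 80% of range area (ranges <= 100 km²) down
to 5% (ranges >= 50,000 km²); species achieving under half their target are
classed as neglected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # occurrence QC
    min_occurrences: int = 15
    uncertainty_max_m: float = 1000.0
    # predictor screening
    vif_threshold: float = 10.0
    # SDM stage
    n_background: int = 10000
    train_fraction: float = 0.7
    n_replicates: int = 10
    tss_keep: float = 0.7
    decay_distance: float | None = None  # map units; default 10 cells, set at run time
    techniques: tuple[str, ...] = ("logistic", "envelope")
    # conservation targets
    target_area_low: float = 100.0  # km²; at or below -> target_pct_high
    target_area_high: float = 50000.0  # km²; at or above -> target_pct_low
    target_pct_high: float = 80.0
    target_pct_low: float = 5.0
    # achievement classification
    neglected_cut: float = 0.5
    neglected_inclusive: bool = False  # True: achievement == cut counts as neglected
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.target_area_low < self.target_area_high:
            raise ValueError("target_area_low must be below target_area_high")
        if not self.target_pct_low < self.target_pct_high:
            raise ValueError("target_pct_low must be below target_pct_high")
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be positive")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["techniques"] = list(self.techniques)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "techniques" in d:
            d["techniques"] = tuple(d["techniques"])
        return cls(**d)
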