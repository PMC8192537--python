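"""Synthetic landscapes, virtual species and protected-area networks.

Every downstream stage is tested against scenarios with known ground truth:

* predictors are smooth random fields (low-pass-filtered noise plus broad
  gradients), orthogonalized so their pairwise correlation is zero unless a
  designated pair is blended to a requested collinearity;
* a virtual species responds to the predictors through a product of
  Gaussian niche responses; its suitability is rescaled to [0, 1] and cells
  at or above the 0.5 occupancy threshold form the true range.  Niche
  breadths are calibrated by bisection so realized range areas follow a
  lognormal distribution spanning orders of magnitude, mirroring the
  strongly right-skewed range sizes of real faunas;
* occurrence samples are drawn from the true range proportional to
  suitability times an accessibility (sampling-bias) layer, then corrupted
  at controlled rates with the error types typical of public biodiversity
  databases: records at country centroids, records with coarse coordinate
  uncertainty, exact duplicates, and records unidentified to species;
* PA networks of controlled size are placed at random, biased toward
  "remote" (high-remoteness-field) cells, or constructed by running the
  reserve solver on a designated species subset, which gives prioritization
  a known perfect-specificity case.

Centroid coordinates are always placed in cells outside every species'
true range, so the QC stage's removal counts are exactly predictable.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RunConfig
from .grid import BinaryMask, Grid, Layer
from .occurrences import OccurrenceRecord, write_occurrences
from .raster import write_raster

PA_BIAS_MODES = ("random", "remote", "optimal-for-subset")


# --------------------------------------------------------------------------
# predictors
# --------------------------------------------------------------------------

def make_predictors(
    grid: Grid,
    n_vars: int,
    collinearity: float = 0.0,
    seed: int = 0,
    collinear_pairs: list[tuple[int, int]] | None = None,
    smoothness: float = 8.0,
) -> list[Layer]:
    """Smooth standardized random fields with controlled collinearity.

    Fields are Gaussian-filtered white noise plus a random linear gradient,
    orthogonalized over valid cells (pairwise r = 0) and scaled to unit
    variance.  For each designated pair (i, j) — default (0, 1) when
    ``collinearity`` > 0 — field j is replaced by
    ``r * field_i + sqrt(1 - r²) * field_j`` so its correlation with field i
    equals ``collinearity`` exactly on this landscape.
    """
    if n_vars < 2:
        raise ValueError("need at least two predictors")
    if not 0.0 <= collinearity < 1.0:
        raise ValueError("collinearity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    valid = ~grid.nodata_mask
    n_cells = int(valid.sum())
    if n_cells <= n_vars:
        raise ValueError("grid too small for the requested number of predictors")

    fields = []
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    for _ in range(n_vars):
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), smoothness)
        gx, gy = rng.standard_normal(2)
        gradient = (gx * cc / max(grid.n_cols - 1, 1)) + (gy * rr / max(grid.n_rows - 1, 1))
        f = noise / max(noise.std(), 1e-12) + 0.5 * gradient
        fields.append(f[valid])
    X = np.column_stack(fields)
    X = X - X.mean(axis=0)
    Q, R = np.linalg.qr(X)
    Q *= np.sign(np.diag(R))  # deterministic orientation
    X = Q / Q.std(axis=0)

    if collinearity > 0:
        pairs = collinear_pairs or [(0, 1)]
        r = collinearity
        for i, j in pairs:
            X[:, j] = r * X[:, i] + np.sqrt(1 - r * r) * X[:, j]

    layers = []
    for k in range(n_vars):
        vals = np.zeros(grid.shape)
        vals[valid] = X[:, k]
        layer = Layer(grid, vals)
        layer.values[~valid] = np.nan
        layers.append(layer)
    return layers


# --------------------------------------------------------------------------
# virtual species
# --------------------------------------------------------------------------

@dataclass
class VirtualSpecies:
    """A simulated species with known niche, suitability and range."""

    species_id: str
    niche_optimum: np.ndarray  # per-predictor optimum
    niche_breadth: np.ndarray  # per-predictor Gaussian sd (> 0)
    true_suitability: Layer
    true_range: BinaryMask
    true_range_area: float  # km²
    occupancy_threshold: float = 0.5


def _suitability_from_niche(
    predictors: list[Layer], optimum: np.ndarray, breadth: np.ndarray
) -> np.ndarray:
    grid = predictors[0].grid
    valid = ~grid.nodata_mask
    log_s = np.zeros(grid.shape)
    for k, layer in enumerate(predictors):
        z = (layer.values - optimum[k]) / breadth[k]
        log_s = log_s - 0.5 * np.where(valid, z * z, 0.0)
    s = np.exp(log_s)
    mx = s[valid].max()
    return np.where(valid, s / mx, 0.0)


def make_species(
    predictors: list[Layer],
    n_species: int,
    range_sigma: float = 1.5,
    range_median_fraction: float = 0.05,
    seed: int = 0,
    occupancy_threshold: float = 0.5,
    n_limiting: int | None = None,
) -> list[VirtualSpecies]:
    """Virtual species with lognormally distributed range sizes.

    Each species' niche optimum is the predictor vector at a random anchor
    cell (so peak suitability is 1 there).  ``n_limiting`` randomly chosen
    predictors act as the species' limiting variables (narrow breadth); the
    remaining responses are four times broader, reflecting that real niches
    are constrained by a few variables rather than all equally.  The common
    breadth scale is calibrated by bisection so the realized range area
    (suitability >= ``occupancy_threshold``) matches a lognormal draw with
    median ``range_median_fraction`` of the domain area and log-sd
    ``range_sigma``.  With ``range_sigma >= 1`` realized areas span at least
    two orders of magnitude across a few dozen species.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    grid = predictors[0].grid
    valid = ~grid.nodata_mask
    valid_cells = np.argwhere(valid)
    n_valid = len(valid_cells)
    rng = np.random.default_rng(seed)
    base_breadth = np.array([np.nanstd(p.values) for p in predictors])
    if np.any(base_breadth <= 0):
        raise ValueError("degenerate predictor (zero variance) gives zero niche breadth")
    domain_area = n_valid * grid.cell_area
    min_cells, max_cells = 3, int(0.5 * n_valid)

    out = []
    if n_limiting is None:
        n_limiting = len(predictors)
    n_limiting = int(np.clip(n_limiting, 1, len(predictors)))
    for i in range(n_species):
        anchor = valid_cells[rng.integers(n_valid)]
        optimum = np.array([p.values[anchor[0], anchor[1]] for p in predictors])
        if n_limiting == len(predictors):
            widths = np.ones(len(predictors))
        else:
            limiting = rng.choice(len(predictors), size=n_limiting, replace=False)
            widths = np.full(len(predictors), 4.0)
            widths[limiting] = 1.0
        target_area = range_median_fraction * domain_area * rng.lognormal(0.0, range_sigma)
        target_cells = int(np.clip(round(target_area / grid.cell_area), min_cells, max_cells))

        def realized_cells(scale: float) -> int:
            s = _suitability_from_niche(predictors, optimum, scale * widths * base_breadth)
            return int((s[valid] >= occupancy_threshold).sum())

        lo, hi = 1e-3, 1e3
        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if realized_cells(mid) < target_cells:
                lo = mid
            else:
                hi = mid
        scale = np.sqrt(lo * hi)
        breadth = scale * widths * base_breadth
        suit_vals = _suitability_from_niche(predictors, optimum, breadth)
        suit = Layer(grid, suit_vals)
        suit.values[~valid] = np.nan
        rng_mask = BinaryMask(grid, ((suit_vals >= occupancy_threshold) & valid).astype(np.uint8))
        out.append(
            VirtualSpecies(
                species_id=f"sp{i:03d}",
                niche_optimum=optimum,
                niche_breadth=breadth,
                true_suitability=suit,
                true_range=rng_mask,
                true_range_area=rng_mask.area_km2,
                occupancy_threshold=occupancy_threshold,
            )
        )
    return out


# --------------------------------------------------------------------------
# occurrence sampling with injected errors
# --------------------------------------------------------------------------

@dataclass
class ErrorRates:
    """Fractions of records corrupted per error type; the rest are clean."""

    centroid: float = 0.0
    high_uncertainty: float = 0.0
    duplicate: float = 0.0
    unidentified: float = 0.0

    def total(self) -> float:
        return self.centroid + self.high_uncertainty + self.duplicate + self.unidentified


def pick_centroids(
    species: list[VirtualSpecies], grid: Grid, k: int = 3, seed: int = 0
) -> list[tuple[float, float]]:
    """k "country centroid" coordinates in cells outside every true range,
    so centroid-error removal counts are exactly predictable."""
    occupied = np.zeros(grid.shape, dtype=bool)
    for sp in species:
        occupied |= sp.true_range.as_bool
    candidates = np.argwhere(~occupied & ~grid.nodata_mask)
    if len(candidates) < k:  # fall back to least-suitable cells
        total = np.zeros(grid.shape)
        for sp in species:
            total += np.nan_to_num(sp.true_suitability.values)
        flat = np.argsort(total[~grid.nodata_mask])[:k]
        candidates = np.argwhere(~grid.nodata_mask)[flat]
    rng = np.random.default_rng(seed)
    chosen = candidates[rng.choice(len(candidates), size=k, replace=False)]
    return [tuple(np.array(grid.cell_center(r, c), dtype=float)) for r, c in chosen]


def sample_occurrences(
    species: list[VirtualSpecies],
    n_per_species: int,
    bias_layer: Layer | None = None,
    error_rates: ErrorRates | None = None,
    seed: int = 0,
    centroids: list[tuple[float, float]] | None = None,
) -> tuple[list[OccurrenceRecord], pd.DataFrame]:
    """Occurrence records with known error labels.

    Clean records fall in cells of the species' true range with probability
    proportional to suitability x accessibility bias, jittered within the
    cell, with coordinate uncertainty <= 500 m.  Error records are injected
    at the given rates: placed at a centroid coordinate, given uncertainty
    above 1 km, duplicated from a clean record of the same species, or
    flagged ``unidentified``.  Returns the records and a truth table with
    one row per record (``error_type`` = clean/centroid/high_uncertainty/
    duplicate/unidentified).
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    rates = error_rates or ErrorRates()
    if rates.total() > 0.9:
        raise ValueError("error rates leave too few clean records")
    if rates.centroid > 0 and not centroids:
        raise ValueError("centroid errors requested but no centroid coordinates given")
    grid = species[0].true_range.grid
    rng = np.random.default_rng(seed)
    records: list[OccurrenceRecord] = []
    truth_rows = []

    kinds = ("clean", "centroid", "high_uncertainty", "duplicate", "unidentified")
    probs = np.array(
        [1 - rates.total(), rates.centroid, rates.high_uncertainty, rates.duplicate,
         rates.unidentified]
    )

    for sp in species:
        cells = np.argwhere(sp.true_range.as_bool)
        if len(cells) == 0:
            raise ValueError(f"{sp.species_id}: empty true range")
        w = sp.true_suitability.values[cells[:, 0], cells[:, 1]]
        if bias_layer is not None:
            b = bias_layer.values[cells[:, 0], cells[:, 1]]
            w = w * np.clip(b, 0.0, None)
        if w.sum() <= 0:
            w = np.ones(len(cells))
        w = w / w.sum()

        labels = rng.choice(len(kinds), size=n_per_species, p=probs)
        # ensure at least one clean record so duplicates have a source
        if (labels == 3).any() and not (labels == 0).any():
            labels[0] = 0
        # clean records first so every duplicate has an existing source
        labels = np.sort(labels)
        clean_coords: list[tuple[float, float]] = []

        def draw_clean() -> tuple[float, float]:
            c = cells[rng.choice(len(cells), p=w)]
            jx = (rng.random() - 0.5) * 0.98 * grid.dx
            jy = (rng.random() - 0.5) * 0.98 * grid.dy
            x, y = grid.cell_center(c[0], c[1])
            return float(x + jx), float(y + jy)

        for lab in labels:
            kind = kinds[lab]
            if kind == "clean":
                x, y = draw_clean()
                clean_coords.append((x, y))
                rec = OccurrenceRecord(sp.species_id, x, y, float(rng.uniform(0, 500)))
            elif kind == "centroid":
                x, y = centroids[rng.integers(len(centroids))]
                rec = OccurrenceRecord(sp.species_id, x, y, float(rng.uniform(0, 500)))
            elif kind == "high_uncertainty":
                x, y = draw_clean()
                rec = OccurrenceRecord(sp.species_id, x, y, float(rng.uniform(1001, 10000)))
            elif kind == "duplicate":
                if clean_coords:
                    x, y = clean_coords[rng.integers(len(clean_coords))]
                else:
                    x, y = draw_clean()
                rec = OccurrenceRecord(sp.species_id, x, y, float(rng.uniform(0, 500)))
            else:  # unidentified
                x, y = draw_clean()
                rec = OccurrenceRecord(
                    sp.species_id, x, y, float(rng.uniform(0, 500)),
                    flags=frozenset({"unidentified"}),
                )
            records.append(rec)
            truth_rows.append({"species": sp.species_id, "error_type": kind})

    truth = pd.DataFrame(truth_rows)
    truth.index.name = "record_index"
    return records, truth


def make_bias_layer(grid: Grid, strength: float = 1.0, seed: int = 0) -> Layer:
    """Accessibility field in (0, 1]: smooth lognormal-ish surface emulating
    road/museum sampling bias.  ``strength`` 0 gives a flat field."""
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 10.0)
    f = (f - f.mean()) / max(f.std(), 1e-12)
    vals = np.exp(strength * f)
    vals = vals / vals.max()
    layer = Layer(grid, np.where(~grid.nodata_mask, vals, 0.0))
    layer.values[grid.nodata_mask] = np.nan
    return layer


# --------------------------------------------------------------------------
# protected-area networks
# --------------------------------------------------------------------------

def make_pa_network(
    grid: Grid,
    coverage_fraction: float,
    bias_mode: str = "random",
    seed: int = 0,
    remoteness: Layer | None = None,
    species: list[VirtualSpecies] | None = None,
    config: RunConfig | None = None,
) -> BinaryMask:
    """PA mask covering ``coverage_fraction`` of valid cells.

    Modes: ``random`` (uniform placement), ``remote`` (placement weighted
    toward high values of a remoteness field, emulating the residual-land
    bias of real networks), ``optimal-for-subset`` (the exact reserve
    solution for the given species' true ranges, padded at random up to the
    requested coverage — never trimmed, so the designated subset keeps a
    perfect-specificity network by construction).
    """
    if not 0.0 < coverage_fraction < 1.0:
        raise ValueError("coverage_fraction must be in (0, 1)")
    if bias_mode not in PA_BIAS_MODES:
        raise ValueError(f"bias_mode must be one of {PA_BIAS_MODES}")
    valid_cells = np.argwhere(~grid.nodata_mask)
    n_valid = len(valid_cells)
    n_target = int(round(coverage_fraction * n_valid))
    if n_target < 1:
        raise ValueError("coverage_fraction selects no cells on this grid")
    rng = np.random.default_rng(seed)
    chosen = np.zeros(grid.shape, dtype=bool)

    if bias_mode == "random":
        idx = rng.choice(n_valid, size=n_target, replace=False)
        sel = valid_cells[idx]
        chosen[sel[:, 0], sel[:, 1]] = True
    elif bias_mode == "remote":
        if remoteness is None:
            f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 10.0)
            remoteness = Layer(grid, np.where(~grid.nodata_mask, f, 0.0))
            remoteness.values[grid.nodata_mask] = np.nan
        z = remoteness.values[valid_cells[:, 0], valid_cells[:, 1]]
        z = (z - np.nanmean(z)) / max(np.nanstd(z), 1e-12)
        # Gumbel top-k = weighted sampling without replacement
        keys = 2.0 * z + rng.gumbel(size=n_valid)
        sel = valid_cells[np.argsort(keys)[-n_target:]]
        chosen[sel[:, 0], sel[:, 1]] = True
    else:  # optimal-for-subset
        if not species:
            raise ValueError("optimal-for-subset needs a species subset")
        from .prioritize import build_problem, solve_exact

        ranges = {sp.species_id: sp.true_range for sp in species}
        empty_pa = BinaryMask(grid, np.zeros(grid.shape, dtype=np.uint8))
        problem = build_problem(ranges, empty_pa, mode="specificity", config=config)
        sol = solve_exact(problem)
        sel = problem.unit_cells[sol.selected]
        chosen[sel[:, 0], sel[:, 1]] = True
        deficit = n_target - int(chosen.sum())
        if deficit > 0:
            pool = np.flatnonzero(~chosen[valid_cells[:, 0], valid_cells[:, 1]])
            extra = valid_cells[rng.choice(pool, size=deficit, replace=False)]
            chosen[extra[:, 0], extra[:, 1]] = True

    return BinaryMask(grid, chosen.astype(np.uint8))


# --------------------------------------------------------------------------
# full scenarios
# --------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Generator settings for one synthetic study landscape.

    Defaults describe the standard test landscape: a 100x100 equal-area
    grid of 10-km cells (a country-scale domain of 10⁶ km², the coarsest
    resolution used in national gap analyses), eight orthogonal predictors,
    20 species with lognormal range sizes (median 12,500 km², log-sd 1.5,
    spanning both conservation-target anchors), 60 records per species
    under moderate sampling bias, error rates typical of raw aggregated
    occurrence data, and a random network protecting 15% of the land —
    between the national coverages of the networks this framework is aimed
    at.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_area: float = 100.0  # km² (10-km cells)
    n_vars: int = 8
    collinearity: float = 0.0
    predictor_smoothness: float = 4.0  # Gaussian filter sigma, cells
    n_species: int = 20
    range_sigma: float = 1.5
    range_median_fraction: float = 0.0125
    n_per_species: int = 60
    bias_strength: float = 1.0
    error_rates: ErrorRates = field(
        default_factory=lambda: ErrorRates(
            centroid=0.05, high_uncertainty=0.05, duplicate=0.10, unidentified=0.05
        )
    )
    n_centroids: int = 3
    pa_coverage: float = 0.15
    pa_bias_mode: str = "random"
    seed: int = 0


@dataclass
class Scenario:
    """A complete synthetic study system with ground truth."""

    config: ScenarioConfig
    grid: Grid
    predictors: list[Layer]
    species: list[VirtualSpecies]
    occurrences: list[OccurrenceRecord]
    occurrence_truth: pd.DataFrame
    bias: Layer
    pa_mask: BinaryMask
    centroids: list[tuple[float, float]]
    exclusion_mask: BinaryMask | None = None

    def truth_table(self, run_config: RunConfig | None = None) -> pd.DataFrame:
        """Per-species truth: range area, fraction inside the PA network,
        and the achievement class computed from the true range."""
        from .representation import achievement, conservation_target

        cfg = run_config or RunConfig()
        rows = []
        for sp in self.species:
            tf = conservation_target(sp.true_range_area, cfg)
            rec = achievement(sp.species_id, sp.true_range, self.pa_mask, tf, cfg)
            rows.append(
                {
                    "species": sp.species_id,
                    "true_range_area_km2": sp.true_range_area,
                    "true_fraction_in_pa": rec.protected_area_of_range / rec.range_area,
                    "true_target_fraction": tf,
                    "true_achievement": rec.achievement,
                    "true_class": rec.achievement_class,
                }
            )
        return pd.DataFrame(rows)


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Build a full scenario from one seed; every stage is reproducible."""
    cfg = config or ScenarioConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(5)
    grid = Grid(cfg.n_rows, cfg.n_cols, cell_area=cfg.cell_area)
    predictors = make_predictors(
        grid, cfg.n_vars, cfg.collinearity, seed=int(seeds[0]),
        smoothness=cfg.predictor_smoothness,
    )
    species = make_species(
        predictors,
        cfg.n_species,
        range_sigma=cfg.range_sigma,
        range_median_fraction=cfg.range_median_fraction,
        seed=int(seeds[1]),
    )
    centroids = pick_centroids(species, grid, k=cfg.n_centroids, seed=int(seeds[2]))
    bias = make_bias_layer(grid, strength=cfg.bias_strength, seed=int(seeds[2]))
    occurrences, truth = sample_occurrences(
        species,
        cfg.n_per_species,
        bias_layer=bias,
        error_rates=cfg.error_rates,
        seed=int(seeds[3]),
        centroids=centroids,
    )
    pa = make_pa_network(
        grid,
        cfg.pa_coverage,
        bias_mode=cfg.pa_bias_mode,
        seed=int(seeds[4]),
        species=species if cfg.pa_bias_mode == "optimal-for-subset" else None,
    )
    return Scenario(
        config=cfg,
        grid=grid,
        predictors=predictors,
        species=species,
        occurrences=occurrences,
        occurrence_truth=truth,
        bias=bias,
        pa_mask=pa,
        centroids=centroids,
    )


def write_scenario(scenario: Scenario, out_dir: str) -> None:
    """Write the scenario as the file set the pipeline stages consume."""
    os.makedirs(os.path.join(out_dir, "predictors"), exist_ok=True)
    for i, p in enumerate(scenario.predictors):
        write_raster(p, os.path.join(out_dir, "predictors", f"var{i:02d}.tif"))
    write_raster(scenario.pa_mask, os.path.join(out_dir, "pa.tif"))
    if scenario.exclusion_mask is not None:
        write_raster(scenario.exclusion_mask, os.path.join(out_dir, "exclusion.tif"))
    write_occurrences(scenario.occurrences, os.path.join(out_dir, "occurrences.csv"))
    pd.DataFrame(scenario.centroids, columns=["x", "y"]).to_csv(
        os.path.join(out_dir, "centroids.csv"), index=False
    )
    pd.DataFrame(columns=["x", "y"]).to_csv(
        os.path.join(out_dir, "institutions.csv"), index=False
    )
    scenario.truth_table().to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    scenario.occurrence_truth.to_csv(os.path.join(out_dir, "occurrence_truth.csv"))
    params = asdict(scenario.config)
    with open(os.path.join(out_dir, "scenario.json"), "w") as fh:
        json.dump(params, fh, indent=2)
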