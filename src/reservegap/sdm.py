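"""Presence-background distribution modelling with TSS-weighted ensembles.

The stage mirrors the standard ensemble workflow for large species batches:

* background points are drawn from the occurrence cells of *other* species
  of the same group (target-group background), which cancels shared sampling
  bias because presences and backgrounds then carry the same accessibility
  footprint;
* each technique is fitted on 70% of the presences and evaluated on the
  held-out 30% via the True Skill Statistic (TSS = sensitivity +
  specificity - 1) at the max-TSS threshold;
* replicate train/test splits are averaged per technique, techniques with
  TSS <= ``tss_keep`` (default 0.7) are discarded, and the survivors are
  combined by TSS-weighted averaging;
* the ensemble is multiplied by exp(-d/delta), d = distance to the nearest
  known presence cell, to curb overprediction far from the occupied area;
* the restricted ensemble is thresholded at the max-TSS cut to give the
  binary range map.

The learners themselves are deliberately simple and pluggable: a regularized
logistic presence-background model on linear + quadratic predictor terms,
and a percentile environmental envelope.  The machinery around them —
weighting, filtering, restriction, thresholding — is the analysis.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .grid import BinaryMask, Grid, Layer
from .occurrences import OccurrenceRecord

logger = logging.getLogger(__name__)

TECHNIQUES = ("logistic", "envelope")


# --------------------------------------------------------------------------
# background sampling and data splitting
# --------------------------------------------------------------------------

def sample_background(
    focal_species: str,
    pool_records: list[OccurrenceRecord],
    n: int,
    grid: Grid,
    seed: int,
) -> np.ndarray:
    """Background cells drawn from other species' occurrence cells.

    Records of the focal species are excluded; the remaining records are
    collapsed to unique grid cells and min(n, pool size) cells are sampled
    uniformly without replacement.  Returns an (m, 2) array of (row, col).
    """
    cells: set[tuple[int, int]] = set()
    for r in pool_records:
        if r.species_id == focal_species:
            continue
        c = grid.cell_of(r.x, r.y)
        if c is not None and not grid.nodata_mask[c]:
            cells.add(c)
    if not cells:
        raise ValueError(f"{focal_species}: empty background pool")
    pool = np.array(sorted(cells), dtype=int)
    if len(pool) <= n:
        if len(pool) < n:
            logger.warning(
                "%s: background pool (%d cells) smaller than requested %d",
                focal_species,
                len(pool),
                n,
            )
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool[np.sort(idx)]


@dataclass
class Partition:
    """One train/test split of presence and background cells."""

    train_presence: np.ndarray
    test_presence: np.ndarray
    train_background: np.ndarray
    test_background: np.ndarray


def _split_count(n: int, fraction: float) -> int:
    """Round-half-up train size, clamped so both sides are non-empty."""
    k = int(np.floor(fraction * n + 0.5))
    return min(max(k, 1), n - 1)


def split_train_test(
    presences: np.ndarray,
    backgrounds: np.ndarray,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> Partition:
    """Split presences and backgrounds independently into train/test.

    Train size is round-half-up of fraction x n with at least one cell on
    each side; requires >= 2 presences.
    """
    presences = np.asarray(presences)
    backgrounds = np.asarray(backgrounds)
    if len(presences) < 2:
        raise ValueError("need at least 2 presences to split")
    rng = np.random.default_rng(seed)

    def _one(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = len(cells)
        k = _split_count(n, train_fraction)
        perm = rng.permutation(n)
        return cells[np.sort(perm[:k])], cells[np.sort(perm[k:])]

    tr_p, te_p = _one(presences)
    tr_b, te_b = _one(backgrounds)
    return Partition(tr_p, te_p, tr_b, te_b)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def compute_tss(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """True Skill Statistic at a threshold.

    ``labels`` is boolean (True = presence); a score >= threshold predicts
    presence.  TSS = a/(a+c) + d/(b+d) - 1 with a,b,c,d the confusion counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("TSS needs both presences and backgrounds")
    pred = scores >= threshold
    a = int((pred & labels).sum())
    c = int((~pred & labels).sum())
    b = int((pred & ~labels).sum())
    d = int((~pred & ~labels).sum())
    sens = a / (a + c)
    spec = d / (b + d)
    return sens + spec - 1.0


THRESHOLD_GRID = np.round(np.arange(0, 101) * 0.01, 2)


def max_tss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(threshold, tss) maximizing TSS over the 0.01-step grid in [0, 1];
    ties broken by the lowest threshold."""
    best_t, best_tss = 0.0, -np.inf
    for t in THRESHOLD_GRID:
        tss = compute_tss(scores, labels, t)
        if tss > best_tss + 1e-12:
            best_t, best_tss = float(t), tss
    return best_t, best_tss


# --------------------------------------------------------------------------
# learners
# --------------------------------------------------------------------------

def _features_at(cells: np.ndarray, predictors: list[Layer]) -> np.ndarray:
    rows, cols = cells[:, 0], cells[:, 1]
    return np.column_stack([p.values[rows, cols] for p in predictors])


def _rescale01(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    lo = np.nanmin(values[valid])
    hi = np.nanmax(values[valid])
    if hi - lo < 1e-12:
        out = np.where(valid, 1.0, np.nan)
        return out
    return (values - lo) / (hi - lo)


@dataclass
class FittedModel:
    """One fitted technique (or a per-technique replicate mean)."""

    technique_id: str
    suitability: Layer
    tss: float
    replicate_index: int = 0
    threshold: float = 0.0


def _fit_logistic(part: Partition, predictors: list[Layer], seed: int) -> np.ndarray:
    """L2-regularized presence-background logistic model with linear +
    quadratic terms; returns raw suitability over the whole grid."""
    Xp = _features_at(part.train_presence, predictors)
    Xb = _features_at(part.train_background, predictors)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0

    def expand(M: np.ndarray) -> np.ndarray:
        Z = (M - mu) / sd
        return np.hstack([Z, Z**2])

    # balanced class weights give presences and backgrounds equal total
    # weight (the standard infinitely-weighted presence-background scheme);
    # mild L2 keeps the quadratic terms stable at small presence counts
    clf = LogisticRegression(C=10.0, max_iter=2000, class_weight="balanced", random_state=seed)
    clf.fit(expand(X), y)
    grid = predictors[0].grid
    valid = ~grid.nodata_mask
    cells = np.argwhere(valid)
    scores = clf.predict_proba(expand(_features_at(cells, predictors)))[:, 1]
    out = np.full(grid.shape, np.nan)
    out[valid] = scores
    return out


def _fit_envelope(part: Partition, predictors: list[Layer], seed: int) -> np.ndarray:
    """Percentile environmental envelope (BIOCLIM-style): per predictor the
    score is 1 - 2*|F(v) - 0.5| with F the empirical CDF of the training
    presences; per-cell suitability is the minimum over predictors (the
    most limiting variable)."""
    Xp = _features_at(part.train_presence, predictors)
    grid = predictors[0].grid
    valid = ~grid.nodata_mask
    out = np.where(valid, 1.0, np.nan)
    for j, layer in enumerate(predictors):
        train = np.sort(Xp[:, j])
        v = layer.values
        # empirical CDF with midpoint convention
        ranks = np.searchsorted(train, v, side="left") + np.searchsorted(
            train, v, side="right"
        )
        F = ranks / (2.0 * len(train))
        out = np.minimum(out, 1.0 - 2.0 * np.abs(F - 0.5))
    return out


_LEARNERS = {"logistic": _fit_logistic, "envelope": _fit_envelope}


def fit_suitability(
    part: Partition,
    predictors: list[Layer],
    technique: str,
    seed: int = 0,
    replicate_index: int = 0,
) -> FittedModel:
    """Fit one technique on the training side of a partition.

    Suitability is rescaled to [0, 1] over valid cells; TSS is evaluated on
    the held-out presences/backgrounds at the max-TSS threshold.
    """
    if technique not in _LEARNERS:
        raise ValueError(f"unknown technique {technique!r}; choose from {sorted(_LEARNERS)}")
    if len(part.train_presence) < 1 or len(part.train_background) < 1:
        raise ValueError("degenerate training data")
    grid = predictors[0].grid
    raw = _LEARNERS[technique](part, predictors, seed)
    valid = ~grid.nodata_mask
    suit = _rescale01(raw, valid)
    layer = Layer(grid, np.where(valid, suit, 0.0))
    layer.values[~valid] = np.nan
    eval_cells = np.vstack([part.test_presence, part.test_background])
    labels = np.concatenate(
        [np.ones(len(part.test_presence), bool), np.zeros(len(part.test_background), bool)]
    )
    scores = layer.values[eval_cells[:, 0], eval_cells[:, 1]]
    thr, tss = max_tss_threshold(scores, labels)
    return FittedModel(
        technique_id=technique,
        suitability=layer,
        tss=tss,
        replicate_index=replicate_index,
        threshold=thr,
    )


# --------------------------------------------------------------------------
# ensembling, geographic restriction, binarization
# --------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    species_id: str
    suitability: Layer | None
    ensemble_tss: float
    contributing: list[FittedModel] = field(default_factory=list)
    kept: bool = False


def ensemble(
    models: list[FittedModel], tss_keep: float = 0.7, species_id: str = ""
) -> EnsembleModel:
    """TSS-weighted average of the models exceeding the keep cutoff.

    Models with tss <= ``tss_keep`` are excluded; survivor weights are their
    TSS values normalized to sum 1.  With no survivor, or an ensemble TSS
    still at or below the cutoff, the species is flagged ``kept=False`` (to
    be replaced upstream).  The ensemble TSS is the weighted mean of the
    survivors' TSS.
    """
    if not models:
        raise ValueError("ensemble of zero models")
    survivors = [m for m in models if m.tss > tss_keep]
    if not survivors:
        return EnsembleModel(species_id, None, max(m.tss for m in models), [], kept=False)
    w = np.array([m.tss for m in survivors], dtype=float)
    w = w / w.sum()
    grid = survivors[0].suitability.grid
    vals = np.zeros(grid.shape)
    for wi, m in zip(w, survivors):
        vals += wi * np.nan_to_num(m.suitability.values)
    valid = ~grid.nodata_mask
    layer = Layer(grid, np.where(valid, vals, 0.0))
    layer.values[~valid] = np.nan
    ens_tss = float(np.dot(w, [m.tss for m in survivors]))
    return EnsembleModel(species_id, layer, ens_tss, survivors, kept=ens_tss > tss_keep)


def apply_distance_decay(
    suitability: Layer, presence_cells: np.ndarray, decay_distance: float
) -> Layer:
    """Multiply suitability by exp(-d/delta), d = Euclidean map-unit distance
    from each cell center to the nearest presence cell center.

    Cells containing presences keep their value (d = 0).  delta -> inf
    recovers the input.
    """
    if decay_distance <= 0:
        raise ValueError("decay_distance must be positive")
    presence_cells = np.asarray(presence_cells)
    if len(presence_cells) == 0:
        raise ValueError("no presence cells to anchor the decay")
    grid = suitability.grid
    occupied = np.zeros(grid.shape, dtype=bool)
    occupied[presence_cells[:, 0], presence_cells[:, 1]] = True
    d = ndimage.distance_transform_edt(~occupied, sampling=(grid.dy, grid.dx))
    out = suitability.values * np.exp(-d / decay_distance)
    return Layer(grid, np.where(~grid.nodata_mask, out, 0.0))


def binarize_max_tss(
    suitability: Layer, eval_cells: np.ndarray, eval_labels: np.ndarray
) -> tuple[BinaryMask, float]:
    """Binary range map at the TSS-maximizing threshold.

    The threshold maximizes TSS of ``suitability >= t`` over a 0.01-step
    grid in [0, 1], evaluated on the given cells/labels; ties go to the
    lowest threshold.  Returns (binary map, threshold).
    """
    scores = suitability.values[eval_cells[:, 0], eval_cells[:, 1]]
    thr, _ = max_tss_threshold(scores, np.asarray(eval_labels, bool))
    grid = suitability.grid
    binary = (np.nan_to_num(suitability.values, nan=-1.0) >= thr) & ~grid.nodata_mask
    return BinaryMask(grid, binary.astype(np.uint8)), thr


# --------------------------------------------------------------------------
# per-species orchestration
# --------------------------------------------------------------------------

@dataclass
class SpeciesSDM:
    """Full SDM result for one species."""

    species_id: str
    ensemble: EnsembleModel
    binary_range: BinaryMask | None
    threshold: float
    technique_tss: dict[str, float]
    replicate_tss: dict[str, list[float]]


def fit_species_sdm(
    species_id: str,
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    predictors: list[Layer],
    config,
    seed: int,
) -> SpeciesSDM:
    """Replicated multi-technique SDM for one species.

    For each of ``config.n_replicates`` train/test splits every technique is
    fitted and evaluated; per-technique suitability and TSS are averaged
    across replicates, the technique means are TSS-weight ensembled, the
    ensemble is restricted by exponential distance decay around the known
    presence cells, and finally thresholded at the max-TSS cut evaluated on
    all presences vs all backgrounds.
    """
    grid = predictors[0].grid
    replicate_tss: dict[str, list[float]] = {t: [] for t in config.techniques}
    tech_sum: dict[str, np.ndarray] = {t: np.zeros(grid.shape) for t in config.techniques}
    ss = np.random.SeedSequence(entropy=(seed, zlib.crc32(species_id.encode())))
    rep_seeds = ss.generate_state(config.n_replicates)
    for r in range(config.n_replicates):
        part = split_train_test(
            presence_cells, background_cells, config.train_fraction, seed=int(rep_seeds[r])
        )
        for t in config.techniques:
            fm = fit_suitability(part, predictors, t, seed=int(rep_seeds[r]) % (2**31), replicate_index=r)
            replicate_tss[t].append(fm.tss)
            tech_sum[t] += np.nan_to_num(fm.suitability.values)

    valid = ~grid.nodata_mask
    tech_models = []
    technique_tss = {}
    for t in config.techniques:
        mean_vals = tech_sum[t] / config.n_replicates
        layer = Layer(grid, np.where(valid, mean_vals, 0.0))
        layer.values[~valid] = np.nan
        mean_tss = float(np.mean(replicate_tss[t]))
        technique_tss[t] = mean_tss
        tech_models.append(FittedModel(technique_id=t, suitability=layer, tss=mean_tss))

    ens = ensemble(tech_models, config.tss_keep, species_id=species_id)
    if not ens.kept or ens.suitability is None:
        return SpeciesSDM(species_id, ens, None, 0.0, technique_tss, replicate_tss)

    delta = config.decay_distance
    if delta is None:
        delta = 10.0 * grid.dx
    restricted = apply_distance_decay(ens.suitability, presence_cells, delta)
    # re-rescale after restriction so the 0.01-step threshold grid spans it
    restricted = Layer(
        grid, np.where(valid, np.nan_to_num(_rescale01(restricted.values, valid)), 0.0)
    )

    eval_cells = np.vstack([presence_cells, background_cells])
    labels = np.concatenate(
        [np.ones(len(presence_cells), bool), np.zeros(len(background_cells), bool)]
    )
    binary, thr = binarize_max_tss(restricted, eval_cells, labels)
    ens.suitability = restricted
    return SpeciesSDM(species_id, ens, binary, thr, technique_tss, replicate_tss)
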