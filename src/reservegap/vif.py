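"""Variance-inflation-factor screening of the predictor stack.

VIF_j = 1 / (1 - R²_j), where R²_j is the coefficient of determination of
an ordinary least-squares regression of predictor j on all the others over
the unmasked cells.  Predictors are pruned iteratively: at each step the
variable with the highest VIF is dropped (ties broken by lowest priority)
and VIFs are recomputed, until every remaining VIF is below the threshold
(default 10).  An exactly collinear variable reports VIF = inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import Layer

logger = logging.getLogger(__name__)


@dataclass
class VIFTable:
    """Per-variable VIFs, the order of removals, and the retained set."""

    vif: dict[str, float]
    removal_order: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def _design_matrix(predictors: dict[str, Layer]) -> tuple[np.ndarray, list[str]]:
    names = list(predictors)
    cols = [predictors[n].valid_values for n in names]
    n_cells = {len(c) for c in cols}
    if len(n_cells) != 1:
        raise ValueError("predictors have differing numbers of unmasked cells")
    X = np.column_stack(cols)
    return X, names

def _vif_from_matrix(X: np.ndarray, names: list[str]) -> dict[str, float]:
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    if n <= p:
        raise ValueError(f"fewer unmasked cells ({n}) than variables + 1 ({p + 1})")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant predictor(s): {bad}")
    out: dict[str, float] = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(names):
        yj = X[:, j]
        Xo = np.column_stack([ones, np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        # guard tiny negative residual error; exact collinearity -> inf
        if r2 >= 1.0 - 1e-12:
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def compute_vif(predictors: dict[str, Layer]) -> VIFTable:
    """VIF of every predictor over unmasked cells.

    Raises ``ValueError`` for a constant predictor or when there are fewer
    cells than variables.
    """
    X, names = _design_matrix(predictors)
    vifs = _vif_from_matrix(X, names)
    return VIFTable(vif=vifs, retained=list(names))


def prune_predictors(
    predictors: dict[str, Layer],
    threshold: float = 10.0,
    priority_order: list[str] | None = None,
) -> tuple[dict[str, Layer], VIFTable]:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    ``priority_order`` ranks variables by relevance (earlier = keep harder);
    default is input order.  Among equally inflated variables the lowest
    priority one is removed.  Raises if pruning would remove every variable.
    """
    names = list(predictors)
    priority = {n: i for i, n in enumerate(priority_order or names)}
    for n in names:
        priority.setdefault(n, len(priority))
    X, _ = _design_matrix(predictors)
    current = names[:]
    removal_order: list[str] = []
    vifs = _vif_from_matrix(X, current)
    while True:
        worst = max(vifs.values())
        if worst < threshold:
            break
        if len(current) <= 1:
            raise ValueError("pruning removed all variables: pathological collinearity")
        # ties on VIF broken by *lowest* priority (largest priority index)
        candidates = [n for n, v in vifs.items() if v == worst]
        drop = max(candidates, key=lambda n: priority[n])
        idx = current.index(drop)
        current.pop(idx)
        X = np.delete(X, idx, axis=1)
        removal_order.append(drop)
        logger.info("vif prune: dropped %s (VIF=%.3g)", drop, worst)
        if len(current) == 1:
            vifs = {current[0]: 1.0}
            break
        vifs = _vif_from_matrix(X, current)
    table = VIFTable(vif=vifs, removal_order=removal_order, retained=current)
    return {n: predictors[n] for n in current}, table
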