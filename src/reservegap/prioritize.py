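"""Minimum-set reserve selection and the two network-efficiency metrics.

The reserve-design problem is a minimum-cost set multicover: choose planning
units (grid cells, cost = cell area) so that every species' absolute target
amount of range is covered, respecting locked-in units (forced into the
solution) and locked-out units (excluded, e.g. degraded sites):

    minimize    sum_u cost_u * x_u
    subject to  sum_u amount_{s,u} * x_u >= target_s   for every species s
                x_u = 1 for locked-in u;  x_u = 0 for locked-out u
                x_u in {0, 1}

Two runs of this problem yield the network-efficiency metrics:

* **completeness** — lock the existing PA network in, measure how much extra
  area the solver must add: completeness = 100 * pa / (pa + added);
* **specificity** — solve unconstrained, measure what share of the optimal
  solution the existing network already covers:
  specificity = 100 * area(solution ∩ PA) / area(solution).

The exact solver enumerates all subsets on small instances (with exact
lexicographic tie-breaking) and otherwise solves the integer program by
branch-and-bound (HiGHS via scipy), with a geometric index perturbation
steering ties toward the lexicographically smallest unit set.  A greedy
largest-shortfall-reduction-per-cost heuristic is provided for instances
where exact solving is unnecessary or too slow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .grid import BinaryMask, Grid
from .representation import conservation_target

logger = logging.getLogger(__name__)

MODES = ("completeness", "specificity")


class InfeasibleProblemError(RuntimeError):
    pass


@dataclass
class PrioritizationProblem:
    """Set-multicover instance over the valid cells of a grid.

    ``coverage`` is a boolean (n_species, n_units) matrix; the amount a unit
    contributes to a species is ``cell_area`` where True.  Targets are in
    km², already clamped to what is attainable outside locked-out units.
    """

    grid: Grid
    unit_cells: np.ndarray  # (n_units, 2) int (row, col)
    costs: np.ndarray  # (n_units,) km²
    species_ids: list[str]
    coverage: np.ndarray  # bool (n_species, n_units)
    targets_km2: np.ndarray  # (n_species,)
    locked_in: np.ndarray  # bool (n_units,)
    locked_out: np.ndarray  # bool (n_units,)

    @property
    def n_units(self) -> int:
        return len(self.costs)

    def amounts_held(self, selected: np.ndarray) -> np.ndarray:
        """Per-species amount (km²) held by a boolean unit selection."""
        return self.coverage[:, selected].sum(axis=1) * self.grid.cell_area


@dataclass
class Solution:
    selected: np.ndarray  # bool (n_units,)
    total_cost: float
    amount_held: np.ndarray  # (n_species,) km²
    all_targets_met: bool
    solver: str  # "exact" | "greedy"
    optimality_gap: float | None = None

    def selected_mask(self, problem: PrioritizationProblem) -> BinaryMask:
        vals = np.zeros(problem.grid.shape, dtype=np.uint8)
        cells = problem.unit_cells[self.selected]
        vals[cells[:, 0], cells[:, 1]] = 1
        return BinaryMask(problem.grid, vals)


def build_problem(
    ranges: dict[str, BinaryMask],
    pa_mask: BinaryMask,
    mode: str,
    exclusion_mask: BinaryMask | None = None,
    target_fractions: dict[str, float] | None = None,
    config=None,
) -> PrioritizationProblem:
    """Assemble the set-multicover instance for one prioritization mode.

    ``mode="completeness"`` locks the PA cells in; ``mode="specificity"``
    leaves the solver unconstrained.  Exclusion cells are locked out in both
    modes.  Target fractions default to the range-size-scaled rule; absolute
    targets are fraction x range area, clamped (with a warning) to the
    amount attainable outside locked-out units.  A species whose entire
    range is excluded raises :class:`InfeasibleProblemError`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    grid = pa_mask.grid
    for rng in ranges.values():
        grid.require_compatible(rng.grid)
    if exclusion_mask is not None:
        grid.require_compatible(exclusion_mask.grid)

    unit_cells = np.argwhere(~grid.nodata_mask)
    n_units = len(unit_cells)
    rows, cols = unit_cells[:, 0], unit_cells[:, 1]
    costs = np.full(n_units, grid.cell_area)

    species_ids = sorted(ranges)
    coverage = np.zeros((len(species_ids), n_units), dtype=bool)
    for i, sp in enumerate(species_ids):
        coverage[i] = ranges[sp].as_bool[rows, cols]

    locked_in = (
        pa_mask.as_bool[rows, cols] if mode == "completeness" else np.zeros(n_units, bool)
    )
    locked_out = (
        exclusion_mask.as_bool[rows, cols] if exclusion_mask is not None else np.zeros(n_units, bool)
    )
    locked_in = locked_in & ~locked_out  # exclusion dominates

    cell_area = grid.cell_area
    targets = np.zeros(len(species_ids))
    for i, sp in enumerate(species_ids):
        range_area = coverage[i].sum() * cell_area
        if range_area == 0:
            raise InfeasibleProblemError(f"{sp}: range empty on the planning grid")
        tf = (
            target_fractions[sp]
            if target_fractions is not None
            else conservation_target(range_area, config)
        )
        target = tf * range_area
        available = coverage[i, ~locked_out].sum() * cell_area
        if available == 0:
            raise InfeasibleProblemError(f"{sp}: zero available amount outside locked-out units")
        if target > available:
            logger.warning(
                "%s: target %.3f km² clamped to available %.3f km²", sp, target, available
            )
            target = available
        targets[i] = target

    return PrioritizationProblem(
        grid=grid,
        unit_cells=unit_cells,
        costs=costs,
        species_ids=species_ids,
        coverage=coverage,
        targets_km2=targets,
        locked_in=locked_in,
        locked_out=locked_out,
    )


# --------------------------------------------------------------------------
# solvers
# --------------------------------------------------------------------------

def _residual_counts(problem: PrioritizationProblem) -> np.ndarray:
    """Per-species residual target in *cell counts* after locked-in coverage."""
    cell_area = problem.grid.cell_area
    held = problem.amounts_held(problem.locked_in)
    resid = np.ceil((problem.targets_km2 - held) / cell_area - 1e-9)
    return np.maximum(resid, 0).astype(int)


def _finish(problem: PrioritizationProblem, selected: np.ndarray, solver: str,
            gap: float | None = None) -> Solution:
    held = problem.amounts_held(selected)
    met = bool(np.all(held >= problem.targets_km2 - 1e-9))
    return Solution(
        selected=selected,
        total_cost=float(problem.costs[selected].sum()),
        amount_held=held,
        all_targets_met=met,
        solver=solver,
        optimality_gap=gap,
    )


def solve_exact(problem: PrioritizationProblem, size_limit: int = 15) -> Solution:
    """Cost-minimal feasible selection.

    Instances with at most ``size_limit`` free units are solved by
    exhaustive enumeration with exact lexicographic tie-breaking; larger
    instances go to the HiGHS branch-and-bound integer programming solver
    with zero relative gap, perturbed so ties fall toward the
    lexicographically smallest selected-unit set.
    """
    free = ~problem.locked_in & ~problem.locked_out
    resid = _residual_counts(problem)
    need = resid > 0
    # units covering no needy species can never help
    useful = free & problem.coverage[need].any(axis=0) if need.any() else np.zeros_like(free)
    free_idx = np.flatnonzero(useful)

    attainable = problem.coverage[:, problem.locked_in | useful].sum(axis=1)
    short = attainable * problem.grid.cell_area < problem.targets_km2 - 1e-9
    if short.any():
        bad = [problem.species_ids[i] for i in np.flatnonzero(short)]
        raise InfeasibleProblemError(f"targets unattainable for species: {bad}")

    if not need.any():
        return _finish(problem, problem.locked_in.copy(), "exact", gap=0.0)

    if len(free_idx) <= size_limit:
        chosen = _enumerate_optimal(problem, free_idx, resid)
    else:
        chosen = _milp_optimal(problem, free_idx, resid)
    selected = problem.locked_in.copy()
    selected[chosen] = True
    return _finish(problem, selected, "exact", gap=0.0)


def _enumerate_optimal(
    problem: PrioritizationProblem, free_idx: np.ndarray, resid: np.ndarray
) -> np.ndarray:
    """Brute force over all subsets of the free units; minimal cost, then
    lexicographically smallest index set."""
    need_rows = np.flatnonzero(resid > 0)
    cover_bits = np.zeros(len(need_rows), dtype=object)
    for k, s in enumerate(need_rows):
        bits = 0
        for j, u in enumerate(free_idx):
            if problem.coverage[s, u]:
                bits |= 1 << j
        cover_bits[k] = bits
    costs = problem.costs[free_idx]
    best_cost = np.inf
    best_subset: tuple[int, ...] | None = None
    m = len(free_idx)
    for mask in range(1 << m):
        ok = all(
            int.bit_count(cover_bits[k] & mask) >= resid[s]
            for k, s in enumerate(need_rows)
        )
        if not ok:
            continue
        members = tuple(j for j in range(m) if mask >> j & 1)
        cost = float(sum(costs[j] for j in members))
        key = (cost, tuple(free_idx[j] for j in members))
        if best_subset is None or key < (best_cost, best_subset):
            best_cost, best_subset = key
    if best_subset is None:
        raise InfeasibleProblemError("no feasible subset found")
    return np.array(best_subset, dtype=int)


def _milp_optimal(
    problem: PrioritizationProblem, free_idx: np.ndarray, resid: np.ndarray
) -> np.ndarray:
    need_rows = np.flatnonzero(resid > 0)
    A = sparse.csr_matrix(problem.coverage[np.ix_(need_rows, free_idx)].astype(float))
    lb = resid[need_rows].astype(float)
    costs = problem.costs[free_idx].astype(float)
    # geometric index perturbation: prefer the lexicographically smallest
    # optimal set (exact for the first ~40 free units, see docs)
    eps = 0.25 * float(problem.costs.min())
    reward = eps * np.power(2.0, -np.minimum(np.arange(len(free_idx)), 40))
    res = milp(
        c=costs - reward,
        constraints=LinearConstraint(A, lb=lb, ub=np.inf),
        integrality=np.ones(len(free_idx)),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if not res.success or res.x is None:
        raise InfeasibleProblemError(f"integer program failed: {res.message}")
    chosen = free_idx[res.x > 0.5]
    return chosen


def solve_greedy(problem: PrioritizationProblem) -> Solution:
    """Greedy complementarity heuristic.

    Starting from the locked-in units, repeatedly add the unit with the
    largest total shortfall reduction per unit cost (ties broken by lowest
    unit index) until every target is met.  Feasible by construction when
    the problem is feasible; cost is an upper bound on the exact optimum.
    """
    cell_area = problem.grid.cell_area
    free = ~problem.locked_in & ~problem.locked_out
    selected = problem.locked_in.copy()
    shortfall = np.maximum(problem.targets_km2 - problem.amounts_held(selected), 0.0)

    attainable = problem.amounts_held(problem.locked_in | free)
    if np.any(attainable < problem.targets_km2 - 1e-9):
        bad = [
            problem.species_ids[i]
            for i in np.flatnonzero(attainable < problem.targets_km2 - 1e-9)
        ]
        raise InfeasibleProblemError(f"targets unattainable for species: {bad}")

    cover_f = problem.coverage.astype(float)
    while shortfall.sum() > 1e-9:
        per_species_gain = np.minimum(cover_f * cell_area, shortfall[:, None])
        gain = per_species_gain.sum(axis=0) / problem.costs
        gain[~free] = -np.inf
        best = int(np.argmax(gain))  # argmax returns the first (lowest) index on ties
        if gain[best] <= 0:
            raise InfeasibleProblemError("greedy stalled with positive shortfall")
        selected[best] = True
        free[best] = False
        shortfall = np.maximum(shortfall - per_species_gain[:, best], 0.0)
    return _finish(problem, selected, "greedy")


# --------------------------------------------------------------------------
# efficiency metrics
# --------------------------------------------------------------------------

@dataclass
class EfficiencyReport:
    """Areas and percentages summarizing both prioritization runs.

    ``completeness_pct`` uses pa / (pa + added); because the literature also
    quotes the expansion as a percentage *of the current network*, the
    report carries ``expansion_of_current_pa_pct`` (100 * added / pa) and
    its complement ``completeness_alt_pct`` so both readings are available.
    """

    pa_area_km2: float = 0.0
    added_area_km2: float = 0.0
    completeness_pct: float = 100.0
    expansion_pct: float = 0.0
    expansion_of_current_pa_pct: float = 0.0
    completeness_alt_pct: float = 100.0
    free_solution_area_km2: float = 0.0
    overlap_area_km2: float = 0.0
    specificity_pct: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def completeness_metric(
    problem: PrioritizationProblem, locked_solution: Solution
) -> EfficiencyReport:
    """Completeness of the PA network from the locked-in prioritization run:
    how close the current network is to needing no expansion."""
    pa_area = float(problem.costs[problem.locked_in].sum())
    added = locked_solution.selected & ~problem.locked_in
    added_area = float(problem.costs[added].sum())
    completeness = 100.0 * pa_area / (pa_area + added_area) if pa_area + added_area > 0 else 100.0
    exp_of_pa = 100.0 * added_area / pa_area if pa_area > 0 else float("inf")
    return EfficiencyReport(
        pa_area_km2=pa_area,
        added_area_km2=added_area,
        completeness_pct=completeness,
        expansion_pct=100.0 - completeness,
        expansion_of_current_pa_pct=exp_of_pa,
        completeness_alt_pct=100.0 - exp_of_pa if np.isfinite(exp_of_pa) else float("-inf"),
    )


def specificity_metric(
    problem: PrioritizationProblem, pa_mask: BinaryMask, free_solution: Solution
) -> EfficiencyReport:
    """Specificity of the PA network from the unconstrained run: percent of
    the optimal solution area already inside the network."""
    if not free_solution.selected.any():
        raise ValueError("empty free-mode solution")
    sel_area = float(problem.costs[free_solution.selected].sum())
    rows, cols = problem.unit_cells[:, 0], problem.unit_cells[:, 1]
    in_pa = pa_mask.as_bool[rows, cols]
    overlap = float(problem.costs[free_solution.selected & in_pa].sum())
    return EfficiencyReport(
        pa_area_km2=pa_mask.area_km2,
        free_solution_area_km2=sel_area,
        overlap_area_km2=overlap,
        specificity_pct=100.0 * overlap / sel_area,
    )
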