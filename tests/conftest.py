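import numpy as np
import pytest

import reservegap as rg


@pytest.fixture(scope="session")
def small_grid():
    return rg.Grid(30, 30, cell_area=100.0)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact error-free scenario shared by fast tests."""
    return rg.generate_scenario(
        rg.ScenarioConfig(
            n_rows=40,
            n_cols=40,
            n_species=8,
            n_per_species=50,
            range_sigma=0.8,
            range_median_fraction=0.04,
            error_rates=rg.ErrorRates(),
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default-condition scenario with injected record errors."""
    return rg.generate_scenario(rg.ScenarioConfig(seed=0))


def random_cover_problem(rng, n_units=12, n_species=5, cell_area=10.0,
                         locked_in_frac=0.0, locked_out_frac=0.0):
    """Random feasible set-multicover instance on a 1 x n_units grid."""
    grid = rg.Grid(1, n_units, cell_area=cell_area)
    pa_vals = np.zeros((1, n_units), dtype=np.uint8)
    if locked_in_frac:
        pa_vals[0, rng.random(n_units) < locked_in_frac] = 1
    pa = rg.BinaryMask(grid, pa_vals)
    excl = None
    if locked_out_frac:
        ex = (rng.random(n_units) < locked_out_frac) & (pa_vals[0] == 0)
        excl = rg.BinaryMask(grid, ex.reshape(1, -1).astype(np.uint8))
    ranges = {}
    fractions = {}
    for s in range(n_species):
        cover = rng.random(n_units) < rng.uniform(0.2, 0.7)
        if excl is not None:
            avail = cover & ~excl.as_bool[0]
        else:
            avail = cover
        if not avail.any():
            cover[rng.integers(n_units)] = True
            if excl is not None:
                excl.values[0, np.flatnonzero(cover)[0]] = 0
        ranges[f"s{s}"] = rg.BinaryMask(grid, cover.reshape(1, -1).astype(np.uint8))
        fractions[f"s{s}"] = float(rng.uniform(0.2, 0.9))
    mode = "completeness" if locked_in_frac else "specificity"
    return rg.build_problem(ranges, pa, mode=mode, exclusion_mask=excl,
                            target_fractions=fractions)


def brute_force_min_cover(problem):
    """Independent exhaustive oracle: minimal feasible cost over all subsets
    of the free units (locked-in units always included)."""
    import itertools

    free = np.flatnonzero(~problem.locked_in & ~problem.locked_out)
    best = None
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            sel = problem.locked_in.copy()
            sel[list(combo)] = True
            held = problem.amounts_held(sel)
            if np.all(held >= problem.targets_km2 - 1e-9):
                cost = problem.costs[sel].sum()
                if best is None or cost < best:
                    best = cost
        if best is not None:
            break  # all-equal unit costs: smallest feasible cardinality wins
    return best
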