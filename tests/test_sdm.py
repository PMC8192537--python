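"""SDM stage: background sampling, splitting, TSS, ensembling, decay,
max-TSS binarization, and range recovery on synthetic truth."""

import numpy as np
import pytest

import reservegap as rg
from reservegap.sdm import Partition, max_tss_threshold


def make_records(grid, cells, species="a"):
    out = []
    for r, c in cells:
        x, y = grid.cell_center(r, c)
        out.append(rg.OccurrenceRecord(species, float(x), float(y)))
    return out


class TestSampleBackground:
    @pytest.fixture
    def grid(self):
        return rg.Grid(40, 40)

    def test_caps_at_pool_size(self, grid):
        pool = make_records(grid, [(i, i) for i in range(20)], species="other")
        bg = rg.sample_background("focal", pool, 10000, grid, seed=0)
        assert len(bg) == 20

    def test_focal_records_excluded(self, grid):
        pool = make_records(grid, [(0, 0), (1, 1)], species="focal") + make_records(
            grid, [(2, 2), (3, 3)], species="other"
        )
        bg = rg.sample_background("focal", pool, 10, grid, seed=0)
        assert {tuple(c) for c in bg} == {(2, 2), (3, 3)}

    def test_deterministic(self, grid):
        pool = make_records(grid, [(i, j) for i in range(30) for j in range(10)],
                            species="other")
        a = rg.sample_background("focal", pool, 50, grid, seed=5)
        b = rg.sample_background("focal", pool, 50, grid, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empty_pool_rejected(self, grid):
        with pytest.raises(ValueError, match="empty background pool"):
            rg.sample_background("focal", make_records(grid, [(0, 0)], "focal"),
                                 10, grid, seed=0)


class TestSplit:
    @pytest.mark.parametrize("n,expected_train", [(10, 7), (15, 11), (2, 1), (3, 2)])
    def test_round_half_up_with_floor(self, n, expected_train):
        pres = np.arange(n * 2).reshape(n, 2)
        bg = np.arange(40).reshape(20, 2)
        part = rg.split_train_test(pres, bg, 0.7, seed=0)
        assert len(part.train_presence) == expected_train
        assert len(part.test_presence) == n - expected_train
        assert len(part.train_background) == 14

    def test_partition_is_disjoint_and_complete(self):
        pres = np.arange(26).reshape(13, 2)
        part = rg.split_train_test(pres, np.arange(20).reshape(10, 2), 0.7, seed=1)
        joined = {tuple(c) for c in part.train_presence} | {
            tuple(c) for c in part.test_presence
        }
        assert joined == {tuple(c) for c in pres}
        assert len(part.train_presence) + len(part.test_presence) == 13

    def test_single_presence_rejected(self):
        with pytest.raises(ValueError):
            rg.split_train_test(np.array([[0, 0]]), np.arange(8).reshape(4, 2), 0.7, 0)


class TestTSS:
    def test_perfect_separation(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert rg.compute_tss(scores, labels, 0.5) == pytest.approx(1.0)

    def test_all_predicted_presence_is_no_skill(self):
        scores = np.full(20, 0.8)
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert rg.compute_tss(scores, labels, 0.5) == pytest.approx(0.0)

    def test_hand_computed_confusion_table(self):
        # a=40 hits, c=5 misses, b=10 false alarms, d=45 correct rejections
        scores = np.r_[np.full(40, 0.9), np.full(5, 0.1), np.full(10, 0.9), np.full(45, 0.1)]
        labels = np.r_[np.ones(45, bool), np.zeros(55, bool)]
        expected = 40 / 45 + 45 / 55 - 1
        assert rg.compute_tss(scores, labels, 0.5) == pytest.approx(expected, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rg.compute_tss(np.ones(5), np.ones(5, bool), 0.5)


class TestEnsemble:
    def _model(self, tss, value, grid):
        layer = rg.Layer(grid, np.full(grid.shape, value))
        return rg.FittedModel("t", layer, tss)

    def test_single_model_identity(self):
        grid = rg.Grid(5, 5)
        m = self._model(0.9, 0.4, grid)
        ens = rg.ensemble([m], 0.7)
        assert ens.kept
        np.testing.assert_allclose(ens.suitability.values, 0.4)
        assert ens.ensemble_tss == pytest.approx(0.9)

    def test_weights_are_normalized_tss(self):
        grid = rg.Grid(5, 5)
        ens = rg.ensemble([self._model(0.8, 1.0, grid), self._model(0.72, 0.0, grid)], 0.7)
        # weighted mean: 1.0 * 0.8/1.52 + 0.0 * 0.72/1.52
        np.testing.assert_allclose(ens.suitability.values, 0.8 / 1.52)

    def test_low_tss_members_excluded(self):
        grid = rg.Grid(5, 5)
        ens = rg.ensemble([self._model(0.9, 1.0, grid), self._model(0.5, 0.0, grid)], 0.7)
        assert len(ens.contributing) == 1
        np.testing.assert_allclose(ens.suitability.values, 1.0)

    def test_all_below_cutoff_not_kept(self):
        grid = rg.Grid(5, 5)
        ens = rg.ensemble([self._model(0.6, 1.0, grid), self._model(0.7, 0.0, grid)], 0.7)
        assert not ens.kept and ens.suitability is None

    def test_bounded_by_member_range(self):
        grid = rg.Grid(6, 6)
        rng = np.random.default_rng(0)
        models = [
            rg.FittedModel("t", rg.Layer(grid, rng.random(grid.shape)), tss)
            for tss in (0.75, 0.8, 0.95)
        ]
        ens = rg.ensemble(models, 0.7)
        stack = np.stack([m.suitability.values for m in models])
        assert np.all(ens.suitability.values >= stack.min(axis=0) - 1e-12)
        assert np.all(ens.suitability.values <= stack.max(axis=0) + 1e-12)


class TestDistanceDecay:
    def test_multiplier_closed_form(self):
        grid = rg.Grid(1, 21)
        suit = rg.Layer(grid, np.ones((1, 21)))
        out = rg.apply_distance_decay(suit, np.array([[0, 0]]), decay_distance=5.0)
        assert out.values[0, 0] == pytest.approx(1.0)  # d = 0
        assert out.values[0, 5] == pytest.approx(np.exp(-1.0))  # d = delta
        assert out.values[0, 10] == pytest.approx(np.exp(-2.0))

    def test_large_delta_is_identity(self):
        grid = rg.Grid(10, 10)
        rng = np.random.default_rng(1)
        suit = rg.Layer(grid, rng.random(grid.shape))
        out = rg.apply_distance_decay(suit, np.array([[5, 5]]), decay_distance=1e9)
        np.testing.assert_allclose(out.values, suit.values, atol=1e-6)

    def test_never_increases_values(self):
        grid = rg.Grid(15, 15)
        rng = np.random.default_rng(2)
        suit = rg.Layer(grid, rng.random(grid.shape))
        out = rg.apply_distance_decay(suit, np.array([[0, 0], [7, 7]]), 3.0)
        assert np.all(out.values <= suit.values + 1e-15)

    def test_binary_area_non_increasing_in_restriction(self):
        grid = rg.Grid(20, 20)
        rng = np.random.default_rng(3)
        suit = rg.Layer(grid, rng.random(grid.shape))
        pres = np.array([[10, 10]])
        areas = []
        for delta in (50.0, 10.0, 3.0, 1.0):  # increasing restriction 1/delta
            out = rg.apply_distance_decay(suit, pres, delta)
            areas.append(int((out.values >= 0.3).sum()))
        assert areas == sorted(areas, reverse=True)

    def test_no_presences_rejected(self):
        grid = rg.Grid(5, 5)
        with pytest.raises(ValueError):
            rg.apply_distance_decay(rg.Layer(grid, np.ones(grid.shape)),
                                    np.empty((0, 2), int), 5.0)


class TestBinarize:
    def test_tie_goes_to_lowest_threshold(self):
        grid = rg.Grid(1, 4)
        suit = rg.Layer(grid, np.array([[0.9, 0.9, 0.1, 0.1]]))
        cells = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        labels = np.array([True, True, False, False])
        binary, thr = rg.binarize_max_tss(suit, cells, labels)
        assert thr == pytest.approx(0.11)
        assert binary.count() == 2

    def test_degenerate_all_equal_scores(self):
        grid = rg.Grid(1, 4)
        suit = rg.Layer(grid, np.full((1, 4), 0.5))
        cells = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        labels = np.array([True, False, True, False])
        binary, thr = rg.binarize_max_tss(suit, cells, labels)
        assert thr == 0.0
        assert binary.count() == 4  # all-presence map

    def test_chosen_threshold_maximizes_tss_over_grid(self):
        rng = np.random.default_rng(4)
        grid = rg.Grid(10, 10)
        suit = rg.Layer(grid, rng.random(grid.shape))
        cells = np.array([[i, j] for i in range(10) for j in range(10)])
        labels = rng.random(100) < suit.values[cells[:, 0], cells[:, 1]]
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, thr = rg.binarize_max_tss(suit, cells, labels)
        scores = suit.values[cells[:, 0], cells[:, 1]]
        best = rg.compute_tss(scores, labels, thr)
        for t in np.arange(0, 101) * 0.01:
            assert best >= rg.compute_tss(scores, labels, t) - 1e-12

    def test_binary_area_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        grid = rg.Grid(10, 10)
        suit = rg.Layer(grid, rng.random(grid.shape))
        areas = [int((suit.values >= t).sum()) for t in np.linspace(0, 1, 20)]
        assert areas == sorted(areas, reverse=True)


class TestFitSuitability:
    @pytest.fixture(scope="class")
    def landscape(self):
        grid = rg.Grid(40, 40)
        preds = rg.make_predictors(grid, 3, seed=10)
        return grid, preds

    def _partition_for_highend(self, grid, preds, rng, n_pres=40, n_bg=300):
        """Presences where predictor 0 is in its top decile."""
        v = preds[0].values
        cut = np.nanquantile(v, 0.9)
        pres_pool = np.argwhere(v >= cut)
        bg_pool = np.argwhere(~grid.nodata_mask)
        pres = pres_pool[rng.choice(len(pres_pool), n_pres, replace=False)]
        bg = bg_pool[rng.choice(len(bg_pool), n_bg, replace=False)]
        return rg.split_train_test(pres, bg, 0.7, seed=int(rng.integers(2**31)))

    @pytest.mark.parametrize("technique", ["logistic", "envelope"])
    def test_recovers_high_end_niche(self, landscape, technique):
        grid, preds = landscape
        rng = np.random.default_rng(11)
        part = self._partition_for_highend(grid, preds, rng)
        fm = rg.fit_suitability(part, preds, technique, seed=0)
        assert fm.tss > 0.7
        assert np.nanmin(fm.suitability.values) >= 0
        assert np.nanmax(fm.suitability.values) <= 1

    def test_shuffled_labels_give_no_skill(self, landscape):
        grid, preds = landscape
        rng = np.random.default_rng(12)
        cells = np.argwhere(~grid.nodata_mask)
        chosen = cells[rng.choice(len(cells), 500, replace=False)]
        pres, bg = chosen[:250], chosen[250:]  # random split: no signal
        part = rg.split_train_test(pres, bg, 0.7, seed=0)
        fm = rg.fit_suitability(part, preds, "logistic", seed=0)
        assert abs(fm.tss) < 0.15

    def test_deterministic(self, landscape):
        grid, preds = landscape
        rng = np.random.default_rng(13)
        part = self._partition_for_highend(grid, preds, rng)
        a = rg.fit_suitability(part, preds, "logistic", seed=3)
        b = rg.fit_suitability(part, preds, "logistic", seed=3)
        np.testing.assert_array_equal(a.suitability.values, b.suitability.values)
        assert a.tss == b.tss

    def test_unknown_technique_rejected(self, landscape):
        grid, preds = landscape
        part = Partition(*(np.array([[0, 0], [1, 1]]),) * 4)
        with pytest.raises(ValueError, match="unknown technique"):
            rg.fit_suitability(part, preds, "maxent")


class TestRangeRecovery:
    def test_noise_free_species_recovered_with_good_jaccard(self):
        """On an error-free scenario with ~50 unique presence cells per
        species and a dense target-group background pool, the binarized
        ensemble overlaps the true range with median Jaccard >= 0.7 across
        kept species."""
        scen = rg.generate_scenario(
            rg.ScenarioConfig(
                n_species=100, n_per_species=70, error_rates=rg.ErrorRates(), seed=0
            )
        )
        cfg = rg.RunConfig(seed=0)
        res = rg.run_on_scenario(scen, cfg, run_prioritization=False)
        truth = {sp.species_id: sp.true_range.as_bool for sp in scen.species}
        jacc = []
        for sid, rng_mask in res.ranges.items():
            a, b = truth[sid], rng_mask.as_bool
            jacc.append((a & b).sum() / (a | b).sum())
        assert len(jacc) >= 20
        assert np.median(jacc) >= 0.7
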