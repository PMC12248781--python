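"""Habitat MLP: training table, learning behavior, raster prediction, ROC/AUC."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import treegrid as tg
from treegrid.errors import ValidationError


def make_samples(x, y):
    return [tg.TrainingSample(*row, label=int(lab)) for row, lab in zip(x, y)]


def separable_samples(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(-1.5, 1.0, size=(n // 2, 5))
    x1 = rng.normal(1.5, 1.0, size=(n - n // 2, 5))
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    return make_samples(x, y)


class TestBuildTrainingTable:
    def test_labels_follow_bird_support(self, small_db, lst_grid):
        # Ficus & Azadirachta support birds; Cassia does not
        locs = [lst_grid.pixel_center(i, i) for i in (5, 10, 15)]
        layout = tg.PlantingLayout()
        for name, loc in zip(["Ficus religiosa", "Azadirachta indica", "Cassia fistula"], locs):
            tg.place_tree(layout, name, loc, small_db)
        samples = tg.build_training_table(layout, small_db, lst_grid)
        assert [s.label for s in samples] == [1, 1, 0]

    def test_features_match_scores_and_raster(self, small_db, lst_grid):
        loc = lst_grid.pixel_center(7, 9)
        layout = tg.place_tree(tg.PlantingLayout(), "Dalbergia sissoo", loc, small_db)
        (sample,) = tg.build_training_table(layout, small_db, lst_grid)
        sp = small_db.get("Dalbergia sissoo")
        scores = tg.derive_scores(sp.name, small_db)
        assert sample.lst == pytest.approx(lst_grid.value_at(loc))
        assert sample.cooling_index == scores.cooling_index
        assert sample.shade_index == scores.shade_index
        assert sample.height == sp.tree_height
        assert sample.diameter == sp.canopy_width

    def test_offgrid_tree_dropped_with_warning(self, small_db, lst_grid, caplog):
        layout = tg.PlantingLayout()
        tg.place_tree(layout, "Cassia fistula", lst_grid.pixel_center(3, 3), small_db)
        tg.place_tree(layout, "Cassia fistula", tg.GeoPoint(0.0, 0.0), small_db)
        with caplog.at_level("WARNING"):
            samples = tg.build_training_table(layout, small_db, lst_grid)
        assert len(samples) == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_all_dropped_is_error(self, small_db, lst_grid):
        layout = tg.place_tree(tg.PlantingLayout(), "Cassia fistula", tg.GeoPoint(0, 0), small_db)
        with pytest.raises(ValidationError):
            tg.build_training_table(layout, small_db, lst_grid)


class TestTrain:
    def test_separable_clusters_reach_high_accuracy(self):
        model = tg.train(separable_samples(200, seed=0), tg.ModelConfig(seed=1))
        assert model.history.iloc[-1].train_acc >= 0.95

    def test_random_labels_stay_near_chance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, size=200)
        model = tg.train(make_samples(x, y), tg.ModelConfig(seed=2))
        assert 0.35 <= model.history.iloc[-1].val_acc <= 0.65

    def test_deterministic_given_seed(self):
        samples = separable_samples(60, seed=3)
        cfg = tg.ModelConfig(seed=9, epochs=20)
        m1, m2 = tg.train(samples, cfg), tg.train(samples, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        assert m1.history.equals(m2.history)

    def test_history_length_and_split_sizes(self):
        model = tg.train(separable_samples(50, seed=1), tg.ModelConfig(seed=0, epochs=12))
        assert len(model.history) == 12
        assert list(model.history.columns) == ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            tg.train(separable_samples(8, seed=0))

    def test_single_class_split_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 5))
        samples = make_samples(x, np.zeros(40))
        with pytest.raises(ValidationError, match="single class"):
            tg.train(samples, tg.ModelConfig(seed=0, epochs=1))

    def test_normalizer_uses_training_split_only(self):
        """Changing validation-side samples must not move the normalizer stats."""
        samples = separable_samples(100, seed=5)
        cfg = tg.ModelConfig(seed=4, epochs=1)
        base = tg.train(samples, cfg)
        order = np.random.default_rng(cfg.seed).permutation(100)
        val_idx = set(order[int(round(0.8 * 100)) :])
        perturbed = [
            tg.TrainingSample(s.lst + 100, s.cooling_index, s.shade_index, s.height, s.diameter, s.label)
            if i in val_idx
            else s
            for i, s in enumerate(samples)
        ]
        again = tg.train(perturbed, cfg)
        assert np.array_equal(base.norm_mean, again.norm_mean)
        assert np.array_equal(base.norm_std, again.norm_std)

    def test_linear_score_label_recovery_auc(self):
        """Labels driven by a noisy linear score of the features are learnable:
        held-out AUC >= 0.8."""
        rng = np.random.default_rng(42)
        x = rng.normal(size=(400, 5))
        w = np.array([1.0, -0.8, 0.6, 1.2, -0.5])
        score = x @ w + rng.normal(0, 0.5, size=400)
        y = (score > np.median(score)).astype(int)
        samples = make_samples(x, y)
        cfg = tg.ModelConfig(seed=3)
        model = tg.train(samples, cfg)
        order = np.random.default_rng(cfg.seed).permutation(400)
        val = order[int(round(0.8 * 400)) :]
        xn = (x[val] - model.norm_mean) / model.norm_std
        auc = tg.roc_auc(y[val], model.forward(xn)).auc
        assert auc >= 0.8


class TestPredict:
    def zero_model(self):
        sizes = [5, 2, 2, 1]
        weights = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            weights.append(np.zeros((a, b)))
            weights.append(np.zeros(b))
        import pandas as pd

        return tg.HabitatModel(
            weights=weights,
            norm_mean=np.zeros(5),
            norm_std=np.ones(5),
            feature_means=np.zeros(5),
            history=pd.DataFrame(),
            config=tg.ModelConfig(hidden_sizes=(2, 2)),
        )

    def test_zero_weights_give_half(self):
        assert tg.predict_proba(self.zero_model(), [1, 2, 3, 4, 5]) == 0.5

    def test_hand_computed_one_unit_network(self):
        import pandas as pd

        # 5 -> 1 -> 1 -> 1 with all-ones weights on feature 0 only
        weights = [
            np.array([[1.0], [0.0], [0.0], [0.0], [0.0]]), np.array([0.5]),
            np.array([[2.0]]), np.array([-1.0]),
            np.array([[1.5]]), np.array([0.25]),
        ]
        model = tg.HabitatModel(
            weights=weights, norm_mean=np.zeros(5), norm_std=np.ones(5),
            feature_means=np.zeros(5), history=pd.DataFrame(),
            config=tg.ModelConfig(hidden_sizes=(1, 1)),
        )
        x0 = 0.8
        h1 = max(0.0, x0 * 1.0 + 0.5)
        h2 = max(0.0, h1 * 2.0 - 1.0)
        z = h2 * 1.5 + 0.25
        expected = 1.0 / (1.0 + math.exp(-z))
        assert tg.predict_proba(model, [x0, 0, 0, 0, 0]) == pytest.approx(expected, abs=1e-12)

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValidationError):
            tg.predict_proba(self.zero_model(), [1, 2, 3])

    def test_repeat_call_identical(self):
        model = tg.train(separable_samples(50, seed=2), tg.ModelConfig(seed=1, epochs=5))
        f = [0.3, 5.0, 200.0, 20.0, 10.0]
        assert tg.predict_proba(model, f) == tg.predict_proba(model, f)

    def test_save_load_roundtrip(self, tmp_path):
        model = tg.train(separable_samples(50, seed=2), tg.ModelConfig(seed=1, epochs=5))
        p = tmp_path / "model.json"
        model.save(p)
        back = tg.HabitatModel.load(p)
        f = [0.1, 4.0, 100.0, 15.0, 8.0]
        assert tg.predict_proba(back, f) == pytest.approx(tg.predict_proba(model, f), abs=1e-12)
        assert back.history.shape == model.history.shape


class TestPredictRaster:
    @pytest.fixture
    def model(self):
        return tg.train(separable_samples(80, seed=6), tg.ModelConfig(seed=5, epochs=10))

    def test_constant_lst_gives_constant_surface(self, model):
        grid = tg.LSTGrid(np.full((8, 8), 0.7, dtype=np.float32), 78.0, 30.35, 0.00027)
        prob = tg.predict_raster(model, grid)
        assert np.unique(prob.values).size == 1
        assert 0.0 < prob.values[0, 0] < 1.0

    def test_nodata_preserved(self, model):
        vals = np.full((6, 6), 0.5, dtype=np.float32)
        vals[2, 3] = np.nan
        prob = tg.predict_raster(model, tg.LSTGrid(vals, 78.0, 30.35, 0.00027))
        assert np.isnan(prob.values[2, 3])
        assert np.isnan(prob.values).sum() == 1

    def test_matches_pointwise_prediction(self, model):
        grid = tg.LSTGrid(
            np.linspace(0, 1, 16, dtype=np.float32).reshape(4, 4), 78.0, 30.35, 0.00027
        )
        prob = tg.predict_raster(model, grid)
        r, c = 2, 3
        f = np.concatenate(([grid.values[r, c]], model.feature_means[1:]))
        assert prob.values[r, c] == pytest.approx(tg.predict_proba(model, f), abs=1e-6)


class TestClassifyHotspots:
    def _grid(self, fill):
        return tg.LSTGrid(np.full((4, 4), fill, dtype=np.float32), 78.0, 30.35, 0.00027)

    def test_above_threshold_all_one(self):
        assert (tg.classify_hotspots(self._grid(0.9)).values == 1).all()

    def test_below_threshold_all_zero(self):
        assert (tg.classify_hotspots(self._grid(0.4)).values == 0).all()

    def test_exactly_half_is_not_hotspot(self):
        assert (tg.classify_hotspots(self._grid(0.5)).values == 0).all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            tg.classify_hotspots(self._grid(0.5), threshold=1.5)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        assert tg.roc_auc([1, 0], [0.9, 0.1]).auc == 1.0
        assert tg.roc_auc([1, 0], [0.1, 0.9]).auc == 0.0

    def test_chance_level_on_independent_scores(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=10_000)
        s = rng.random(10_000)
        assert tg.roc_auc(y, s).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            tg.roc_auc([1, 1], [0.2, 0.8])

    def test_rank_auc_equals_trapezoid_and_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=500)
        s = np.round(rng.random(500), 2)  # coarse scores force ties
        res = tg.roc_auc(y, s)
        trapezoid = np.trapezoid(res.tpr, res.fpr)
        assert res.auc == pytest.approx(trapezoid, abs=1e-9)
        assert res.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(4)
        res = tg.roc_auc(rng.integers(0, 2, 50), rng.random(50))
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()
        assert res.fpr[0] == 0 and res.tpr[0] == 0 and res.fpr[-1] == 1 and res.tpr[-1] == 1


class TestEndToEndDeterminism:
    def test_pipeline_reproducible_with_seed(self, synth_db, lst_grid, raster_polygon):
        def run():
            layout = tg.gen_layout(raster_polygon, synth_db, 40, seed=8)
            samples = tg.build_training_table(layout, synth_db, lst_grid)
            model = tg.train(samples, tg.ModelConfig(seed=8, epochs=15))
            prob = tg.predict_raster(model, lst_grid)
            return model, prob

        m1, p1 = run()
        m2, p2 = run()
        assert m1.history.equals(m2.history)
        assert np.array_equal(p1.values, p2.values, equal_nan=True)
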