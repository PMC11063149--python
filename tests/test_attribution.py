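import warnings

import numpy as np
import pytest

from deepmapper.attribution import (
    OVERALL,
    accumulate_attributions,
    attribute_correct,
    rank_features,
)
from deepmapper.folding import compute_fold_spec, fold_vector
from deepmapper.nn import make_network


class OnePixelModel:
    """Linear stand-in whose logits depend on exactly one pixel.

    logit[c] = w[c] * x[pixel]; the input gradient is therefore w[target]
    at that pixel and 0 everywhere else — computable by hand, which makes it
    an oracle for the attribution plumbing.
    """

    def __init__(self, pixel: tuple[int, int], w=(-1.0, 1.0)):
        self.pixel = pixel
        self.w = np.asarray(w)

    def forward(self, x, train=False):
        r, c = self.pixel
        return x[:, 0, r, c][:, None] * self.w[None, :]

    def input_gradient(self, x, targets, contrast=False):
        g = np.zeros_like(np.asarray(x, dtype=np.float64))
        r, c = self.pixel
        w = self.w[targets]
        if contrast:
            # logit difference: target weight minus mean of the others
            other = (self.w.sum() - self.w[targets]) / (len(self.w) - 1)
            w = w - other
        g[:, 0, r, c] = w
        return g


class TestAttributeCorrect:
    @pytest.mark.parametrize("method", ["saliency", "integrated-gradients"])
    def test_one_pixel_model_concentrates_all_attribution(self, method):
        rng = np.random.default_rng(0)
        x = rng.random((20, 1, 6, 6))
        model = OnePixelModel((2, 3))
        labels = (x[:, 0, 2, 3] > 0.5).astype(int)
        preds = model.forward(x).argmax(axis=1)
        maps, mask = attribute_correct(model, x, labels, preds, method=method)
        assert maps.shape == (mask.sum(), 6, 6)
        total = np.abs(maps).sum()
        on_pixel = np.abs(maps[:, 2, 3]).sum()
        assert on_pixel / total >= 0.99

    def test_only_correct_samples_contribute(self):
        x = np.random.default_rng(1).random((10, 1, 4, 4))
        model = OnePixelModel((0, 0))
        preds = model.forward(x).argmax(axis=1)
        labels = preds.copy()
        labels[:4] = 1 - labels[:4]  # force 4 mistakes
        maps, mask = attribute_correct(model, x, labels, preds)
        assert mask.sum() == 6 and maps.shape[0] == 6

    def test_all_misclassified_warns_and_returns_empty(self):
        x = np.random.default_rng(2).random((5, 1, 4, 4))
        model = OnePixelModel((0, 0))
        preds = model.forward(x).argmax(axis=1)
        labels = 1 - preds
        with pytest.warns(UserWarning):
            maps, mask = attribute_correct(model, x, labels, preds)
        assert maps.shape[0] == 0 and not mask.any()

    def test_unknown_method_rejected(self):
        x = np.zeros((1, 1, 4, 4))
        with pytest.raises(ValueError, match="saliency"):
            attribute_correct(
                OnePixelModel((0, 0)), x, np.array([0]), np.array([0]),
                method="shap",
            )

    def test_works_with_real_network(self):
        net = make_network("small", 2, seed=0)
        x = np.random.default_rng(3).random((4, 1, 16, 16)).astype(np.float32)
        labels = np.array([0, 1, 0, 1])
        preds = net.predict(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps, mask = attribute_correct(net, x, labels, preds)
        assert maps.shape[1:] == (16, 16)
        assert np.isfinite(maps).all()


class TestAccumulate:
    def test_identical_maps_mean_is_the_map(self):
        m = np.random.default_rng(0).random((1, 3, 3))
        maps = np.concatenate([m, m])
        s = accumulate_attributions(maps, np.array([1, 1]), n_classes=2)
        np.testing.assert_allclose(s.per_class_mean[1], m[0])
        assert list(s.n_samples_per_class) == [0, 2]
        assert s.empty_classes == [0]

    def test_sign_cancellation_prevented_by_absolute_values(self):
        v = np.random.default_rng(1).random((1, 3, 3)) - 0.5
        maps = np.concatenate([v, -v])
        s = accumulate_attributions(maps, np.array([0, 0]), n_classes=1)
        np.testing.assert_allclose(s.per_class_mean[0], np.abs(v[0]))

    def test_classes_accumulate_independently(self):
        rng = np.random.default_rng(2)
        maps = rng.random((6, 4, 4))
        labels = np.array([0, 0, 0, 1, 1, 1])
        base = accumulate_attributions(maps, labels, n_classes=2)
        altered = maps.copy()
        altered[3:] *= 100.0
        again = accumulate_attributions(altered, labels, n_classes=2)
        np.testing.assert_array_equal(
            base.per_class_mean[0], again.per_class_mean[0]
        )

    def test_sample_order_invariant(self):
        rng = np.random.default_rng(3)
        maps = rng.random((8, 2, 2))
        labels = rng.integers(0, 2, 8)
        perm = rng.permutation(8)
        a = accumulate_attributions(maps, labels, n_classes=2)
        b = accumulate_attributions(maps[perm], labels[perm], n_classes=2)
        np.testing.assert_allclose(a.per_class_mean, b.per_class_mean)

    def test_shape_mismatch_rejected(self):
        from deepmapper.attribution import AttributionAccumulator

        acc = AttributionAccumulator(2, 4, "saliency")
        with pytest.raises(ValueError):
            acc.add(np.zeros((1, 3, 3)), np.array([0]))

    def test_pooled_mean_is_count_weighted(self):
        maps = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 1.0),
                         np.full((2, 2), 4.0)])
        s = accumulate_attributions(maps, np.array([0, 0, 1]), n_classes=2)
        np.testing.assert_allclose(s.pooled_mean, np.full((2, 2), 2.0))

    def test_overall_mean_is_per_class_max(self):
        maps = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 4.0)])
        s = accumulate_attributions(maps, np.array([0, 1]), n_classes=2)
        np.testing.assert_allclose(s.overall_mean, np.full((2, 2), 4.0))


class TestRankFeatures:
    def test_uniform_summary_orders_by_feature_index(self):
        spec = compute_fold_spec(6)
        s = accumulate_attributions(
            np.ones((2, 3, 3)), np.array([0, 1]), n_classes=2
        )
        ranking = rank_features(s, spec, [f"f{j}" for j in range(6)])
        for c in (0, 1, OVERALL):
            sub = ranking.table[ranking.table["class"] == c]
            assert sub["feature_index"].tolist() == list(range(6))
            assert sub["rank"].tolist() == list(range(1, 7))

    def test_padding_pixels_never_ranked(self):
        spec = compute_fold_spec(3)  # 2x2 grid, one padding pixel
        maps = np.random.default_rng(0).random((4, 2, 2))
        s = accumulate_attributions(maps, np.array([0, 0, 1, 1]), n_classes=2)
        ranking = rank_features(s, spec, ["a", "b", "c"], include_overall=False)
        assert len(ranking.table) == 2 * 3
        for c in (0, 1):
            sub = ranking.table[ranking.table["class"] == c]
            assert sorted(sub["feature_index"]) == [0, 1, 2]
            assert sub["rank"].tolist() == [1, 2, 3]

    def test_scores_attach_to_features_not_pixels(self):
        # same per-feature attribution signal folded under two different
        # orders must rank identically in feature space
        rng = np.random.default_rng(4)
        f = 10
        per_feature = rng.random((5, f))  # 5 samples, one score per feature
        labels = np.array([0, 1, 0, 1, 0])
        names = [f"g{j}" for j in range(f)]
        results = {}
        for tag, order in (("identity", None), ("permuted", rng.permutation(f))):
            spec = compute_fold_spec(f, order=order)
            maps = np.stack([fold_vector(s, spec) for s in per_feature])
            summ = accumulate_attributions(maps, labels, n_classes=2)
            ranking = rank_features(summ, spec, names)
            sub = ranking.table[ranking.table["class"] == OVERALL]
            results[tag] = dict(zip(sub["feature_name"], sub["mean_score"]))
        assert results["identity"] == pytest.approx(results["permuted"])

    def test_geometry_mismatch_rejected(self):
        s = accumulate_attributions(np.ones((1, 3, 3)), np.array([0]))
        with pytest.raises(ValueError):
            rank_features(s, compute_fold_spec(16), [f"f{j}" for j in range(16)])

    def test_top_helpers(self):
        spec = compute_fold_spec(4)
        maps = np.array([[[0.1, 0.9], [0.3, 0.2]]])
        s = accumulate_attributions(maps, np.array([0]), n_classes=1)
        ranking = rank_features(s, spec, ["w", "x", "y", "z"])
        assert ranking.top_features(0, 2) == ["x", "y"]
        assert ranking.top_indices(0, 2) == [1, 2]
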