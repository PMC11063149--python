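import numpy as np
import pytest

from deepmapper.synthetic import (
    InformativeFeatureSpec,
    NIHSConfig,
    generate_nihs,
    generate_toy_patterns,
)
from deepmapper.training import (
    RunConfig,
    build_model,
    derive_seed,
    run_pipeline,
    split_data,
    train_model,
)


class TestSplitData:
    def test_holdout_size_exact(self):
        labels = np.arange(10_000) % 2
        train, test = split_data(10_000, labels, 0.375, seed=0)
        assert len(test) == 3_750
        assert len(train) == 6_250

    def test_disjoint_exhaustive_stratified(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 600)
        train, test = split_data(600, labels, 0.25, seed=1)
        assert set(train) | set(test) == set(range(600))
        assert set(train) & set(test) == set()
        for c in range(3):
            n_c = (labels == c).sum()
            got = (labels[test] == c).sum()
            assert abs(got - 0.25 * n_c) <= 1

    def test_balanced_classes_balanced_test_set(self):
        labels = np.arange(400) % 2
        _, test = split_data(400, labels, 0.5, seed=3)
        counts = np.bincount(labels[test])
        assert abs(int(counts[0]) - int(counts[1])) <= 1

    def test_reproducible_and_seed_sensitive(self):
        labels = np.arange(100) % 2
        a = split_data(100, labels, 0.3, seed=7)
        b = split_data(100, labels, 0.3, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        c = split_data(100, labels, 0.3, seed=8)
        assert not np.array_equal(a[1], c[1])

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            split_data(10, np.arange(10) % 2, fraction, seed=0)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            split_data(5, np.array([0, 0, 0, 0, 1]), 0.4, seed=0)


class TestDeriveSeed:
    def test_deterministic_distinct_and_bounded(self):
        s = derive_seed(1, 0, "split")
        assert s == derive_seed(1, 0, "split")
        assert 0 <= s < 2**31
        others = {derive_seed(1, i, st) for i in range(3)
                  for st in ("split", "init", "train")}
        assert len(others) == 9


class TestBuildModel:
    def test_one_code_path_for_different_sides(self):
        model = build_model(135, 2, arch="small", seed=0)
        for side in (135, 139):
            logits = model.forward(np.zeros((1, 1, side, side)), train=False)
            assert logits.shape == (1, 2) and np.isfinite(logits).all()

    def test_too_small_side_rejected(self):
        with pytest.raises(ValueError):
            build_model(8, 2)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="resnet18"):
            build_model(32, 2, arch="nope")


@pytest.fixture(scope="module")
def toy_run():
    """One seeded training run on easy toy patterns, shared across tests."""
    images, labels = generate_toy_patterns(400, side=28, noise_sd=0.05, seed=0)
    config = RunConfig(epochs=5, arch="small", seed=0, accuracy_target=0.95,
                       batch_size=32)
    train_idx, test_idx = split_data(400, labels, 0.25, seed=1)
    model = build_model(28, 2, "small", seed=2)
    result = train_model(
        model,
        (images[train_idx], labels[train_idx]),
        (images[test_idx], labels[test_idx]),
        config,
        seed=3,
    )
    return result, labels[test_idx]


class TestTrainModel:
    def test_learns_toy_patterns(self, toy_run):
        result, _ = toy_run
        assert result.best_test_accuracy >= 0.95
        assert result.epochs_run <= 5

    def test_metric_arrays_match_epochs_run(self, toy_run):
        result, _ = toy_run
        n = result.epochs_run
        assert len(result.train_loss) == n
        assert len(result.train_accuracy) == n
        assert len(result.test_loss) == n
        assert all(0 <= a <= 1 for a in result.test_accuracy)

    def test_correctness_flags_consistent(self, toy_run):
        result, y_test = toy_run
        np.testing.assert_array_equal(
            result.correct, result.predictions == y_test
        )

    def test_permuted_labels_stay_at_chance(self):
        images, labels = generate_toy_patterns(200, side=16, noise_sd=0.05,
                                               seed=4)
        labels = np.random.default_rng(5).permutation(labels)
        config = RunConfig(epochs=3, arch="small", seed=0,
                           accuracy_target=0.999)
        train_idx, test_idx = split_data(200, labels, 0.3, seed=6)
        model = build_model(16, 2, "small", seed=7)
        result = train_model(
            model,
            (images[train_idx], labels[train_idx]),
            (images[test_idx], labels[test_idx]),
            config,
            seed=8,
        )
        assert abs(result.test_accuracy[-1] - 0.5) <= 0.1


def tiny_nihs(seed=0, n_obs=240, n_features=400):
    return generate_nihs(NIHSConfig(
        n_obs=n_obs, n_features=n_features,
        informative=[
            InformativeFeatureSpec(20, {0: (0.00, 0.20), 1: (0.20, 0.40)}),
        ],
        seed=seed,
    ))


class TestRunPipeline:
    def test_single_iteration(self):
        table = tiny_nihs()
        config = RunConfig(epochs=1, max_iterations=1, arch="small", seed=0)
        result = run_pipeline(table, config)
        assert len(result.iterations) == 1
        assert result.fold_spec.side == 20

    def test_degenerate_tolerance_stops_after_two_iterations(self):
        table = tiny_nihs(seed=1)
        config = RunConfig(epochs=1, max_iterations=5, convergence_tol=1.0,
                           arch="small", seed=0)
        result = run_pipeline(table, config)
        assert len(result.iterations) == 2

    def test_splits_differ_across_iterations_but_stay_stratified(self):
        table = tiny_nihs(seed=2)
        config = RunConfig(epochs=1, max_iterations=2, convergence_tol=0.0,
                           arch="small", seed=0, holdout_fraction=0.25)
        result = run_pipeline(table, config)
        it0, it1 = result.iterations
        assert not np.array_equal(it0.test_indices, it1.test_indices)
        for it in (it0, it1):
            assert len(it.test_indices) == round(0.25 * table.n_obs)
            counts = np.bincount(table.labels[it.test_indices])
            assert abs(int(counts[0]) - int(counts[1])) <= 1
            assert set(it.train_indices) & set(it.test_indices) == set()

    def test_unlabelled_table_rejected(self):
        table = tiny_nihs()
        table.labels = None
        with pytest.raises(ValueError):
            run_pipeline(table, RunConfig())

    def test_signal_free_accuracy_near_chance(self):
        # no planted features: mean held-out accuracy over 3 iterations must
        # hover around 0.5 for balanced binary labels
        table = generate_nihs(NIHSConfig(
            n_obs=300, n_features=256, informative=[], seed=5
        ))
        config = RunConfig(epochs=2, max_iterations=3, convergence_tol=0.0,
                           arch="small", seed=1, accuracy_target=1.01)
        result = run_pipeline(table, config)
        mean_acc = float(np.mean(
            [it.test_accuracy[-1] for it in result.iterations]
        ))
        assert 0.4 <= mean_acc <= 0.6
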