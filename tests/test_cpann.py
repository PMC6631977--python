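import numpy as np
import pytest

from nirdx import errors
from nirdx.cpann import (
    CPANNModel,
    accuracy_pct,
    cross_validate,
    init_map,
    one_hot,
    predict,
    project_map,
    train,
    _grouped_stratified_folds,
)
from nirdx.spectra_io import Label

from conftest import make_meta


def nearest_prototype_oracle(scores, labels, queries):
    """Independent oracle: classify by nearest per-class training mean."""
    centers = {c: scores[labels == c].mean(axis=0) for c in np.unique(labels)}
    out = []
    for q in queries:
        out.append(min(centers, key=lambda c: np.linalg.norm(q - centers[c])))
    return np.asarray(out)


class TestInit:
    def test_same_seed_bit_identical(self):
        a = init_map(5, 3, seed=42)
        b = init_map(5, 3, seed=42)
        np.testing.assert_array_equal(a.kohonen_w, b.kohonen_w)
        np.testing.assert_array_equal(a.output_w, b.output_w)

    def test_output_weights_start_uninformative(self):
        model = init_map(4, 2, C=2, seed=0)
        np.testing.assert_array_equal(model.output_w, np.full((4, 4, 2), 0.5))

    def test_single_neuron_map_allowed(self):
        assert init_map(1, 2, seed=0).kohonen_w.shape == (1, 1, 2)

    def test_invalid_dimensions(self):
        with pytest.raises(errors.ParameterError):
            init_map(0, 2, seed=0)


class TestTraining:
    def test_single_neuron_radius_zero_closed_form(self):
        # one neuron, one epoch, constant lr: w <- w + lr (x - w) per sample
        model = init_map(1, 2, seed=9)
        X = np.array([[1.0, 2.0], [3.0, 0.0]])
        Y = one_hot([0, 1], [0, 1])
        trained = train(model, X, Y, epochs=1, lr_start=0.3, lr_end=0.3, shuffle=False)
        lo, hi = X.min(axis=0), X.max(axis=0)
        w = lo + model.kohonen_w[0, 0] * (hi - lo)  # rescaled initial weight
        for x in X:
            w = w + 0.3 * (x - w)
        np.testing.assert_allclose(trained.kohonen_w[0, 0], w, atol=1e-12)

    def test_order_invariance_with_distinct_winners(self):
        # radius 0, constant lr, each point winning its own neuron: updates
        # are independent, so presentation order cannot matter
        base = init_map(2, 1, seed=0)
        base.kohonen_w = np.array([[[0.0], [5.0]], [[10.0], [15.0]]])
        base.trained = True  # skip range rescaling; weights set explicitly
        X = np.array([[0.5], [14.0]])
        Y = one_hot([0, 1], [0, 1])
        fwd = train(base, X, Y, epochs=1, lr_start=0.4, lr_end=0.4, shuffle=False)
        rev = train(base, X[::-1], Y[::-1], epochs=1, lr_start=0.4, lr_end=0.4, shuffle=False)
        np.testing.assert_allclose(fwd.kohonen_w, rev.kohonen_w, atol=1e-12)
        # and the update itself matches the hand-computed two-step result
        np.testing.assert_allclose(fwd.kohonen_w[0, 0, 0], 0.0 + 0.4 * 0.5)
        np.testing.assert_allclose(fwd.kohonen_w[1, 1, 0], 15.0 + 0.4 * (14.0 - 15.0))

    def test_determinism(self, separable_clusters):
        scores, labels = separable_clusters
        Y = one_hot(labels, [0, 1])
        a = train(init_map(3, 2, seed=11), scores, Y, epochs=20)
        b = train(init_map(3, 2, seed=11), scores, Y, epochs=20)
        np.testing.assert_array_equal(a.kohonen_w, b.kohonen_w)
        np.testing.assert_array_equal(a.output_w, b.output_w)

    def test_output_layer_stays_on_simplex(self, separable_clusters):
        scores, labels = separable_clusters
        for epochs in (1, 5, 50):
            model = train(
                init_map(4, 2, seed=2), scores, one_hot(labels, [0, 1]), epochs=epochs
            )
            assert model.output_w.min() >= 0.0 and model.output_w.max() <= 1.0
            np.testing.assert_allclose(model.output_w.sum(axis=2), 1.0, atol=1e-6)

    def test_two_cluster_oracle_equivalence(self, separable_clusters):
        scores, labels = separable_clusters
        model = train(
            init_map(2, 2, seed=3), scores, one_hot(labels, [0, 1]), epochs=100
        )
        predicted, _ = predict(model, scores)
        oracle = nearest_prototype_oracle(scores, labels, scores)
        np.testing.assert_array_equal(predicted, oracle)
        assert accuracy_pct(model, scores, labels) == 100.0

    def test_accuracy_non_decreasing_in_map_size(self, separable_clusters):
        scores, labels = separable_clusters
        Y = one_hot(labels, [0, 1])
        small = train(init_map(2, 2, seed=4), scores, Y, epochs=50)
        large = train(init_map(12, 2, seed=4), scores, Y, epochs=50)
        assert accuracy_pct(large, scores, labels) >= accuracy_pct(small, scores, labels)

    def test_label_rows_must_be_one_hot(self):
        with pytest.raises(errors.LabelError):
            train(init_map(2, 1, seed=0), np.ones((2, 1)), np.array([[0.5, 0.5], [1, 0]]))

    def test_empty_data_rejected(self):
        with pytest.raises(errors.DataError):
            train(init_map(2, 1, seed=0), np.empty((0, 1)), np.empty((0, 2)))


class TestPrediction:
    def test_argmax_of_winner_output(self):
        model = init_map(1, 1, seed=0)
        model.trained = True
        model.output_w = np.array([[[0.2, 0.8]]])
        labels, coords = predict(model, np.array([[0.5]]))
        assert labels[0] == 1 and coords == [(0, 0)]

    def test_exact_weight_vector_wins(self):
        model = init_map(3, 2, seed=5)
        model.trained = True
        labels, coords = predict(model, model.kohonen_w[1, 2][np.newaxis, :])
        assert coords[0] == (1, 2)

    def test_untrained_model_refuses(self):
        with pytest.raises(errors.StateError):
            predict(init_map(2, 2, seed=0), np.ones((1, 2)))


class TestProjectionMap:
    def test_regions_partition_and_markers(self, separable_clusters):
        scores, labels = separable_clusters
        enum_labels = [Label.MUTANT if l == 0 else Label.WILD_TYPE for l in labels]
        model = train(
            init_map(4, 2, seed=6),
            scores,
            one_hot(enum_labels, [Label.MUTANT, Label.WILD_TYPE]),
            epochs=50,
            classes=[Label.MUTANT, Label.WILD_TYPE],
        )
        meta = make_meta(40, replicates=1, label=lambda s: enum_labels[s])
        report = project_map(model, scores, meta, labels=enum_labels, role="calibration")
        assert report.regions.shape == (4, 4)
        assert set(np.unique(report.regions)) <= {0, 1}
        correct_mutants = [
            p for p in report.placements
            if p.true_label is Label.MUTANT and p.correct
        ]
        assert correct_mutants and all(p.marker == "M" for p in correct_mutants)
        for p in report.placements:
            assert p.correct == (p.marker in ("M", "W", "m", "w"))
        assert isinstance(report.render_text(), str)


class TestCrossValidation:
    def _grouped_scores(self, n_samples=80, replicates=3, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        scores, labels, sids = [], [], []
        for s in range(n_samples):
            label = s % 2
            center = np.array([0.0, 0.0]) if label == 0 else np.array([sep, sep])
            for _ in range(replicates):
                scores.append(center + rng.normal(0, 0.1, 2))
                labels.append(label)
                sids.append(f"S{s:03d}")
        return np.asarray(scores), np.asarray(labels), sids

    def test_fold_sizes_80_samples_5_folds(self):
        _, labels, sids = self._grouped_scores()
        folds = _grouped_stratified_folds(sids, labels, 5, seed=0)
        assert all(f.size == 48 for f in folds)  # 16 samples x 3 spectra
        for f in folds:
            held = {sids[i] for i in f}
            assert len(held) == 16

    def test_replicates_never_straddle_folds(self):
        _, labels, sids = self._grouped_scores(n_samples=10)
        folds = _grouped_stratified_folds(sids, labels, 3, seed=1)
        seen = {}
        for k, fold in enumerate(folds):
            for i in fold:
                assert seen.setdefault(sids[i], k) == k

    def test_separable_data_cacv_100(self):
        scores, labels, sids = self._grouped_scores(n_samples=20)
        cacv = cross_validate(
            scores, labels, None, folds=5, size=2, epochs=30, seed=0, sample_ids=sids
        )
        assert cacv == 100.0

    def test_too_many_folds_rejected(self):
        scores, labels, sids = self._grouped_scores(n_samples=4)
        with pytest.raises(errors.ParameterError):
            cross_validate(scores, labels, None, folds=5, sample_ids=sids)

    def test_shuffled_labels_give_chance_level_cacv(self):
        """With zero class signal, pooled CV accuracy sits at chance.

        The 99% binomial band uses the number of independent samples (not
        spectra, which are correlated within a sample).
        """
        rng = np.random.default_rng(123)
        accs = []
        n_samples = 30
        for seed in range(20):
            scores, labels, sids = self._grouped_scores(
                n_samples=n_samples, sep=0.0, seed=seed
            )
            shuffled = rng.permutation(labels.reshape(n_samples, 3)[:, 0])
            labels_null = np.repeat(shuffled, 3)
            accs.append(
                cross_validate(
                    scores, labels_null, None, folds=3, size=3, epochs=15,
                    seed=seed, sample_ids=sids,
                )
            )
        pooled = np.mean(accs)
        n_indep = 20 * n_samples
        half_width = 100.0 * 2.576 * np.sqrt(0.25 / n_indep)
        assert abs(pooled - 50.0) < half_width + 1e-9, (pooled, half_width)


class TestPersistence:
    def test_save_load_roundtrip(self, separable_clusters, tmp_path):
        scores, labels = separable_clusters
        model = train(
            init_map(3, 2, seed=8), scores, one_hot(labels, [0, 1]), epochs=10
        )
        path = tmp_path / "model.npz"
        model.save(path)
        again = CPANNModel.load(path)
        np.testing.assert_array_equal(again.kohonen_w, model.kohonen_w)
        np.testing.assert_array_equal(again.output_w, model.output_w)
        assert again.trained
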