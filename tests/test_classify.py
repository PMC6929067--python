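"""Training-set sampling, cross-validation, prediction and serialization."""

import numpy as np
import pytest

from ermmap.classify import (
    CLASSIFIER_KINDS,
    cross_validate,
    load_model,
    make_classifier,
    predict_points,
    sample_training_set,
    save_model,
    sweep_feature_counts,
    train_model,
)
from ermmap.core import DataError
from ermmap.features import WindowGeometry
from ermmap.phantom import PhantomSpec, generate_phantom
from ermmap.selection import FeatureRanking, SampleSet, surf_rank
from ermmap.snake import segment_volume
from ermmap.core import AnnotatedVolume


def _identity_ranking(n_features):
    w = np.arange(n_features, 0, -1, dtype=float)
    return FeatureRanking(
        w, np.arange(n_features), [f"f{i}" for i in range(n_features)]
    )


def _separable_set(n=60, f=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, f))
    X[:, 0] = y * 4.0 + rng.random(n) * 0.5  # cleanly separating feature
    return SampleSet(X, y, [f"f{i}" for i in range(f)])


class TestSampling:
    def test_balance_and_determinism(self, annotated_erm):
        data1, _ = sample_training_set([annotated_erm], 100, seed=3)
        data2, _ = sample_training_set([annotated_erm], 100, seed=3)
        assert np.bincount(data1.y).tolist() == [50, 50]
        assert sorted(data1.point_ids) == sorted(data2.point_ids)
        assert np.array_equal(data1.X, data2.X)

    def test_odd_count_rounds_positives_up(self, annotated_erm):
        data, _ = sample_training_set([annotated_erm], 31, seed=0)
        assert int(data.y.sum()) == 16

    def test_phantom_without_erm_rejected(self):
        ph = generate_phantom(PhantomSpec(n_slices=2, rng_seed=1))
        vol = ph.volume()
        av = AnnotatedVolume(
            volume=vol,
            contours=segment_volume(vol),
            truth=ph.true_map,
        )
        with pytest.raises(DataError, match="class exhausted"):
            sample_training_set([av], 20, seed=0)


class TestCrossValidate:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_data_perfect_accuracy(self, kind):
        data = _separable_set()
        report = cross_validate(
            data, kind, 4, _identity_ranking(data.n_features), seed=0
        )
        assert report.mean_accuracy == 1.0
        assert len(report.fold_accuracies) == 10

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(11)
        data = _separable_set(n=200, seed=11)
        y_perm = data.y.copy()
        rng.shuffle(y_perm)
        permuted = SampleSet(data.X, y_perm, data.feature_names)
        report = cross_validate(
            permuted, "kNN-6", 8, _identity_ranking(data.n_features), seed=0
        )
        assert 0.4 <= report.mean_accuracy <= 0.6

    def test_accuracy_against_hand_confusion(self):
        """On a 10-sample toy of two distant clusters, every fold predicts
        perfectly, so accuracy equals the hand confusion (TP+TN)/n = 1."""
        X = np.array([[v] for v in [0, 1, 2, 3, 4, 100, 101, 102, 103, 104]],
                     dtype=float)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        data = SampleSet(X, y, ["x"])
        report = cross_validate(
            data, "kNN-2", 1, _identity_ranking(1), seed=0, n_folds=2
        )
        assert report.mean_accuracy == 1.0

    def test_too_few_samples_rejected(self):
        data = _separable_set(n=12)
        with pytest.raises(DataError, match="10-fold"):
            cross_validate(data, "RF", 2, _identity_ranking(data.n_features))

    def test_determinism(self):
        data = _separable_set(n=80, seed=5)
        r1 = cross_validate(data, "RF", 4, _identity_ranking(8), seed=7)
        r2 = cross_validate(data, "RF", 4, _identity_ranking(8), seed=7)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)


class TestSweep:
    def test_table_shape_and_argmax_bookkeeping(self):
        data = _separable_set(n=60, f=10, seed=2)
        ranking = surf_rank(data)
        result = sweep_feature_counts(
            data, ranking, ks=[2, 5, 8], kinds=("RF", "kNN-2"), seed=0
        )
        assert result.table.shape == (2, 3)
        for kind in ("RF", "kNN-2"):
            row = result.table.loc[kind]
            assert result.best_k[kind] == int(row.idxmax())
            assert result.best_accuracy[kind] == float(row.max())
            assert result.best_accuracy[kind] >= float(row[2])


class TestKnnTieBreak:
    def test_2nn_vote_tie_resolves_to_class_zero(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        clf = make_classifier("kNN-2")
        clf.fit(X, y)
        # the query is equidistant: one neighbor votes 0, the other 1
        assert clf.predict([[0.5]])[0] == 0


@pytest.fixture(scope="module")
def model_and_volume(annotated_erm):
    data, basis = sample_training_set([annotated_erm], 120, seed=2)
    ranking = surf_rank(data)
    model = train_model(
        data, ranking, 30, "RF", basis, WindowGeometry(), seed=2
    )
    return model, annotated_erm


class TestPredictAndSerialize:
    def test_erm_slice_mostly_correct(self, model_and_volume):
        model, av = model_and_volume
        labels = predict_points(model, av.volume.scan(2), av.contours[2])
        truth = av.truth.grid[2]
        assert np.mean(labels == truth) >= 0.9

    def test_clean_slice_mostly_background(self, model_and_volume):
        model, _ = model_and_volume
        ph = generate_phantom(PhantomSpec(n_slices=2, speckle_sigma=0.0, rng_seed=33))
        vol = ph.volume()
        contours = segment_volume(vol)
        labels = predict_points(model, vol.scan(0), contours[0])
        assert np.mean(labels == 0) >= 0.98

    def test_round_trip_predicts_identically(self, model_and_volume, tmp_path):
        model, av = model_and_volume
        save_model(model, tmp_path / "model.joblib")
        loaded = load_model(tmp_path / "model.joblib")
        a = predict_points(model, av.volume.scan(1), av.contours[1])
        b = predict_points(loaded, av.volume.scan(1), av.contours[1])
        assert np.array_equal(a, b)
        assert loaded.classifier_kind == model.classifier_kind

    def test_feature_length_mismatch_rejected(self, model_and_volume):
        model, _ = model_and_volume
        with pytest.raises(DataError, match="columns"):
            model.predict_features(np.zeros((3, 10)))
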