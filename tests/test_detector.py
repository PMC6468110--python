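import numpy as np
import pytest

from ictalpipe.detector import (
    HMMParams,
    decode_events,
    estimate_hmm_params,
    evaluate_detector,
    forward_backward,
    train_epoch_classifier,
)
from ictalpipe.features import EpochFeatureMatrix
from ictalpipe.signal_io import AnnotationTrack, EpochIndex

from conftest import brute_force_posteriors


def make_features(values, index=None):
    values = np.asarray(values, dtype=float)
    index = index or EpochIndex(5.0, 512.0, values.shape[0])
    names = [f"f{i}" for i in range(values.shape[1])]
    return EpochFeatureMatrix(values, names, index)


def random_hmm(rng):
    a = rng.dirichlet(np.ones(2), size=2)
    b = rng.dirichlet(np.ones(2), size=2)
    pi = rng.dirichlet(np.ones(2))
    return HMMParams(pi, a, b)


class TestForwardBackward:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            params = random_hmm(rng)
            T = int(rng.integers(1, 11))
            obs = rng.integers(0, 2, size=T)
            post, ll = forward_backward(obs, params)
            post_bf, ll_bf = brute_force_posteriors(obs, params)
            assert np.max(np.abs(post - post_bf)) < 1e-10
            assert ll == pytest.approx(ll_bf, abs=1e-10)

    def test_rows_sum_to_one_on_long_sequence(self):
        rng = np.random.default_rng(1)
        params = random_hmm(rng)
        obs = rng.integers(0, 2, size=5000)
        post, _ = forward_backward(obs, params)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_identity_emission_pins_posterior_to_observation(self):
        params = HMMParams(
            [0.5, 0.5], [[0.7, 0.3], [0.4, 0.6]], np.eye(2)
        )
        obs = np.array([0, 1, 1, 0, 1])
        post, _ = forward_backward(obs, params)
        assert np.allclose(post[np.arange(5), obs], 1.0)

    def test_uninformative_model_gives_uniform_posterior(self):
        params = HMMParams([0.5, 0.5], np.full((2, 2), 0.5), np.full((2, 2), 0.5))
        post, _ = forward_backward(np.array([0, 1, 0, 0, 1]), params)
        assert np.allclose(post, 0.5)

    def test_impossible_observation_raises(self):
        params = HMMParams([0.5, 0.5], np.full((2, 2), 0.5), [[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero probability"):
            forward_backward(np.array([0, 1]), params)

    def test_agrees_with_hmmlearn(self):
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(2)
        params = random_hmm(rng)
        obs = rng.integers(0, 2, size=200)
        post, ll = forward_backward(obs, params)

        m = CategoricalHMM(n_components=2)
        m.startprob_ = params.initial
        m.transmat_ = params.transition
        m.emissionprob_ = params.emission
        ll_ref, post_ref = m.score_samples(obs.reshape(-1, 1))
        assert np.max(np.abs(post - post_ref)) < 1e-8
        assert ll == pytest.approx(ll_ref, abs=1e-8)


class TestHMMEstimation:
    def test_hand_counted_transitions(self):
        labels = np.array([0, 0, 1, 1, 0])
        params = estimate_hmm_params(labels, labels, pseudocount=0)
        assert np.allclose(params.transition, [[0.5, 0.5], [0.5, 0.5]])

    def test_perfect_predictions_give_identity_emission(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        params = estimate_hmm_params(labels, labels, pseudocount=0)
        assert np.allclose(params.emission, np.eye(2))

    def test_initial_is_stationary(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(500) < 0.3).astype(int)
        params = estimate_hmm_params(labels, labels)
        assert np.allclose(params.initial @ params.transition, params.initial, atol=1e-12)

    def test_recovers_known_confusion_rate(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(20_000) < 0.5).astype(int)
        flip = rng.random(labels.size) < 0.1
        preds = np.where(flip, 1 - labels, labels)
        params = estimate_hmm_params(preds, labels, pseudocount=0)
        n0 = (labels == 0).sum()
        se = np.sqrt(0.1 * 0.9 / n0)
        assert abs(params.emission[0, 1] - 0.1) < 2 * se
        assert abs(params.emission[1, 0] - 0.1) < 2 * se

    def test_pseudocount_avoids_zero_rows(self):
        labels = np.zeros(10, dtype=int)  # no seizure state at all
        params = estimate_hmm_params(labels, labels, pseudocount=1)
        assert np.all(params.transition > 0) and np.all(params.emission > 0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_hmm_params(np.array([]), np.array([]))


class TestClassifier:
    def test_separable_gaussians_high_oof_accuracy(self):
        rng = np.random.default_rng(5)
        x0 = rng.normal(0.0, 1.0, size=(200, 4))
        x1 = rng.normal(5.0, 1.0, size=(200, 4))
        fm = make_features(np.vstack([x0, x1]))
        labels = np.repeat([0, 1], 200)
        _, oof = train_epoch_classifier(fm, labels, seed=0)
        assert (oof == labels).mean() > 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(400, 4))
        labels = rng.permutation(np.repeat([0, 1], [240, 160]))
        _, oof = train_epoch_classifier(fm := make_features(x), labels, seed=0)
        majority = 240 / 400
        se = np.sqrt(majority * (1 - majority) / 400)
        assert (oof == labels).mean() < majority + 3 * se

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(100, 3))
        labels = np.tile([0, 1], 50)
        fm = make_features(x)
        m1, oof1 = train_epoch_classifier(fm, labels, seed=1)
        m2, oof2 = train_epoch_classifier(fm, labels, seed=1)
        assert np.array_equal(oof1, oof2)
        assert np.array_equal(m1.fold_assignment, m2.fold_assignment)

    def test_single_class_rejected(self):
        fm = make_features(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="single class"):
            train_epoch_classifier(fm, np.zeros(20, dtype=int))

    def test_minority_smaller_than_folds_rejected(self):
        fm = make_features(np.random.default_rng(0).normal(size=(20, 2)))
        labels = np.zeros(20, dtype=int)
        labels[:3] = 1
        with pytest.raises(ValueError, match="stratify"):
            train_epoch_classifier(fm, labels, n_folds=5)


class TestEventDecoding:
    @pytest.mark.parametrize(
        "posterior,kwargs,expected",
        [
            ([0, 0, 1, 1, 1, 0], {}, [(10.0, 25.0)]),
            ([1, 1, 0, 1, 1], {"merge_gap_epochs": 1}, [(0.0, 25.0)]),
            ([0, 1, 0, 0], {"min_duration_epochs": 2}, []),
        ],
    )
    def test_decision_rules(self, posterior, kwargs, expected):
        p = np.array(posterior, dtype=float)
        index = EpochIndex(5.0, 512.0, p.size)
        events = decode_events(p, index, **kwargs)
        assert [(e.onset, e.offset) for e in events] == expected

    def test_posterior_summaries(self):
        p = np.array([0.0, 0.9, 0.7, 0.0])
        index = EpochIndex(5.0, 512.0, 4)
        (ev,) = decode_events(p, index)
        assert ev.peak_posterior == pytest.approx(0.9)
        assert ev.mean_posterior == pytest.approx(0.8)
        assert ev.duration == pytest.approx(10.0)


class TestEvaluation:
    def test_perfect_predictions(self):
        truth = AnnotationTrack([(10.0, 110.0, "seizure")], 86_400.0)
        res = evaluate_detector(truth, truth)
        assert res["sensitivity"] == 1.0
        assert res["false_positives_per_24h"] == 0.0

    def test_no_predictions(self):
        truth = AnnotationTrack([(10.0, 110.0, "seizure")], 1000.0)
        res = evaluate_detector([], truth)
        assert res["sensitivity"] == 0.0

    def test_false_positive_rate_scales_with_duration(self):
        truth = AnnotationTrack([], 43_200.0)  # half a day, no true events
        pred = AnnotationTrack([(10.0, 70.0, "seizure")], 43_200.0)
        res = evaluate_detector(pred, truth)
        assert res["false_positives_per_24h"] == pytest.approx(2.0)


class TestSmoothingBenefit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hmm_never_hurts_event_f1_under_noisy_emissions(self, seed):
        """Forward-backward smoothing of noisy epoch labels should match or
        beat raw thresholded labels on event-wise F1 (fixed seeds)."""
        rng = np.random.default_rng(seed)
        # ground-truth state sequence: sticky 2-state chain
        n = 2000
        labels = np.zeros(n, dtype=int)
        state = 0
        for t in range(1, n):
            state = 1 - state if rng.random() < (0.02 if state == 0 else 0.08) else state
            labels[t] = state
        preds = np.where(rng.random(n) < 0.15, 1 - labels, labels)
        params = estimate_hmm_params(preds, labels)
        post, _ = forward_backward(preds, params)
        index = EpochIndex(5.0, 512.0, n)
        truth = AnnotationTrack(
            [
                (index.time_span(a)[0], index.time_span(b - 1)[1], "seizure")
                for a, b in _runs(labels)
            ],
            n * 5.0,
        )

        def f1(events):
            r = evaluate_detector(events, truth)
            tp, fp, fn = r["true_positives"], r["false_positives"], r["false_negatives"]
            return 2 * tp / (2 * tp + fp + fn) if tp else 0.0

        raw_events = decode_events(preds.astype(float), index)
        hmm_events = decode_events(post, index)
        assert f1(hmm_events) >= f1(raw_events)


def _runs(labels):
    runs, start = [], None
    for i, v in enumerate(labels):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs
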