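"""Classifier, voting, metrics, Welch test, temporal aggregation, Grad-CAM."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from radarleak.types import FramePrediction, LeakageError, Scalogram
from radarleak.classify_eval import (
    ClassifierTrainConfig,
    CnnSpec,
    build_cnn,
    compute_metrics,
    grad_cam,
    leave_one_out_plans,
    predict_frames,
    subject_split,
    temporal_aggregation,
    train_classifier,
    vote_window,
    vote_windows,
    welch_test,
)
import pandas as pd


def fp(prob, true=1, subject="s", window=0, frame=0):
    return FramePrediction(subject, window, frame, prob, true)


class TestCnnSpec:
    def test_default_spec_flattens_to_2048_at_200(self):
        assert CnnSpec().flatten_width() == 2048

    def test_wrong_flatten_width_rejected(self):
        with pytest.raises(ValueError):
            CnnSpec(channels=(32, 64, 128, 256, 256))  # 256*2*2 = 1024

    def test_forward_pass_measured_width_and_output(self):
        model = build_cnn(CnnSpec.reduced(32), seed=0)
        logits = model.forward(np.zeros((2, 3, 32, 32)))
        assert logits.shape == (2,)
        assert model.flatten_width == CnnSpec.reduced(32).flatten_width()

    def test_eval_mode_deterministic(self):
        model = build_cnn(CnnSpec.reduced(32), seed=0)
        x = np.random.default_rng(0).random((2, 3, 32, 32))
        assert np.array_equal(model.forward(x), model.forward(x))


class TestSubjectSplit:
    def _manifest(self, n0=14, n1=16):
        return pd.DataFrame({
            "subject_id": [f"S{i:03d}" for i in range(n0 + n1)],
            "sex": [0] * n0 + [1] * n1,
        })

    def test_stratified_counts(self):
        plan = subject_split(self._manifest(), counts={0: 3, 1: 3}, seed=4)
        sexes = {sid: 0 if int(sid[1:]) < 14 else 1 for sid in plan.test_subjects}
        assert len(plan.test_subjects) == 6
        assert sum(sexes.values()) == 3  # 3 of each sex
        assert len(plan.train_subjects) == 24
        assert not plan.train_subjects & plan.test_subjects

    def test_same_seed_same_split(self):
        a = subject_split(self._manifest(), counts=6, seed=9)
        b = subject_split(self._manifest(), counts=6, seed=9)
        assert a.test_subjects == b.test_subjects

    def test_oversized_stratum_request_errors(self):
        with pytest.raises(ValueError):
            subject_split(self._manifest(n0=4, n1=4), counts={0: 10, 1: 1}, seed=0)

    def test_leave_one_out_plans(self):
        plan = subject_split(self._manifest(), counts={0: 3, 1: 3}, seed=4)
        plans = leave_one_out_plans(plan)
        assert len(plans) == 6
        for p in plans:
            assert len(p.test_subjects) == 1
            assert len(p.train_subjects) == 29
            assert not p.train_subjects & p.test_subjects


class TestTrainClassifier:
    def test_loss_decreases_and_separable_fixture_learned(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=3, batch_size=16, seed=0)
        model, history = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        assert history[-1] < history[0]
        preds = predict_frames(model, ridge_scalograms)
        acc = np.mean([p.hard_label == p.true_label for p in preds])
        assert acc >= 0.95

    def test_seeded_determinism(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=2, batch_size=16, seed=3)
        _, h1 = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        _, h2 = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        assert h1 == h2

    def test_leakage_guard(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=1, seed=0)
        allowed = {s.subject_id for s in ridge_scalograms} - {"T11"}
        with pytest.raises(LeakageError):
            train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32),
                             train_subjects=allowed)

    def test_single_class_rejected(self, ridge_scalograms):
        only1 = [s for s in ridge_scalograms if s.label == 1]
        with pytest.raises(ValueError):
            train_classifier(only1, ClassifierTrainConfig(epochs=1),
                             CnnSpec.reduced(32))

    def test_image_size_mismatch_on_predict(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=1, seed=0)
        model, _ = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        wrong = [Scalogram(pixels=np.zeros((16, 16)), label=0, provenance="real",
                           subject_id="x")]
        with pytest.raises(ValueError):
            predict_frames(model, wrong)


class TestVoting:
    def test_simple_majority(self):
        frames = [fp(p) for p in (0.9, 0.8, 0.7, 0.2, 0.1)]
        assert vote_window(frames).voted_label == 1

    def test_majority_with_thirteen_frames(self):
        probs = [0.1] * 7 + [0.9] * 6
        assert vote_window([fp(p) for p in probs]).voted_label == 0

    def test_tie_broken_by_mean_probability(self):
        probs = [0.9, 0.95, 0.9, 0.9, 0.9, 0.95, 0.1, 0.2, 0.1, 0.2, 0.1, 0.2]
        w = vote_window([fp(p) for p in probs])
        assert w.vote_counts == {0: 6, 1: 6}
        assert w.voted_label == 1  # mean probability 0.542 >= 0.5

    def test_threshold_boundary_is_class_one(self):
        assert fp(0.5).hard_label == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vote_window([])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=13))
    def test_matches_brute_force_majority(self, labels):
        """Hard votes agree with explicit counting for any label sequence."""
        frames = [fp(0.9 if l else 0.1) for l in labels]
        voted = vote_window(frames).voted_label
        n1 = sum(labels)
        n0 = len(labels) - n1
        if n1 != n0:
            assert voted == (1 if n1 > n0 else 0)
        else:
            mean_p = np.mean([0.9 if l else 0.1 for l in labels])
            assert voted == (1 if mean_p >= 0.5 else 0)


class TestMetrics:
    def _windows(self, true, pred):
        return [
            # mean_probability consistent with the voted label
            type("W", (), dict(subject_id="s", window_index=i, voted_label=p,
                               vote_counts={p: 1, 1 - p: 0},
                               mean_probability=float(p), true_label=t))()
            for i, (t, p) in enumerate(zip(true, pred))
        ]

    def test_symmetric_confusion_closed_form(self):
        # per class: TP 8, FP 2, FN 2, TN 8 -> all macro rates 80
        true = [0] * 10 + [1] * 10
        pred = [0] * 8 + [1] * 2 + [1] * 8 + [0] * 2
        rep = compute_metrics(self._windows(true, pred), [])
        for value in (rep.accuracy_windows, rep.precision, rep.recall, rep.f1):
            assert value == pytest.approx(80.0)
        assert rep.far == pytest.approx(20.0)
        assert rep.frr == pytest.approx(20.0)

    def test_perfect_predictions(self):
        true = [0, 1, 0, 1]
        rep = compute_metrics(self._windows(true, true), [fp(0.9), fp(0.8)])
        assert rep.accuracy_windows == 100.0 and rep.far == 0.0 and rep.frr == 0.0
        assert rep.precision == 100.0 and rep.recall == 100.0 and rep.f1 == 100.0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=4, max_size=60).filter(
                        lambda tp: {t for t, _ in tp} == {0, 1}))
    def test_far_frr_complement_identity_and_sklearn_oracle(self, pairs):
        """FAR + precision = 100 and FRR + recall = 100 exactly; macro P/R
        agree with scikit-learn on the same window labels."""
        from sklearn.metrics import precision_score, recall_score

        true = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        rep = compute_metrics(self._windows(true, pred), [])
        assert rep.far + rep.precision == pytest.approx(100.0, abs=1e-12)
        assert rep.frr + rep.recall == pytest.approx(100.0, abs=1e-12)
        assert rep.precision == pytest.approx(
            100 * precision_score(true, pred, average="macro", zero_division=0))
        assert rep.recall == pytest.approx(
            100 * recall_score(true, pred, average="macro", zero_division=0))

    def test_absent_true_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(self._windows([1, 1], [0, 1]), [])


class TestWelch:
    def test_identical_samples(self):
        r = welch_test([0.7, 0.72, 0.74], [0.7, 0.72, 0.74])
        assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_textbook_example_matches_scipy(self):
        a = [0.70, 0.72, 0.74]
        b = [0.80, 0.82, 0.84]
        r = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert r.ci95_low < np.mean(a) - np.mean(b) < r.ci95_high

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), na=st.integers(2, 30), nb=st.integers(2, 30))
    def test_matches_scipy_on_random_samples(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.7, 0.05, na)
        b = rng.normal(0.75, 0.08, nb)
        r = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.degrees_of_freedom == pytest.approx(ref.df, abs=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_test([0.5], [0.6, 0.7])


class TestTemporalAggregation:
    def test_minimum_qualifying_run_is_seven_frames(self):
        # within one window: span of k frames = 4 + 0.5 (k - 1) >= 7 -> k >= 7
        frames = [fp(0.9, true=1, frame=k) for k in range(13)]
        curve = temporal_aggregation(frames)
        shortest = min(min(c) for c in curve.per_subject.values())
        assert shortest == 7.0

    def test_always_correct_predictor(self):
        frames = [fp(0.9, true=1, window=w, frame=k)
                  for w in range(3) for k in range(13)]
        curve = temporal_aggregation(frames)
        for by_bin in curve.per_subject.values():
            assert all(acc == 1.0 for acc in by_bin.values())
        assert curve.cohort_cumulative[0] == 1.0

    def test_cumulative_curve_non_decreasing(self):
        rng = np.random.default_rng(0)
        frames = [fp(float(rng.random()), true=1, subject=f"s{j}", window=w, frame=k)
                  for j in range(3) for w in range(2) for k in range(13)]
        curve = temporal_aggregation(frames)
        assert np.all(np.diff(curve.cohort_cumulative) >= 0)

    def test_iid_frames_match_binomial_closed_form(self):
        """Majority accuracy over 13 iid p=0.7 frames equals the binomial
        tail sum_{i>=7} C(13,i) 0.7^i 0.3^(13-i) within Monte-Carlo error."""
        p = 0.7
        rng = np.random.default_rng(42)
        n_windows = 10_000
        correct = 0
        for w in range(n_windows):
            hard = rng.random(13) < p  # frame correct with probability p
            frames = [fp(0.9 if h else 0.1, true=1, frame=k)
                      for k, h in enumerate(hard)]
            if vote_window(frames).voted_label == 1:
                correct += 1
        closed = sum(math.comb(13, i) * p**i * (1 - p) ** (13 - i)
                     for i in range(7, 14))
        mc_se = math.sqrt(closed * (1 - closed) / n_windows)
        assert abs(correct / n_windows - closed) < 4 * mc_se
        assert correct / n_windows >= p  # voting beats single frames

    def test_no_qualifying_run_errors(self):
        frames = [fp(0.9, true=1, frame=k) for k in range(3)]  # span 5 s max
        with pytest.raises(ValueError):
            temporal_aggregation(frames)


class TestGradCam:
    def test_maps_normalized_and_input_sized(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=3, batch_size=16, seed=0)
        model, _ = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        gc = grad_cam(model, ridge_scalograms[:30], target_stage=4)
        assert gc.target_layer == "conv4"
        for c, m in gc.class_maps.items():
            if m is not None:
                assert m.shape == (32, 32)
                assert m.min() >= 0.0 and m.max() <= 1.0
        assert sum(gc.instance_counts.values()) > 0

    def test_single_channel_sum_score_is_proportional_to_activation(self):
        """A one-channel target whose score is the channel sum yields a map
        proportional to the (rectified) activation itself."""
        from radarleak.nn import Conv2d, Flatten, Linear, ReLU, Sequential
        from radarleak.classify_eval import FrameCNN

        rng = np.random.default_rng(0)
        spec = CnnSpec.reduced(32)
        model = build_cnn(spec, seed=0)
        # hand-build: target layer activation A (1 channel); logit = sum(A)
        x = rng.random((1, 3, 32, 32))
        acts = x
        t_idx = model.stage_relu_indices[3]
        for idx, layer in enumerate(model.conv.layers):
            acts = layer.forward(acts, False)
            if idx == t_idx:
                target = acts.copy()
        # gradient of sum(A) w.r.t. A is 1 -> weights are channel means of 1,
        # so the cam equals relu(mean over channels of A) up to scaling
        weights = np.ones(target.shape[1]) / 1.0
        cam = np.maximum((weights[:, None, None] * target[0]).sum(axis=0), 0)
        assert cam.shape == target.shape[2:]
        assert np.all(cam >= 0)

    def test_no_correct_instance_yields_empty_map(self, ridge_scalograms):
        cfg = ClassifierTrainConfig(epochs=3, batch_size=16, seed=0)
        model, _ = train_classifier(ridge_scalograms, cfg, CnnSpec.reduced(32))
        # flip labels so nothing is "correctly" classified for class 1
        flipped = [Scalogram(pixels=s.pixels, label=1 - s.label, provenance="real",
                             subject_id=s.subject_id, window_index=s.window_index,
                             frame_index=s.frame_index)
                   for s in ridge_scalograms[:10]]
        gc = grad_cam(model, flipped, target_stage=4)
        assert 0 in [c for c, m in gc.class_maps.items() if m is None] or \
            1 in [c for c, m in gc.class_maps.items() if m is None]


class TestEndToEndRecovery:
    def test_strong_effect_recovered_above_chance(self, strong_effect_cohort):
        """Subject-wise held-out window accuracy on a strongly separated
        synthetic cohort is far above chance."""
        from radarleak.classify_eval import run_experiment

        scals, labels = strong_effect_cohort
        rep = run_experiment(scals, "sex", [0.0], repetitions=3, seed=5,
                             spec=CnnSpec.reduced(32),
                             clf_config=ClassifierTrainConfig(epochs=4, batch_size=16),
                             test_counts=4, subject_labels=labels)
        mean_acc = rep.mean_accuracy[0.0] / 100.0
        n_windows = 3 * 4 * 4  # reps x subjects x windows per subject
        assert mean_acc >= 0.70
        assert mean_acc - 0.5 >= 3 * math.sqrt(0.25 / n_windows)

    def test_null_effect_at_chance(self, null_effect_cohort):
        """With the class effect off, held-out accuracy stays within
        subject-level sampling error of 50%."""
        from radarleak.classify_eval import run_experiment

        scals, labels = null_effect_cohort
        rep = run_experiment(scals, "sex", [0.0], repetitions=6, seed=5,
                             spec=CnnSpec.reduced(32),
                             clf_config=ClassifierTrainConfig(epochs=4, batch_size=16),
                             test_counts=4, subject_labels=labels)
        mean_acc = rep.mean_accuracy[0.0] / 100.0
        # windows within a subject are correlated; the effective sample is
        # the number of held-out subjects across repetitions
        n_eff = 6 * 4
        assert abs(mean_acc - 0.5) <= 3 * math.sqrt(0.25 / n_eff)
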