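"""Frame-level CNN classification and the evaluation suite.

The classifier is a five-stage convolutional network (kernel sizes 5, 3, 13,
5, 2, stride 1, no padding, each stage followed by batch normalization, a
rectifier and max pooling) whose flattened feature width at the default
200x200 3-channel input is exactly 2048, feeding fully connected layers of
widths 1024, 256, 64 and 1 with dropout 0.5, trained with Adam (lr 0.001)
and binary cross-entropy on the sigmoid of the scalar output.

Frame predictions are aggregated per 10 s window by hard majority voting
(ties broken by mean probability). Metrics follow the convention in which
FAR and FRR are the macro complements of precision and recall:
``FAR = 100 - macro precision`` and ``FRR = 100 - macro recall``; F1 is the
macro average of per-class F1 scores. Evaluation is always subject-wise:
split plans keep every subject on exactly one side, and leakage guards
raise if a held-out subject's scalogram reaches a training set.

The suite also provides Welch's t-test for comparing repeated-run accuracy
distributions, a temporal-aggregation analysis (majority votes over all
contiguous frame runs spanning at least 7 s, binned by duration) that
quantifies how observation time improves demographic inference, and
Grad-CAM explanations hooked at the fourth convolution stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .nn import (
    Adam,
    BatchNorm2d,
    BilinearResize,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)
from .types import (
    AggregationCurve,
    FramePrediction,
    GradCamMap,
    LeakageError,
    MetricsReport,
    REAL,
    Scalogram,
    SplitPlan,
    WelchResult,
    WindowPrediction,
)
from .scalogram import as_channels


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass
class CnnSpec:
    """Architecture of the frame classifier.

    The printed constraints are the kernel sizes, stride/padding, the
    2048-wide flatten at 200x200 input and the 1024-256-64-1 head; channel
    counts and pooling sizes are free parameters fixed so the constraint
    holds (2x2 pooling after stages 1-4, 3x3 after stage 5, final channel
    count 512 giving 512*2*2 = 2048).
    """

    kernels: Tuple[int, ...] = (5, 3, 13, 5, 2)
    channels: Tuple[int, ...] = (32, 64, 128, 256, 512)
    pools: Tuple[int, ...] = (2, 2, 2, 2, 3)
    fc_widths: Tuple[int, ...] = (1024, 256, 64, 1)
    image_size: int = 200
    in_channels: int = 3
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if not (len(self.kernels) == len(self.channels) == len(self.pools)):
            raise ValueError("kernels, channels and pools must have equal length")
        if self.fc_widths[-1] != 1:
            raise ValueError("final fully connected width must be 1")
        if self.image_size == 200 and self.flatten_width() != 2048:
            raise ValueError(
                f"spec flattens to {self.flatten_width()} at 200x200; the "
                "classifier requires exactly 2048")

    def flatten_width(self) -> int:
        h = self.image_size
        for k, p in zip(self.kernels, self.pools):
            h = h - k + 1
            if h < 1:
                raise ValueError("spatial size collapsed below 1; spec invalid")
            h //= p
        return self.channels[-1] * h * h

    @classmethod
    def reduced(cls, image_size: int = 32) -> "CnnSpec":
        """Small test-scale profile for desk-scale experiments."""
        if image_size >= 64:
            return cls(kernels=(5, 3, 5, 3, 2), channels=(8, 16, 32, 32, 32),
                       pools=(2, 2, 2, 1, 1), fc_widths=(64, 32, 16, 1),
                       image_size=image_size, dropout_p=0.25)
        return cls(kernels=(3, 3, 3, 2, 2), channels=(8, 16, 32, 32, 32),
                   pools=(2, 2, 1, 1, 1), fc_widths=(64, 32, 16, 1),
                   image_size=image_size, dropout_p=0.25)


@dataclass
class ClassifierTrainConfig:
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class FrameCNN:
    """Five convolution stages plus a four-layer fully connected head."""

    def __init__(self, spec: CnnSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        layers = []
        self.stage_relu_indices: List[int] = []
        c_prev = spec.in_channels
        for k, c, p in zip(spec.kernels, spec.channels, spec.pools):
            layers.extend([Conv2d(c_prev, c, k, 1, rng), BatchNorm2d(c), ReLU()])
            self.stage_relu_indices.append(len(layers) - 1)
            layers.append(MaxPool2d(p))
            c_prev = c
        layers.append(Flatten())
        self.conv = Sequential(layers)

        head_layers: List = []
        w_prev = spec.flatten_width()
        for w in spec.fc_widths[:-1]:
            head_layers.extend([Linear(w_prev, w, rng), ReLU(),
                                Dropout(spec.dropout_p, rng)])
            w_prev = w
        head_layers.append(Linear(w_prev, 1, rng))
        self.head = Sequential(head_layers)

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        feat = self.conv.forward(images, train)
        return self.head.forward(feat, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.head.backward(np.asarray(dlogits)[:, None]))

    @property
    def flatten_width(self) -> int:
        """Flattened feature width, as measured by a forward pass."""
        flat = self.conv.layers[-1]
        if flat.last_width is None:
            probe = np.zeros((1, self.spec.in_channels,
                              self.spec.image_size, self.spec.image_size))
            self.forward(probe)
        return int(self.conv.layers[-1].last_width)

    def named_params(self):
        for name, p, g in self.conv.named_params():
            yield "conv." + name, p, g
        for name, p, g in self.head.named_params():
            yield "head." + name, p, g

    def zero_grad(self) -> None:
        self.conv.zero_grad()
        self.head.zero_grad()


def build_cnn(spec: Optional[CnnSpec] = None, seed: int = 0) -> FrameCNN:
    return FrameCNN(spec or CnnSpec(), np.random.default_rng(seed))


# --------------------------------------------------------------------------
# splits and training
# --------------------------------------------------------------------------

def subject_split(manifest: pd.DataFrame, protocol: str = "holdout_80_20",
                  counts=None, stratify: str = "sex", seed: int = 0) -> SplitPlan:
    """Subject-wise stratified split.

    ``manifest`` needs columns ``subject_id`` and the stratify variable.
    ``counts`` is the number of test subjects, either a total (split across
    strata proportionally, evenly when it divides evenly) or a per-class
    dict such as ``{0: 3, 1: 3}``.
    """
    subjects = manifest.drop_duplicates("subject_id")
    strata = {lbl: list(grp["subject_id"]) for lbl, grp in subjects.groupby(stratify)}
    labels = sorted(strata)
    if counts is None:
        counts = max(1, round(0.2 * len(subjects)))
    if isinstance(counts, int):
        base = counts // len(labels)
        per_class = {lbl: base for lbl in labels}
        for lbl in labels[: counts - base * len(labels)]:
            per_class[lbl] += 1
    else:
        per_class = dict(counts)
    rng = np.random.default_rng(seed)
    test: List[str] = []
    for lbl in labels:
        pool = sorted(strata[lbl])
        want = per_class.get(lbl, 0)
        if want >= len(pool):
            raise ValueError(
                f"stratum {stratify}={lbl} has only {len(pool)} subjects; "
                f"cannot hold out {want}")
        test.extend(rng.choice(pool, size=want, replace=False))
    train = sorted(set(subjects["subject_id"]) - set(test))
    return SplitPlan(
        train_subjects=frozenset(train), test_subjects=frozenset(test),
        stratify=stratify, seed=seed, protocol=protocol,
    )


def leave_one_out_plans(plan: SplitPlan) -> List[SplitPlan]:
    """One plan per held-out test subject; the other test subjects join the
    training side as additional material."""
    all_subjects = plan.train_subjects | plan.test_subjects
    return [
        SplitPlan(train_subjects=frozenset(all_subjects - {s}),
                  test_subjects=frozenset({s}), stratify=plan.stratify,
                  seed=plan.seed, protocol="loo_over_test_subjects")
        for s in sorted(plan.test_subjects)
    ]


def _guard_training_inputs(scalograms: Sequence[Scalogram], train_subjects) -> None:
    labels = set()
    for s in scalograms:
        if s.provenance == REAL and train_subjects is not None \
                and s.subject_id not in train_subjects:
            raise LeakageError(
                f"scalogram of held-out subject {s.subject_id!r} in classifier "
                "training set")
        labels.add(s.label)
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")


def train_classifier(train_scalograms: Sequence[Scalogram],
                     config: ClassifierTrainConfig,
                     spec: Optional[CnnSpec] = None,
                     train_subjects=None) -> Tuple[FrameCNN, List[float]]:
    """Train the frame CNN; returns the model and the per-epoch loss history.

    Real scalograms must belong to ``train_subjects`` when given (leakage
    guard); synthetic scalograms carry no subject and always pass.
    """
    scalograms = list(train_scalograms)
    _guard_training_inputs(scalograms, train_subjects)
    spec = spec or CnnSpec()
    x = np.stack([as_channels(s, spec.in_channels) for s in scalograms])
    y = np.array([s.label for s in scalograms], dtype=float)
    rng = np.random.default_rng(config.seed)
    model = FrameCNN(spec, np.random.default_rng(int(rng.integers(2**31))))
    opt = Adam(model, config.learning_rate)
    n = len(x)
    bs = min(config.batch_size, n)
    history: List[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n - 1, bs):
            idx = order[start : start + bs]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            logits = model.forward(x[idx], train=True)
            prob = 1.0 / (1.0 + np.exp(-logits))
            loss = float(np.mean(np.logaddexp(0.0, logits) - y[idx] * logits))
            model.zero_grad()
            model.backward((prob - y[idx]) / len(idx))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    return model, history


def predict_frames(model: FrameCNN, scalograms: Sequence[Scalogram],
                   batch_size: int = 64) -> List[FramePrediction]:
    """Deterministic evaluation-mode frame predictions."""
    scalograms = list(scalograms)
    preds: List[FramePrediction] = []
    for start in range(0, len(scalograms), batch_size):
        chunk = scalograms[start : start + batch_size]
        x = np.stack([as_channels(s, model.spec.in_channels) for s in chunk])
        if x.shape[2] != model.spec.image_size:
            raise ValueError(
                f"image size {x.shape[2]} != model size {model.spec.image_size}")
        logits = model.forward(x, train=False)
        probs = 1.0 / (1.0 + np.exp(-logits))
        for s, p in zip(chunk, probs):
            preds.append(FramePrediction(
                subject_id=s.subject_id, window_index=s.window_index,
                frame_index=s.frame_index, probability=float(p),
                true_label=s.label))
    return preds


# --------------------------------------------------------------------------
# voting and metrics
# --------------------------------------------------------------------------

def vote_window(frames: Sequence[FramePrediction]) -> WindowPrediction:
    """Hard majority vote over one window's frames; ties go to the label
    indicated by the mean probability (>= 0.5 -> class 1)."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot vote on an empty frame list")
    counts = {0: 0, 1: 0}
    for f in frames:
        counts[f.hard_label] += 1
    mean_prob = float(np.mean([f.probability for f in frames]))
    if counts[0] == counts[1]:
        voted = 1 if mean_prob >= 0.5 else 0
    else:
        voted = 0 if counts[0] > counts[1] else 1
    return WindowPrediction(
        subject_id=frames[0].subject_id, window_index=frames[0].window_index,
        voted_label=voted, vote_counts=counts, mean_probability=mean_prob,
        true_label=frames[0].true_label)


def vote_windows(frame_preds: Sequence[FramePrediction]) -> List[WindowPrediction]:
    groups: Dict[Tuple[str, int], List[FramePrediction]] = {}
    for f in frame_preds:
        groups.setdefault((f.subject_id, f.window_index), []).append(f)
    return [vote_window(v) for _, v in sorted(groups.items())]


def compute_metrics(window_preds: Sequence[WindowPrediction],
                    frame_preds: Sequence[FramePrediction]) -> MetricsReport:
    """Macro-averaged window-level metrics plus frame accuracy, on the
    FAR = 100 - precision / FRR = 100 - recall convention."""
    window_preds = list(window_preds)
    frame_preds = list(frame_preds)
    if not window_preds:
        raise ValueError("no window predictions")
    true = np.array([w.true_label for w in window_preds])
    pred = np.array([w.voted_label for w in window_preds])
    confusion = {}
    precisions, recalls, f1s = [], [], []
    for c in (0, 1):
        if not np.any(true == c):
            raise ValueError(f"true class {c} absent: rates undefined")
        tp = int(np.sum((pred == c) & (true == c)))
        fp = int(np.sum((pred == c) & (true != c)))
        fn = int(np.sum((pred != c) & (true == c)))
        tn = int(np.sum((pred != c) & (true != c)))
        confusion[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn)
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    precision = 100.0 * float(np.mean(precisions))
    recall = 100.0 * float(np.mean(recalls))
    frame_acc = 100.0 * float(np.mean(
        [f.hard_label == f.true_label for f in frame_preds])) if frame_preds else float("nan")
    return MetricsReport(
        accuracy_windows=100.0 * float(np.mean(pred == true)),
        accuracy_frames=frame_acc,
        far=100.0 - precision,
        frr=100.0 - recall,
        precision=precision,
        recall=recall,
        f1=100.0 * float(np.mean(f1s)),
        confusion=confusion,
    )


def welch_test(acc_runs_a: Sequence[float], acc_runs_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite degrees of
    freedom and a 95% CI for the difference in means (a - b)."""
    a = np.asarray(acc_runs_a, dtype=float)
    b = np.asarray(acc_runs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two runs")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(na + nb - 2), 1.0, 0.0, 0.0)
        raise ValueError("zero variance in both samples with unequal means")
    t = diff / math.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * math.sqrt(se2)
    return WelchResult(float(t), float(df), float(p), float(diff - half), float(diff + half))


# --------------------------------------------------------------------------
# temporal aggregation
# --------------------------------------------------------------------------

def temporal_aggregation(frame_preds: Sequence[FramePrediction],
                         min_span_s: float = 7.0, bin_s: float = 1.0,
                         frame_s: float = 4.0, stride_s: float = 0.5,
                         window_s: float = 10.0,
                         accuracy_threshold: float = 0.95) -> AggregationCurve:
    """Majority-vote accuracy of all contiguous frame runs, binned by span.

    Each subject's frames are one ordered sequence (runs may cross window
    boundaries); a run of frames i..j spans ``start_j + frame_s - start_i``
    seconds and is kept when that span is at least ``min_span_s``. The
    cohort curve gives, per duration, the fraction of subjects whose
    per-bin accuracy has reached ``accuracy_threshold`` at or before it.
    """
    by_subject: Dict[str, List[FramePrediction]] = {}
    for f in frame_preds:
        by_subject.setdefault(f.subject_id, []).append(f)

    per_subject: Dict[str, Dict[float, float]] = {}
    any_runs = False
    for sid, frames in sorted(by_subject.items()):
        frames.sort(key=lambda f: (f.window_index, f.frame_index))
        starts = np.array([f.window_index * window_s + f.frame_index * stride_s
                           for f in frames])
        hard = np.array([f.hard_label for f in frames])
        prob = np.array([f.probability for f in frames])
        truth = frames[0].true_label
        ones = np.concatenate([[0], np.cumsum(hard)])
        psum = np.concatenate([[0.0], np.cumsum(prob)])
        sums: Dict[float, List[float]] = {}
        n = len(frames)
        for i in range(n):
            spans = starts[i:] + frame_s - starts[i]
            j_all = np.nonzero(spans >= min_span_s)[0] + i
            if len(j_all) == 0:
                continue
            lens = j_all - i + 1
            n_ones = ones[j_all + 1] - ones[i]
            mean_p = (psum[j_all + 1] - psum[i]) / lens
            voted = np.where(2 * n_ones > lens, 1,
                             np.where(2 * n_ones < lens, 0,
                                      (mean_p >= 0.5).astype(int)))
            correct = (voted == truth).astype(float)
            bins = np.floor((starts[j_all] + frame_s - starts[i]) / bin_s) * bin_s
            for b, c in zip(bins, correct):
                sums.setdefault(float(b), []).append(c)
        if sums:
            any_runs = True
            per_subject[sid] = {b: float(np.mean(v)) for b, v in sorted(sums.items())}
    if not any_runs:
        raise ValueError(f"no contiguous run spans at least {min_span_s} s")

    all_bins = sorted({b for curve in per_subject.values() for b in curve})
    reach: Dict[str, float] = {}
    for sid, curve in per_subject.items():
        hit = [b for b, acc in sorted(curve.items()) if acc >= accuracy_threshold]
        reach[sid] = hit[0] if hit else math.inf
    durations = np.array(all_bins)
    cumulative = np.array([
        np.mean([reach[sid] <= d for sid in per_subject]) for d in durations])
    return AggregationCurve(per_subject=per_subject,
                            cohort_durations=durations,
                            cohort_cumulative=cumulative)


# --------------------------------------------------------------------------
# Grad-CAM
# --------------------------------------------------------------------------

def grad_cam(model: FrameCNN, scalograms: Sequence[Scalogram],
             target_stage: int = 4) -> GradCamMap:
    """Class-wise mean Grad-CAM heatmaps at the given convolution stage.

    Channel weights are the spatial means of the class-score gradient at the
    target activations; the map is the rectified weighted activation sum,
    bilinearly upsampled to the input size. Only correctly classified
    instances contribute; a class with none yields ``None`` for its map.
    """
    if not (1 <= target_stage <= len(model.stage_relu_indices)):
        raise ValueError(f"no convolution stage {target_stage}")
    t_idx = model.stage_relu_indices[target_stage - 1]
    size = model.spec.image_size
    sums = {0: None, 1: None}
    counts = {0: 0, 1: 0}
    resize = None
    for s in scalograms:
        x = as_channels(s, model.spec.in_channels)[None]
        acts = x
        target_act = None
        for idx, layer in enumerate(model.conv.layers):
            acts = layer.forward(acts, False)
            if idx == t_idx:
                target_act = acts
        logit = model.head.forward(acts, False)[0, 0]
        pred = 1 if 1.0 / (1.0 + math.exp(-logit)) >= 0.5 else 0
        if pred != s.label:
            continue
        sign = 1.0 if s.label == 1 else -1.0  # class score for the true class
        d = model.head.backward(np.array([[sign]]))
        for layer in reversed(model.conv.layers[t_idx + 1 :]):
            d = layer.backward(d)
        weights = d[0].mean(axis=(1, 2))  # (C,)
        cam = np.maximum((weights[:, None, None] * target_act[0]).sum(axis=0), 0.0)
        if resize is None or resize.A.shape[1] != cam.shape[0]:
            resize = BilinearResize(cam.shape, (size, size))
        cam_up = resize.forward(cam[None, None])[0, 0]
        counts[s.label] += 1
        sums[s.label] = cam_up if sums[s.label] is None else sums[s.label] + cam_up
    class_maps = {}
    for c in (0, 1):
        if counts[c] == 0:
            class_maps[c] = None
            continue
        m = sums[c] / counts[c]
        hi = m.max()
        class_maps[c] = m / hi if hi > 0 else m
    return GradCamMap(target_layer=f"conv{target_stage}", class_maps=class_maps,
                      instance_counts=counts)


# --------------------------------------------------------------------------
# experiment driver
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    task: str
    reports: Dict[Tuple[float, int], MetricsReport]
    mean_accuracy: Dict[float, float]
    sd_accuracy: Dict[float, float]
    welch: Optional[WelchResult] = None

    def accuracies(self, amount: float) -> List[float]:
        return [r.accuracy_windows / 100.0 for (a, _), r in sorted(self.reports.items())
                if a == amount]


def run_experiment(scalograms: Sequence[Scalogram], task: str,
                   amounts: Sequence[float], repetitions: int, seed: int,
                   spec: CnnSpec, clf_config: ClassifierTrainConfig,
                   gan_config=None, test_counts=None,
                   subject_labels: Optional[Dict[str, int]] = None) -> ExperimentReport:
    """Repeated split -> (GAN ->) augment -> train -> evaluate experiment.

    ``scalograms`` are real labeled scalograms for the task; their labels
    define the stratification variable. For each repetition a fresh
    subject-wise split is drawn; an augmentation amount of 0 skips GAN
    training entirely. When both 0 and a positive amount are requested, a
    Welch test compares their window-accuracy distributions.
    """
    from .augment_cwgan import augment_training_set, train_cwgan  # local: avoid cycle

    scalograms = list(scalograms)
    if subject_labels is None:
        subject_labels = {}
        for s in scalograms:
            subject_labels.setdefault(s.subject_id, s.label)
    manifest = pd.DataFrame(
        {"subject_id": list(subject_labels), task: list(subject_labels.values())})

    rng = np.random.default_rng(seed)
    reports: Dict[Tuple[float, int], MetricsReport] = {}
    for rep in range(repetitions):
        rep_seed = int(rng.integers(2**31))
        plan = subject_split(manifest, counts=test_counts, stratify=task,
                             seed=rep_seed)
        train_real = [s for s in scalograms if s.subject_id in plan.train_subjects]
        test_real = [s for s in scalograms if s.subject_id in plan.test_subjects]
        checkpoint = None
        if any(a > 0 for a in amounts):
            if gan_config is None:
                raise ValueError("gan_config required for positive amounts")
            checkpoint = train_cwgan(train_real, gan_config,
                                     train_subjects=plan.train_subjects)
        for amount in amounts:
            if amount > 0:
                train_set = augment_training_set(train_real, checkpoint,
                                                 "percent_increase", amount,
                                                 seed=rep_seed)
            else:
                train_set = train_real
            cfg = ClassifierTrainConfig(
                learning_rate=clf_config.learning_rate, epochs=clf_config.epochs,
                batch_size=clf_config.batch_size, seed=rep_seed)
            model, _ = train_classifier(train_set, cfg, spec,
                                        train_subjects=plan.train_subjects)
            frame_preds = predict_frames(model, test_real)
            reports[(amount, rep)] = compute_metrics(vote_windows(frame_preds),
                                                     frame_preds)
    mean_acc = {a: float(np.mean([reports[(a, r)].accuracy_windows
                                  for r in range(repetitions)])) for a in amounts}
    sd_acc = {a: float(np.std([reports[(a, r)].accuracy_windows
                               for r in range(repetitions)], ddof=1))
              if repetitions > 1 else 0.0 for a in amounts}
    welch = None
    positive = [a for a in amounts if a > 0]
    if 0 in amounts and positive and repetitions >= 2:
        base = [reports[(0, r)].accuracy_windows / 100 for r in range(repetitions)]
        aug = [reports[(positive[0], r)].accuracy_windows / 100
               for r in range(repetitions)]
        try:
            welch = welch_test(base, aug)
        except ValueError:
            welch = None
    return ExperimentReport(task=task, reports=reports, mean_accuracy=mean_acc,
                            sd_accuracy=sd_acc, welch=welch)
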