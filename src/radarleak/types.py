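"""Shared domain types for the radar demographic-leakage pipeline.

The pipeline moves through a fixed chain of representations:

``RadarRecording`` (raw I/Q at 2 kHz) -> ``IQWindow`` (non-overlapping 10 s
windows) -> ``DisplacementSignal`` (arctangent-demodulated chest motion) ->
``CardiacSignal`` (MODWT-isolated heartbeat band) -> ``Frame`` (overlapping
4 s segments) -> ``Scalogram`` (normalized time-frequency image) ->
frame/window predictions and reports.

Each type is a plain dataclass validated in ``__post_init__`` so that
invariant violations fail at construction, close to the producing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REAL = "real"
SYNTHETIC = "synthetic"


class LeakageError(ValueError):
    """A scalogram from a held-out subject reached a training set."""


@dataclass
class EllipseDistortion:
    """Quadrature channel imperfections that warp the ideal unit circle.

    A perfect receiver traces ``(cos phi, sin phi)``; DC offsets translate
    the circle, amplitude imbalance stretches it, and quadrature phase error
    shears it into a rotated ellipse.
    """

    dc_offset_i: float = 0.0
    dc_offset_q: float = 0.0
    amplitude_i: float = 1.0
    amplitude_q: float = 1.0
    phase_error: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.amplitude_i <= 0 or self.amplitude_q <= 0:
            raise ValueError("channel amplitudes must be positive")
        if abs(self.phase_error) >= math.pi / 2:
            raise ValueError("quadrature phase error must satisfy |e| < pi/2")


@dataclass
class SubjectProfile:
    """Physiological and demographic parameters of one simulated subject."""

    subject_id: str
    sex_label: int
    age_group_label: int
    heart_rate_mean: float  # beats/min
    heart_rate_sd: float  # beats/min, beat-to-beat variability
    pulse_amplitude: float  # mm
    pulse_width: float  # s
    resp_rate: float  # Hz
    resp_amplitude: float  # mm
    noise_sd: float  # mm, residual body-motion noise on the displacement
    ellipse_distortion: EllipseDistortion = field(default_factory=EllipseDistortion)

    def __post_init__(self) -> None:
        if self.sex_label not in (0, 1) or self.age_group_label not in (0, 1):
            raise ValueError("labels must be 0 or 1")
        if not (40.0 <= self.heart_rate_mean <= 180.0):
            raise ValueError("heart_rate_mean must lie in [40, 180] bpm")
        if not (0.1 <= self.resp_rate <= 0.5):
            raise ValueError("resp_rate must lie in [0.1, 0.5] Hz")
        if self.resp_amplitude > 0 and self.pulse_amplitude >= self.resp_amplitude:
            raise ValueError("cardiac motion must be smaller than respiration")

    def label(self, task: str) -> int:
        if task == "sex":
            return self.sex_label
        if task == "age_group":
            return self.age_group_label
        raise ValueError(f"unknown task {task!r}")


@dataclass
class RadarRecording:
    """Raw quadrature radar output for one subject."""

    subject_id: str
    fs: float
    i_channel: np.ndarray
    q_channel: np.ndarray
    duration: float
    ground_truth_displacement: Optional[np.ndarray] = None
    ground_truth_cardiac: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = round(self.fs * self.duration)
        if len(self.i_channel) != len(self.q_channel) or len(self.i_channel) != n:
            raise ValueError("channel lengths must equal round(fs * duration)")


@dataclass
class CohortConfig:
    """Study-condition knobs for one simulated cohort."""

    n_subjects: int = 30
    class_proportions: dict = field(default_factory=lambda: {0: 14 / 30, 1: 16 / 30})
    age_proportions: dict = field(default_factory=lambda: {0: 0.5, 1: 0.5})
    effect_size: float = 1.0
    duration_per_subject: float = 60.0
    seed: int = 0
    wavelength: float = 12.4  # mm, 24 GHz carrier
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.duration_per_subject < 10:
            raise ValueError("duration_per_subject must be >= 10 s")
        for props in (self.class_proportions, self.age_proportions):
            if set(props) != {0, 1}:
                raise ValueError("class proportions must be keyed by {0, 1}")
            if not math.isclose(sum(props.values()), 1.0, abs_tol=1e-9):
                raise ValueError("class proportions must sum to 1")


@dataclass
class IQWindow:
    """One non-overlapping 10 s window of I/Q samples."""

    subject_id: str
    window_index: int
    fs: float
    i: np.ndarray
    q: np.ndarray
    start_time: float

    def __post_init__(self) -> None:
        if len(self.i) != len(self.q):
            raise ValueError("I and Q must have equal length")


@dataclass
class EllipseFit:
    """Geometric ellipse parameters recovered from one window's I/Q locus."""

    center_i: float
    center_q: float
    semi_axis_major: float
    semi_axis_minor: float
    rotation: float  # radians, in (-pi/2, pi/2]
    rms_residual: float

    def __post_init__(self) -> None:
        if not (self.semi_axis_major >= self.semi_axis_minor > 0):
            raise ValueError("require semi_axis_major >= semi_axis_minor > 0")


@dataclass
class DisplacementSignal:
    """Demodulated thoracic displacement for one window."""

    subject_id: str
    window_index: int
    fs: float
    values: np.ndarray  # mm
    phase: np.ndarray  # radians, unwrapped


@dataclass
class MraDecomposition:
    """Additive undecimated multiresolution analysis of one signal."""

    fs: float
    levels: int
    details: list  # J arrays, level 1 first (highest frequency band)
    smooth: np.ndarray
    wavelet_name: str

    def level_band(self, j: int) -> tuple:
        """Nominal passband [fs / 2^(j+1), fs / 2^j] of detail level ``j`` (1-based)."""
        return (self.fs / 2 ** (j + 1), self.fs / 2**j)


@dataclass
class CardiacSignal:
    """Heartbeat-band component of one window's displacement."""

    subject_id: str
    window_index: int
    fs: float
    values: np.ndarray
    selected_levels: list
    band: tuple

    def __post_init__(self) -> None:
        if not self.selected_levels:
            raise ValueError("selected_levels must be non-empty")


@dataclass
class Frame:
    """One overlapping 4 s segment of a cardiac signal."""

    subject_id: str
    window_index: int
    frame_index: int
    fs: float
    values: np.ndarray
    start_offset: float  # s from window start


@dataclass
class Scalogram:
    """Normalized time-frequency image of one frame.

    ``provenance`` is ``"real"`` for scalograms traced back to a recording
    (which must carry subject linkage) and ``"synthetic"`` for generator
    output (which carries none) — this tag is what the leakage guards check.
    """

    pixels: np.ndarray  # (n_freq, n_time), values in [0, 1]
    label: int
    provenance: str
    subject_id: str = ""
    window_index: int = -1
    frame_index: int = -1
    freq_axis: Optional[np.ndarray] = None  # Hz, descending
    time_axis: Optional[np.ndarray] = None  # s

    def __post_init__(self) -> None:
        if self.provenance not in (REAL, SYNTHETIC):
            raise ValueError("provenance must be 'real' or 'synthetic'")
        if self.provenance == SYNTHETIC and self.subject_id:
            raise ValueError("synthetic scalograms carry no subject linkage")
        if self.provenance == REAL and not self.subject_id:
            raise ValueError("real scalograms must carry a subject_id")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("pixels must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class FramePrediction:
    subject_id: str
    window_index: int
    frame_index: int
    probability: float
    true_label: int

    @property
    def hard_label(self) -> int:
        """Thresholded label; the 0.5 boundary maps to class 1 (inclusive)."""
        return 1 if self.probability >= 0.5 else 0


@dataclass
class WindowPrediction:
    subject_id: str
    window_index: int
    voted_label: int
    vote_counts: dict
    mean_probability: float
    true_label: int


@dataclass
class SplitPlan:
    """Subject-wise train/test assignment; no subject appears on both sides."""

    train_subjects: frozenset
    test_subjects: frozenset
    stratify: str
    seed: int
    protocol: str

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subject sets must be disjoint")


@dataclass
class MetricsReport:
    """Window-level classification metrics under the FAR = 100 - precision,
    FRR = 100 - recall convention (macro-averaged over the two classes)."""

    accuracy_windows: float
    accuracy_frames: float
    far: float
    frr: float
    precision: float
    recall: float
    f1: float
    confusion: dict  # per-class {"tp":, "fp":, "fn":, "tn":}

    def as_dict(self) -> dict:
        return {
            "accuracy_windows": self.accuracy_windows,
            "accuracy_frames": self.accuracy_frames,
            "far": self.far,
            "frr": self.frr,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    ci95_low: float
    ci95_high: float


@dataclass
class AggregationCurve:
    """Accuracy of majority-voted contiguous frame runs versus span duration."""

    per_subject: dict  # subject_id -> {duration_bin_s: mean accuracy}
    cohort_durations: np.ndarray  # s, ascending
    cohort_cumulative: np.ndarray  # fraction of subjects at >= 95% accuracy


@dataclass
class GradCamMap:
    target_layer: str
    class_maps: dict  # label -> (H, W) array in [0, 1] or None
    instance_counts: dict  # label -> number of correctly classified instances
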