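"""End-to-end pipeline orchestration from a single YAML configuration.

``run_pipeline`` chains simulate -> demodulate -> isolate -> scalogram ->
(optional GAN augmentation) -> classify -> evaluate into a deterministic
run directory with stage artifacts and a JSON summary. ``validate_config``
normalizes a partial configuration dict, filling defaults and reporting
every violated invariant with the offending key path.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import cardiac_isolation, demodulate, synthetic_radar
from .augment_cwgan import GanTrainConfig
from .classify_eval import ClassifierTrainConfig, CnnSpec, run_experiment
from .scalogram import ScaleConfig, cwt_scalogram, segment_frames, write_scalograms
from .types import CohortConfig, RadarRecording, Scalogram


@dataclass
class PreprocessingConfig:
    window_s: float = 10.0
    frame_s: float = 4.0
    stride_s: float = 0.5
    working_fs: float = 200.0
    wavelet: str = "sym8"
    levels: int = 8
    band_hz: Tuple[float, float] = (0.5, 3.5)


@dataclass
class ExperimentConfig:
    task: str = "sex"
    amounts: Tuple[float, ...] = (0.0,)
    repetitions: int = 1
    test_subjects: int = 2


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    scalogram: ScaleConfig = field(default_factory=ScaleConfig)
    gan: GanTrainConfig = field(default_factory=GanTrainConfig)
    classifier: ClassifierTrainConfig = field(default_factory=ClassifierTrainConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    out_dir: str = "runs/run0"


def validate_config(raw: Optional[dict]) -> PipelineConfig:
    """Normalize a (possibly partial) configuration mapping.

    Raises ``ValueError`` listing every violated invariant with its key path.
    """
    raw = dict(raw or {})
    errors: List[str] = []

    def build(cls, key, **extra):
        section = dict(raw.get(key) or {})
        section.update(extra)
        try:
            return cls(**section)
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
            return cls(**extra) if not isinstance(exc, TypeError) else cls()

    cohort = build(CohortConfig, "cohort")
    pre_raw = dict(raw.get("preprocessing") or {})
    if "band_hz" in pre_raw:
        pre_raw["band_hz"] = tuple(pre_raw["band_hz"])
    try:
        pre = PreprocessingConfig(**pre_raw)
    except TypeError as exc:
        errors.append(f"preprocessing: {exc}")
        pre = PreprocessingConfig()
    sc_raw = dict(raw.get("scalogram") or {})
    if "band" in sc_raw:
        sc_raw["band"] = tuple(sc_raw["band"])
    try:
        scal = ScaleConfig(**sc_raw)
    except TypeError as exc:
        errors.append(f"scalogram: {exc}")
        scal = ScaleConfig()
    gan = build(GanTrainConfig, "gan")
    clf = build(ClassifierTrainConfig, "classifier")
    exp_raw = dict(raw.get("experiment") or {})
    if "amounts" in exp_raw:
        exp_raw["amounts"] = tuple(exp_raw["amounts"])
    try:
        exp = ExperimentConfig(**exp_raw)
    except TypeError as exc:
        errors.append(f"experiment: {exc}")
        exp = ExperimentConfig()

    if pre.frame_s > pre.window_s:
        errors.append("preprocessing.frame_s: must not exceed window_s")
    if pre.band_hz[1] >= pre.working_fs / 2:
        errors.append("preprocessing.band_hz: upper edge must be below the "
                      "working-rate Nyquist frequency")
    if pre.band_hz[0] <= 0 or pre.band_hz[0] >= pre.band_hz[1]:
        errors.append("preprocessing.band_hz: must satisfy 0 < low < high")
    if any(a < 0 for a in exp.amounts):
        errors.append("experiment.amounts: amounts must be non-negative")
    if exp.task not in ("sex", "age_group"):
        errors.append("experiment.task: must be 'sex' or 'age_group'")
    if scal.n_freqs != scal.n_time:
        errors.append("scalogram: n_freqs and n_time must match (square images)")
    if scal.n_freqs != gan.image_size:
        errors.append("gan.image_size: must equal the scalogram size")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    return PipelineConfig(
        cohort=cohort, preprocessing=pre, scalogram=scal, gan=gan,
        classifier=clf, experiment=exp, seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/run0")))


def load_config(path: str) -> PipelineConfig:
    with open(path) as f:
        return validate_config(yaml.safe_load(f))


def scalograms_for_recording(recording: RadarRecording, label: int,
                             pre: PreprocessingConfig = PreprocessingConfig(),
                             scale: ScaleConfig = ScaleConfig(),
                             wavelength: float = 12.4) -> List[Scalogram]:
    """Full preprocessing chain for one recording: windows -> ellipse-fit
    demodulation -> MODWT cardiac isolation -> frames -> scalograms."""
    out: List[Scalogram] = []
    for window in demodulate.segment_windows(recording, pre.window_s):
        disp = demodulate.demodulate_window(window, wavelength)
        cardiac = cardiac_isolation.isolate_cardiac(
            disp, pre.working_fs, pre.wavelet, pre.levels, pre.band_hz)
        for frame in segment_frames(cardiac, pre.frame_s, pre.stride_s):
            out.append(cwt_scalogram(frame, scale, label=label))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written to
    ``<out_dir>/reports/summary.json``)."""
    out = config.out_dir
    for sub in ("recordings", "scalograms", "reports"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)
    with open(os.path.join(out, "config.yaml"), "w") as f:
        yaml.safe_dump(_config_dict(config), f)

    stage = "simulate"
    try:
        manifest = synthetic_radar.generate_dataset(
            config.cohort, os.path.join(out, "recordings"))
        stage = "preprocess"
        task = config.experiment.task
        all_scalograms: List[Scalogram] = []
        subject_labels: Dict[str, int] = {}
        h5_path = os.path.join(out, "recordings", "recordings.h5")
        for row in manifest.itertuples(index=False):
            rec = synthetic_radar.load_recording(h5_path, row.subject_id)
            label = int(getattr(row, task))
            subject_labels[row.subject_id] = label
            all_scalograms.extend(scalograms_for_recording(
                rec, label, config.preprocessing, config.scalogram,
                config.cohort.wavelength))
        write_scalograms(all_scalograms, os.path.join(out, "scalograms"))
        stage = "experiment"
        spec = (CnnSpec() if config.scalogram.n_freqs == 200
                else CnnSpec.reduced(config.scalogram.n_freqs))
        report = run_experiment(
            all_scalograms, task, config.experiment.amounts,
            config.experiment.repetitions, config.seed, spec, config.classifier,
            gan_config=config.gan, test_counts=config.experiment.test_subjects,
            subject_labels=subject_labels)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "task": report.task,
        "n_subjects": config.cohort.n_subjects,
        "n_scalograms": len(all_scalograms),
        "mean_accuracy_windows": report.mean_accuracy,
        "sd_accuracy_windows": report.sd_accuracy,
        "metrics": {f"amount={a}/rep={r}": m.as_dict()
                    for (a, r), m in sorted(report.reports.items())},
        "welch": (None if report.welch is None else vars(report.welch)),
        "seed": config.seed,
    }
    with open(os.path.join(out, "reports", "summary.json"), "w") as f:
        json.dump(summary, f, indent=2, default=float)
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for key in ("preprocessing", "scalogram", "experiment"):
        for k, v in d[key].items():
            if isinstance(v, tuple):
                d[key][k] = list(v)
    return json.loads(json.dumps(d, default=float))
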