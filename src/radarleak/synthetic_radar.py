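"""Synthetic cohorts of quadrature radar recordings.

The simulator emulates resting-scenario continuous-wave radar data: chest
displacement is a slow, high-amplitude respiration sinusoid plus a fast,
low-amplitude heartbeat pulse train plus white body-motion noise.  The
displacement phase-modulates an I/Q pair through the two-way path relation
``phi(t) = 4 pi d(t) / lambda`` and the channels are warped by DC offsets,
amplitude imbalance and quadrature phase error — exactly the distortions the
downstream ellipse fit must undo.

Class structure: the sex label shifts heart rate, pulse width and pulse
amplitude; the age-group label shifts beat-to-beat heart-rate variability.
The separation between class means is ``effect_size`` pooled standard
deviations, so ``effect_size = 0`` produces exchangeable classes and a
chance-level classification problem by construction.
"""

from __future__ import annotations

import math
import os
from typing import List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import CohortConfig, EllipseDistortion, RadarRecording, SubjectProfile

# Baseline population parameters (mean, between-subject sd). Chosen as
# plausible resting adult values; class effects are applied around them.
_HR_BASE, _HR_SD = 72.0, 8.0  # beats/min
_PW_BASE, _PW_SD = 0.20, 0.02  # s (FWHM; chest-surface cardiac motion is smooth)
_PA_BASE, _PA_SD = 0.35, 0.05  # mm
_HRV_BASE, _HRV_SD = 3.0, 0.8  # beats/min
_RESP_AMP_BASE, _RESP_AMP_SD = 4.0, 0.5  # mm


def _class_shift(label: int, effect_size: float, pooled_sd: float) -> float:
    """Symmetric mean shift: label 0 sits effect_size/2 sd below the grand
    mean, label 1 the same amount above."""
    return (label - 0.5) * effect_size * pooled_sd


def _assign_labels(n: int, proportions: dict, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts (largest remainder), shuffled order."""
    n0 = round(n * proportions[0])
    n0 = min(max(n0, 1), n - 1)  # every class keeps at least one subject
    labels = np.array([0] * n0 + [1] * (n - n0))
    rng.shuffle(labels)
    return labels


def sample_cohort(config: CohortConfig) -> List[SubjectProfile]:
    """Draw ``config.n_subjects`` subject profiles with class-conditional
    parameter distributions.

    Raises
    ------
    ValueError
        If a class would receive zero subjects.
    """
    for props in (config.class_proportions, config.age_proportions):
        for lbl in (0, 1):
            if round(config.n_subjects * props[lbl]) < 1 and props[lbl] * config.n_subjects < 0.5:
                raise ValueError(f"class {lbl} would receive zero subjects")
    rng = np.random.default_rng(config.seed)
    sex = _assign_labels(config.n_subjects, config.class_proportions, rng)
    age = _assign_labels(config.n_subjects, config.age_proportions, rng)
    e = config.effect_size

    profiles = []
    for k in range(config.n_subjects):
        hr = rng.normal(_HR_BASE + _class_shift(sex[k], e, _HR_SD), _HR_SD * 0.6)
        pw = rng.normal(_PW_BASE + _class_shift(sex[k], e, _PW_SD), _PW_SD * 0.6)
        pa = rng.normal(_PA_BASE + _class_shift(sex[k], e, _PA_SD), _PA_SD * 0.6)
        hrv = rng.normal(_HRV_BASE + _class_shift(age[k], e, _HRV_SD), _HRV_SD * 0.6)
        resp_amp = rng.normal(_RESP_AMP_BASE, _RESP_AMP_SD)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{k:03d}",
                sex_label=int(sex[k]),
                age_group_label=int(age[k]),
                heart_rate_mean=float(np.clip(hr, 45.0, 175.0)),
                heart_rate_sd=float(np.clip(hrv, 0.2, 15.0)),
                pulse_amplitude=float(np.clip(pa, 0.05, 1.5)),
                pulse_width=float(np.clip(pw, 0.04, 0.3)),
                resp_rate=float(rng.uniform(0.18, 0.35)),
                resp_amplitude=float(np.clip(resp_amp, 2.0, 8.0)),
                noise_sd=0.01,  # mm residual motion noise
                ellipse_distortion=EllipseDistortion(
                    dc_offset_i=float(rng.uniform(-0.5, 0.5)),
                    dc_offset_q=float(rng.uniform(-0.5, 0.5)),
                    amplitude_i=float(rng.uniform(0.8, 1.2)),
                    amplitude_q=float(rng.uniform(0.8, 1.2)),
                    phase_error=float(rng.uniform(-0.3, 0.3)),
                ),
            )
        )
    return profiles


def _gaussian_pulse_train(
    t: np.ndarray,
    heart_rate_mean: float,
    heart_rate_sd: float,
    amplitude: float,
    width: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cardiac displacement: one Gaussian bump per beat.

    Inter-beat intervals are Gaussian with mean 60/hr; the beat-to-beat sd is
    mapped from heart-rate variability through the local linearization
    ``sd_ibi = 60 * hr_sd / hr^2``.
    """
    if amplitude == 0:
        return np.zeros_like(t)
    duration = t[-1] + (t[1] - t[0]) if len(t) > 1 else 0.0
    ibi_mean = 60.0 / heart_rate_mean
    ibi_sd = 60.0 * heart_rate_sd / heart_rate_mean**2
    centers = []
    c = 0.5 * ibi_mean
    while c < duration + 3 * width:
        centers.append(c)
        c += max(0.2 * ibi_mean, rng.normal(ibi_mean, ibi_sd))
    out = np.zeros_like(t)
    sigma = width / 2.355  # interpret pulse_width as FWHM
    for c in centers:
        lo = np.searchsorted(t, c - 4 * sigma)
        hi = np.searchsorted(t, c + 4 * sigma)
        out[lo:hi] += amplitude * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def chest_displacement(
    profile: SubjectProfile, duration: float, fs: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthesize total chest displacement and its cardiac-only component.

    Returns ``(total, cardiac)`` in mm, each of length ``round(fs*duration)``.
    Total = respiration sinusoid with slow phase drift + cardiac pulse train
    + white motion noise of sd ``profile.noise_sd``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = round(fs * duration)
    t = np.arange(n) / fs

    if profile.resp_amplitude > 0:
        # Breathing rate wanders slowly (~5% jitter, ~10 s correlation time):
        # an AR(1) modulation of the instantaneous rate keeps respiration
        # narrowband, as calm breathing is.
        alpha = 1.0 / (10.0 * fs)
        z = lfilter([alpha], [1.0, -(1.0 - alpha)], rng.standard_normal(n))
        z /= math.sqrt(alpha / 2.0)  # approximately unit stationary sd
        f_inst = profile.resp_rate * (1.0 + 0.05 * z)
        phase = 2 * math.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * math.pi)
        resp = profile.resp_amplitude * np.sin(phase)
    else:
        resp = np.zeros(n)

    cardiac = _gaussian_pulse_train(
        t,
        profile.heart_rate_mean,
        profile.heart_rate_sd,
        profile.pulse_amplitude,
        profile.pulse_width,
        rng,
    )
    noise = rng.normal(0.0, profile.noise_sd, n) if profile.noise_sd > 0 else np.zeros(n)
    return resp + cardiac + noise, cardiac


def modulate_iq(
    displacement: np.ndarray,
    distortion: EllipseDistortion,
    wavelength: float = 12.4,
    noise_sd: float = 0.0,
    fs: float = 2000.0,
    seed: int = 0,
    subject_id: str = "",
    phase_offset: float = 0.7,
    ground_truth_cardiac: Optional[np.ndarray] = None,
) -> RadarRecording:
    """Quadrature-modulate a displacement signal into a distorted I/Q pair.

    Phase follows the two-way path convention ``phi = 4 pi d / lambda``; the
    channels are then warped as

    ``i = dc_i + A_i cos(phi + phi0) + n_i``,
    ``q = dc_q + A_q sin(phi + phi0 + phase_error) + n_q``.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.size == 0:
        raise ValueError("displacement must be non-empty")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    rng = np.random.default_rng(seed)
    phi = 4 * math.pi * displacement / wavelength + phase_offset
    i = distortion.dc_offset_i + distortion.amplitude_i * np.cos(phi)
    q = distortion.dc_offset_q + distortion.amplitude_q * np.sin(phi + distortion.phase_error)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, len(i))
        q = q + rng.normal(0.0, noise_sd, len(q))
    return RadarRecording(
        subject_id=subject_id,
        fs=fs,
        i_channel=i,
        q_channel=q,
        duration=len(displacement) / fs,
        ground_truth_displacement=displacement,
        ground_truth_cardiac=ground_truth_cardiac,
    )


def simulate_recording(
    profile: SubjectProfile, config: CohortConfig, seed: int
) -> RadarRecording:
    """Full simulation chain for one subject: displacement then modulation."""
    total, cardiac = chest_displacement(
        profile, config.duration_per_subject, config.fs, seed
    )
    return modulate_iq(
        total,
        profile.ellipse_distortion,
        wavelength=config.wavelength,
        noise_sd=0.02,
        fs=config.fs,
        seed=seed + 1,
        subject_id=profile.subject_id,
        ground_truth_cardiac=cardiac,
    )


def generate_dataset(config: CohortConfig, out_path: str) -> pd.DataFrame:
    """Simulate a cohort and persist it as HDF5 + CSV manifest.

    Layout: one HDF5 group per subject with datasets ``i``, ``q``,
    ``displacement``, ``cardiac`` and attributes ``fs``, ``sex``,
    ``age_group``. The manifest has one row per subject with columns
    ``subject_id,sex,age_group,duration_s,path``.
    """
    os.makedirs(out_path, exist_ok=True)
    profiles = sample_cohort(config)
    h5_path = os.path.join(out_path, "recordings.h5")
    rows = []
    try:
        with h5py.File(h5_path, "w") as f:
            for k, profile in enumerate(profiles):
                rec = simulate_recording(profile, config, seed=config.seed * 100003 + k)
                g = f.create_group(profile.subject_id)
                g.create_dataset("i", data=rec.i_channel)
                g.create_dataset("q", data=rec.q_channel)
                g.create_dataset("displacement", data=rec.ground_truth_displacement)
                g.create_dataset("cardiac", data=rec.ground_truth_cardiac)
                g.attrs["fs"] = config.fs
                g.attrs["sex"] = profile.sex_label
                g.attrs["age_group"] = profile.age_group_label
                rows.append(
                    {
                        "subject_id": profile.subject_id,
                        "sex": profile.sex_label,
                        "age_group": profile.age_group_label,
                        "duration_s": rec.duration,
                        "path": h5_path,
                    }
                )
    except OSError as exc:
        raise OSError(f"failed to write dataset under {out_path!r}: {exc}") from exc
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_path, "manifest.csv"), index=False)
    return manifest


def load_recording(h5_path: str, subject_id: str) -> RadarRecording:
    """Read one subject's recording back from a generated dataset."""
    with h5py.File(h5_path, "r") as f:
        g = f[subject_id]
        fs = float(g.attrs["fs"])
        i = g["i"][:]
        return RadarRecording(
            subject_id=subject_id,
            fs=fs,
            i_channel=i,
            q_channel=g["q"][:],
            duration=len(i) / fs,
            ground_truth_displacement=g["displacement"][:],
            ground_truth_cardiac=g["cardiac"][:],
        )
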