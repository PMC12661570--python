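"""Shared fixtures: synthetic ridge-image sets and preprocessed mini-cohorts.

Everything is generated programmatically at session scope so the expensive
simulation + demodulation + isolation + scalogram chain runs once per test
session.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from radarleak.types import CohortConfig, Scalogram, SubjectProfile
from radarleak.pipeline import PreprocessingConfig, scalograms_for_recording
from radarleak.scalogram import ScaleConfig
from radarleak.synthetic_radar import sample_cohort, simulate_recording


def make_ridge_scalograms(n_per_class: int, size: int = 32, n_subjects: int = 4,
                          seed: int = 0, noise: float = 0.1):
    """Separable two-class fixture: horizontal ridges at disjoint rows."""
    rng = np.random.default_rng(seed)
    out = []
    for lbl in (0, 1):
        for k in range(n_per_class):
            img = np.zeros((size, size))
            row = (size // 4 if lbl == 0 else 3 * size // 4) + int(rng.integers(-2, 3))
            img[row - 1 : row + 2, :] = 1.0
            img += noise * rng.random((size, size))
            out.append(Scalogram(
                pixels=np.clip(img, 0, 1), label=lbl, provenance="real",
                subject_id=f"T{lbl}{k % n_subjects}", window_index=k // 13,
                frame_index=k % 13))
    return out


@pytest.fixture(scope="session")
def ridge_scalograms():
    return make_ridge_scalograms(52, size=32)


@pytest.fixture(scope="session")
def resting_profile():
    return SubjectProfile(
        subject_id="s0", sex_label=0, age_group_label=0,
        heart_rate_mean=72.0, heart_rate_sd=2.0, pulse_amplitude=0.3,
        pulse_width=0.2, resp_rate=0.25, resp_amplitude=4.0, noise_sd=0.01)


def preprocess_cohort(effect_size: float, seed: int, n_subjects: int = 12,
                      duration: float = 40.0, image: int = 32, task: str = "sex"):
    """Simulate a cohort and run the full preprocessing chain."""
    cfg = CohortConfig(n_subjects=n_subjects,
                       class_proportions={0: 0.5, 1: 0.5},
                       effect_size=effect_size,
                       duration_per_subject=duration, seed=seed)
    scale = ScaleConfig(n_freqs=image, n_time=image)
    pre = PreprocessingConfig()
    scals, labels = [], {}
    for k, profile in enumerate(sample_cohort(cfg)):
        rec = simulate_recording(profile, cfg, seed=seed * 1000 + k)
        label = profile.label(task)
        scals.extend(scalograms_for_recording(rec, label, pre, scale))
        labels[profile.subject_id] = label
    return scals, labels


@pytest.fixture(scope="session")
def strong_effect_cohort():
    """12 subjects, strong sex effect, reduced 32x32 profile."""
    return preprocess_cohort(effect_size=3.0, seed=11)


@pytest.fixture(scope="session")
def null_effect_cohort():
    """Same cohort conditions with the class effect switched off."""
    return preprocess_cohort(effect_size=0.0, seed=11)
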