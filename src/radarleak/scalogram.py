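"""Time-frequency imaging of cardiac frames.

Each 10 s cardiac signal is cut into overlapping 4 s frames (stride 0.5 s,
hence 13 frames per full window) and each frame is rendered as the magnitude
of an analytic-Morlet continuous wavelet transform on logarithmically spaced
frequencies, reduced to a fixed pixel grid and min-max normalized to [0, 1].
The default grid is 200x200, stored as 8-bit grayscale PNG; the classifier
replicates the single channel to three at load time.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
import pywt
from PIL import Image

from .types import Frame, CardiacSignal, Scalogram, REAL


@dataclass
class ScaleConfig:
    """Rendering parameters for scalograms."""

    n_freqs: int = 200
    n_time: int = 200
    band: Tuple[float, float] = (0.3, 20.0)  # Hz
    wavelet: str = "cmor1.5-1.0"

    def frequencies(self) -> np.ndarray:
        """Log-spaced analysis frequencies, descending (row 0 = highest)."""
        lo, hi = self.band
        return np.logspace(math.log10(hi), math.log10(lo), self.n_freqs)


def segment_frames(
    cardiac: CardiacSignal, frame_s: float = 4.0, stride_s: float = 0.5
) -> List[Frame]:
    """Overlapping frames; count = floor((T - frame_s)/stride_s) + 1."""
    n = len(cardiac.values)
    duration = n / cardiac.fs
    if duration < frame_s:
        raise ValueError(f"{duration:.2f} s signal shorter than {frame_s} s frame")
    frame_n = round(frame_s * cardiac.fs)
    stride_n = round(stride_s * cardiac.fs)
    count = (n - frame_n) // stride_n + 1
    return [
        Frame(
            subject_id=cardiac.subject_id,
            window_index=cardiac.window_index,
            frame_index=k,
            fs=cardiac.fs,
            values=cardiac.values[k * stride_n : k * stride_n + frame_n],
            start_offset=k * stride_s,
        )
        for k in range(count)
    ]


def cwt_scalogram(frame: Frame, scale_config: ScaleConfig | None = None,
                  label: int = 0) -> Scalogram:
    """Render one frame as a normalized scalogram image.

    The CWT magnitude is computed on ``n_freqs`` log-spaced frequencies, the
    time axis is reduced to ``n_time`` columns by block averaging, and the
    image is min-max normalized (a constant frame maps to all zeros).
    """
    cfg = scale_config or ScaleConfig()
    x = np.asarray(frame.values, dtype=float)
    duration = len(x) / frame.fs
    if duration * cfg.band[0] < 1.0:
        raise ValueError(
            f"frame of {duration:.2f} s is shorter than one period of the "
            f"lowest analysis frequency {cfg.band[0]} Hz"
        )
    freqs = cfg.frequencies()
    fc = pywt.central_frequency(cfg.wavelet)
    scales = fc * frame.fs / freqs
    coeffs, _ = pywt.cwt(x - x.mean(), scales, cfg.wavelet,
                         sampling_period=1.0 / frame.fs, method="fft")
    mag = np.abs(coeffs)  # (n_freqs, n_samples)

    block = mag.shape[1] // cfg.n_time
    if block < 1:
        raise ValueError("frame has fewer samples than requested time columns")
    trimmed = mag[:, : block * cfg.n_time]
    img = trimmed.reshape(cfg.n_freqs, cfg.n_time, block).mean(axis=2)

    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        pixels = np.zeros_like(img)
    else:
        pixels = (img - lo) / (hi - lo)
    times = frame.start_offset + (np.arange(cfg.n_time) + 0.5) * block / frame.fs
    return Scalogram(
        pixels=pixels,
        label=label,
        provenance=REAL,
        subject_id=frame.subject_id,
        window_index=frame.window_index,
        frame_index=frame.frame_index,
        freq_axis=freqs,
        time_axis=times,
    )


def as_channels(scalogram: Scalogram, n_channels: int = 3) -> np.ndarray:
    """Replicate the grayscale image into ``n_channels`` identical channels,
    shape (C, H, W)."""
    return np.repeat(scalogram.pixels[np.newaxis], n_channels, axis=0)


def write_scalograms(scalograms: Iterable[Scalogram], out_dir: str) -> pd.DataFrame:
    """Save images as 8-bit grayscale PNG plus a manifest CSV.

    Manifest columns: path,label,provenance,subject_id,window_index,frame_index.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for k, s in enumerate(scalograms):
        name = f"scalogram_{k:06d}.png"
        path = os.path.join(out_dir, name)
        arr = np.clip(np.round(s.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
        rows.append(
            {
                "path": name,
                "label": s.label,
                "provenance": s.provenance,
                "subject_id": s.subject_id,
                "window_index": s.window_index,
                "frame_index": s.frame_index,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def read_scalograms(manifest_path: str) -> List[Scalogram]:
    """Inverse of :func:`write_scalograms` up to 8-bit quantization."""
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    base = os.path.dirname(os.path.abspath(manifest_path))
    out = []
    for row in manifest.itertuples(index=False):
        path = os.path.join(base, row.path)
        if not os.path.exists(path):
            raise IOError(f"manifest references missing image {row.path!r}")
        arr = np.asarray(Image.open(path), dtype=float) / 255.0
        out.append(
            Scalogram(
                pixels=arr,
                label=int(row.label),
                provenance=str(row.provenance),
                subject_id=str(row.subject_id),
                window_index=int(row.window_index),
                frame_index=int(row.frame_index),
            )
        )
    return out
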