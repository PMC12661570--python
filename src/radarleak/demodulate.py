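"""Arctangent demodulation of quadrature radar windows.

Each recording is cut into non-overlapping 10 s windows. Within a window the
I/Q sample cloud traces an ellipse whose center encodes the DC offsets,
whose axes encode amplitude imbalance, and whose tilt encodes quadrature
phase error. A direct least-squares conic fit recovers these parameters;
the affine de-distortion maps the cloud back onto the unit circle, where the
unwrapped ``atan2(q, i)`` angle is, up to an additive constant, the radar
phase ``4 pi d(t) / lambda``.

The de-distortion (translate, rotate by the fitted tilt, rescale the axes)
is orientation-preserving, so for noiseless points the recovered angle
equals the generating phase plus a constant exactly — no sign ambiguity.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from skimage.measure import EllipseModel

from .types import DisplacementSignal, EllipseFit, IQWindow, RadarRecording


def segment_windows(recording: RadarRecording, window_s: float = 10.0) -> List[IQWindow]:
    """Split a recording into non-overlapping windows, dropping the tail.

    Raises ``ValueError`` when the recording is shorter than one window.
    """
    n_win_samples = round(recording.fs * window_s)
    n = len(recording.i_channel)
    if n < n_win_samples:
        raise ValueError(
            f"recording of {recording.duration:.2f} s is shorter than one "
            f"{window_s:.0f} s window"
        )
    windows = []
    for k in range(n // n_win_samples):
        sl = slice(k * n_win_samples, (k + 1) * n_win_samples)
        windows.append(
            IQWindow(
                subject_id=recording.subject_id,
                window_index=k,
                fs=recording.fs,
                i=recording.i_channel[sl],
                q=recording.q_channel[sl],
                start_time=k * window_s,
            )
        )
    return windows


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit of an (N, 2) point cloud.

    Returns geometric parameters with ``semi_axis_major >= semi_axis_minor``
    and ``rotation`` (major-axis angle) folded into ``(-pi/2, pi/2]``.

    Raises ``ValueError`` for fewer than 6 points or degenerate geometry
    (e.g. collinear points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if len(pts) < 6:
        raise ValueError("ellipse fitting needs at least 6 points")
    # Degenerate clouds make the conic system rank-deficient; EllipseModel
    # then fails to estimate or produces non-finite/non-elliptical parameters.
    params = None
    try:
        if hasattr(EllipseModel, "from_estimate"):
            model = EllipseModel.from_estimate(pts)
            if model:
                params = (*model.center, *model.axis_lengths, model.theta)
        else:  # scikit-image < 0.26
            model = EllipseModel()
            if model.estimate(pts):
                params = tuple(model.params)
    except Exception:
        params = None
    if params is None or not np.all(np.isfinite(params)):
        raise ValueError("degenerate geometry: points do not determine an ellipse")
    xc, yc, a, b, theta = params
    if a <= 0 or b <= 0:
        raise ValueError("degenerate geometry: non-positive semi-axis")
    if b > a:
        a, b = b, a
        theta += math.pi / 2
    # fold rotation into (-pi/2, pi/2]
    theta = (theta + math.pi / 2) % math.pi - math.pi / 2
    if theta == -math.pi / 2:
        theta = math.pi / 2
    # rms of the normalized radial residual in the de-distorted frame
    u = _to_unit_circle(pts[:, 0], pts[:, 1], xc, yc, a, b, theta)
    rms = float(np.sqrt(np.mean((np.hypot(u[0], u[1]) - 1.0) ** 2)))
    return EllipseFit(
        center_i=float(xc),
        center_q=float(yc),
        semi_axis_major=float(a),
        semi_axis_minor=float(b),
        rotation=float(theta),
        rms_residual=rms,
    )


def _to_unit_circle(i, q, xc, yc, a, b, theta):
    ci, si = math.cos(theta), math.sin(theta)
    x = i - xc
    y = q - yc
    xr = ci * x + si * y  # rotate by -theta
    yr = -si * x + ci * y
    return xr / a, yr / b


def compensate(window: IQWindow, fit: EllipseFit) -> Tuple[np.ndarray, np.ndarray]:
    """Undo DC offset, rotation and axis imbalance; output lies on the unit
    circle for noiseless elliptical input."""
    if fit.semi_axis_minor <= 0:
        raise ValueError("semi-axes must be positive")
    return _to_unit_circle(
        window.i,
        window.q,
        fit.center_i,
        fit.center_q,
        fit.semi_axis_major,
        fit.semi_axis_minor,
        fit.rotation,
    )


def arctan_demodulate(
    i_corr: np.ndarray,
    q_corr: np.ndarray,
    fs: float,
    wavelength: float = 12.4,
    subject_id: str = "",
    window_index: int = 0,
) -> DisplacementSignal:
    """Unwrapped-angle demodulation of compensated I/Q.

    ``values = wavelength / (4 pi) * (phase - phase[0])`` in mm; the first
    sample is anchored to zero displacement (the additive phase constant is
    unobservable).
    """
    i_corr = np.asarray(i_corr, dtype=float)
    q_corr = np.asarray(q_corr, dtype=float)
    if i_corr.shape != q_corr.shape:
        raise ValueError("corrected I and Q must have the same shape")
    mag = np.hypot(i_corr, q_corr)
    if np.any(mag == 0):
        raise ValueError("zero-magnitude I/Q sample: angle undefined")
    phase = np.unwrap(np.arctan2(q_corr, i_corr))
    values = wavelength / (4 * math.pi) * (phase - phase[0])
    return DisplacementSignal(
        subject_id=subject_id,
        window_index=window_index,
        fs=fs,
        values=values,
        phase=phase,
    )


def demodulate_window(
    window: IQWindow, wavelength: float = 12.4
) -> DisplacementSignal:
    """Convenience chain: fit ellipse on the window, compensate, demodulate."""
    fit = fit_ellipse(np.column_stack([window.i, window.q]))
    i_c, q_c = compensate(window, fit)
    return arctan_demodulate(
        i_c, q_c, window.fs, wavelength, window.subject_id, window.window_index
    )
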