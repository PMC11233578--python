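"""Conversion of raw ROI fluorescence to stimulus-aligned ΔF/F0.

The normalisation follows the two-baseline convention used for
GRIN-lens two-photon recordings of GCaMP signals:

    ΔF/F0(t) = (f(t) − f_b) / f0(t)

where ``f`` is the ROI fluorescence, ``f_b`` is the event-local baseline
(mean fluorescence over the 0.5 s preceding each stimulus onset) and
``f0`` is the slow baseline, the 8th percentile of the ROI fluorescence
plus the background signal overlapping the ROI, evaluated over a 1-s
moving window.  ``f_b`` removes the event-local offset; ``f0`` tracks
slow drift of the indicator brightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "DffParams",
    "AlignedResponse",
    "running_percentile_baseline",
    "compute_dff",
    "align_to_events",
    "gaussian_smooth",
]


@dataclass(frozen=True)
class DffParams:
    """Parameters of the ΔF/F0 computation.

    baseline_pre_window : s
        Window before each stimulus onset over which the event-local
        baseline ``f_b`` (mean fluorescence) is taken.
    percentile, percentile_window : percentile of (ROI + background)
        fluorescence over a moving window, defining the slow baseline
        ``f0``.
    percentile_centered : whether the moving window is centred on the
        current frame (True) or trailing (False).
    smoothing_sigma : s; Gaussian smoothing for display only — never
        applied before quantitative statistics.
    """

    baseline_pre_window: float = 0.5
    percentile: float = 8.0
    percentile_window: float = 1.0
    percentile_centered: bool = True
    smoothing_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.percentile_window <= 0 or self.baseline_pre_window <= 0:
            raise ValueError("windows must be positive")


@dataclass
class AlignedResponse:
    """Per-neuron stimulus-aligned ΔF/F0 matrix (trials × frames).

    ``time_axis`` is in seconds relative to stimulus onset; the onset
    frame is the first frame of the post window (half-open intervals,
    onset included in the post window).
    """

    dff: np.ndarray
    time_axis: np.ndarray
    neuron_id: int
    session_id: int
    frame_rate: float
    n_dropped: int = 0
    invalid_trials: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.dff.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.dff.mean(axis=0)


def running_percentile_baseline(
    f_total: np.ndarray,
    frame_rate: float,
    window: float = 1.0,
    q: float = 8.0,
    centered: bool = True,
) -> np.ndarray:
    """Per-frame q-th percentile of ``f_total`` over a moving window.

    The window width is ``window`` seconds (rounded to frames); edges use
    truncated windows.  Percentiles interpolate linearly between order
    statistics (numpy's default), so an exhaustive sort-and-index
    computation reproduces this output exactly.
    """
    f_total = np.asarray(f_total, dtype=float)
    if f_total.ndim != 1 or f_total.size == 0:
        raise ValueError("f_total must be a non-empty 1-D trace")
    n = int(round(window * frame_rate))
    if n < 2:
        raise ValueError(f"window of {window} s is under 2 frames at {frame_rate} Hz")
    T = f_total.size
    if centered:
        lo, hi = (n - 1) // 2, n // 2  # window [i-lo, i+hi]
    else:
        lo, hi = n - 1, 0  # trailing window [i-n+1, i]
    out = np.empty(T)
    # full windows in one vectorised call; truncated edges individually
    first_full = lo
    last_full = T - 1 - hi
    if last_full >= first_full:
        views = sliding_window_view(f_total, n)
        out[first_full : last_full + 1] = np.percentile(views, q, axis=1)
    for i in range(min(first_full, T)):
        out[i] = np.percentile(f_total[max(0, i - lo) : i + hi + 1], q)
    for i in range(max(last_full + 1, 0), T):
        out[i] = np.percentile(f_total[max(0, i - lo) : min(T, i + hi + 1)], q)
    return out


def compute_dff(
    f: np.ndarray,
    background: np.ndarray,
    onsets: np.ndarray,
    frame_rate: float,
    params: DffParams | None = None,
    pre: float = 1.0,
    post: float = 5.0,
):
    """Per-event ΔF/F0 segments around stimulus onsets.

    For each onset, ``f_b`` is the mean of ``f`` over the
    ``baseline_pre_window`` seconds preceding the onset, ``f0`` is the
    running-percentile baseline of ``f + background``, and the segment is
    ``(f − f_b) / f0`` cut to ``[−pre, +post)`` seconds around the onset.

    Returns ``(segments, valid, f0)`` where ``segments`` has one row per
    onset (NaN rows for events whose window leaves the session or whose
    ``f0`` is non-positive anywhere in the segment) and ``valid`` flags
    usable rows.
    """
    params = params or DffParams()
    f = np.asarray(f, dtype=float)
    background = np.asarray(background, dtype=float)
    if f.shape != background.shape:
        raise ValueError("f and background must have equal length")
    onsets = np.asarray(onsets, dtype=int)
    T = f.size
    f0 = running_percentile_baseline(
        f + background,
        frame_rate,
        window=params.percentile_window,
        q=params.percentile,
        centered=params.percentile_centered,
    )
    n_pre = int(round(pre * frame_rate))
    n_post = int(round(post * frame_rate))
    n_base = int(round(params.baseline_pre_window * frame_rate))
    segments = np.full((onsets.size, n_pre + n_post), np.nan)
    valid = np.zeros(onsets.size, dtype=bool)
    for j, o in enumerate(onsets):
        if o - n_pre < 0 or o + n_post > T or o - n_base < 0:
            logger.warning("event at frame %d too close to session edge; dropped", o)
            continue
        f_b = f[o - n_base : o].mean()
        seg_f0 = f0[o - n_pre : o + n_post]
        if np.any(seg_f0 <= 0):
            logger.warning("event at frame %d has non-positive f0; excluded", o)
            continue
        segments[j] = (f[o - n_pre : o + n_post] - f_b) / seg_f0
        valid[j] = True
    return segments, valid, f0


def align_to_events(
    segments: np.ndarray,
    valid: np.ndarray,
    frame_rate: float,
    pre: float = 1.0,
    post: float = 5.0,
    neuron_id: int = -1,
    session_id: int = -1,
) -> AlignedResponse:
    """Stack valid per-event ΔF/F0 segments into an AlignedResponse."""
    segments = np.asarray(segments, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n_pre = int(round(pre * frame_rate))
    n_post = int(round(post * frame_rate))
    if segments.shape[1] != n_pre + n_post:
        raise ValueError("segment length does not match the requested window")
    time_axis = (np.arange(n_pre + n_post) - n_pre) / frame_rate
    kept = segments[valid]
    if kept.size == 0:
        raise ValueError("no valid events to align")
    return AlignedResponse(
        dff=kept,
        time_axis=time_axis,
        neuron_id=neuron_id,
        session_id=session_id,
        frame_rate=frame_rate,
        n_dropped=int((~valid).sum()),
        invalid_trials=list(np.flatnonzero(~valid)),
    )


def gaussian_smooth(trace: np.ndarray, sigma: float, frame_rate: float) -> np.ndarray:
    """Gaussian smoothing (sigma in seconds, reflected boundaries).

    For display only; quantitative statistics run on unsmoothed data.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(trace, dtype=float).copy()
    return gaussian_filter1d(np.asarray(trace, dtype=float), sigma * frame_rate, mode="reflect")
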