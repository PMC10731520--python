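"""Behavior quantification: motion energy, event detection, and the
coordination statistics between the two mice.

Movement is measured inside user-drawn ROIs over each mouse's whiskers
and forelimbs as the absolute temporal gradient of the ROI mean pixel
value.  The energy trace is smoothed with a wide Gaussian kernel
(sigma = 25 video frames) and thresholded at its mean + 1 SD; contiguous
supra-threshold runs become behavior bouts.  The threshold adapts to
the trace's own statistics, so detection is invariant to affine
rescaling of the raw intensities.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import EventSeries, MotionEnergyTrace

SMOOTH_SIGMA_FRAMES = 25.0
THRESHOLD_SD = 1.0  # threshold = mean + 1 SD of the smoothed trace


def motion_energy(
    roi_mean_trace: np.ndarray, clock: np.ndarray, roi_id: str = ""
) -> MotionEnergyTrace:
    """energy(t) = |x(t+1) - x(t)| on the video clock.

    The output is one sample shorter than the input; samples where
    either flanking trace value is undefined (mouse out of frame) are
    NaN.
    """
    x = np.asarray(roi_mean_trace, dtype=np.float64)
    clock = np.asarray(clock, dtype=np.float64)
    if x.shape != clock.shape:
        raise ValueError("trace/clock length mismatch")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    energy = np.abs(np.diff(x))
    return MotionEnergyTrace(clock[:-1], energy, roi_id=roi_id)


def detect_events(
    me: MotionEnergyTrace,
    sigma_frames: float = SMOOTH_SIGMA_FRAMES,
    channel: str = "whisker",
    mouse: str = "stationary",
) -> EventSeries:
    """Smooth the motion energy and threshold at its mean + 1 SD.

    Operates on the defined (finite) span of the trace only, so a
    partially visible mouse yields a partially defined series: ``valid``
    marks where detection was possible at all.  An all-flat trace has
    SD 0 and therefore no supra-threshold samples — no events, no error.
    """
    energy = np.asarray(me.energy, dtype=np.float64)
    valid = np.isfinite(energy)
    binary = np.zeros(energy.shape, dtype=bool)
    if valid.any():
        seg = energy[valid]
        if len(seg) < 3 * sigma_frames:
            raise ValueError(
                f"trace too short ({len(seg)} samples) for sigma={sigma_frames}"
            )
        smoothed = ndimage.gaussian_filter1d(seg, sigma_frames, mode="reflect")
        thresh = smoothed.mean() + THRESHOLD_SD * smoothed.std()
        binary[valid] = smoothed > thresh
    return EventSeries.from_binary(
        me.clock, binary, channel=channel, mouse=mouse, valid=valid
    )


def _window_indices(
    clock: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    t0, t1 = window
    return (clock >= t0) & (clock < t1)


def percent_time_behaving(
    es: EventSeries, window: tuple[float, float]
) -> float:
    """Fraction of defined samples inside the window that are behaving."""
    sel = _window_indices(es.clock, window) & es.valid
    if not sel.any():
        raise ValueError(f"window {window} contains no defined samples")
    return float(es.binary[sel].mean())


def crosscorr_binary(
    a: EventSeries,
    b: EventSeries,
    max_lag_s: float = 30.0,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of the two binary vectors at every integer-
    sample lag within +/-``max_lag_s``.

    Positive lag means ``b`` follows ``a``.  Each lag's correlation is
    computed on the overlapping span only; lags where either vector is
    constant (or has no defined overlap) are NaN.
    """
    if len(a.clock) != len(b.clock) or not np.allclose(a.clock, b.clock):
        raise ValueError("series must share a clock")
    sel = np.ones(len(a.clock), dtype=bool)
    if window is not None:
        sel = _window_indices(a.clock, window)
    xa = np.where(sel & a.valid, a.binary.astype(np.float64), np.nan)
    xb = np.where(sel & b.valid, b.binary.astype(np.float64), np.nan)
    fs = a.fs
    max_lag = int(round(max_lag_s * fs))
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full(lags.shape, np.nan)
    n = len(xa)
    for i, lag in enumerate(lags):
        if lag >= 0:
            u, v = xa[: n - lag], xb[lag:]
        else:
            u, v = xa[-lag:], xb[: n + lag]
        ok = np.isfinite(u) & np.isfinite(v)
        if ok.sum() < 2:
            continue
        u, v = u[ok], v[ok]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            continue
        out[i] = ((u - u.mean()) * (v - v.mean())).mean() / (su * sv)
    return lags / fs, out


def jaccard(
    a: EventSeries,
    b: EventSeries,
    window: tuple[float, float] | None = None,
) -> float:
    """Intersection over union of the two binary vectors, over the
    defined samples of the window; 0 when the union is empty."""
    if len(a.clock) != len(b.clock) or not np.allclose(a.clock, b.clock):
        raise ValueError("series must share a clock")
    sel = a.valid & b.valid
    if window is not None:
        sel &= _window_indices(a.clock, window)
    inter = np.count_nonzero(a.binary & b.binary & sel)
    union = np.count_nonzero((a.binary | b.binary) & sel)
    return inter / union if union else 0.0


def extract_events_from_session(
    behavior_traces: dict[tuple[str, str], np.ndarray],
    clock: np.ndarray,
) -> dict[tuple[str, str], EventSeries]:
    """Motion energy + thresholding for every (mouse, channel) ROI trace."""
    out = {}
    for (mouse, channel), trace in behavior_traces.items():
        me = motion_energy(trace, clock, roi_id=f"{mouse}_{channel}")
        out[(mouse, channel)] = detect_events(me, channel=channel, mouse=mouse)
    return out


def plot_ethogram(
    events: dict[tuple[str, str], EventSeries],
    schedule=None,
    ax=None,
):
    """Raster of behavior bouts per (mouse, channel) row; phase
    boundaries drawn if a schedule is given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2 + 0.5 * len(events)))
    for row, ((mouse, channel), es) in enumerate(sorted(events.items())):
        for onset, offset, _ in es.events:
            ax.fill_between([onset, offset], row, row + 0.8, color="k")
        ax.text(0, row + 0.4, f"{mouse}/{channel} ", ha="right", va="center")
    if schedule is not None:
        for _, start, _ in schedule.phases[1:]:
            ax.axvline(start, color="r", ls="--", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    return ax
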