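"""Raw dual-channel stacks -> synchronized, corrected, filtered dF/F0.

Fixed pipeline order, recorded in each stack's provenance:

1. LED-onset detection and cropping (synchronizes cameras);
2. interpolation of dropped frames onto the nominal frame grid;
3. dF/F0 with F0 the temporal mean image over the whole recording;
4. per-pixel clipping of extreme values (mean +/- 3.5 SD for GCaMP,
   +/-15% dF/F0 for reflectance);
5. hemodynamic correction: reflectance dF/F0 subtracted from
   fluorescence dF/F0;
6. spatial Gaussian smoothing (sigma = 1 px) and a zero-phase 4th-order
   Butterworth band-pass, 0.01-12.0 Hz.

Clipping precedes smoothing/filtering so isolated extreme pixels do not
bleed into their neighborhood.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage, signal as sps

from .core import BLUE, GREEN, AlignmentError, DffStack, RawSession, RawStack, SyncError

log = logging.getLogger(__name__)

BANDPASS_HZ = (0.01, 12.0)
BUTTER_ORDER = 4
GCAMP_CLIP_SD = 3.5
REFLECTANCE_CLIP = 0.15
SPATIAL_SIGMA_PX = 1.0


class DegeneratePixelError(ValueError):
    """F0 <= 0 somewhere inside the mask; offending pixels attached."""

    def __init__(self, pixels: np.ndarray):
        self.pixels = pixels
        super().__init__(
            f"{len(pixels)} masked pixel(s) have nonpositive baseline F0; "
            f"first few: {pixels[:5].tolist()}"
        )


# ---------------------------------------------------------------------------
# synchronization


def detect_led_onset(stack: RawStack, min_amplitude: float = 1.0) -> int:
    """First frame whose mean intensity exceeds the midpoint between the
    dark (pre-LED) and lit plateau means.

    The abrupt LED switch-on at trial start is the common temporal
    fiducial across all cameras.
    """
    series = stack.frames.reshape(stack.frames.shape[0], -1).mean(axis=1)
    span = float(series.max() - series.min())
    if span < min_amplitude:
        raise SyncError(
            f"no illumination transition found (amplitude {span:.3g} "
            f"< floor {min_amplitude:.3g})"
        )
    mid = 0.5 * (series.max() + series.min())
    # medians, so activity transients on the lit plateau do not bias it
    lo = np.median(series[series <= mid])
    hi = np.median(series[series > mid])
    thresh = 0.5 * (lo + hi)
    onset = int(np.argmax(series > thresh))
    return onset


def crop_to_onset(stack: RawStack, min_amplitude: float = 1.0) -> RawStack:
    return stack.crop(detect_led_onset(stack, min_amplitude))


# ---------------------------------------------------------------------------
# dropped frames


def interpolate_dropped_frames(stack: RawStack, nominal_fs: float) -> RawStack:
    """Fill timestamp gaps larger than 1.5 frame periods by per-pixel
    linear interpolation onto the nominal frame grid.

    Output is uniformly sampled at ``nominal_fs``.  Gaps cannot extend
    beyond the recorded span; if a requested grid point fell outside it
    the edge frame would be replicated (with a logged warning).
    """
    t = stack.timestamps
    dt = 1.0 / nominal_fs
    n_out = int(round((t[-1] - t[0]) / dt)) + 1
    grid = t[0] + np.arange(n_out) * dt
    if grid[0] < t[0] - 0.5 * dt or grid[-1] > t[-1] + 0.5 * dt:
        log.warning("grid extends beyond recorded span; edge frames replicated")
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(t) - 2)
    denom = t[idx + 1] - t[idx]
    w = np.clip((grid - t[idx]) / denom, 0.0, 1.0)
    exact = np.isclose(w, 0.0)
    frames = stack.frames
    out = np.empty((n_out,) + frames.shape[1:], dtype=frames.dtype)
    out[exact] = frames[idx[exact]]
    rest = ~exact
    if np.any(rest):
        wr = w[rest].astype(frames.dtype)[:, None, None]
        out[rest] = (1 - wr) * frames[idx[rest]] + wr * frames[idx[rest] + 1]
    return RawStack(out, grid - grid[0], stack.channel_label)


# ---------------------------------------------------------------------------
# dF/F0


def auto_mask(stack: RawStack, rel_threshold: float = 0.25) -> np.ndarray:
    """Fallback mask: pixels whose mean intensity exceeds a fraction of
    the image's brightest mean pixel."""
    mean_img = stack.frames.mean(axis=0)
    return mean_img > rel_threshold * mean_img.max()


def compute_dff(stack: RawStack, mask: np.ndarray | None = None) -> DffStack:
    """dF/F0 per pixel with F0 the temporal mean over the whole
    recording.  Pixels outside the mask are set to zero and excluded
    from every downstream statistic."""
    if mask is None:
        mask = auto_mask(stack)
    mask = np.asarray(mask, dtype=bool)
    f0 = stack.frames.mean(axis=0)
    bad = mask & (f0 <= 0)
    if np.any(bad):
        raise DegeneratePixelError(np.argwhere(bad))
    values = np.zeros(stack.frames.shape, dtype=np.float32)
    values[:, mask] = (stack.frames[:, mask] - f0[mask]) / f0[mask]
    dts = np.diff(stack.timestamps)
    fs = 1.0 / float(np.median(dts))
    return DffStack(values, mask, fs, ["dff"])


def clip_extremes(dff: DffStack, mode: str) -> DffStack:
    """Replace extreme dF/F0 samples by the nearer threshold.

    ``gcamp`` mode: per-pixel mean +/- 3.5 x SD of that pixel's time
    series.  ``reflectance`` mode: a fixed +/-15% dF/F0 band (far larger
    than physiological reflectance changes).  Idempotent.
    """
    if mode not in ("gcamp", "reflectance"):
        raise ValueError(f"unknown clip mode {mode!r}")
    values = dff.values.copy()
    m = dff.mask
    if mode == "gcamp":
        mu = values[:, m].mean(axis=0)
        sd = values[:, m].std(axis=0)
        lo, hi = mu - GCAMP_CLIP_SD * sd, mu + GCAMP_CLIP_SD * sd
        values[:, m] = np.clip(values[:, m], lo, hi)
    else:
        values[:, m] = np.clip(values[:, m], -REFLECTANCE_CLIP, REFLECTANCE_CLIP)
    return dff.with_values(values, f"clip[{mode}]")


def hemodynamic_correct(green: DffStack, blue: DffStack) -> DffStack:
    """Subtract the reflectance dF/F0 from the fluorescence dF/F0.

    Blood-volume changes absorb both the 470 nm excitation and the
    emitted green light; the near-isosbestic 440 nm reflectance tracks
    that absorption without a calcium component, so the elementwise
    difference removes the shared artifact.
    """
    if green.values.shape != blue.values.shape:
        raise AlignmentError("green/blue shape mismatch")
    if not np.isclose(green.fs, blue.fs, rtol=1e-6):
        raise AlignmentError("green/blue clock mismatch")
    values = green.values - blue.values
    mask = green.mask & blue.mask
    values[:, ~mask] = 0.0
    prov = green.provenance + [
        "hemodynamic_correct[green-blue]",
        *(f"  blue:{p}" for p in blue.provenance),
    ]
    return DffStack(values, mask, green.fs, prov)


# ---------------------------------------------------------------------------
# smoothing and temporal filtering


def smooth_and_bandpass(
    dff: DffStack,
    sigma_px: float = SPATIAL_SIGMA_PX,
    band_hz: tuple[float, float] = BANDPASS_HZ,
    order: int = BUTTER_ORDER,
) -> DffStack:
    """Spatial Gaussian blur (sigma = 1 px) per frame, then a zero-phase
    (forward-backward) 4th-order Butterworth band-pass per pixel.

    Zero-phase filtering keeps event timing intact, which the lag and
    correlation analyses downstream rely on.
    """
    if dff.fs <= 2 * band_hz[1]:
        raise ValueError(
            f"sampling rate {dff.fs:.3g} Hz too low for a {band_hz[1]} Hz band edge"
        )
    tau = 1.0 / (2.0 * np.pi * band_hz[0])
    if dff.n_frames / dff.fs < 3.0 * tau:
        warnings.warn(
            "recording shorter than 3x the high-pass time constant; "
            "band-pass applied anyway",
            stacklevel=2,
        )
    smoothed = ndimage.gaussian_filter(
        dff.values, sigma=(0.0, sigma_px, sigma_px)
    )
    sos = sps.butter(order, band_hz, btype="bandpass", fs=dff.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, smoothed, axis=0).astype(np.float32)
    filtered[:, ~dff.mask] = 0.0
    out = dff.with_values(
        np.ascontiguousarray(filtered), f"gaussian[sigma={sigma_px}]"
    )
    out.provenance.append(
        f"bandpass[{band_hz[0]}-{band_hz[1]}Hz,order={order},zero-phase]"
    )
    return out


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_stacks(
    green: RawStack,
    blue: RawStack,
    mask: np.ndarray | None = None,
    nominal_fs: float | None = None,
    correct: bool = True,
    keep_green: bool = True,
) -> dict[str, DffStack]:
    """Run the full per-mouse pipeline on one green/blue pair.

    Returns ``{"corrected": ..., "green": ...}`` — the hemodynamics-
    corrected stack and the uncorrected (green-only) stack, both
    smoothed and band-passed.  Set ``correct=False`` to skip the blue
    channel entirely, or ``keep_green=False`` to skip the uncorrected
    output.
    """
    if nominal_fs is None:
        nominal_fs = 1.0 / float(np.median(np.diff(green.timestamps)))
    g = interpolate_dropped_frames(crop_to_onset(green), nominal_fs)
    out: dict[str, DffStack] = {}
    if correct:
        b = interpolate_dropped_frames(crop_to_onset(blue), nominal_fs)
        n = min(g.shape[0], b.shape[0])
        g, b = g.crop(0, n), b.crop(0, n)
        gd = clip_extremes(compute_dff(g, mask), "gcamp")
        bd = clip_extremes(compute_dff(b, mask), "reflectance")
        out["corrected"] = smooth_and_bandpass(hemodynamic_correct(gd, bd))
        if keep_green:
            out["green"] = smooth_and_bandpass(gd)
    else:
        out["green"] = smooth_and_bandpass(
            clip_extremes(compute_dff(g, mask), "gcamp")
        )
    return out


def preprocess_session(
    session: RawSession, correct: bool = True, keep_green: bool = True
) -> dict[str, dict[str, DffStack]]:
    """Preprocess both mice of a raw session.

    Returns ``{mouse: {"corrected": DffStack, "green": DffStack}}``.
    """
    results: dict[str, dict[str, DffStack]] = {}
    for mouse, chans in session.stacks.items():
        results[mouse] = preprocess_stacks(
            chans["green"],
            chans["blue"],
            mask=session.masks.get(mouse),
            correct=correct,
            keep_green=keep_green,
        )
    # after LED synchronization all cameras share t=0; trailing length
    # differences (dropped-frame bookkeeping) are trimmed to the common span
    n = min(s.n_frames for stacks in results.values() for s in stacks.values())
    for stacks in results.values():
        for kind, stack in stacks.items():
            if stack.n_frames > n:
                stacks[kind] = DffStack(
                    stack.values[:n], stack.mask, stack.fs, stack.provenance
                )
    return results
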