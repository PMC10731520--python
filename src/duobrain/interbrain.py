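"""Interbrain correlation and coherence statistics.

Global signals are the spatial median dF/F0 over the masked dorsal
cortex.  Synchrony between the two mice is quantified as the Pearson
correlation of global (or regional) signals within a one-minute window
per trial phase, compared against a trial-shuffle null in which the
stationary-mouse signal of one trial is paired with the moving-mouse
signal of another — destroying true simultaneity while preserving each
signal's own statistics.  Frequency structure is resolved with sliding-
window DPSS multitaper coherence (45 s windows, 50% overlap, NW = 5,
K = 9 tapers).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .core import DffStack, GlobalSignal
from .registration import RegionSet

ANALYSIS_WINDOW_S = 60.0
MT_WINDOW_S = 45.0
MT_OVERLAP_S = 22.5
MT_NW = 5.0
MT_K = 9
REGION_BLOCK = 5  # five-by-five pixel neighborhood per region


@dataclass
class CorrelationMatrixPair:
    """Inter- and intrabrain region-by-region correlations for a phase."""

    inter: np.ndarray  # stationary regions x moving regions
    intra_a: np.ndarray
    intra_b: np.ndarray
    names: list[str]
    phase: str = ""


@dataclass
class CoherenceMap:
    """Time-varying multitaper magnitude-squared coherence."""

    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # Hz
    coherence: np.ndarray  # (n_windows, n_freqs), in [0, 1]
    window_s: float = MT_WINDOW_S
    overlap_s: float = MT_OVERLAP_S
    nw: float = MT_NW
    k: int = MT_K

    def band_mean(
        self, t_window: tuple[float, float], f_band: tuple[float, float]
    ) -> float:
        """Mean coherence over windows centered in ``t_window`` and
        frequencies in ``f_band``."""
        ti = (self.times >= t_window[0]) & (self.times < t_window[1])
        fi = (self.freqs >= f_band[0]) & (self.freqs < f_band[1])
        if not ti.any() or not fi.any():
            raise ValueError("empty time/frequency selection")
        return float(self.coherence[np.ix_(ti, fi)].mean())


# ---------------------------------------------------------------------------
# signals


def global_signal(
    dff: DffStack, mouse: str = "stationary", trial: str = ""
) -> GlobalSignal:
    """Per-frame spatial median over the masked pixels."""
    if not dff.mask.any():
        raise ValueError("empty mask")
    values = np.median(dff.values[:, dff.mask], axis=1)
    return GlobalSignal(values, dff.fs, mouse=mouse, trial=trial)


def region_timeseries(dff: DffStack, rs: RegionSet) -> np.ndarray:
    """regions x time matrix: per frame, the median over the 5x5-pixel
    block centered on each region's placed pixel."""
    half = REGION_BLOCK // 2
    T = dff.n_frames
    H, W = dff.mask.shape
    out = np.empty((len(rs.names), T))
    for i, name in enumerate(rs.names):
        x, y = rs.pixel_index(name)
        if not (half <= x < W - half and half <= y < H - half):
            raise ValueError(
                f"5x5 block for region {name!r} exceeds image bounds"
            )
        block = dff.values[:, y - half : y + half + 1, x - half : x + half + 1]
        mblock = dff.mask[y - half : y + half + 1, x - half : x + half + 1]
        if not mblock.any():
            raise ValueError(f"region {name!r} block entirely outside mask")
        out[i] = np.median(block.reshape(T, -1)[:, mblock.ravel()], axis=1)
    return out


# ---------------------------------------------------------------------------
# correlations


def _pairwise_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with pairwise-complete deletion of NaNs;
    NaN when either input is constant."""
    ok = np.isfinite(x) & np.isfinite(y)
    frac_missing = 1.0 - ok.mean()
    if frac_missing > 0.05:
        warnings.warn(
            f"{frac_missing:.0%} of samples missing in correlation window",
            stacklevel=3,
        )
    if ok.sum() < 2:
        return float("nan")
    u, v = x[ok], y[ok]
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return float("nan")
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def phase_pcc(
    a: GlobalSignal,
    b: GlobalSignal,
    phase_window: tuple[float, float],
) -> float:
    """Pearson correlation of the two signals over the analysis window
    (by convention a 60 s span centered within the phase)."""
    xa = a.slice_window(phase_window)
    xb = b.slice_window(phase_window)
    n = min(len(xa), len(xb))
    if n < 2:
        raise ValueError("window too short")
    return _pairwise_pcc(xa[:n], xb[:n])


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def shuffled_null(
    trial_signals: list[tuple[GlobalSignal, GlobalSignal]],
    phase_window: tuple[float, float],
) -> np.ndarray:
    """Trial-shuffle null: correlate mouse-A of trial i with mouse-B of
    trial j over the interaction-phase window, for every unordered pair
    i < j.  Returns all n(n-1)/2 values (595 for n = 35)."""
    if len(trial_signals) < 2:
        raise ValueError("need at least 2 trials for a shuffle null")
    windows = []
    for ga, gb in trial_signals:
        wa = ga.slice_window(phase_window)
        wb = gb.slice_window(phase_window)
        windows.append((wa, wb))
    n_min = min(min(len(wa), len(wb)) for wa, wb in windows)
    if any(len(wa) != n_min or len(wb) != n_min for wa, wb in windows):
        warnings.warn(
            "unequal window lengths across trials; truncating to shortest",
            stacklevel=2,
        )
    vals = []
    for i, j in combinations(range(len(windows)), 2):
        vals.append(_pairwise_pcc(windows[i][0][:n_min], windows[j][1][:n_min]))
    return np.array(vals)


def correlation_matrices(
    ts_a: np.ndarray,
    ts_b: np.ndarray,
    names: list[str],
    window_idx: slice | np.ndarray | None = None,
    phase: str = "",
) -> CorrelationMatrixPair:
    """Region-by-region correlation matrices over a phase window.

    ``inter[i, j]`` = PCC(region i of mouse A, region j of mouse B);
    the intrabrain matrices are the usual symmetric unit-diagonal
    correlation matrices of each mouse.
    """
    if ts_a.shape != ts_b.shape:
        raise ValueError("region matrices must share shape")
    if window_idx is not None:
        ts_a = ts_a[:, window_idx]
        ts_b = ts_b[:, window_idx]
    nr = ts_a.shape[0]
    inter = np.empty((nr, nr))
    for i in range(nr):
        for j in range(nr):
            inter[i, j] = _pairwise_pcc(ts_a[i], ts_b[j])
    intra_a = np.corrcoef(ts_a)
    intra_b = np.corrcoef(ts_b)
    return CorrelationMatrixPair(inter, intra_a, intra_b, list(names), phase)


def delta_matrices(
    together: CorrelationMatrixPair, before: CorrelationMatrixPair
) -> dict[str, np.ndarray]:
    """Together-minus-before change matrices, plus each region's row
    mean against all partner regions (the per-region summary)."""
    d_inter = together.inter - before.inter
    return {
        "inter": d_inter,
        "intra_a": together.intra_a - before.intra_a,
        "intra_b": together.intra_b - before.intra_b,
        "inter_row_mean": d_inter.mean(axis=1),
    }


def seed_pixel_map(
    dff: DffStack, seed_xy: tuple[int, int]
) -> np.ndarray:
    """Correlation between the seed's 5x5-median trace and every masked
    pixel's trace over the full trial; NaN outside the mask."""
    if not dff.mask.any():
        raise ValueError("empty mask")
    half = REGION_BLOCK // 2
    x, y = seed_xy
    block = dff.values[:, y - half : y + half + 1, x - half : x + half + 1]
    seed = np.median(block.reshape(dff.n_frames, -1), axis=1)
    seed = seed - seed.mean()
    ssd = seed.std()
    if ssd == 0:
        raise ValueError("seed trace is constant")
    pix = dff.values[:, dff.mask].astype(np.float64)
    pix -= pix.mean(axis=0)
    psd = pix.std(axis=0)
    psd[psd == 0] = np.nan
    r = (seed @ pix) / (len(seed) * ssd * psd)
    out = np.full(dff.mask.shape, np.nan)
    out[dff.mask] = r
    return out


# ---------------------------------------------------------------------------
# multitaper coherence


def mt_coherence(
    a: GlobalSignal,
    b: GlobalSignal,
    window_s: float = MT_WINDOW_S,
    overlap_s: float = MT_OVERLAP_S,
    nw: float = MT_NW,
    k: int = MT_K,
) -> CoherenceMap:
    """Sliding-window DPSS multitaper magnitude-squared coherence.

    Per window, cross- and auto-spectra are averaged over the K tapers
    and combined as |sum S_ab|^2 / (sum S_aa * sum S_bb), which is 1 for
    identical signals and has a bias floor of roughly 1/K for
    independent noise.
    """
    if not np.isclose(a.fs, b.fs):
        raise ValueError("signals must share a sampling rate")
    fs = a.fs
    n = min(len(a.values), len(b.values))
    win = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    if win > n:
        raise ValueError("window longer than signal")
    tapers = dpss(win, nw, Kmax=k)  # (k, win)
    freqs = rfftfreq(win, d=1.0 / fs)
    starts = np.arange(0, n - win + 1, step)
    coh = np.empty((len(starts), len(freqs)))
    for wi, s in enumerate(starts):
        xa = a.values[s : s + win] - a.values[s : s + win].mean()
        xb = b.values[s : s + win] - b.values[s : s + win].mean()
        fa = rfft(tapers * xa, axis=1)
        fb = rfft(tapers * xb, axis=1)
        sab = (fa * np.conj(fb)).mean(axis=0)
        saa = (np.abs(fa) ** 2).mean(axis=0)
        sbb = (np.abs(fb) ** 2).mean(axis=0)
        coh[wi] = np.clip(np.abs(sab) ** 2 / (saa * sbb), 0.0, 1.0)
    times = (starts + win / 2.0) / fs
    return CoherenceMap(times, freqs, coh, window_s, overlap_s, nw, k)
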