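"""Ridge-regression encoding model with unique-variance partitioning.

Cortical dF/F0 movies (brain-masked, trials concatenated) are reduced
to their top principal components by SVD; a design matrix of time-
lagged indicator columns built from binary behavior and trial events is
fitted against the component time courses by ridge regression; and
cross-validated explained variance is projected back through the
spatial components onto the cortical map.  A variable's unique
contribution (delta R^2) is the drop in cross-validated R^2 after that
variable's events are randomly permuted in time.

Event kernels: behavior and stage-translation events span every sample
from the event up to 2 s after it; approach events span the 5 s before
arrival; leave events the 5 s after departure.  Kernels never cross
trial boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .core import EventSeries, PhaseSchedule

N_COMPONENTS = 200
N_FOLDS = 10
LAMBDA_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)

#: variable -> (pre_s, post_s) kernel window
DEFAULT_KERNEL_WINDOWS: dict[str, tuple[float, float]] = {
    "stat_whisk_alone": (0.0, 2.0),
    "stat_whisk_together": (0.0, 2.0),
    "stat_forelimb": (0.0, 2.0),
    "partner_whisk_together": (0.0, 2.0),
    "partner_forelimb_together": (0.0, 2.0),
    "stage_translation": (0.0, 2.0),
    "approach": (5.0, 0.0),
    "leave": (0.0, 5.0),
}


@dataclass
class DesignMatrix:
    """Time x columns matrix of lagged event indicators.

    ``column_groups`` maps each variable to its (start, stop) column
    range; within a group the columns are ordered by lag.  ``sources``
    keeps each variable's un-expanded onset indicator so permutation
    can shuffle whole events and re-expand the lags.
    """

    X: np.ndarray
    column_groups: dict[str, tuple[int, int]]
    kernel_windows: dict[str, tuple[float, float]]
    fs: float
    trial_bounds: list[tuple[int, int]]
    sources: dict[str, np.ndarray]
    empty_variables: list[str] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.column_groups)

    def lags_for(self, variable: str) -> np.ndarray:
        pre_s, post_s = self.kernel_windows[variable]
        return _lag_range(pre_s, post_s, self.fs)


@dataclass
class ReducedNeural:
    """Rank-k SVD factorization of the masked, concatenated movie."""

    temporal: np.ndarray  # time x k  (left singular vectors * singular values)
    spatial: np.ndarray  # k x pixels (right singular vectors)
    pixel_mean: np.ndarray  # per-pixel temporal mean removed before SVD
    mask: np.ndarray  # H x W boolean

    @property
    def k(self) -> int:
        return self.temporal.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.temporal @ self.spatial + self.pixel_mean


@dataclass
class EncodingResult:
    betas: np.ndarray
    ridge_penalty: float
    folds: int
    r2_map: np.ndarray  # H x W, NaN outside mask
    r2_pixels: np.ndarray  # masked-pixel vector, pooled over folds
    r2_per_fold: np.ndarray  # folds x pixels
    dr2_maps: dict[str, np.ndarray] = field(default_factory=dict)
    dr2_pixels: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design matrix


def _lag_range(pre_s: float, post_s: float, fs: float) -> np.ndarray:
    """Integer sample lags for a kernel window.

    Post-only windows cover lags 0 .. ceil(post*fs)-1 (so a 2 s window
    at 28.9 fps is exactly 58 columns); pre-only windows cover
    -ceil(pre*fs) .. 0 inclusive.
    """
    n_pre = int(np.ceil(pre_s * fs))
    n_post = int(np.ceil(post_s * fs))
    if n_post == 0:
        return np.arange(-n_pre, 1)
    return np.arange(-n_pre, n_post)


def _expand_lags(
    src: np.ndarray,
    lags: np.ndarray,
    trial_bounds: list[tuple[int, int]],
) -> np.ndarray:
    T = len(src)
    out = np.zeros((T, len(lags)), dtype=np.float64)
    for s, e in trial_bounds:
        seg = src[s:e]
        for ci, lag in enumerate(lags):
            if lag >= 0:
                out[s + lag : e, ci] = seg[: e - s - lag]
            else:
                out[s : e + lag, ci] = seg[-lag:]
    return out


def build_design_matrix(
    sources: dict[str, np.ndarray],
    fs: float,
    trial_bounds: list[tuple[int, int]] | None = None,
    kernel_windows: dict[str, tuple[float, float]] | None = None,
) -> DesignMatrix:
    """Expand each variable's onset indicator into lagged columns.

    ``sources[name]`` is a binary vector on the concatenated neural
    clock with a 1 at each event onset.  Variables with no events are
    kept (all-zero columns) but flagged for exclusion.
    """
    if kernel_windows is None:
        kernel_windows = DEFAULT_KERNEL_WINDOWS
    lengths = {len(v) for v in sources.values()}
    if len(lengths) != 1:
        raise ValueError("all source vectors must share the neural clock")
    T = lengths.pop()
    if trial_bounds is None:
        trial_bounds = [(0, T)]
    if trial_bounds[-1][1] != T or trial_bounds[0][0] != 0:
        raise ValueError("trial bounds must tile the concatenated clock")

    cols: list[np.ndarray] = []
    groups: dict[str, tuple[int, int]] = {}
    empty: list[str] = []
    start = 0
    srcs: dict[str, np.ndarray] = {}
    for name, src in sources.items():
        if name not in kernel_windows:
            raise KeyError(f"no kernel window defined for variable {name!r}")
        src = np.asarray(src, dtype=np.float64)
        if np.any((src != 0) & (src != 1)):
            raise ValueError(f"source for {name!r} must be binary")
        srcs[name] = src
        lags = _lag_range(*kernel_windows[name], fs)
        block = _expand_lags(src, lags, trial_bounds)
        cols.append(block)
        groups[name] = (start, start + block.shape[1])
        start += block.shape[1]
        if not src.any():
            empty.append(name)
    X = np.concatenate(cols, axis=1) if cols else np.zeros((T, 0))
    return DesignMatrix(
        X, groups, dict(kernel_windows), fs, list(trial_bounds), srcs, empty
    )


def _onsets(binary: np.ndarray) -> np.ndarray:
    b = np.asarray(binary, dtype=bool)
    on = np.zeros_like(b)
    on[0] = b[0]
    on[1:] = b[1:] & ~b[:-1]
    return on.astype(np.float64)


def variables_from_events(
    events: dict[tuple[str, str], EventSeries],
    schedule: PhaseSchedule,
    brain_clock: np.ndarray,
) -> dict[str, np.ndarray]:
    """Map one trial's behavior events and phase schedule onto the
    standard encoding variables, as onset indicators on the brain clock.

    Stationary-mouse whisking is split by context — alone versus
    together — according to the phase at bout onset.  Trial-associated
    events (stage translation, approach, leave) come from the schedule.
    """
    T = len(brain_clock)
    out = {name: np.zeros(T) for name in DEFAULT_KERNEL_WINDOWS}

    def mark(name: str, t: float) -> None:
        i = int(np.argmin(np.abs(brain_clock - t)))
        out[name][i] = 1.0

    tog0, tog1 = schedule.window("together")
    for (mouse, channel), es in events.items():
        for onset, _, _ in es.events:
            if onset > brain_clock[-1]:
                continue
            in_together = tog0 <= onset < tog1
            if mouse == "stationary" and channel == "whisker":
                mark(
                    "stat_whisk_together" if in_together else "stat_whisk_alone",
                    onset,
                )
            elif mouse == "stationary" and channel == "forelimb":
                mark("stat_forelimb", onset)
            elif mouse == "moving" and in_together:
                if channel == "whisker":
                    mark("partner_whisk_together", onset)
                else:
                    mark("partner_forelimb_together", onset)
    mark("stage_translation", schedule.window("translate_in")[0])
    mark("stage_translation", schedule.window("translate_out")[0])
    mark("approach", tog0)
    mark("leave", schedule.window("translate_out")[0])
    return out


def concatenate_trials(
    per_trial: list[dict[str, np.ndarray]]
) -> tuple[dict[str, np.ndarray], list[tuple[int, int]]]:
    """Concatenate per-trial variable dictionaries, recording trial
    boundaries so kernels cannot leak across them."""
    names = list(per_trial[0])
    bounds = []
    start = 0
    for d in per_trial:
        T = len(d[names[0]])
        bounds.append((start, start + T))
        start += T
    merged = {
        name: np.concatenate([d[name] for d in per_trial]) for name in names
    }
    return merged, bounds


# ---------------------------------------------------------------------------
# SVD reduction


def svd_reduce(
    data: np.ndarray,
    k: int = N_COMPONENTS,
    mask: np.ndarray | None = None,
    random_state: int = 0,
) -> ReducedNeural:
    """Top-k singular triplets of the (time x masked-pixels) movie,
    mean-centered per pixel.  ``temporal`` carries the singular values
    (U * S) so that ``temporal @ spatial`` reconstructs the centered
    data."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be time x pixels")
    T, P = data.shape
    kmax = min(T, P)
    if k > kmax:
        warnings.warn(f"k={k} truncated to min(dims)={kmax}", stacklevel=2)
        k = kmax
    mean = data.mean(axis=0)
    centered = data - mean
    if kmax <= max(4 * k, 500):
        # exact decomposition when affordable; randomized otherwise
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    else:
        U, S, Vt = randomized_svd(
            centered, n_components=k, n_iter=7, random_state=random_state
        )
    if mask is None:
        mask = np.ones((1, P), dtype=bool)
    return ReducedNeural(U * S, Vt, mean, np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# ridge regression


def ridge_fit(Y: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge: B = (X'X + lam I)^-1 X'Y, per target column."""
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    XtX = X.T @ X
    A = XtX + lam * np.eye(X.shape[1])
    XtY = X.T @ Y
    try:
        return np.linalg.solve(A, XtY)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, XtY, rcond=None)[0]


def _contiguous_folds(T: int, folds: int) -> list[np.ndarray]:
    """Contiguous time blocks, which limits leakage of autocorrelated
    activity between train and test."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    return [np.asarray(ix) for ix in np.array_split(np.arange(T), folds)]


def _pixel_quadratic(E: np.ndarray, spatial: np.ndarray) -> np.ndarray:
    """sum_t ((E @ spatial)_{t,p})^2 for every pixel p, via the k x k
    Gram matrix (avoids materializing the full pixel prediction)."""
    M = E.T @ E
    return np.einsum("ip,ij,jp->p", spatial, M, spatial, optimize=True)


def cv_explained_variance(
    reduced: ReducedNeural,
    dm: DesignMatrix,
    folds: int = N_FOLDS,
    lam: float = 1.0,
    X_override: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel cross-validated R^2 of the rank-k movie.

    Contiguous-block folds; per fold the model is fitted on the training
    rows and held-out component time courses are predicted, then
    projected through the spatial components.  Returns ``(pooled,
    per_fold)``: pooled R^2 = 1 - SSE/SStot with errors summed over all
    folds (also reported per fold).  R^2 is measured against the rank-k
    reconstruction the model can in principle explain.
    """
    X = dm.X if X_override is None else X_override
    Y = reduced.temporal
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and neural data must share rows")
    keep = np.ones(X.shape[1], dtype=bool)
    for name in dm.empty_variables:
        s, e = dm.column_groups[name]
        keep[s:e] = False
    Xk = X[:, keep]
    fold_idx = _contiguous_folds(X.shape[0], folds)
    P = reduced.spatial.shape[1]
    sse = np.zeros(P)
    sst = np.zeros(P)
    per_fold = np.empty((folds, P))
    for fi, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(X.shape[0]), test, assume_unique=True)
        xm = Xk[train].mean(axis=0)
        ym = Y[train].mean(axis=0)
        B = ridge_fit(Y[train] - ym, Xk[train] - xm, lam)
        pred = (Xk[test] - xm) @ B + ym
        E = Y[test] - pred
        D = Y[test] - ym
        sse_f = _pixel_quadratic(E, reduced.spatial)
        sst_f = _pixel_quadratic(D, reduced.spatial)
        sse += sse_f
        sst += sst_f
        with np.errstate(divide="ignore", invalid="ignore"):
            per_fold[fi] = 1.0 - sse_f / sst_f
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = 1.0 - sse / sst
    pooled[sst == 0] = np.nan
    return pooled, per_fold


def permute_variable(
    dm: DesignMatrix, variable: str, seed: int
) -> np.ndarray:
    """Design matrix with one variable's events randomly permuted.

    The variable's onset series is circularly shifted by a seeded random
    offset within each trial and its lag columns re-expanded, so kernel
    structure survives the permutation while any alignment with the
    neural data is destroyed.
    """
    if variable not in dm.column_groups:
        raise KeyError(f"unknown variable {variable!r}")
    rng = np.random.default_rng(seed)
    src = dm.sources[variable].copy()
    for s, e in dm.trial_bounds:
        if e - s > 1:
            shift = int(rng.integers(1, e - s))
            src[s:e] = np.roll(src[s:e], shift)
    X = dm.X.copy()
    s, e = dm.column_groups[variable]
    X[:, s:e] = _expand_lags(src, dm.lags_for(variable), dm.trial_bounds)
    return X


def unique_contribution(
    reduced: ReducedNeural,
    dm: DesignMatrix,
    variable: str,
    folds: int = N_FOLDS,
    lam: float = 1.0,
    seed: int = 0,
    r2_full: np.ndarray | None = None,
) -> np.ndarray:
    """delta R^2 map for one variable: full-model CV R^2 minus the CV
    R^2 of the model with that variable permuted."""
    if r2_full is None:
        r2_full, _ = cv_explained_variance(reduced, dm, folds, lam)
    Xp = permute_variable(dm, variable, seed)
    r2_reduced, _ = cv_explained_variance(
        reduced, dm, folds, lam, X_override=Xp
    )
    return r2_full - r2_reduced


def select_lambda(
    reduced: ReducedNeural,
    dm: DesignMatrix,
    grid: tuple[float, ...] = LAMBDA_GRID,
    folds: int = N_FOLDS,
) -> float:
    """Ridge penalty chosen by grid search: the value minimizing the
    pooled cross-validated SSE on the component time courses."""
    best_lam, best_sse = None, np.inf
    keep = np.ones(dm.X.shape[1], dtype=bool)
    for name in dm.empty_variables:
        s, e = dm.column_groups[name]
        keep[s:e] = False
    Xk = dm.X[:, keep]
    Y = reduced.temporal
    fold_idx = _contiguous_folds(Xk.shape[0], folds)
    for lam in grid:
        sse = 0.0
        for test in fold_idx:
            train = np.setdiff1d(
                np.arange(Xk.shape[0]), test, assume_unique=True
            )
            xm = Xk[train].mean(axis=0)
            ym = Y[train].mean(axis=0)
            B = ridge_fit(Y[train] - ym, Xk[train] - xm, lam)
            pred = (Xk[test] - xm) @ B + ym
            sse += float(((Y[test] - pred) ** 2).sum())
        if sse < best_sse:
            best_lam, best_sse = lam, sse
    return float(best_lam)


def _to_map(mask: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = pixels
    return out


def fit_encoding_model(
    reduced: ReducedNeural,
    dm: DesignMatrix,
    variables: list[str] | None = None,
    folds: int = N_FOLDS,
    lam: float | None = None,
    seed: int = 0,
) -> EncodingResult:
    """Full pipeline: penalty selection (unless fixed), pooled CV R^2
    map, and delta R^2 maps for the requested variables."""
    if lam is None:
        lam = select_lambda(reduced, dm, folds=folds)
    r2_pix, per_fold = cv_explained_variance(reduced, dm, folds, lam)
    betas = ridge_fit(
        reduced.temporal - reduced.temporal.mean(axis=0),
        dm.X - dm.X.mean(axis=0),
        lam,
    )
    result = EncodingResult(
        betas=betas,
        ridge_penalty=lam,
        folds=folds,
        r2_map=_to_map(reduced.mask, r2_pix),
        r2_pixels=r2_pix,
        r2_per_fold=per_fold,
    )
    if variables is None:
        variables = [v for v in dm.variables if v not in dm.empty_variables]
    for var in variables:
        dr2 = unique_contribution(
            reduced, dm, var, folds, lam, seed=seed, r2_full=r2_pix
        )
        result.dr2_pixels[var] = dr2
        result.dr2_maps[var] = _to_map(reduced.mask, dr2)
    return result
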