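"""Synthetic paired two-mouse sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* behavior bouts (whisker / forelimb) as a Poisson process with
  exponential durations, per mouse;
* a social coupling active only while the mice are together, where a
  bout of the stationary mouse triggers a time-locked bout in the moving
  mouse with some probability at a short lag;
* regional GCaMP responses: each behavior channel drives a Gaussian
  blob at a named cortical region, convolved with a slow double-
  exponential calcium kernel (GCaMP6s-like: 0.2 s rise, 1.5 s decay),
  on top of a diffuse cortex-wide movement-related component;
* a mutual-touch drive: while together, the partner's whisking drives
  posterior barrel cortex of the other mouse (absent with a barrier);
* a slow shared hemodynamic artifact present in both the green
  (fluorescence) and blue (reflectance) channels;
* per-pixel sensor noise, pre-LED dark frames, and randomly dropped
  frames (0.1% of frames by default).

``gfp_mode`` models an activity-independent fluorophore control: the
green channel then carries only the hemodynamic artifact and noise, so
any interbrain correlation that survives hemodynamic correction would be
an artifact of the pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import (
    BEHAVIOR_CHANNELS,
    BLUE,
    GREEN,
    MICE,
    EventSeries,
    PhaseSchedule,
    RawSession,
    RawStack,
)
from .registration import (
    DEFAULT_ATLAS_KEYPOINTS_MM,
    KeyPoints,
    RegionSet,
    SimilarityTransform,
    fit_transform,
    place_regions,
)

#: Behavior channel -> cortical region it drives (own movements).
DRIVEN_REGIONS = {"whisker": "aBC", "forelimb": "FL"}
#: Partner whisking (touch) drives posterior barrel cortex.
PARTNER_DRIVEN_REGION = "pBC"

#: Field of view of the widefield camera, mm (square window).
FIELD_OF_VIEW_MM = 10.2


@dataclass(frozen=True)
class SessionParams:
    """Generator settings.  Defaults follow the staged-interaction
    paradigm: five phases (2 min apart, ~27.5 s translation, 2 min
    together), 28.9 fps dual-channel brain imaging, 90 fps behavior."""

    schedule: PhaseSchedule = field(
        default_factory=PhaseSchedule.from_durations
    )
    fs_brain: float = 28.9
    fs_behavior: float = 90.0
    image_size: int = 64
    event_rate_hz: float = 0.1
    mean_bout_s: float = 1.5
    coupling: float = 0.5
    response_gain: float = 0.05
    global_gain: float = 0.02
    partner_gain: float = 0.03
    hemo_gain: float = 0.02
    noise_sd: float = 0.01
    drop_frac: float = 0.001
    gfp_mode: bool = False
    condition: str = "open"
    seed: int = 0
    n_dark_frames: int = 12
    baseline_green: float = 100.0
    baseline_blue: float = 80.0
    ca_rise_s: float = 0.2
    ca_decay_s: float = 1.5
    blob_sigma_px: float | None = None
    lag_range_s: tuple[float, float] = (0.0, 1.0)
    roi_baseline: float = 50.0
    roi_noise_quiet: float = 0.2
    roi_noise_active: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 0.0 <= self.drop_frac <= 0.05:
            raise ValueError("drop_frac must be in [0, 0.05]")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if self.mean_bout_s <= 0:
            raise ValueError("mean_bout_s must be > 0")
        if self.condition not in ("open", "mesh", "opaque"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fs_brain <= 24.0:
            raise ValueError("fs_brain must exceed 24 Hz")
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if self.lag_range_s[0] < 0 or self.lag_range_s[1] < self.lag_range_s[0]:
            raise ValueError("invalid lag range")

    @property
    def duration_s(self) -> float:
        return self.schedule.duration_s

    @property
    def blob_sigma(self) -> float:
        if self.blob_sigma_px is not None:
            return self.blob_sigma_px
        return 3.0 * self.image_size / 64.0

    @property
    def effective_coupling(self) -> float:
        """Behavioral coupling requires whisker contact: zero with a
        mesh or opaque barrier in place."""
        return self.coupling if self.condition == "open" else 0.0

    @property
    def effective_partner_gain(self) -> float:
        if self.condition != "open" or self.gfp_mode:
            return 0.0
        return self.partner_gain


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    events: dict[tuple[str, str], EventSeries]
    triggered: dict[str, list[tuple[float, float]]]
    driven_region_map: dict[str, str]
    hemo_trace: np.ndarray
    dropped_frame_indices: dict[tuple[str, str], np.ndarray]
    region_set: RegionSet
    mask: np.ndarray
    transform: SimilarityTransform
    keypoints: KeyPoints

    def __post_init__(self) -> None:
        for region in self.driven_region_map.values():
            if region not in self.region_set.regions_mm:
                raise ValueError(f"driven region {region!r} not in region set")
        for idx in self.dropped_frame_indices.values():
            if len(idx) and (np.any(np.diff(idx) <= 0)):
                raise ValueError("dropped indices must be unique and sorted")


# ---------------------------------------------------------------------------
# geometry


def default_geometry(
    image_size: int,
) -> tuple[np.ndarray, KeyPoints, SimilarityTransform, RegionSet]:
    """Window geometry for a synthetic session of a given image size.

    Bregma sits on the vertical midline with anterior up; the pixel
    scale puts the full 10.2 mm field of view across the image.  The
    mask is a rounded superellipse covering both hemispheres.
    """
    n = image_size
    scale = n / FIELD_OF_VIEW_MM  # px per mm
    cx, cy = n / 2.0, 0.42 * n
    kp = KeyPoints(
        bregma_px=(cx, cy),
        sinus_px=(cx, cy + 4.5 * scale),
        ob_frontal_px=(cx, cy - 3.8 * scale),
    )
    transform = fit_transform(kp, DEFAULT_ATLAS_KEYPOINTS_MM)
    yy, xx = np.mgrid[0:n, 0:n]
    a, b = 0.45 * n, 0.40 * n
    mask = ((xx - cx) / a) ** 4 + ((yy - 0.47 * n) / b) ** 4 < 1.0
    regions = place_regions(transform, RegionSet(), mask)
    return mask, kp, transform, regions


def gaussian_blob(
    shape: tuple[int, int], center_xy: tuple[float, float], sigma: float
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = center_xy
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))


def calcium_kernel(
    fs: float,
    rise_s: float = 0.2,
    decay_s: float = 1.5,
    normalize: str = "peak",
) -> np.ndarray:
    """Difference-of-exponentials GCaMP6s-like impulse response.

    ``normalize="peak"`` scales to unit maximum (the analytic kernel
    shape); ``"area"`` scales to unit sum, so that convolving a binary
    bout indicator yields a response that saturates at 1 during a
    sustained bout — the rendering convention, which makes the gain
    parameters interpretable as plateau dF/F0 amplitudes.
    """
    t = np.arange(0.0, 8.0 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    if normalize == "area":
        return k / k.sum()
    return k / k.max()


# ---------------------------------------------------------------------------
# events


def _merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for onset, offset in intervals[1:]:
        if onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    return [(a, b) for a, b in merged]


def _poisson_bouts(
    rng: np.random.Generator, rate_hz: float, mean_bout_s: float, duration_s: float
) -> list[tuple[float, float]]:
    if rate_hz == 0:
        return []
    bouts = []
    t = rng.exponential(1.0 / rate_hz)
    while t < duration_s:
        dur = rng.exponential(mean_bout_s)
        bouts.append((t, min(t + dur, duration_s)))
        t += rng.exponential(1.0 / rate_hz)
    return bouts


def generate_events(params: SessionParams) -> tuple[dict, GroundTruth]:
    """Draw behavior bouts for both mice and assemble the ground truth.

    Returns ``(events, truth)`` where ``events[(mouse, channel)]`` is an
    ``EventSeries`` on the behavior clock.  During the together phase,
    each stationary-mouse bout independently triggers a moving-mouse
    bout of the same channel and duration with probability ``coupling``
    at a lag drawn uniformly from ``lag_range_s``; outside that phase
    the mice are independent.
    """
    rng = np.random.default_rng(params.seed)
    duration = params.duration_s
    clock = np.arange(round(duration * params.fs_behavior)) / params.fs_behavior
    tog0, tog1 = params.schedule.window("together")

    raw: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for mouse in MICE:
        for channel in BEHAVIOR_CHANNELS:
            raw[(mouse, channel)] = _poisson_bouts(
                rng, params.event_rate_hz, params.mean_bout_s, duration
            )

    triggered: dict[str, list[tuple[float, float]]] = {
        c: [] for c in BEHAVIOR_CHANNELS
    }
    c_eff = params.effective_coupling
    if c_eff > 0:
        lo, hi = params.lag_range_s
        for channel in BEHAVIOR_CHANNELS:
            for onset, offset in raw[("stationary", channel)]:
                if not (tog0 <= onset < tog1):
                    continue
                if rng.random() >= c_eff:
                    continue
                lag = lo if hi == lo else rng.uniform(lo, hi)
                t_on = onset + lag
                if t_on >= duration:
                    continue
                t_off = min(t_on + (offset - onset), duration)
                if t_off > t_on:
                    triggered[channel].append((t_on, t_off))
                    raw[("moving", channel)].append((t_on, t_off))

    events: dict[tuple[str, str], EventSeries] = {}
    for (mouse, channel), bouts in raw.items():
        merged = _merge_intervals(bouts)
        events[(mouse, channel)] = EventSeries.from_events(
            clock, merged, channel=channel, mouse=mouse
        )

    mask, kp, transform, regions = default_geometry(params.image_size)

    n_frames = round(duration * params.fs_brain)
    hemo = _hemo_trace(rng, n_frames, params.fs_brain)

    truth = GroundTruth(
        events=events,
        triggered=triggered,
        driven_region_map={
            **DRIVEN_REGIONS,
            "partner_whisker": PARTNER_DRIVEN_REGION,
        },
        hemo_trace=hemo,
        dropped_frame_indices={},
        region_set=regions,
        mask=mask,
        transform=transform,
        keypoints=kp,
    )
    return events, truth


def _hemo_trace(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-SD slow shared artifact, band-limited below ~0.15 Hz."""
    white = rng.standard_normal(n + 256)
    sos = sps.butter(2, 0.15, btype="low", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos, white)[128 : 128 + n]
    sd = slow.std()
    return slow / sd if sd > 0 else slow


# ---------------------------------------------------------------------------
# rendering


def _bout_indicator(
    bouts: list[tuple[float, float, float]], times: np.ndarray
) -> np.ndarray:
    out = np.zeros(times.shape, dtype=np.float64)
    for onset, offset, _ in bouts:
        out[(times >= onset) & (times < offset)] = 1.0
    return out


def render_session(params: SessionParams, truth: GroundTruth) -> RawSession:
    """Render raw camera streams (green + blue per mouse) and behavior
    ROI traces from the drawn events.

    The green stack is baseline x (1 + neural signal + hemodynamic
    artifact) + noise; the blue stack shares the hemodynamic artifact
    but carries no neural signal, which is what makes subtraction-based
    correction exact in expectation.  Dark frames precede the LED onset
    and a random subset of frames is dropped per camera (timestamps are
    preserved so the gaps are identifiable).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = params.image_size
    fs = params.fs_brain
    n_frames = round(params.duration_s * fs)
    times = np.arange(n_frames) / fs
    mask = truth.mask
    maskf = mask.astype(np.float32)
    kern = calcium_kernel(fs, params.ca_rise_s, params.ca_decay_s, normalize="area")
    tog0, tog1 = params.schedule.window("together")

    if len(truth.hemo_trace) != n_frames:
        raise ValueError("ground truth inconsistent with params (hemo length)")

    # convolved response per mouse per channel, on the brain clock
    resp: dict[tuple[str, str], np.ndarray] = {}
    for key, es in truth.events.items():
        ind = _bout_indicator(es.events, times)
        resp[key] = sps.fftconvolve(ind, kern)[:n_frames]

    blobs = {
        name: gaussian_blob(
            (n, n), truth.region_set.pixel_coords[name], params.blob_sigma
        ).astype(np.float32)
        for name in set(truth.driven_region_map.values())
    }
    together_gate = ((times >= tog0) & (times < tog1)).astype(np.float64)

    stacks: dict[str, dict[str, RawStack]] = {}
    dropped: dict[tuple[str, str], np.ndarray] = {}
    other = {"stationary": "moving", "moving": "stationary"}
    for mouse in MICE:
        sig = np.zeros((n_frames, n, n), dtype=np.float32)
        if not params.gfp_mode:
            for channel in BEHAVIOR_CHANNELS:
                r = resp[(mouse, channel)].astype(np.float32)
                region = truth.driven_region_map[channel]
                sig += (
                    params.response_gain
                    * r[:, None, None]
                    * blobs[region][None, :, :]
                )
                sig += (
                    params.global_gain * r[:, None, None] * maskf[None, :, :]
                )
            pg = params.effective_partner_gain
            if pg > 0:
                partner_whisk = resp[(other[mouse], "whisker")] * together_gate
                sig += (
                    pg
                    * partner_whisk.astype(np.float32)[:, None, None]
                    * blobs[PARTNER_DRIVEN_REGION][None, :, :]
                )

        hemo = params.hemo_gain * truth.hemo_trace.astype(np.float32)
        for channel_label, baseline, neural in (
            (GREEN, params.baseline_green, sig),
            (BLUE, params.baseline_blue, None),
        ):
            frames = np.empty((n_frames, n, n), dtype=np.float32)
            frames[:] = hemo[:, None, None]
            if neural is not None:
                frames += neural
            frames += 1.0
            frames *= baseline
            frames += rng.standard_normal(frames.shape, dtype=np.float32) * (
                params.noise_sd * baseline
            )
            frames = np.maximum(frames, 0.0)
            # dark lead-in before the synchronization LED switches on
            dark = np.full(
                (params.n_dark_frames, n, n), 1.0, dtype=np.float32
            ) + 0.05 * rng.standard_normal(
                (params.n_dark_frames, n, n), dtype=np.float32
            )
            full = np.concatenate([np.maximum(dark, 0.0), frames])
            ts = np.arange(len(full)) / fs
            # dropped frames: random, never the flanks of the lit span
            lo = params.n_dark_frames + 1
            hi = len(full) - 2
            drop = np.flatnonzero(
                rng.random(len(full)) < params.drop_frac
            )
            drop = drop[(drop >= lo) & (drop <= hi)]
            keep = np.ones(len(full), dtype=bool)
            keep[drop] = False
            stacks.setdefault(mouse, {})[
                "green" if channel_label == GREEN else "blue"
            ] = RawStack(full[keep], ts[keep], channel_label)
            dropped[(mouse, "green" if channel_label == GREEN else "blue")] = drop

    truth.dropped_frame_indices = dropped

    # behavior ROI traces: higher-variance jitter of the ROI mean during
    # bouts (motion), quiet jitter otherwise; moving mouse visible only
    # while together
    b_clock = np.arange(round(params.duration_s * params.fs_behavior)) / (
        params.fs_behavior
    )
    traces: dict[tuple[str, str], np.ndarray] = {}
    for (mouse, channel), es in truth.events.items():
        active = es.binary.astype(np.float64)
        noise = rng.standard_normal(len(b_clock))
        trace = params.roi_baseline + noise * (
            params.roi_noise_quiet
            + (params.roi_noise_active - params.roi_noise_quiet) * active
        )
        if mouse == "moving":
            visible = (b_clock >= tog0) & (b_clock < tog1)
            trace = np.where(visible, trace, np.nan)
        traces[(mouse, channel)] = trace

    kp_dict = {
        "bregma": truth.keypoints.bregma_px,
        "sinus": truth.keypoints.sinus_px,
        "ob_frontal": truth.keypoints.ob_frontal_px,
    }
    return RawSession(
        stacks=stacks,
        behavior_traces=traces,
        behavior_clock=b_clock,
        schedule=params.schedule,
        masks={m: mask.copy() for m in MICE},
        keypoints={m: kp_dict for m in MICE},
        condition=params.condition,
        trial_id=f"seed{params.seed}",
    )


def simulate_session(params: SessionParams) -> tuple[RawSession, GroundTruth]:
    """Convenience: draw events and render the full raw session."""
    events, truth = generate_events(params)
    session = render_session(params, truth)
    return session, truth
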