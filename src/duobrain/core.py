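"""Shared data containers for the dual-brain widefield pipeline.

A session pairs two head-fixed mice, each imaged with a dual-channel
widefield camera (green = GCaMP epifluorescence, blue = near-isosbestic
reflectance used to estimate hemodynamic contamination), while a third
camera records behavior.  A trial walks through five phases: the mice
start apart, the stage translates one mouse in, they sit whisker-to-whisker
("together"), the stage translates back out, and they finish apart.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PHASE_LABELS = ("separate1", "translate_in", "together", "translate_out", "separate2")

GREEN = "green_gcamp"
BLUE = "blue_reflectance"

BEHAVIOR_CHANNELS = ("whisker", "forelimb")
MICE = ("stationary", "moving")


class AlignmentError(ValueError):
    """Raised when two streams that must share a clock/shape do not."""


class SyncError(RuntimeError):
    """Raised when the LED synchronization transition cannot be found."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous trial phases covering [0, duration_s].

    ``phases`` is a tuple of (label, start_s, end_s).
    """

    phases: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("phase schedule is empty")
        prev_end = 0.0
        for label, start, end in self.phases:
            if label not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {label!r}")
            if not np.isclose(start, prev_end):
                raise ValueError("phases must be contiguous and start at 0")
            if end <= start:
                raise ValueError(f"phase {label!r} has nonpositive duration")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.phases[-1][2]

    def window(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.phases:
            if lab == label:
                return (start, end)
        raise KeyError(label)

    def label_at(self, t: float) -> str:
        for lab, start, end in self.phases:
            if start <= t < end:
                return lab
        if np.isclose(t, self.duration_s):
            return self.phases[-1][0]
        raise ValueError(f"time {t} outside schedule")

    def centered_window(self, label: str, width_s: float) -> tuple[float, float]:
        """A ``width_s`` analysis window centered within the phase.

        If the phase is shorter than ``width_s`` the whole phase is
        returned.
        """
        start, end = self.window(label)
        if end - start <= width_s:
            return (start, end)
        mid = 0.5 * (start + end)
        return (mid - width_s / 2.0, mid + width_s / 2.0)

    @classmethod
    def from_durations(
        cls,
        separate_s: float = 120.0,
        translate_s: float = 27.5,
        together_s: float | None = None,
    ) -> "PhaseSchedule":
        """Standard five-phase layout: separate / translate / together /
        translate / separate.  Defaults follow the staged-interaction
        paradigm (2 min apart, ~27.5 s stage translation, 2 min together).
        """
        if together_s is None:
            together_s = separate_s
        t = 0.0
        spans = []
        for label, dur in zip(
            PHASE_LABELS,
            (separate_s, translate_s, together_s, translate_s, separate_s),
        ):
            spans.append((label, t, t + dur))
            t += dur
        return cls(tuple(spans))


@dataclass
class RawStack:
    """One camera channel: T x H x W intensities plus per-frame timestamps."""

    frames: np.ndarray
    timestamps: np.ndarray
    channel_label: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("timestamps must match frame count")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if min(self.frames.shape[1:]) < 1:
            raise ValueError("empty image plane")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def crop(self, start: int, stop: int | None = None) -> "RawStack":
        sl = slice(start, stop)
        t = self.timestamps[sl]
        return RawStack(self.frames[sl], t - t[0], self.channel_label)


@dataclass
class DffStack:
    """Fractional fluorescence change dF/F0 with mask and provenance.

    ``provenance`` records the processing steps in the order applied so
    downstream code can assert the pipeline ran dff -> clip -> correct ->
    smooth -> bandpass.
    """

    values: np.ndarray
    mask: np.ndarray
    fs: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be T x H x W")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape mismatch")
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ValueError("non-finite dF/F0 inside mask")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def with_values(self, values: np.ndarray, step: str) -> "DffStack":
        return DffStack(values, self.mask, self.fs, self.provenance + [step])


@dataclass
class EventSeries:
    """Binary behavior vector plus its event list on a stated clock.

    ``valid`` marks the samples where the series is defined at all: the
    moving mouse only enters the behavior camera's field of view during
    the together phase, so its series is partially defined.
    """

    clock: np.ndarray
    binary: np.ndarray
    events: list[tuple[float, float, float]]
    channel: str = "whisker"
    mouse: str = "stationary"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.clock = np.asarray(self.clock, dtype=np.float64)
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.clock.shape != self.binary.shape:
            raise ValueError("clock/binary length mismatch")
        if self.valid is None:
            self.valid = np.ones_like(self.binary, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        prev_off = -np.inf
        for onset, offset, dur in self.events:
            if offset <= onset or dur <= 0:
                raise ValueError("events must have positive duration")
            if onset < prev_off:
                raise ValueError("events must be ordered and non-overlapping")
            prev_off = offset

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.clock)))

    @classmethod
    def from_events(
        cls,
        clock: np.ndarray,
        events: Iterable[tuple[float, float]],
        channel: str = "whisker",
        mouse: str = "stationary",
        valid: np.ndarray | None = None,
    ) -> "EventSeries":
        clock = np.asarray(clock, dtype=np.float64)
        binary = np.zeros(clock.shape, dtype=bool)
        evs = []
        for onset, offset in events:
            binary |= (clock >= onset) & (clock < offset)
            evs.append((float(onset), float(offset), float(offset - onset)))
        return cls(clock, binary, evs, channel=channel, mouse=mouse, valid=valid)

    @classmethod
    def from_binary(
        cls,
        clock: np.ndarray,
        binary: np.ndarray,
        channel: str = "whisker",
        mouse: str = "stationary",
        valid: np.ndarray | None = None,
    ) -> "EventSeries":
        clock = np.asarray(clock, dtype=np.float64)
        binary = np.asarray(binary, dtype=bool)
        if len(clock) < 2:
            raise ValueError("clock too short")
        dt = float(np.median(np.diff(clock)))
        evs = []
        padded = np.concatenate(([False], binary, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            onset = clock[i0]
            offset = clock[i1] if i1 < len(clock) else clock[-1] + dt
            evs.append((float(onset), float(offset), float(offset - onset)))
        return cls(clock, binary, evs, channel=channel, mouse=mouse, valid=valid)

    def to_binary(self) -> np.ndarray:
        """Recompute the binary vector from the event list (round-trip)."""
        out = np.zeros_like(self.binary)
        for onset, offset, _ in self.events:
            out |= (self.clock >= onset) & (self.clock < offset)
        return out

    def resample(self, new_clock: np.ndarray) -> "EventSeries":
        """Nearest-sample mapping of the series onto another clock
        (e.g., 90 fps behavior onto the 28.9 fps brain clock)."""
        new_clock = np.asarray(new_clock, dtype=np.float64)
        idx = np.clip(
            np.searchsorted(self.clock, new_clock), 0, len(self.clock) - 1
        )
        left = np.clip(idx - 1, 0, len(self.clock) - 1)
        use_left = np.abs(new_clock - self.clock[left]) <= np.abs(
            self.clock[idx] - new_clock
        )
        nearest = np.where(use_left, left, idx)
        return EventSeries(
            new_clock,
            self.binary[nearest],
            list(self.events),
            channel=self.channel,
            mouse=self.mouse,
            valid=self.valid[nearest],
        )


@dataclass
class MotionEnergyTrace:
    """Absolute temporal gradient of an ROI's mean pixel value."""

    clock: np.ndarray
    energy: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.clock = np.asarray(self.clock, dtype=np.float64)
        self.energy = np.asarray(self.energy, dtype=np.float64)
        if self.clock.shape != self.energy.shape:
            raise ValueError("clock/energy length mismatch")
        finite = np.isfinite(self.energy)
        if np.any(self.energy[finite] < 0):
            raise ValueError("motion energy must be nonnegative")


@dataclass
class GlobalSignal:
    """Spatial median dF/F0 over the masked dorsal cortex, per frame."""

    values: np.ndarray
    fs: float
    mouse: str = "stationary"
    trial: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("global signal must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    def slice_window(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        i0 = int(np.ceil(t0 * self.fs - 1e-9))
        i1 = int(np.floor(t1 * self.fs + 1e-9)) + 1
        return self.values[max(i0, 0) : min(i1, len(self.values))]


@dataclass
class RawSession:
    """One paired two-mouse trial as emitted by the generator or loader.

    ``stacks[mouse][channel]`` holds the raw camera streams (including any
    pre-LED dark frames and dropped frames); ``behavior_traces[(mouse,
    channel)]`` are ROI mean-pixel traces on ``behavior_clock`` (NaN where
    the mouse is out of frame).
    """

    stacks: dict[str, dict[str, RawStack]]
    behavior_traces: dict[tuple[str, str], np.ndarray]
    behavior_clock: np.ndarray
    schedule: PhaseSchedule
    masks: dict[str, np.ndarray]
    keypoints: dict[str, dict[str, tuple[float, float]]]
    condition: str = "open"
    trial_id: str = "trial0"

    def __post_init__(self) -> None:
        if self.condition not in ("open", "mesh", "opaque"):
            raise ValueError(f"unknown condition {self.condition!r}")
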