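"""Session manifests, format readers/writers, and result bundles.

On-disk layout of a session directory:

* ``manifest.yaml`` — trial metadata, fs values, phase schedule,
  condition, key-points, and relative paths to every artifact;
* ``<mouse>_<green|blue>.tif`` — multi-page TIFF stacks;
* ``<mouse>_<green|blue>_timestamps.csv`` — per-frame timestamps;
* ``behavior_rois.csv`` — behavior clock plus one ROI-mean column per
  (mouse, channel);
* ``mask_<mouse>.tif`` — uint8 cortical masks;
* ``events_truth.csv`` — ground-truth bouts (synthetic sessions only).

Multidimensional results go to HDF5, tabular results to CSV; every
result file embeds the config hash and seed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import BLUE, GREEN, EventSeries, PhaseSchedule, RawSession, RawStack


class ManifestError(ValueError):
    pass


@dataclass
class Manifest:
    """Validated description of one trial's files and parameters."""

    trial_id: str
    root: Path
    stack_paths: dict[str, dict[str, str]]
    timestamp_paths: dict[str, dict[str, str]]
    behavior_path: str
    mask_paths: dict[str, str]
    keypoints: dict[str, dict[str, tuple[float, float]]]
    fs_brain: float
    fs_behavior: float
    schedule: PhaseSchedule
    condition: str = "open"
    mice: tuple[str, str] = ("stationary", "moving")
    cagemates: bool = True
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("open", "mesh", "opaque"):
            raise ManifestError(f"condition must be open/mesh/opaque, got {self.condition!r}")
        for label, rel in self._all_paths():
            if not (self.root / rel).exists():
                raise ManifestError(f"missing file for {label}: {rel}")

    def _all_paths(self):
        for mouse, chans in self.stack_paths.items():
            for chan, rel in chans.items():
                yield f"stack_paths[{mouse}][{chan}]", rel
        for mouse, chans in self.timestamp_paths.items():
            for chan, rel in chans.items():
                yield f"timestamp_paths[{mouse}][{chan}]", rel
        yield "behavior_path", self.behavior_path
        for mouse, rel in self.mask_paths.items():
            yield f"mask_paths[{mouse}]", rel


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# writing


def write_session(
    out_dir: str | Path,
    session: RawSession,
    truth=None,
    params=None,
) -> Path:
    """Write a session directory (stacks, manifest, behavior traces,
    masks, and ground-truth events if available).  Returns the manifest
    path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_paths: dict[str, dict[str, str]] = {}
    ts_paths: dict[str, dict[str, str]] = {}
    for mouse, chans in session.stacks.items():
        for chan, stack in chans.items():
            rel = f"{mouse}_{chan}.tif"
            tifffile.imwrite(out / rel, stack.frames, dtype=np.float32)
            ts_rel = f"{mouse}_{chan}_timestamps.csv"
            pd.DataFrame({"timestamp_s": stack.timestamps}).to_csv(
                out / ts_rel, index=False
            )
            stack_paths.setdefault(mouse, {})[chan] = rel
            ts_paths.setdefault(mouse, {})[chan] = ts_rel

    beh = pd.DataFrame({"time_s": session.behavior_clock})
    for (mouse, channel), trace in session.behavior_traces.items():
        beh[f"{mouse}_{channel}"] = trace
    beh.to_csv(out / "behavior_rois.csv", index=False)

    mask_paths = {}
    for mouse, mask in session.masks.items():
        rel = f"mask_{mouse}.tif"
        tifffile.imwrite(out / rel, mask.astype(np.uint8))
        mask_paths[mouse] = rel

    if truth is not None:
        rows = []
        for (mouse, channel), es in truth.events.items():
            for onset, offset, dur in es.events:
                rows.append(
                    {
                        "mouse": mouse,
                        "channel": channel,
                        "onset_s": onset,
                        "offset_s": offset,
                        "duration_s": dur,
                    }
                )
        pd.DataFrame(
            rows, columns=["mouse", "channel", "onset_s", "offset_s", "duration_s"]
        ).to_csv(out / "events_truth.csv", index=False)

    manifest = {
        "trial_id": session.trial_id,
        "condition": session.condition,
        "fs_brain": float(params.fs_brain) if params is not None else None,
        "fs_behavior": float(params.fs_behavior) if params is not None else None,
        "seed": int(params.seed) if params is not None else None,
        "phase_schedule": [
            [label, float(s), float(e)] for label, s, e in session.schedule.phases
        ],
        "stacks": stack_paths,
        "timestamps": ts_paths,
        "behavior": "behavior_rois.csv",
        "masks": mask_paths,
        "keypoints": {
            mouse: {k: [float(v[0]), float(v[1])] for k, v in kps.items()}
            for mouse, kps in session.keypoints.items()
        },
        "events_truth": "events_truth.csv" if truth is not None else None,
        "mice": ["stationary", "moving"],
        "cagemates": True,
    }
    path = out / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# reading


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    required = ("stacks", "behavior", "masks", "phase_schedule")
    for key in required:
        if d.get(key) is None:
            raise ManifestError(f"manifest missing required field {key!r}")
    schedule = PhaseSchedule(
        tuple((lab, float(s), float(e)) for lab, s, e in d["phase_schedule"])
    )
    return Manifest(
        trial_id=d.get("trial_id", path.parent.name),
        root=path.parent,
        stack_paths=d["stacks"],
        timestamp_paths=d.get("timestamps", {}),
        behavior_path=d["behavior"],
        mask_paths=d["masks"],
        keypoints={
            mouse: {k: tuple(v) for k, v in kps.items()}
            for mouse, kps in (d.get("keypoints") or {}).items()
        },
        fs_brain=d.get("fs_brain") or 28.9,
        fs_behavior=d.get("fs_behavior") or 90.0,
        schedule=schedule,
        condition=d.get("condition", "open"),
        cagemates=bool(d.get("cagemates", True)),
        seed=d.get("seed"),
        extra={"events_truth": d.get("events_truth")},
    )


def read_session(manifest: Manifest | str | Path) -> RawSession:
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    root = manifest.root
    stacks: dict[str, dict[str, RawStack]] = {}
    for mouse, chans in manifest.stack_paths.items():
        for chan, rel in chans.items():
            frames = tifffile.imread(root / rel)
            ts_rel = manifest.timestamp_paths.get(mouse, {}).get(chan)
            if ts_rel is not None:
                ts = pd.read_csv(root / ts_rel)["timestamp_s"].to_numpy()
            else:
                ts = np.arange(len(frames)) / manifest.fs_brain
            label = GREEN if chan == "green" else BLUE
            stacks.setdefault(mouse, {})[chan] = RawStack(frames, ts, label)

    beh = pd.read_csv(root / manifest.behavior_path)
    clock = beh["time_s"].to_numpy()
    traces = {}
    for col in beh.columns:
        if col == "time_s":
            continue
        mouse, channel = col.split("_", 1)
        traces[(mouse, channel)] = beh[col].to_numpy()

    masks = {
        mouse: tifffile.imread(root / rel).astype(bool)
        for mouse, rel in manifest.mask_paths.items()
    }
    return RawSession(
        stacks=stacks,
        behavior_traces=traces,
        behavior_clock=clock,
        schedule=manifest.schedule,
        masks=masks,
        keypoints=manifest.keypoints,
        condition=manifest.condition,
        trial_id=manifest.trial_id,
    )


def read_truth_events(manifest: Manifest) -> dict[tuple[str, str], list]:
    rel = manifest.extra.get("events_truth")
    if rel is None:
        raise ManifestError("manifest has no ground-truth event table")
    df = pd.read_csv(manifest.root / rel)
    out: dict[tuple[str, str], list] = {}
    for _, row in df.iterrows():
        out.setdefault((row["mouse"], row["channel"]), []).append(
            (row["onset_s"], row["offset_s"])
        )
    return out


# ---------------------------------------------------------------------------
# results


def write_events_csv(
    path: str | Path, events: dict[tuple[str, str], EventSeries]
) -> None:
    rows = []
    for (mouse, channel), es in events.items():
        for onset, offset, dur in es.events:
            rows.append(
                {
                    "mouse": mouse,
                    "channel": channel,
                    "onset_s": onset,
                    "offset_s": offset,
                    "duration_s": dur,
                }
            )
    pd.DataFrame(
        rows, columns=["mouse", "channel", "onset_s", "offset_s", "duration_s"]
    ).to_csv(path, index=False)


def write_h5_results(
    path: str | Path,
    arrays: dict[str, np.ndarray],
    attrs: dict | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        for key, arr in arrays.items():
            fh.create_dataset(key, data=np.asarray(arr))
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val


def read_h5_results(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    arrays, attrs = {}, {}
    with h5py.File(path, "r") as fh:
        def _visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[()]
        fh.visititems(_visit)
        attrs = dict(fh.attrs)
    return arrays, attrs
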