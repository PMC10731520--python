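"""End-to-end orchestration: simulate -> preprocess -> behavior ->
interbrain -> encode, with provenance-stamped intermediates.

Each stage writes its outputs under the results directory and is
skipped on re-runs when its output already exists (unless forced), so a
re-run with unchanged inputs is byte-stable.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import encoding as enc
from . import interbrain as ib
from . import preprocess as pp
from .io import (
    Manifest,
    config_hash,
    read_manifest,
    read_session,
    write_events_csv,
    write_h5_results,
)
from .registration import KeyPoints, RegionSet, fit_transform, place_regions

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, input_hash: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed (input {input_hash}): {cause}")


def _stage(name: str, out_path: Path, force: bool):
    """True when the stage must run (output missing or forced)."""
    if out_path.exists() and not force:
        log.info("stage %s: output exists, skipping", name)
        return False
    return True


def run_pipeline(
    manifest: Manifest | str | Path,
    out_dir: str | Path,
    config: dict | None = None,
    force: bool = False,
    encode: bool = True,
) -> dict:
    """Run the full analysis on one trial and write the results bundle.

    Returns a dictionary with the in-memory results: behavior events,
    per-phase PCC table, correlation matrices, the coherence map, and
    (optionally) the encoding maps.
    """
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    config = dict(config or {})
    seed = int(config.get("seed", manifest.seed or 0))
    chash = config_hash({"config": config, "trial": manifest.trial_id})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attrs = {"config_hash": chash, "seed": seed, "trial_id": manifest.trial_id}
    results: dict = {"manifest": manifest, "attrs": attrs}

    t0 = time.perf_counter()
    session = read_session(manifest)
    schedule = session.schedule

    # --- preprocess -------------------------------------------------------
    try:
        processed = pp.preprocess_session(session)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise StageError("preprocess", chash, exc) from exc
    results["processed"] = processed
    log.info("preprocess done in %.1fs", time.perf_counter() - t0)

    # --- registration -----------------------------------------------------
    regions = {}
    for mouse in processed:
        kp = KeyPoints.from_dict(manifest.keypoints[mouse])
        transform = fit_transform(kp)
        regions[mouse] = place_regions(
            transform, RegionSet(), session.masks[mouse]
        )
    results["regions"] = regions

    # --- behavior ---------------------------------------------------------
    ev_path = out / "behavior_events.csv"
    events = beh.extract_events_from_session(
        session.behavior_traces, session.behavior_clock
    )
    results["events"] = events
    if _stage("behavior", ev_path, force):
        write_events_csv(ev_path, events)

    # --- interbrain -------------------------------------------------------
    ib_h5 = out / "interbrain.h5"
    pcc_csv = out / "pcc_table.csv"
    gs = {
        mouse: {
            kind: ib.global_signal(stack, mouse=mouse, trial=manifest.trial_id)
            for kind, stack in stacks.items()
        }
        for mouse, stacks in processed.items()
    }
    results["global_signals"] = gs
    rows = []
    for phase in ("separate1", "together", "separate2"):
        window = schedule.centered_window(phase, ib.ANALYSIS_WINDOW_S)
        for kind in ("corrected", "green"):
            r = ib.phase_pcc(gs["stationary"][kind], gs["moving"][kind], window)
            rows.append(
                {
                    "trial": manifest.trial_id,
                    "phase": phase,
                    "signal": kind,
                    "pcc": r,
                    "fisher_z": ib.fisher_z(r) if abs(r) < 1 else np.nan,
                }
            )
    pcc_table = pd.DataFrame(rows)
    results["pcc_table"] = pcc_table

    ts = {
        mouse: ib.region_timeseries(processed[mouse]["corrected"], regions[mouse])
        for mouse in processed
    }
    fs = processed["stationary"]["corrected"].fs
    mats = {}
    for phase in ("separate1", "together"):
        w0, w1 = schedule.centered_window(phase, ib.ANALYSIS_WINDOW_S)
        idx = slice(int(w0 * fs), int(w1 * fs))
        mats[phase] = ib.correlation_matrices(
            ts["stationary"], ts["moving"], regions["stationary"].names, idx, phase
        )
    results["matrices"] = mats
    results["delta_matrices"] = ib.delta_matrices(
        mats["together"], mats["separate1"]
    )
    coh = ib.mt_coherence(gs["stationary"]["corrected"], gs["moving"]["corrected"])
    results["coherence"] = coh

    if _stage("interbrain", ib_h5, force):
        pcc_table.to_csv(pcc_csv, index=False)
        write_h5_results(
            ib_h5,
            {
                "global/stationary": gs["stationary"]["corrected"].values,
                "global/moving": gs["moving"]["corrected"].values,
                "matrices/inter_separate1": mats["separate1"].inter,
                "matrices/inter_together": mats["together"].inter,
                "matrices/delta_inter": results["delta_matrices"]["inter"],
                "coherence/values": coh.coherence,
                "coherence/times": coh.times,
                "coherence/freqs": coh.freqs,
            },
            attrs,
        )

    # --- encoding ---------------------------------------------------------
    if encode:
        enc_h5 = out / "encoding.h5"
        stack = processed["stationary"]["corrected"]
        brain_clock = stack.times
        ev_brain = {k: es for k, es in events.items()}
        variables = enc.variables_from_events(ev_brain, schedule, brain_clock)
        dm = enc.build_design_matrix(variables, fs=stack.fs)
        data = stack.values[:, stack.mask].astype(np.float64)
        k = int(config.get("n_components", enc.N_COMPONENTS))
        reduced = enc.svd_reduce(data, k=k, mask=stack.mask, random_state=seed)
        lam = config.get("ridge_lambda")
        model = enc.fit_encoding_model(
            reduced,
            dm,
            variables=config.get("dr2_variables"),
            folds=int(config.get("folds", enc.N_FOLDS)),
            lam=None if lam is None else float(lam),
            seed=seed,
        )
        results["encoding"] = model
        if _stage("encoding", enc_h5, force):
            arrays = {"r2_map": model.r2_map}
            for var, m in model.dr2_maps.items():
                arrays[f"dr2/{var}"] = m
            write_h5_results(
                enc_h5,
                arrays,
                {**attrs, "ridge_penalty": model.ridge_penalty},
            )
    log.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return results
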