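"""File formats: TSV trial tables, array containers with JSON sidecars
for epochs and decompositions, CSV/JSON analysis outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EpochSet, OddballTrial, StopTrial, trials_to_frame


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def write_trials_tsv(trials, path) -> None:
    # %.17g keeps RT floats exact across a write/read cycle
    trials_to_frame(trials).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_oddball_tsv(path) -> list[OddballTrial]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for rec in df.to_dict("records"):
        rt = rec.get("rt_ms")
        rec["rt_ms"] = None if pd.isna(rt) else float(rt)
        out.append(OddballTrial(**rec))
    return out


def read_stop_tsv(path) -> list[StopTrial]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for rec in df.to_dict("records"):
        for key in ("rt_ms", "ssd_ms"):
            v = rec.get(key)
            rec[key] = None if pd.isna(v) else float(v)
        out.append(StopTrial(**rec))
    return out


def write_epochs(epochs: EpochSet, stem) -> None:
    """One `.npy` array per epoch set plus a JSON sidecar and events TSV."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), epochs.data)
    write_json(
        {
            "subject_id": epochs.subject_id,
            "channel_labels": list(epochs.channel_labels),
            "sensor_layout": epochs.sensor_layout,
            "sfreq_hz": epochs.sfreq_hz,
            "tmin_ms": epochs.tmin_ms,
        },
        stem.with_suffix(".json"),
    )
    epochs.events.to_csv(stem.with_suffix(".events.tsv"), sep="\t", index=False)


def read_epochs(stem) -> EpochSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(
        subject_id=meta["subject_id"],
        data=np.load(stem.with_suffix(".npy")),
        channel_labels=tuple(meta["channel_labels"]),
        sensor_layout=np.asarray(meta["sensor_layout"]),
        sfreq_hz=meta["sfreq_hz"],
        tmin_ms=meta["tmin_ms"],
        events=pd.read_csv(stem.with_suffix(".events.tsv"), sep="\t"),
    )


def write_statmap_csv(statmap, path) -> None:
    """Long-format channel x window table for a group statistics map."""
    rows = []
    for i, ch in enumerate(statmap.channel_labels):
        for j, c in enumerate(statmap.centers_ms):
            rows.append(
                {
                    "channel": ch,
                    "window_center_ms": c,
                    "mean_beta": statmap.mean_beta[i, j],
                    "t": statmap.t[i, j],
                    "p": statmap.p[i, j],
                    "significant": bool(statmap.sig_mask[i, j])
                    if statmap.sig_mask is not None
                    else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_decomposition(decomp, stem) -> None:
    stem = Path(stem)
    np.savez(stem.with_suffix(".npz"), mixing=decomp.mixing, unmixing=decomp.unmixing)
    write_json(
        {"subject_id": decomp.subject_id, "component_ids": list(decomp.component_ids)},
        stem.with_suffix(".json"),
    )


def read_decomposition(stem):
    from .components import Decomposition

    stem = Path(stem)
    arr = np.load(stem.with_suffix(".npz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return Decomposition(
        subject_id=meta["subject_id"],
        mixing=arr["mixing"],
        unmixing=arr["unmixing"],
        component_ids=tuple(meta["component_ids"]),
    )
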