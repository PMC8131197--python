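"""File I/O contracts: trial-table CSV + JSON sidecar, HDF5 array container."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .stimuli import CategoryRule, StimulusSpace


def write_trial_table(trials: pd.DataFrame, path: str | Path, rule: CategoryRule | None = None) -> None:
    """Write a trial table as CSV with a JSON sidecar of rule/space metadata.

    Lick-time lists are serialized as semicolon-joined seconds.
    """
    path = Path(path)
    out = trials.copy()
    if "lick_times" in out:
        out["lick_times"] = out["lick_times"].map(
            lambda v: ";".join(f"{t:.4f}" for t in v) if isinstance(v, (list, np.ndarray)) else v
        )
    out.to_csv(path, index=False)
    if rule is not None:
        meta = {
            "orientations": list(rule.space.orientations),
            "spatial_frequencies": list(rule.space.spatial_frequencies),
            "relevant_feature": rule.relevant_feature,
            "boundary": rule.boundary,
            "go_side": rule.go_side,
            "dense_mode": rule.dense_mode,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trial_table(path: str | Path) -> tuple[pd.DataFrame, CategoryRule | None]:
    """Read a trial-table CSV (and its rule sidecar when present)."""
    path = Path(path)
    trials = pd.read_csv(path)
    if "lick_times" in trials:
        trials["lick_times"] = trials["lick_times"].map(
            lambda v: [float(x) for x in str(v).split(";")] if isinstance(v, str) and v else []
        )
    rule = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        from .stimuli import assign_categories, build_stimulus_grid

        meta = json.loads(sidecar.read_text())
        space = build_stimulus_grid(meta["orientations"], meta["spatial_frequencies"])
        rule = assign_categories(
            space,
            meta["relevant_feature"],
            meta["boundary"],
            dense_mode=meta["dense_mode"],
            go_side=meta["go_side"],
        )
    return trials, rule


def write_container(
    path: str | Path,
    rates: np.ndarray | None = None,
    F: np.ndarray | None = None,
    Fneu: np.ndarray | None = None,
    events: np.ndarray | None = None,
    frame_rate: float | None = None,
    seed: int | None = None,
    windows: np.ndarray | None = None,
) -> None:
    """HDF5 container with named datasets /rates, /fluo/F, /fluo/Fneu, /events."""
    with h5py.File(path, "w") as f:
        if rates is not None:
            f.create_dataset("rates", data=np.asarray(rates))
        if F is not None:
            f.create_dataset("fluo/F", data=np.asarray(F))
        if Fneu is not None:
            f.create_dataset("fluo/Fneu", data=np.asarray(Fneu))
        if events is not None:
            f.create_dataset("events", data=np.asarray(events))
        if windows is not None:
            f.create_dataset("windows", data=np.asarray(windows))
        if frame_rate is not None:
            f.attrs["frame_rate"] = frame_rate
        if seed is not None:
            f.attrs["seed"] = seed


def read_container(path: str | Path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for key in ("rates", "events", "windows"):
            if key in f:
                out[key] = f[key][()]
        if "fluo" in f:
            out["F"] = f["fluo/F"][()]
            out["Fneu"] = f["fluo/Fneu"][()]
        out.update(dict(f.attrs))
    return out
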