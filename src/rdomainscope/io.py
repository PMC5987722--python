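"""File formats: the package CSV dialects, TIFF stacks and YAML sidecars.

Canonical localization table: CSV with columns frame, x_nm, y_nm, photons.
Scenes: one row per stretch (scene_id, rd_id | -1 solitary, x_nm, y_nm,
z_nm, channel).  Tracks: track_id, channel, frame, x_nm, y_nm.  Confocal
stacks: one multi-page TIFF per channel with voxel sizes in a YAML
sidecar.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coupling import TrackSet
from .registration import ConfocalStack
from .storm_qc import EventList


def write_events(events: EventList, path) -> None:
    df = pd.DataFrame({"frame": events.frame, "x_nm": events.x,
                       "y_nm": events.y, "photons": events.photons})
    if events.stretch_id is not None:
        df["stretch_id"] = events.stretch_id
    df.to_csv(path, index=False)


def read_events(path, n_frames: Optional[int] = None,
                pixel_hint: float = 10.0) -> EventList:
    df = pd.read_csv(path)
    frames = df["frame"].to_numpy(dtype=int)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 1
    sid = df["stretch_id"].to_numpy() if "stretch_id" in df.columns else None
    return EventList(frames, df["x_nm"].to_numpy(dtype=float),
                     df["y_nm"].to_numpy(dtype=float),
                     df["photons"].to_numpy(dtype=float),
                     n_frames, pixel_hint, sid)


def write_scene(scene, path, scene_id: int = 0) -> None:
    tab = scene.stretch_table()
    tab.insert(0, "scene_id", scene_id)
    tab.to_csv(path, index=False)


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.data.to_csv(path, index=False)


def read_tracks(path, frame_interval: float = 0.5) -> TrackSet:
    return TrackSet(pd.read_csv(path), frame_interval)


def write_stack(stack: ConfocalStack, out_dir, stem: str = "stack") -> Dict[str, Path]:
    """One multi-page TIFF per channel plus a YAML sidecar with voxel sizes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for chan, arr in stack.channels.items():
        p = out_dir / f"{stem}_{chan}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32),
                         photometric="minisblack")
        paths[chan] = p
    sidecar = out_dir / f"{stem}.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"voxel_nm": list(stack.voxel),
                        "channels": {c: str(p.name) for c, p in paths.items()}}, fh)
    paths["sidecar"] = sidecar
    return paths


def read_stack(sidecar_path) -> ConfocalStack:
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    channels = {c: tifffile.imread(sidecar_path.parent / name).astype(float)
                for c, name in meta["channels"].items()}
    return ConfocalStack(channels, tuple(meta["voxel_nm"]))


def atomic_write_yaml(obj, path) -> None:
    """Write YAML via a temp file + rename so partial reports never appear."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    os.replace(tmp, path)
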