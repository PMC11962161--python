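"""Tabular and image I/O: TIFF movies/stacks, CSV tables, YAML configs.

CSV outputs carry a ``# config_sha256: ...`` header comment so every table
can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import Focus
from .link import Track

__all__ = ["write_movie", "read_movie", "write_stack", "read_stack",
           "foci_to_frame", "foci_from_frame", "tracks_to_frame",
           "tracks_from_frame", "write_table", "read_table", "config_hash",
           "load_config", "ConfigError", "validate_keys"]


class ConfigError(ValueError):
    """Invalid or unknown configuration contents."""


def write_movie(path, movie: np.ndarray) -> None:
    """Write a (frames, y, x) movie as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (channels, z, y, x) or (z, y, x) stack as TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def foci_to_frame(foci_by_frame) -> pd.DataFrame:
    rows = []
    items = foci_by_frame.items() if isinstance(foci_by_frame, dict) \
        else enumerate(foci_by_frame)
    for frame, foci in items:
        for f in foci:
            rows.append({"frame": frame, "x_um": f.position[0],
                         "y_um": f.position[1], "intensity": f.intensity,
                         "snr": f.snr, "precision_um": f.localization_precision})
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity",
                                       "snr", "precision_um"])


def foci_from_frame(df: pd.DataFrame) -> dict[int, list[Focus]]:
    out: dict[int, list[Focus]] = {}
    for _, r in df.iterrows():
        out.setdefault(int(r["frame"]), []).append(
            Focus(frame=int(r["frame"]), position=(float(r["x_um"]), float(r["y_um"])),
                  intensity=float(r["intensity"]), snr=float(r["snr"]),
                  localization_precision=float(r["precision_um"])))
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f in t.foci:
            rows.append({"track_id": t.id, "frame": f.frame,
                         "x_um": f.position[0], "y_um": f.position[1],
                         "intensity": f.intensity,
                         "nucleus_id": t.nucleus_id if t.nucleus_id is not None else -1})
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "intensity", "nucleus_id"])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        foci = [Focus(frame=int(r["frame"]),
                      position=(float(r["x_um"]), float(r["y_um"])),
                      intensity=float(r["intensity"]), snr=np.nan,
                      localization_precision=np.nan)
                for _, r in sub.iterrows()]
        nid = int(sub["nucleus_id"].iloc[0]) if "nucleus_id" in sub else -1
        tracks.append(Track(id=int(tid), foci=foci,
                            nucleus_id=None if nid < 0 else nid))
    return tracks


def config_hash(config: dict) -> str:
    """Hash of the analysis-relevant configuration.

    Filesystem locations are excluded so that the same analysis written to a
    different directory produces byte-identical tables.
    """
    cfg = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(cfg, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def write_table(path, df: pd.DataFrame, config: dict | None = None) -> None:
    """RFC-4180 CSV with a config-hash header comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if config is not None:
            fh.write(f"# config_sha256: {config_hash(config)}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg
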