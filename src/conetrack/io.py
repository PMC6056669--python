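"""File I/O: TIFF stacks, CSV tables, YAML configs, provenance.

Stacks are written as one multi-page TIFF per burst with the burst index
encoded in the filename (``burst_000.tif`` ...); ground-truth masks go to
a companion label TIFF. Tables round-trip through CSV at full float
precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .schedule import AcquisitionSchedule

__all__ = [
    "write_burst_stacks",
    "read_stack",
    "discover_bursts",
    "write_tables",
    "read_table",
    "save_config",
    "load_config",
    "save_provenance",
]

_BURST_RE = re.compile(r"burst_(\d+)\.tiff?$")


def write_burst_stacks(stack: np.ndarray, schedule: AcquisitionSchedule,
                       outdir: str | Path, prefix: str = "") -> list[Path]:
    """Split a burst-major stack into one multi-page TIFF per burst."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fpb = schedule.frames_per_burst
    for b in range(schedule.n_bursts):
        path = outdir / f"{prefix}burst_{b:03d}.tif"
        tifffile.imwrite(path, stack[b * fpb:(b + 1) * fpb],
                         photometric="minisblack")
        paths.append(path)
    return paths


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (frames, rows, cols) array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    return np.atleast_3d(arr) if arr.ndim == 2 else arr


def discover_bursts(directory: str | Path) -> list[Path]:
    """Burst TIFFs in a directory, ordered by the encoded burst index."""
    directory = Path(directory)
    found = []
    for p in directory.iterdir():
        m = _BURST_RE.search(p.name)
        if m:
            found.append((int(m.group(1)), p))
    return [p for _, p in sorted(found)]


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path
                 ) -> dict[str, Path]:
    """Write each table as ``<name>.csv``; full float precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        paths[name] = path
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_provenance(params: dict, path: str | Path) -> None:
    """Echo all run parameters to a JSON sidecar."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=default)
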