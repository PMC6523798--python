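"""Plain-text serialisation: extended XYZ conformations and JSON manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = ["write_xyz", "read_xyz", "write_json", "file_sha256"]


def write_xyz(path: str | Path, frames, comments=None, symbol: str = "C") -> None:
    """Write frames (list of (n, 3) arrays) as extended XYZ, one per frame."""
    path = Path(path)
    if comments is None:
        comments = ["" for _ in frames]
    with open(path, "w") as fh:
        for coords, comment in zip(frames, comments):
            coords = np.asarray(coords)
            fh.write(f"{coords.shape[0]}\n{comment}\n")
            for x, y, z in coords:
                fh.write(f"{symbol} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path: str | Path):
    """Read an (extended) XYZ file; returns (frames, comments)."""
    frames = []
    comments = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comments.append(lines[i + 1])
        block = lines[i + 2 : i + 2 + n]
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block], dtype=np.float64
        )
        frames.append(coords)
        i += 2 + n
    return frames, comments


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
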