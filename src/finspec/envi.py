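"""Minimal ENVI-style hypercube container (text header + BSQ float32 binary).

Covers exactly what the pipeline needs: writing and reading a hypercube with
its white/dark calibration references and a small JSON metadata sidecar.  The
header follows the ENVI convention (``samples``/``lines``/``bands``,
``interleave = bsq``, ``data type = 4`` i.e. float32, ``byte order = 0``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_cube_dir", "read_cube_dir"]


def _write_envi(stem: Path, arr: np.ndarray) -> None:
    """Write ``arr`` (lines, samples[, bands]) as <stem>.hdr + <stem>.bsq."""
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim == 2:
        a = a[:, :, None]
    lines, samples, bands = a.shape
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
    )
    stem.with_suffix(".hdr").write_text(hdr)
    # BSQ: band-sequential — all of band 0, then band 1, ...
    np.ascontiguousarray(np.moveaxis(a, 2, 0)).tofile(stem.with_suffix(".bsq"))


def _read_envi(stem: Path) -> np.ndarray:
    fields = {}
    for line in stem.with_suffix(".hdr").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    if fields.get("interleave", "bsq").lower() != "bsq" or int(fields.get("data type", 4)) != 4:
        raise ValueError(f"{stem}: only bsq float32 containers are supported")
    lines, samples, bands = (int(fields[k]) for k in ("lines", "samples", "bands"))
    raw = np.fromfile(stem.with_suffix(".bsq"), dtype=np.float32)
    if raw.size != lines * samples * bands:
        raise ValueError(f"{stem}: binary size does not match header dimensions")
    a = np.moveaxis(raw.reshape(bands, lines, samples), 0, 2)
    return a[:, :, 0] if bands == 1 else a


def write_cube_dir(path: str | Path, cube: np.ndarray, refs: dict, meta: dict) -> Path:
    """Write cube + white/dark refs + metadata into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_envi(path / "cube", cube)
    _write_envi(path / "white", refs["white"])
    _write_envi(path / "dark", refs["dark"])
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_cube_dir(path: str | Path) -> tuple[np.ndarray, dict, dict]:
    """Read back ``(cube, refs, meta)`` written by :func:`write_cube_dir`."""
    path = Path(path)
    cube = _read_envi(path / "cube").astype(float)
    refs = {
        "white": _read_envi(path / "white").astype(float),
        "dark": _read_envi(path / "dark").astype(float),
    }
    meta = json.loads((path / "meta.json").read_text())
    return cube, refs, meta
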