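"""Hypercube preprocessing: calibration, masking, voxelization.

Raw hyperspectral images are converted into voxel-mean point spectra in four
steps: (1) flat-field calibration against white/dark references (reflectance
modes) or dark subtraction plus a constant scale (fluorescence); (2) a
spatial mask separating the fillet from the background; (3) grouping of
masked pixels into 10x10 voxels with an outlier-exclusion rule — a voxel is
discarded when more than 10% of its pixels have broadband intensity outside
μ ± 2σ of the whole fillet's pixel-intensity distribution; (4) averaging the
surviving voxels' pixel spectra into one point spectrum each.

The pipeline is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ModeBlock, SpectralDataset
from .modes import ModeSpec

__all__ = [
    "CalibrationError",
    "MaskingError",
    "VoxelGrid",
    "calibrate_reflectance",
    "calibrate_fluorescence",
    "compute_fillet_mask",
    "voxelize",
    "voxel_mean_spectra",
    "preprocess_cube",
    "write_pgm",
]


def write_pgm(path, mask: np.ndarray) -> None:
    """Write a boolean map as plain-text PGM (P2) for visual inspection."""
    mask = np.asarray(mask)
    h, w = mask.shape
    rows = "\n".join(" ".join(str(255 if v else 0) for v in row) for row in mask)
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n255\n{rows}\n")

FLUOR_SCALE = 6000.0  # approximate data-wide maximum fluorescence count


class CalibrationError(ValueError):
    pass


class MaskingError(ValueError):
    pass


def calibrate_reflectance(cube: np.ndarray, white: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Flat-field calibration: (I_sample − I_dark) / (I_white − I_dark).

    ``white``/``dark`` may be 2-D (per pixel) or match the cube shape.  In-gamut
    pixels land in [0, 1] up to noise.
    """
    cube = np.asarray(cube, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.ndim == 2:
        white = white[:, :, None]
    if dark.ndim == 2:
        dark = dark[:, :, None]
    denom = white - dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        loc = tuple(int(v) for v in bad[0])
        raise CalibrationError(f"white and dark references coincide at {loc}")
    return (cube - dark) / denom


def calibrate_fluorescence(cube: np.ndarray, dark: np.ndarray, scale: float = FLUOR_SCALE) -> np.ndarray:
    """Fluorescence calibration: subtract the dark, divide by a constant scale."""
    if scale <= 0:
        raise CalibrationError(f"scale must be positive, got {scale}")
    cube = np.asarray(cube, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if dark.ndim == 2:
        dark = dark[:, :, None]
    return (cube - dark) / scale


def compute_fillet_mask(cube: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Intensity-threshold mask separating fillet from background.

    Thresholds each pixel's broadband mean of the *calibrated* cube.  With
    ``threshold=None`` the threshold is the midpoint between the background
    floor and the bright-pixel level (robust percentiles), which cleanly
    splits a dark background from a reflective fillet.
    """
    broadband = np.asarray(cube, dtype=float).mean(axis=2)
    if threshold is None:
        lo, hi = np.percentile(broadband, [2, 98])
        if hi - lo < 1e-6:
            raise MaskingError("image has no intensity contrast; cannot separate fillet")
        threshold = 0.5 * (lo + hi)
    mask = broadband > threshold
    if threshold != -np.inf and not mask.any():
        raise MaskingError("mask is empty: no pixel above threshold")
    if threshold == -np.inf:
        mask = np.ones_like(mask, dtype=bool)
    return mask


@dataclass
class VoxelGrid:
    """Valid flags and mean spectra of the voxel decomposition of one cube."""

    voxel_size: int
    index: np.ndarray  # (n_valid, 2) voxel (i, j) coordinates
    spectra: np.ndarray  # (n_valid, n_bands)
    n_voxels_considered: int
    n_excluded_outliers: int
    n_dropped_small: int = 0
    valid_map: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_valid(self) -> int:
        return self.spectra.shape[0]


def voxelize(
    cube: np.ndarray,
    mask: np.ndarray,
    voxel_size: int = 10,
    outlier_fraction: float = 0.10,
    sigma_mult: float = 2.0,
    min_pixels: int | None = None,
) -> VoxelGrid:
    """Group masked pixels into voxels and apply the μ ± 2σ exclusion rule.

    μ and σ are computed over the broadband mean intensity of *all* masked
    (fillet) pixels of the cube.  A pixel is an outlier iff its broadband
    intensity falls outside [μ − 2σ, μ + 2σ]; a voxel is excluded iff its
    outlier pixels exceed ``outlier_fraction`` of its masked pixels — strictly
    "more than", so 10 outliers of 100 are retained and 11 are excluded.
    Voxels whose masked-pixel population is below ``min_pixels`` (default:
    half a full voxel) are dropped as edge fragments.  Voxel (i, j) covers
    pixel rows [s·i, s·i + s) and columns [s·j, s·j + s), 0-based, half-open.
    """
    cube = np.asarray(cube, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w, n_bands = cube.shape
    if mask.shape != (h, w):
        raise ValueError("mask shape does not match cube")
    s = voxel_size
    if min_pixels is None:
        min_pixels = (s * s) // 2

    broadband = cube.mean(axis=2)
    fillet_vals = broadband[mask]
    if fillet_vals.size == 0:
        raise MaskingError("mask selects no pixels")
    mu, sigma = float(fillet_vals.mean()), float(fillet_vals.std())
    outlier = mask & ((broadband < mu - sigma_mult * sigma) | (broadband > mu + sigma_mult * sigma))

    ni, nj = h // s, w // s  # partial edge voxels beyond the grid are dropped
    valid_map = np.zeros((ni, nj), dtype=bool)
    index, spectra = [], []
    n_considered = n_excluded = n_small = 0
    for i in range(ni):
        for j in range(nj):
            m = mask[s * i : s * i + s, s * j : s * j + s]
            npix = int(m.sum())
            if npix == 0:
                continue
            n_considered += 1
            if npix < min_pixels:
                n_small += 1
                continue
            nout = int(outlier[s * i : s * i + s, s * j : s * j + s].sum())
            if nout > outlier_fraction * npix:
                n_excluded += 1
                continue
            block = cube[s * i : s * i + s, s * j : s * j + s][m]
            index.append((i, j))
            spectra.append(block.mean(axis=0))
            valid_map[i, j] = True
    if not index:
        import warnings

        warnings.warn("voxelization produced no valid voxels", stacklevel=2)
        return VoxelGrid(s, np.empty((0, 2), int), np.empty((0, n_bands)), n_considered,
                         n_excluded, n_small, valid_map)
    return VoxelGrid(s, np.array(index), np.vstack(spectra), n_considered,
                     n_excluded, n_small, valid_map)


def voxel_mean_spectra(grid: VoxelGrid, mode: ModeSpec, species: str, fillet_id: str) -> SpectralDataset:
    """One dataset row per valid voxel, inheriting fillet/species/mode labels."""
    if grid.n_valid == 0:
        raise ValueError("voxel grid has no valid voxels")
    meta = pd.DataFrame(
        {
            "sample_id": [f"{fillet_id}_x{i}y{j}" for i, j in grid.index],
            "fillet_id": fillet_id,
            "species": species,
        }
    )
    return SpectralDataset({mode.name: ModeBlock(mode, meta, grid.spectra)})


def preprocess_cube(
    cube: np.ndarray,
    refs: dict,
    mode: ModeSpec,
    species: str,
    fillet_id: str,
    voxel_size: int = 10,
    outlier_fraction: float = 0.10,
    fluor_scale: float = FLUOR_SCALE,
) -> SpectralDataset:
    """Full pipeline for one cube: calibrate, mask, voxelize, average."""
    if mode.name == "Fluor":
        cal = calibrate_fluorescence(cube, refs["dark"], scale=fluor_scale)
    else:
        cal = calibrate_reflectance(cube, refs["white"], refs["dark"])
    mask = compute_fillet_mask(cal)
    grid = voxelize(cal, mask, voxel_size=voxel_size, outlier_fraction=outlier_fraction)
    return voxel_mean_spectra(grid, mode, species, fillet_id)
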