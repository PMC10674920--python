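"""Synthetic multi-mode, multi-fillet fish-fillet spectra.

The generator emulates the structure of a market-survey dataset: many species
measured in three spectroscopic modes, several physical fillets per species,
and many voxel-level point spectra per fillet.  Its central dial is a
*confusability* structure: species are organised into clusters whose mean
spectra differ by a small within-cluster separation ``d_w`` while clusters
(and singleton species) differ by a larger between-cluster separation
``d_b``.  Small ``d_w`` produces exactly the failure mode the dispute-model
hierarchy exists for: a global classifier that confuses the members of a
cluster with one another while separating the clusters cleanly.

Mean spectra are smooth (sums of Gaussian bumps over the wavelength grid plus
a smooth baseline).  Each fillet carries a smooth additive random offset —
fillet-to-fillet variation is spectrally structured, which is what makes
leave-fillet-out validation genuinely harder than a row-level split — and
each measurement adds independent per-band noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ModeBlock, SpectralDataset
from .modes import MODE_NAMES, ModeSpec, default_modes

__all__ = [
    "GeneratorConfig",
    "SpeciesLibrary",
    "generate_species_library",
    "generate_point_spectra",
    "generate_hypercube",
    "confusable_preset",
    "separable_preset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset.

    ``between_cluster_sep`` (d_b) and ``within_cluster_sep`` (d_w) are
    Euclidean distances between mean spectra, in the same (calibrated
    reflectance / scaled fluorescence) units as the spectra themselves;
    ``fillet_effect_sd`` and ``noise_sd`` are per-band standard deviations.
    """

    n_species: int = 43
    cluster_sizes: tuple[int, ...] = (2, 2, 3, 3, 4, 4)
    fillets_per_species: int = 4
    voxels_per_fillet: int = 10
    between_cluster_sep: float = 1.0
    within_cluster_sep: float = 0.07
    fillet_effect_sd: float = 0.04
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 2 (singletons are implicit)")
        if sum(self.cluster_sizes) > self.n_species:
            raise ValueError(
                f"cluster_sizes sum to {sum(self.cluster_sizes)} > n_species={self.n_species}"
            )
        if self.within_cluster_sep > self.between_cluster_sep:
            raise ValueError("within_cluster_sep must not exceed between_cluster_sep")
        for name in ("between_cluster_sep", "within_cluster_sep", "fillet_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.fillets_per_species < 1 or self.voxels_per_fillet < 1:
            raise ValueError("fillets_per_species and voxels_per_fillet must be >= 1")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(self.n_species)]


@dataclass
class SpeciesLibrary:
    """Per-species, per-mode mean spectra plus the cluster assignment."""

    cfg: GeneratorConfig
    modes: dict[str, ModeSpec]
    means: dict[str, np.ndarray]  # mode -> (n_species, n_bands)
    cluster_of: np.ndarray = field(repr=False)  # center index per species

    @property
    def species(self) -> list[str]:
        return self.cfg.species_names

    def clustered_species(self) -> list[list[str]]:
        """Species names per declared (non-singleton) cluster."""
        names = self.species
        out = []
        for c in range(self.cfg.n_clusters):
            out.append([names[i] for i in np.flatnonzero(self.cluster_of == c)])
        return out


def _smooth_unit(rng: np.random.Generator, wl: np.ndarray, n_bumps: tuple[int, int] = (3, 6)) -> np.ndarray:
    """A random smooth vector on the grid, L2-normalized: sum of Gaussian bumps."""
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    k = int(rng.integers(n_bumps[0], n_bumps[1] + 1))
    v = np.zeros_like(t)
    for _ in range(k):
        center = rng.uniform(0.05, 0.95)
        width = rng.uniform(0.05, 0.25)
        v += rng.uniform(-1.0, 1.0) * np.exp(-0.5 * ((t - center) / width) ** 2)
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:  # vanishing bump sum; retry deterministically
        return _smooth_unit(rng, wl, n_bumps)
    return v / nrm


def generate_species_library(cfg: GeneratorConfig, modes: dict[str, ModeSpec] | None = None) -> SpeciesLibrary:
    """Build per-mode mean spectra honouring the d_w/d_b separation structure.

    Each declared cluster, and each leftover singleton species, gets its own
    *center direction*; a clustered species additionally gets a *deviation
    direction*.  All directions are built as random smooth bump sums and then
    jointly orthonormalized, so within one mode any two species of the same
    cluster are exactly ``d_w * sqrt(2)`` apart and species of different
    centers are ``sqrt(2 d_b**2 + ...)`` apart — the d_w/d_b ordering holds by
    construction, not on average.  Spectra are shifted to be nonnegative; the
    shift is common to all species of a mode and preserves every pairwise
    distance.
    """
    if modes is None:
        modes = default_modes()
    rng = np.random.default_rng(cfg.seed)
    n_clustered = sum(cfg.cluster_sizes)
    n_singletons = cfg.n_species - n_clustered
    n_centers = cfg.n_clusters + n_singletons
    n_dirs = n_centers + n_clustered

    cluster_of = np.empty(cfg.n_species, dtype=int)
    i = 0
    for c, size in enumerate(cfg.cluster_sizes):
        cluster_of[i : i + size] = c
        i += size
    cluster_of[i:] = np.arange(cfg.n_clusters, n_centers)

    means: dict[str, np.ndarray] = {}
    for name in sorted(modes):
        mode = modes[name]
        wl = mode.wavelengths
        if mode.n_bands < n_dirs:
            raise ValueError(
                f"mode {name!r}: {mode.n_bands} bands cannot host {n_dirs} orthogonal directions"
            )
        t = (wl - wl[0]) / (wl[-1] - wl[0])
        baseline = 0.25 + 0.15 * t + 0.2 * np.exp(-0.5 * ((t - 0.5) / 0.3) ** 2)

        raw = np.column_stack([_smooth_unit(rng, wl) for _ in range(n_dirs)])
        q, _ = np.linalg.qr(raw)  # orthonormal columns, still smooth mixtures
        centers = q[:, :n_centers].T  # (n_centers, n_bands)
        devs = q[:, n_centers:].T  # (n_clustered, n_bands), species order

        m = np.empty((cfg.n_species, mode.n_bands))
        for s in range(cfg.n_species):
            dev = np.zeros(mode.n_bands)
            if s < n_clustered:
                dev = cfg.within_cluster_sep * devs[s]
            m[s] = baseline + cfg.between_cluster_sep * centers[cluster_of[s]] + dev
        lo = m.min()
        if lo < 0:
            m -= lo  # distance-preserving nonnegativity shift
        means[name] = m
    return SpeciesLibrary(cfg=cfg, modes=dict(modes), means=means, cluster_of=cluster_of)


def _fillet_offset(rng: np.random.Generator, wl: np.ndarray, sd: float, degree: int = 3) -> np.ndarray:
    """Smooth additive fillet effect: random low-order Legendre polynomial.

    Basis polynomials are normalized to unit RMS on the grid and coefficients
    scaled so the per-band variance of the offset averages ``sd**2``.
    """
    t = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    basis = np.polynomial.legendre.legvander(t, degree)  # (n_bands, degree+1)
    basis = basis / np.sqrt((basis**2).mean(axis=0))
    coef = rng.normal(0.0, sd / np.sqrt(degree + 1), size=degree + 1)
    return basis @ coef


def generate_point_spectra(lib: SpeciesLibrary, cfg: GeneratorConfig | None = None) -> SpectralDataset:
    """Draw voxel-level point spectra for every species/fillet/mode.

    Each measurement is ``species mean + fillet offset + iid band noise``; the
    fillet offset is drawn once per (fillet, mode) and shared by all voxels of
    that fillet.  Rows of the same physical voxel share one ``sample_id``
    across modes, so decision-level fusion can align votes per sample.
    """
    cfg = cfg or lib.cfg
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    species = lib.species
    blocks: dict[str, ModeBlock] = {}
    mode_names = sorted(lib.modes)
    # fillet offsets drawn per fillet then per mode, in a fixed order
    offsets: dict[tuple[str, str], np.ndarray] = {}
    fillet_ids: dict[str, list[str]] = {}
    for s in species:
        fillet_ids[s] = [f"{s}_f{j}" for j in range(cfg.fillets_per_species)]
        for fid in fillet_ids[s]:
            for m in mode_names:
                offsets[(fid, m)] = _fillet_offset(rng, lib.modes[m].wavelengths, cfg.fillet_effect_sd)

    for m in mode_names:
        mode = lib.modes[m]
        rows_meta = []
        rows_x = []
        for si, s in enumerate(species):
            mean = lib.means[m][si]
            for fid in fillet_ids[s]:
                noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.voxels_per_fillet, mode.n_bands))
                spectra = mean + offsets[(fid, m)] + noise
                rows_x.append(spectra)
                for v in range(cfg.voxels_per_fillet):
                    rows_meta.append((f"{fid}_v{v}", fid, s))
        meta = pd.DataFrame(rows_meta, columns=["sample_id", "fillet_id", "species"])
        blocks[m] = ModeBlock(mode, meta, np.vstack(rows_x))
    return SpectralDataset(blocks)


def generate_hypercube(
    lib: SpeciesLibrary,
    species: str,
    fillet_id: str,
    mode: ModeSpec,
    outlier_rate: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (40, 40),
    ellipse_axes: tuple[float, float] | None = None,
):
    """A raw hypercube of one fillet with calibration references and truth.

    Returns ``(cube, refs, truth)`` where ``cube`` is a raw-counts
    ``(H, W, n_bands)`` array of an elliptical fillet on a dark background,
    ``refs`` is a dict with ``white``/``dark`` 2-D reference images, and
    ``truth`` is a dict holding the fillet mask and the injected-outlier mask.

    Outliers are injected at ``round(outlier_rate * n_fillet_pixels)``
    uniformly chosen fillet pixels by inflating the pixel's intensity far
    beyond the μ±2σ band of the fillet's broadband-intensity distribution.
    """
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier_rate must be in [0, 1]")
    h, w = shape
    ax = ellipse_axes or (h * 0.38, w * 0.38)
    if 2 * ax[0] > h or 2 * ax[1] > w:
        raise ValueError("ellipse larger than frame")
    rng = np.random.default_rng(seed)
    si = lib.species.index(species)
    mean = lib.means[mode.name][si]
    offset = _fillet_offset(rng, mode.wavelengths, lib.cfg.fillet_effect_sd)

    rr, cc = np.mgrid[0:h, 0:w]
    mask = (((rr - (h - 1) / 2) / ax[0]) ** 2 + ((cc - (w - 1) / 2) / ax[1]) ** 2) <= 1.0

    # raw counts model: dark floor + gain * physical intensity + shot-ish noise
    dark_level, gain = 100.0, 4000.0
    dark = np.full((h, w), dark_level)
    white = np.full((h, w), dark_level + gain)
    cube = np.empty((h, w, mode.n_bands))
    bg = dark_level + rng.normal(0.0, 1.0, size=(h, w, mode.n_bands))
    cube[:] = bg
    fillet_pix = np.flatnonzero(mask.ravel())
    spectra = mean + offset + rng.normal(0.0, lib.cfg.noise_sd, size=(fillet_pix.size, mode.n_bands))
    cube.reshape(-1, mode.n_bands)[fillet_pix] = dark_level + gain * np.clip(spectra, 0.0, None)

    outlier_mask = np.zeros((h, w), dtype=bool)
    n_out = round(outlier_rate * fillet_pix.size)
    if n_out:
        chosen = rng.choice(fillet_pix, size=n_out, replace=False)
        flat = cube.reshape(-1, mode.n_bands)
        flat[chosen] = dark_level + gain * (np.abs(spectra).max() * 5.0 + 1.0)
        outlier_mask.ravel()[chosen] = True

    refs = {"white": white, "dark": dark}
    truth = {"fillet_mask": mask, "outlier_mask": outlier_mask,
             "species": species, "fillet_id": fillet_id, "mode": mode.name}
    return cube, refs, truth


def confusable_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study condition: 43 species, 6 confusable clusters.

    Cluster sizes {2,2,3,3,4,4} plus 25 singletons mirror the range of
    dispute-group sizes (2-4 classes) seen in real fillet surveys.
    """
    kw = dict(
        n_species=43,
        cluster_sizes=(2, 2, 3, 3, 4, 4),
        fillets_per_species=4,
        voxels_per_fillet=10,
        between_cluster_sep=1.0,
        within_cluster_sep=0.07,
        fillet_effect_sd=0.04,
        noise_sd=0.05,
        seed=seed,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def separable_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """Well-separated limit: within-cluster separation far above the noise."""
    kw = dict(within_cluster_sep=1.0, between_cluster_sep=1.4)
    kw.update(overrides)
    return confusable_preset(seed=seed, **kw)
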