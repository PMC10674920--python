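"""Spectroscopic mode definitions.

A *mode* is one measurement family: fluorescence emission (Fluor), visible/
near-infrared reflectance (VNIR) or short-wave-infrared reflectance (SWIR).
Each mode has a fixed wavelength grid; every spectrum of that mode is a
vector on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModeSpec", "default_modes", "MODE_NAMES"]

MODE_NAMES = ("Fluor", "VNIR", "SWIR")

# (n_bands, low nm, high nm) of the three instrument families.
_DEFAULT_GRIDS = {
    "Fluor": (60, 438.0, 718.0),
    "VNIR": (125, 419.0, 1007.0),
    "SWIR": (287, 842.0, 2532.0),
}


@dataclass(frozen=True)
class ModeSpec:
    """One spectroscopic mode: a name and a strictly increasing nm grid."""

    name: str
    wavelengths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths must be a 1-D vector of >=2 values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"mode {self.name!r}: wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    @classmethod
    def default(cls, name: str) -> "ModeSpec":
        """The instrument-default grid for ``name`` (Fluor/VNIR/SWIR)."""
        try:
            n, lo, hi = _DEFAULT_GRIDS[name]
        except KeyError:
            raise ValueError(f"unknown mode {name!r}; known: {sorted(_DEFAULT_GRIDS)}") from None
        return cls(name, np.linspace(lo, hi, n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModeSpec):
            return NotImplemented
        return self.name == other.name and np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self) -> int:
        return hash((self.name, self.n_bands, float(self.wavelengths[0]), float(self.wavelengths[-1])))


def default_modes(names: tuple[str, ...] = MODE_NAMES) -> dict[str, ModeSpec]:
    """Default ModeSpec per mode name, keyed by name."""
    return {n: ModeSpec.default(n) for n in names}
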