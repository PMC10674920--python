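"""Labeled spectral dataset and fillet-exclusive cross-validation folds.

The :class:`SpectralDataset` is the currency between every pipeline stage:
a collection of labeled point spectra (one row per measurement) grouped by
physical fillet and spectroscopic mode.  Because several measurements come
from the same fillet, random row-level splits leak fillet identity into the
test set; :func:`make_fillet_folds` therefore builds folds in which every
fillet is entirely on one side of the split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .modes import ModeSpec

__all__ = ["ModeBlock", "SpectralDataset", "FoldPlan", "make_fillet_folds", "split"]

META_COLUMNS = ["sample_id", "fillet_id", "species", "mode"]


@dataclass
class ModeBlock:
    """All rows of one mode: metadata aligned row-for-row with a spectra matrix."""

    mode: ModeSpec
    meta: pd.DataFrame  # columns sample_id, fillet_id, species
    X: np.ndarray  # shape (n_rows, mode.n_bands)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.mode.n_bands:
            raise ValueError(
                f"mode {self.mode.name!r}: spectra shape {self.X.shape} does not match "
                f"{self.mode.n_bands} bands"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata and spectra row counts differ")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def take(self, idx: np.ndarray) -> "ModeBlock":
        return ModeBlock(self.mode, self.meta.iloc[idx].reset_index(drop=True), self.X[idx])


class SpectralDataset:
    """Labeled point spectra across one or more modes.

    Invariants: within a mode all spectra share the mode's band count, and
    every fillet id maps to exactly one species (checked at construction).
    """

    def __init__(self, blocks: dict[str, ModeBlock]):
        if not blocks:
            raise ValueError("dataset needs at least one mode block")
        self.blocks = dict(blocks)
        self._check_fillet_species()

    def _check_fillet_species(self) -> None:
        seen: dict[str, str] = {}
        for b in self.blocks.values():
            for fid, sp in zip(b.meta["fillet_id"], b.meta["species"]):
                if seen.setdefault(fid, sp) != sp:
                    raise ValueError(f"fillet {fid!r} labeled with more than one species")
        self._fillet_species = seen

    # -- introspection -------------------------------------------------
    @property
    def modes(self) -> list[str]:
        return list(self.blocks)

    @property
    def n_rows(self) -> int:
        return sum(b.n_rows for b in self.blocks.values())

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for b in self.blocks.values():
            out.update(b.meta["species"])
        return sorted(out)

    @property
    def fillet_species(self) -> dict[str, str]:
        """Mapping fillet_id -> species over all modes."""
        return dict(self._fillet_species)

    def block(self, mode: str) -> ModeBlock:
        return self.blocks[mode]

    # -- subsetting ----------------------------------------------------
    def subset_fillets(self, fillet_ids) -> "SpectralDataset":
        """Rows whose fillet is in ``fillet_ids`` (possibly empty blocks kept)."""
        fids = set(fillet_ids)
        out = {}
        for name, b in self.blocks.items():
            keep = b.meta["fillet_id"].isin(fids).to_numpy()
            out[name] = b.take(np.flatnonzero(keep))
        return SpectralDataset(out)

    def subset_species(self, species) -> "SpectralDataset":
        sp = set(species)
        out = {}
        for name, b in self.blocks.items():
            keep = b.meta["species"].isin(sp).to_numpy()
            out[name] = b.take(np.flatnonzero(keep))
        return SpectralDataset(out)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write one CSV with columns sample_id,fillet_id,species,mode,w_<nm>...

        Modes with different grids contribute different ``w_`` columns; cells
        outside a row's mode are left empty.
        """
        frames = []
        for b in self.blocks.values():
            cols = [f"w_{w:g}" for w in b.mode.wavelengths]
            df = b.meta[["sample_id", "fillet_id", "species"]].copy()
            df["mode"] = b.mode.name
            df = pd.concat([df, pd.DataFrame(b.X, columns=cols)], axis=1)
            frames.append(df)
        all_rows = pd.concat(frames, axis=0, ignore_index=True)
        meta_cols = META_COLUMNS
        w_cols = [c for c in all_rows.columns if c.startswith("w_")]
        all_rows[meta_cols + w_cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        df = pd.read_csv(path)
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CSV missing required columns {missing}")
        blocks = {}
        for mode_name, sub in df.groupby("mode", sort=True):
            w_cols = [c for c in sub.columns if c.startswith("w_") and sub[c].notna().all()]
            wl = np.array([float(c[2:]) for c in w_cols])
            order = np.argsort(wl)
            wl = wl[order]
            w_cols = [w_cols[i] for i in order]
            mode = ModeSpec(str(mode_name), wl)
            blocks[mode.name] = ModeBlock(
                mode, sub[["sample_id", "fillet_id", "species"]].copy(), sub[w_cols].to_numpy(float)
            )
        return cls(blocks)

    @staticmethod
    def concat(parts: list["SpectralDataset"]) -> "SpectralDataset":
        blocks: dict[str, ModeBlock] = {}
        for ds in parts:
            for name, b in ds.blocks.items():
                if name in blocks:
                    prev = blocks[name]
                    blocks[name] = ModeBlock(
                        prev.mode,
                        pd.concat([prev.meta, b.meta], ignore_index=True),
                        np.vstack([prev.X, b.X]),
                    )
                else:
                    blocks[name] = b
        return SpectralDataset(blocks)


@dataclass
class FoldPlan:
    """Fillet-exclusive fold assignment: per fold, disjoint test/train fillet sets."""

    k: int
    test_fillets: list[set] = field(default_factory=list)
    train_fillets: list[set] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in range(self.k):
            overlap = self.test_fillets[f] & self.train_fillets[f]
            if overlap:
                raise ValueError(f"fold {f}: fillets on both sides: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "k": self.k,
            "folds": [
                {"test": sorted(self.test_fillets[f]), "train": sorted(self.train_fillets[f])}
                for f in range(self.k)
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        obj = json.loads(Path(path).read_text())
        return cls(
            k=obj["k"],
            test_fillets=[set(f["test"]) for f in obj["folds"]],
            train_fillets=[set(f["train"]) for f in obj["folds"]],
        )


def make_fillet_folds(ds: SpectralDataset, k: int = 4, seed: int = 0) -> FoldPlan:
    """Build k folds in which each fold's test fillets never appear in its train set.

    For every species with at least ``k`` fillets, ``k`` distinct fillets are
    drawn (seeded) and assigned one per fold as that species' test fillet; any
    further fillets of the species train in every fold.  Species with fewer
    than ``k`` fillets cycle their fillets across folds with replacement, but a
    fillet never sits on both sides of one fold.  A single-fillet species is
    tested in exactly one fold (it has no training data there; a warning is
    emitted) and trains in the others.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[str]] = {}
    for fid, sp in sorted(ds.fillet_species.items()):
        by_species.setdefault(sp, []).append(fid)

    test: list[set] = [set() for _ in range(k)]
    train: list[set] = [set() for _ in range(k)]
    for sp in sorted(by_species):
        fids = list(by_species[sp])
        rng.shuffle(fids)
        if len(fids) == 1:
            warnings.warn(
                f"species {sp!r} has a single fillet; it is tested untrained in one fold",
                stacklevel=2,
            )
            f_test = int(rng.integers(k))
            for f in range(k):
                (test if f == f_test else train)[f].add(fids[0])
            continue
        if len(fids) >= k:
            for f in range(k):
                test[f].add(fids[f])
            extras = fids[k:]
            for f in range(k):
                train[f].update(extras)
                train[f].update(fids[g] for g in range(k) if g != f)
        else:
            for f in range(k):
                t = fids[f % len(fids)]
                test[f].add(t)
                train[f].update(x for x in fids if x != t)
    return FoldPlan(k=k, test_fillets=test, train_fillets=train)


def split(ds: SpectralDataset, plan: FoldPlan, fold_index: int) -> tuple[SpectralDataset, SpectralDataset]:
    """Partition ``ds`` into (train, test) by fillet membership of one fold."""
    if not 0 <= fold_index < plan.k:
        raise IndexError(f"fold_index {fold_index} out of range for k={plan.k}")
    return (
        ds.subset_fillets(plan.train_fillets[fold_index]),
        ds.subset_fillets(plan.test_fillets[fold_index]),
    )
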