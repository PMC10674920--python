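"""Hierarchical (hybrid) inference and multi-mode majority-vote fusion.

A :class:`HybridModel` wraps one mode's global classifier and its dispute
set: if the global prediction is a forming species, the sample is re-decided
by that species' group classifier (over the group's classes only); otherwise
the global prediction stands.  A :class:`FusionModel` holds one hybrid model
per mode and fuses their per-sample votes by plurality, with a configurable
tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import TrainedClassifier, predict
from .dispute import DisputeSet

__all__ = ["HybridModel", "FusionModel", "hybrid_predict", "fuse_predict", "fuse_votes", "tie_break"]

DEFAULT_PRIORITY = ("Fluor", "VNIR", "SWIR")  # descending single-mode accuracy


@dataclass
class HybridModel:
    """Global classifier + dispute set for one mode."""

    global_model: TrainedClassifier
    dispute_set: DisputeSet
    mode: str | None = None

    def __post_init__(self):
        for g in self.dispute_set.groups:
            if g.classifier is None:
                raise ValueError(
                    f"dispute group for {g.forming_species!r} has no trained classifier"
                )

    @property
    def routing(self) -> dict[str, TrainedClassifier]:
        return {g.forming_species: g.classifier for g in self.dispute_set.groups}

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        return hybrid_predict(self, spectra)

    def predict_global(self, spectra: np.ndarray) -> np.ndarray:
        labels, _ = predict(self.global_model, spectra)
        return labels


def hybrid_predict(hm: HybridModel, spectra: np.ndarray) -> np.ndarray:
    """Two-stage prediction: global first, dispute model where it routes."""
    spectra = np.asarray(spectra, dtype=float)
    labels, _ = predict(hm.global_model, spectra)
    for forming, clf in hm.routing.items():
        idx = np.flatnonzero(labels == forming)
        if idx.size:
            labels[idx], _ = predict(clf, spectra[idx])
    return labels


@dataclass
class FusionModel:
    """Per-mode hybrid models + the vote tie-break policy."""

    hybrids: dict[str, HybridModel]
    policy: str = "mode_priority"
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self):
        if len(self.hybrids) < 2:
            raise ValueError("fusion requires at least 2 modes")
        if self.policy not in ("mode_priority", "max_confidence"):
            raise ValueError(f"unknown tie-break policy {self.policy!r}")
        present = [m for m in self.priority if m in self.hybrids]
        leftover = [m for m in self.hybrids if m not in present]
        self.priority = tuple(present + leftover)

    def predict(self, spectra_by_mode: dict[str, np.ndarray], use_hybrid: bool = True) -> np.ndarray:
        return fuse_predict(self, spectra_by_mode, use_hybrid=use_hybrid)


def tie_break(
    votes: dict[str, str],
    policy: str = "mode_priority",
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    confidences: dict[str, float] | None = None,
) -> str:
    """Resolve a full tie among per-mode votes.

    ``mode_priority`` returns the highest-priority mode's vote;
    ``max_confidence`` returns the vote whose mode reports the highest
    posterior probability.
    """
    if not votes:
        raise ValueError("votes must be nonempty")
    if policy == "mode_priority":
        for m in priority:
            if m in votes:
                return votes[m]
        return votes[sorted(votes)[0]]
    if policy == "max_confidence":
        if confidences is None:
            raise ValueError("max_confidence policy needs per-mode confidences")
        return votes[max(votes, key=lambda m: confidences[m])]
    raise ValueError(f"unknown tie-break policy {policy!r}")


def fuse_predict(
    fm: FusionModel,
    spectra_by_mode: dict[str, np.ndarray],
    use_hybrid: bool = True,
) -> np.ndarray:
    """Plurality vote over per-mode predictions, row-aligned across modes.

    ``spectra_by_mode`` maps mode name to an ``(n, bands_mode)`` array; row i
    of every mode is the same physical sample.  With ``use_hybrid=False`` the
    vote uses the raw global predictions (the global-fusion figure); with
    ``True`` it uses hybrid predictions (the hybrid-fusion figure).
    """
    modes = [m for m in spectra_by_mode if m in fm.hybrids]
    if len(modes) < 2:
        raise ValueError("fusion needs spectra from at least 2 modes")
    n_rows = {m: np.asarray(spectra_by_mode[m]).shape[0] for m in modes}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"modes disagree on sample count: {n_rows}")
    n = next(iter(n_rows.values()))

    votes: dict[str, np.ndarray] = {}
    conf: dict[str, np.ndarray] = {}
    for m in modes:
        hm = fm.hybrids[m]
        X = np.asarray(spectra_by_mode[m], dtype=float)
        if use_hybrid:
            votes[m] = hybrid_predict(hm, X)
        else:
            votes[m] = hm.predict_global(X)
        if fm.policy == "max_confidence":
            _, probs = predict(hm.global_model, X)
            conf[m] = probs.max(axis=1) if probs.size else np.zeros(n)

    order = tuple(m for m in fm.priority if m in modes)
    return fuse_votes(votes, policy=fm.policy, priority=order, confidences=conf or None)


def fuse_votes(
    votes_by_mode: dict[str, np.ndarray],
    policy: str = "mode_priority",
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    confidences: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Plurality winner per row over aligned per-mode label vectors."""
    modes = list(votes_by_mode)
    n = len(next(iter(votes_by_mode.values())))
    out = np.empty(n, dtype=object)
    for i in range(n):
        row = {m: votes_by_mode[m][i] for m in modes}
        tally: dict[str, int] = {}
        for v in row.values():
            tally[v] = tally.get(v, 0) + 1
        top = max(tally.values())
        winners = {v for v, c in tally.items() if c == top}
        if len(winners) == 1:
            out[i] = next(iter(winners))
        else:
            tied = {m: v for m, v in row.items() if v in winners}
            out[i] = tie_break(
                tied,
                policy=policy,
                priority=priority,
                confidences={m: float(confidences[m][i]) for m in tied} if confidences else None,
            )
    return out
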