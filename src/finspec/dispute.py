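"""Confusion-driven dispute groups: formation, exclusivity, training.

The global classifier's confusion matrix identifies *forming species* —
classes whose recall falls below a threshold T (default 0.78, the
single-measurement accuracy from which seven repeated measurements reach 95%
fillet-level accuracy).  Each forming species proposes a small group
containing itself and the classes it is most often mistaken for.  Because no
species may belong to more than one group, overlapping proposals are resolved
greedily by measured net recall gain, and groups whose best configuration
does not improve on the global model are dropped.  Each surviving group gets
its own specialized classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifiers import DisputeModelSpec, TrainedClassifier, predict, train_dispute_cnn
from .dataset import SpectralDataset

__all__ = [
    "ConfusionMatrix",
    "DisputeGroup",
    "DisputeSet",
    "confusion_from_predictions",
    "find_forming_species",
    "candidate_members",
    "resolve_exclusivity",
    "build_dispute_set",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.78


@dataclass
class ConfusionMatrix:
    """Counts matrix (rows = truth, columns = prediction) over a class list."""

    classes: list[str]
    counts: np.ndarray  # (C, C) nonnegative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts shape does not match class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def percent(self) -> np.ndarray:
        """Row-normalized view in percent; empty rows are all-NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    @property
    def recalls(self) -> pd.Series:
        """Per-class recall (diagonal of the row-normalized view), in [0, 1]."""
        totals = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(totals > 0, np.diag(self.counts) / totals, np.nan)
        return pd.Series(r, index=self.classes)

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.classes != self.classes:
            raise ValueError("cannot pool confusion matrices over different class lists")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


def confusion_from_predictions(truth, predicted, classes: list[str]) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    unknown = (set(truth) | set(predicted)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    counts = _sk_confusion(truth, predicted, labels=classes) if truth.size else np.zeros(
        (len(classes), len(classes)), dtype=int
    )
    return ConfusionMatrix(list(classes), counts)


def find_forming_species(cm: ConfusionMatrix, threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """Classes with recall < threshold, in descending misclassified mass.

    Misclassified mass is the class's off-diagonal row count — the number of
    its measurements the global model sent elsewhere.
    """
    recalls = cm.recalls
    off_mass = cm.counts.sum(axis=1) - np.diag(cm.counts)
    order = np.argsort(-off_mass, kind="stable")
    out = []
    for i in order:
        r = recalls.iloc[i]
        if np.isfinite(r) and r < threshold:
            out.append(cm.classes[i])
    return out


def candidate_members(
    cm: ConfusionMatrix,
    forming_species: str,
    mass_fraction: float = 0.20,
    max_members: int = 3,
) -> list[str]:
    """Classes absorbing >= ``mass_fraction`` of the forming species' errors.

    Ranked by absorbed share, capped at ``max_members``.  If no class reaches
    the fraction, the single largest absorber is returned.
    """
    i = cm.classes.index(forming_species)
    row = cm.counts[i].astype(float)
    off = row.copy()
    off[i] = 0.0
    total = off.sum()
    if total <= 0:
        raise ValueError(f"{forming_species!r} has no misclassified mass (recall = 1)")
    share = off / total
    order = np.argsort(-share, kind="stable")
    picks = [j for j in order if share[j] >= mass_fraction][:max_members]
    if not picks:
        picks = [int(order[0])]
    return [cm.classes[j] for j in picks]


@dataclass
class DisputeGroup:
    forming_species: str
    members: list[str]  # added classes, excluding the forming species
    classifier: TrainedClassifier | None = None
    net_gain: float = float("nan")

    def __post_init__(self):
        if self.forming_species in self.members:
            raise ValueError("forming species cannot be its own member")
        if not 1 <= len(self.members) <= 3:
            raise ValueError("a dispute group has 1-3 added members (group size 2-4)")

    @property
    def classes(self) -> list[str]:
        return [self.forming_species] + list(self.members)


@dataclass
class DisputeSet:
    groups: list[DisputeGroup] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    mode: str | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen & set(g.classes)
            if overlap:
                raise ValueError(f"species in more than one dispute group: {sorted(overlap)}")
            seen.update(g.classes)

    @property
    def forming_species(self) -> list[str]:
        return [g.forming_species for g in self.groups]

    def group_for(self, species: str) -> DisputeGroup | None:
        for g in self.groups:
            if g.forming_species == species:
                return g
        return None

    def to_records(self) -> pd.DataFrame:
        """Report-shaped table: one row per group (target, added members, gain)."""
        return pd.DataFrame(
            [
                {
                    "target": g.forming_species,
                    "added_members": ";".join(g.members),
                    "net_gain": g.net_gain,
                }
                for g in self.groups
            ]
        )


def resolve_exclusivity(
    proposals: list[tuple[str, list[str]]],
    evaluator: Callable[[str, list[str]], float],
) -> list[DisputeGroup]:
    """Greedy best-marginal-gain assignment of species to exclusive groups.

    At each round every still-open proposal is re-evaluated with the members
    that remain unclaimed; the proposal with the largest measured net gain is
    committed and its classes become unavailable to the rest.  Proposals whose
    best configuration has net gain <= 0, or whose members are all claimed,
    are dropped.
    """
    open_props = [(f, list(m)) for f, m in proposals]
    taken: set[str] = set()
    committed: list[DisputeGroup] = []
    cache: dict[tuple[str, tuple[str, ...]], float] = {}
    while open_props:
        scored = []
        for f, members in open_props:
            if f in taken:
                continue
            avail = [m for m in members if m not in taken][:3]
            if not avail:
                continue
            key = (f, tuple(avail))
            if key not in cache:
                cache[key] = float(evaluator(f, avail))
            scored.append((cache[key], f, avail))
        if not scored:
            break
        scored.sort(key=lambda t: -t[0])
        gain, f, avail = scored[0]
        open_props = [(pf, pm) for pf, pm in open_props if pf != f]
        if gain <= 0:
            # best remaining proposal does not improve; nothing later can claim
            # a positive gain for this forming species either — drop it
            continue
        committed.append(DisputeGroup(f, avail, net_gain=gain))
        taken.update([f], avail)
    return committed


def build_dispute_set(
    train: SpectralDataset,
    validation: SpectralDataset,
    global_model: TrainedClassifier,
    threshold: float = DEFAULT_THRESHOLD,
    spec: DisputeModelSpec | None = None,
    mode: str | None = None,
    mass_fraction: float = 0.20,
    max_members: int = 3,
    gain_data: SpectralDataset | None = None,
) -> DisputeSet:
    """End-to-end group formation for one mode.

    Forming species and their candidate members come from the global model's
    confusion on ``validation``.  Candidate group classifiers are trained on
    ``train`` and a configuration's score is the net change, summed over the
    group's classes, of recall on ``gain_data`` when the group classifier
    overrides the global prediction (hybrid) versus the global prediction
    alone.  ``gain_data`` defaults to ``validation`` — the same held-out
    predictions used to form the groups, so retained groups improve on the
    data that revealed the confusion; pass a separate dataset to decouple
    retention from formation.
    """
    spec = spec or DisputeModelSpec()
    mode = mode or next(iter(train.blocks))
    vblock = validation.block(mode)
    truth = vblock.meta["species"].to_numpy(dtype=object)
    g_pred, _ = predict(global_model, vblock.X)
    cm = confusion_from_predictions(truth, g_pred, global_model.classes)

    forming = find_forming_species(cm, threshold)
    if not forming:
        return DisputeSet([], threshold, mode)
    proposals = [(f, candidate_members(cm, f, mass_fraction, max_members)) for f in forming]

    gblock = (gain_data or validation).block(mode)
    gain_truth = gblock.meta["species"].to_numpy(dtype=object)
    gain_gpred, _ = predict(global_model, gblock.X)

    trained: dict[tuple[str, tuple[str, ...]], TrainedClassifier] = {}

    def evaluator(f: str, members: list[str]) -> float:
        classes = [f] + members
        key = (f, tuple(members))
        try:
            clf = train_dispute_cnn(train.subset_species(classes), classes, spec, mode=mode)
        except ValueError as err:
            raise RuntimeError(f"dispute group {classes} failed to train: {err}") from err
        trained[key] = clf
        hybrid = gain_gpred.copy()
        idx = np.flatnonzero(gain_gpred == f)
        if idx.size:
            hybrid[idx], _ = predict(clf, gblock.X[idx])
        gain = 0.0
        for c in classes:
            rows = gain_truth == c
            if rows.any():
                gain += float((hybrid[rows] == c).mean() - (gain_gpred[rows] == c).mean())
        return gain

    groups = resolve_exclusivity(proposals, evaluator)
    for g in groups:
        g.classifier = trained[(g.forming_species, tuple(g.members))]
    return DisputeSet(groups, threshold, mode)
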