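"""Model/Results facade over the dispute-hierarchy pipeline.

:class:`DisputeHierarchy` is constructed from a multi-mode
:class:`~finspec.dataset.SpectralDataset` (or a long-format DataFrame) and
holds the study design: fold count, recall threshold T, classifier
hyperparameters, fusion policy.  Calling :meth:`~DisputeHierarchy.fit` runs
fillet-exclusive cross-validation of the global, hybrid and fused decision
rules and returns a :class:`DisputeHierarchyResults` carrying the pooled
confusion matrices, per-species recalls, kappas, the dispute groups that
formed, and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import DisputeModelSpec, GlobalModelSpec
from .dataset import FoldPlan, SpectralDataset, make_fillet_folds
from .dispute import DEFAULT_THRESHOLD
from .evaluation import (
    EvalReport,
    cross_validate,
    min_measurements_for_target,
    repeated_measurement_probability,
)
from .fusion import DEFAULT_PRIORITY

__all__ = ["DisputeHierarchy", "DisputeHierarchyResults"]


class DisputeHierarchy:
    """Hierarchy-of-dispute-models experiment on a labeled spectral dataset."""

    def __init__(
        self,
        data: SpectralDataset,
        threshold: float = DEFAULT_THRESHOLD,
        k: int = 4,
        global_spec: GlobalModelSpec | None = None,
        dispute_spec: DisputeModelSpec | None = None,
        priority: tuple[str, ...] = DEFAULT_PRIORITY,
    ):
        self.data = data
        self.threshold = threshold
        self.k = k
        self.global_spec = global_spec or GlobalModelSpec()
        self.dispute_spec = dispute_spec or DisputeModelSpec()
        self.priority = priority

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DisputeHierarchy":
        """Build from a long-format frame (sample_id, fillet_id, species, mode, w_<nm>...)."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(SpectralDataset.from_csv(buf), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DisputeHierarchy":
        return cls(SpectralDataset.from_csv(path), **kwargs)

    def fit(
        self,
        seed: int = 0,
        folds: list[int] | None = None,
        plan: FoldPlan | None = None,
    ) -> "DisputeHierarchyResults":
        """Run the cross-validated experiment; ``folds`` restricts which folds run."""
        plan = plan or make_fillet_folds(self.data, k=self.k, seed=seed)
        report = cross_validate(
            self.data,
            plan=plan,
            seed=seed,
            global_spec=self.global_spec,
            dispute_spec=self.dispute_spec,
            threshold=self.threshold,
            folds=folds,
            priority=self.priority,
        )
        return DisputeHierarchyResults(model=self, report=report)


@dataclass
class DisputeHierarchyResults:
    """Fitted-experiment results: accuracies, kappas, groups, diagnostics."""

    model: DisputeHierarchy
    report: EvalReport = field(repr=False)

    # -- headline quantities -------------------------------------------
    def accuracy(self, mode: str, family: str = "global") -> float:
        """Mean-over-species accuracy, as a fraction in [0, 1]."""
        return self.report.accuracy(mode, family)

    def kappa(self, mode: str, family: str = "global") -> float:
        return self.report.kappa(mode, family)

    @property
    def mode_table(self) -> pd.DataFrame:
        return self.report.mode_table()

    def species_table(self, mode: str) -> pd.DataFrame:
        return self.report.species_table(mode)

    @property
    def dispute_groups(self) -> pd.DataFrame:
        return self.report.dispute_records

    def planner(self, mode: str = "fusion", family: str = "hybrid",
                target: float = 0.95) -> dict:
        """Repeated-measurement planning at this experiment's accuracy level."""
        p = self.accuracy(mode, family)
        out = {"single_measurement_accuracy": p, "target": target}
        try:
            n = min_measurements_for_target(p, target=target)
            out["n_measurements"] = n
            out["majority_accuracy"] = repeated_measurement_probability(p, n)
        except ValueError as err:
            out["n_measurements"] = None
            out["note"] = str(err)
        return out

    def summary(self) -> str:
        """Human-readable summary of the fitted experiment."""
        rep = self.report
        lines = [
            "Dispute-hierarchy classification results",
            "=" * 48,
            f"species: {len(rep.classes)}   modes: {', '.join(rep.modes)}",
            f"folds run: {rep.config.get('folds_run')} of k={rep.config.get('k')}"
            f"   threshold T: {rep.config.get('threshold')}",
            "",
            "mean-over-species accuracy (%)",
            f"{'mode':<10}{'global':>9}{'hybrid':>9}{'delta':>8}  kappa(g->h)",
        ]
        for _, row in self.mode_table.iterrows():
            m = row["mode"]
            try:
                kg, kh = self.kappa(m, "global"), self.kappa(m, "hybrid")
                ktxt = f"{kg:.2f} -> {kh:.2f}"
            except KeyError:
                ktxt = ""
            lines.append(
                f"{m:<10}{row['global_pct']:>9.2f}{row['hybrid_pct']:>9.2f}"
                f"{row['delta_pct']:>8.2f}  {ktxt}"
            )
        n_groups = len(rep.dispute_records)
        lines.append("")
        lines.append(f"dispute groups formed (all folds/modes): {n_groups}")
        if n_groups:
            by_mode = rep.dispute_records.groupby("mode").size()
            lines.append("  " + ", ".join(f"{m}: {c}" for m, c in by_mode.items()))
        return "\n".join(lines)

    def plot_confusion(self, mode: str = "fusion", family: str = "hybrid", ax=None):
        """Heatmap of the row-normalized confusion matrix (percent)."""
        import matplotlib.pyplot as plt

        cm = self.report.confusions[(mode, family)]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(cm.percent, vmin=0, vmax=100, cmap="viridis")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{mode} {family}: row-normalized confusion (%)")
        plt.colorbar(im, ax=ax, label="% of species' samples")
        return ax

    def save(self, outdir) -> None:
        self.report.save(outdir)
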