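"""Metrics, the repeated-measurement planner, and the experiment driver.

Accuracy throughout is the *mean-over-species accuracy*: the unweighted mean
of per-species recalls (diagonal of the row-normalized confusion matrix), so
rare species count as much as common ones.  Agreement beyond chance is
summarized by Cohen's kappa.  The planner converts a single-measurement
accuracy p into the fillet-level accuracy achievable by majority vote over n
independent point measurements — a binomial tail — and inverts it to find
the smallest odd n reaching a target.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .classifiers import DisputeModelSpec, GlobalModelSpec, predict, train_global_mlp
from .dataset import FoldPlan, SpectralDataset, make_fillet_folds, split
from .dispute import DEFAULT_THRESHOLD, ConfusionMatrix, build_dispute_set, confusion_from_predictions
from .fusion import DEFAULT_PRIORITY, HybridModel, fuse_votes, hybrid_predict

__all__ = [
    "mean_species_accuracy",
    "cohens_kappa",
    "repeated_measurement_probability",
    "min_measurements_for_target",
    "EvalReport",
    "cross_validate",
]


def mean_species_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls; empty classes excluded with a warning."""
    recalls = cm.recalls
    empty = recalls.index[recalls.isna()]
    if len(empty):
        warnings.warn(f"classes with no test rows excluded from the mean: {list(empty)}",
                      stacklevel=2)
    return float(recalls.dropna().mean())


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """κ = (p_o − p_e)/(1 − p_e) from the confusion counts.

    p_o is the observed agreement (trace fraction); p_e the chance agreement
    implied by the row and column marginals.
    """
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1) / total
    cols = cm.counts.sum(axis=0) / total
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        warnings.warn("chance agreement is 1; kappa undefined", stacklevel=2)
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def repeated_measurement_probability(p: float, n: int) -> float:
    """Majority-vote accuracy of n independent measurements of accuracy p.

    Σ_{i=(n+1)/2}^{n} C(n, i) p^i (1 − p)^{n−i} — the probability that more
    than half of the n votes are correct.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1 or n % 2 == 0:
        raise ValueError("n must be an odd positive count")
    # survival function at (n-1)/2 counts i >= (n+1)/2 inclusive
    return float(binom.sf((n - 1) // 2, n, p))


def min_measurements_for_target(p: float, target: float = 0.95, n_max: int = 99) -> int:
    """Smallest odd n whose majority vote reaches ``target`` accuracy."""
    if p <= 0.5 and target > p:
        raise ValueError(f"p={p} <= 0.5: majority voting cannot reach {target}")
    for n in range(1, n_max + 1, 2):
        if repeated_measurement_probability(p, n) >= target:
            return n
    raise ValueError(f"no odd n <= {n_max} reaches target {target} from p={p}")


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class EvalReport:
    """Pooled-over-folds evaluation of global vs hybrid vs fused decisions."""

    classes: list[str]
    modes: list[str]
    confusions: dict  # (mode, family) -> ConfusionMatrix; ("fusion", family) for fused
    dispute_records: pd.DataFrame  # per fold/mode group table
    predictions: pd.DataFrame  # raw per-sample dump: fold, mode, sample_id, truth, global, hybrid
    fused_predictions: pd.DataFrame  # fold, sample_id, truth, fused_global, fused_hybrid
    plan: FoldPlan | None = None
    config: dict = field(default_factory=dict)

    def accuracy(self, mode: str, family: str = "global") -> float:
        return mean_species_accuracy(self.confusions[(mode, family)])

    def kappa(self, mode: str, family: str = "global") -> float:
        return cohens_kappa(self.confusions[(mode, family)])

    def mode_table(self) -> pd.DataFrame:
        """Summary table: per mode and for fusion, global vs hybrid accuracy (%)."""
        rows = []
        targets = self.modes + (["fusion"] if ("fusion", "global") in self.confusions else [])
        for m in targets:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = 100 * self.accuracy(m, "global")
                h = 100 * self.accuracy(m, "hybrid")
            rows.append({"mode": m, "global_pct": g, "hybrid_pct": h, "delta_pct": h - g})
        return pd.DataFrame(rows)

    def species_table(self, mode: str) -> pd.DataFrame:
        """Per-species recall (%) under global and hybrid, with the delta."""
        g = self.confusions[(mode, "global")].recalls
        h = self.confusions[(mode, "hybrid")].recalls
        return pd.DataFrame(
            {"species": self.classes, "global_pct": 100 * g.values, "hybrid_pct": 100 * h.values,
             "delta_pct": 100 * (h.values - g.values)}
        )

    def save(self, outdir) -> None:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.mode_table().to_csv(outdir / "mode_summary.csv", index=False)
        for m in self.modes:
            self.species_table(m).to_csv(outdir / f"species_{m}.csv", index=False)
        if len(self.dispute_records):
            self.dispute_records.to_csv(outdir / "dispute_groups.csv", index=False)
        self.predictions.to_csv(outdir / "predictions.csv", index=False)
        self.fused_predictions.to_csv(outdir / "fused_predictions.csv", index=False)
        kappas = {
            f"{m}_{fam}": self.kappa(m, fam)
            for m in self.modes + ["fusion"]
            for fam in ("global", "hybrid")
            if (m, fam) in self.confusions
        }
        (outdir / "report.json").write_text(
            json.dumps({"config": self.config, "kappa": kappas,
                        "mode_summary": self.mode_table().to_dict(orient="records")}, indent=2)
        )
        if self.plan is not None:
            self.plan.to_json(outdir / "fold_plan.json")


def cross_validate(
    ds: SpectralDataset,
    plan: FoldPlan | None = None,
    k: int = 4,
    seed: int = 0,
    global_spec: GlobalModelSpec | None = None,
    dispute_spec: DisputeModelSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    folds: list[int] | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    config_echo: dict | None = None,
) -> EvalReport:
    """Fillet-exclusive cross-validation of global, hybrid and fused decisions.

    Per fold and mode: fit the global MLP on the training fillets, form the
    dispute set from the test-fold confusion (with retention gains measured
    on the same held-out predictions), then record global and hybrid
    predictions on the test fold.  Fused predictions align test rows across
    modes by sample id and take the majority vote.  Counts are pooled over
    folds before recalls are computed.
    """
    plan = plan or make_fillet_folds(ds, k=k, seed=seed)
    folds = list(range(plan.k)) if folds is None else list(folds)
    classes = ds.species
    modes = ds.modes
    gspec = global_spec or GlobalModelSpec()
    dspec = dispute_spec or DisputeModelSpec()

    pred_rows = []
    fused_rows = []
    dispute_rows = []
    for f in folds:
        train_full, test = split(ds, plan, f)
        per_mode_votes: dict[str, dict] = {}
        for m in modes:
            gm = train_global_mlp(train_full, gspec, mode=m)
            tb = test.block(m)
            truth = tb.meta["species"].to_numpy(dtype=object)
            g_labels, _ = predict(gm, tb.X)
            dset = build_dispute_set(
                train_full, test, gm, threshold=threshold, spec=dspec, mode=m,
            )
            hm = HybridModel(gm, dset, mode=m)
            h_labels = hybrid_predict(hm, tb.X)
            for sid, t, g, h in zip(tb.meta["sample_id"], truth, g_labels, h_labels):
                pred_rows.append((f, m, sid, t, g, h))
            per_mode_votes[m] = dict(zip(tb.meta["sample_id"], zip(truth, g_labels, h_labels)))
            rec = dset.to_records()
            if len(rec):
                rec.insert(0, "mode", m)
                rec.insert(0, "fold", f)
                dispute_rows.append(rec)

        if len(modes) >= 2:
            common = set.intersection(*(set(v) for v in per_mode_votes.values()))
            sids = sorted(common)
            g_votes = {m: np.array([per_mode_votes[m][s][1] for s in sids], dtype=object) for m in modes}
            h_votes = {m: np.array([per_mode_votes[m][s][2] for s in sids], dtype=object) for m in modes}
            order = tuple(m for m in priority if m in modes) + tuple(m for m in modes if m not in priority)
            fg = fuse_votes(g_votes, priority=order)
            fh = fuse_votes(h_votes, priority=order)
            for i, s in enumerate(sids):
                truth_s = per_mode_votes[modes[0]][s][0]
                fused_rows.append((f, s, truth_s, fg[i], fh[i]))

    predictions = pd.DataFrame(pred_rows, columns=["fold", "mode", "sample_id", "truth", "global", "hybrid"])
    fused = pd.DataFrame(fused_rows, columns=["fold", "sample_id", "truth", "fused_global", "fused_hybrid"])

    confusions = {}
    for m in modes:
        sub = predictions[predictions["mode"] == m]
        confusions[(m, "global")] = confusion_from_predictions(sub["truth"], sub["global"], classes)
        confusions[(m, "hybrid")] = confusion_from_predictions(sub["truth"], sub["hybrid"], classes)
    if len(fused):
        confusions[("fusion", "global")] = confusion_from_predictions(
            fused["truth"], fused["fused_global"], classes)
        confusions[("fusion", "hybrid")] = confusion_from_predictions(
            fused["truth"], fused["fused_hybrid"], classes)

    return EvalReport(
        classes=classes,
        modes=modes,
        confusions=confusions,
        dispute_records=pd.concat(dispute_rows, ignore_index=True) if dispute_rows else pd.DataFrame(
            columns=["fold", "mode", "target", "added_members", "net_gain"]),
        predictions=predictions,
        fused_predictions=fused,
        plan=plan,
        config={
            "k": plan.k, "folds_run": folds, "seed": seed, "threshold": threshold,
            "global_spec": dataclasses.asdict(gspec),
            "dispute_spec": dataclasses.asdict(dspec),
            **(config_echo or {}),
        },
    )
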