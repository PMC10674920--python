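"""The two trainable classifier families behind one train/predict contract.

*Global model*: a multilayer perceptron over all species of a mode — two
hidden layers of 512 and 128 ReLU units, dropout 0.5 on both, L2 weight decay
λ = 1e-4, softmax output.  The training objective is class-weighted
cross-entropy (the differentiable surrogate); epoch selection uses the
complement of class-weighted mean recall on a fillet-stratified slice of the
training data, so the model kept is the one best on the imbalance-corrected
accuracy rather than on raw loss.

*Dispute model*: a small 1-D CNN for a group of 2-4 confusable species — 64
filters of size 5 at stride 4 with SELU, then dense 128 (ELU), dense 128
(Swish), each followed by dropout 0.5, and a softmax output over exactly the
group's classes; Adam, categorical cross-entropy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import ModeBlock
from . import nnet

__all__ = [
    "GlobalModelSpec",
    "DisputeModelSpec",
    "TrainedClassifier",
    "train_global_mlp",
    "train_dispute_cnn",
    "predict",
]


@dataclass(frozen=True)
class GlobalModelSpec:
    hidden: tuple[int, int] = (512, 128)
    dropout: float = 0.5
    l2: float = 1e-4
    epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class DisputeModelSpec:
    n_filters: int = 64
    kernel: int = 5
    stride: int = 4
    dense: tuple[int, int] = (128, 128)
    dropout: float = 0.5
    epochs: int = 200
    patience: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    val_fraction: float = 0.15
    seed: int = 0


@dataclass
class TrainedClassifier:
    """A fitted network with its preprocessing state and label list."""

    net: nnet.Network = field(repr=False)
    classes: list[str]
    mean: np.ndarray = field(repr=False)
    std: np.ndarray = field(repr=False)
    spec: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict, repr=False)

    @property
    def n_bands(self) -> int:
        return self.mean.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_bands:
            raise ValueError(f"expected spectra with {self.n_bands} bands, got shape {X.shape}")
        return self.net.predict_proba((X - self.mean) / self.std)

    # -- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        spec_text = json.dumps({"classes": self.classes, "spec": self.spec}, sort_keys=True)
        (path / "spec.json").write_text(
            json.dumps(
                {
                    "classes": self.classes,
                    "spec": self.spec,
                    "hash": hashlib.sha256(spec_text.encode()).hexdigest(),
                },
                indent=2,
            )
        )
        arrays = {"mean": self.mean, "std": self.std}
        for i, p in enumerate(self.net.get_params()):
            arrays[f"p{i}"] = p
        np.savez(path / "weights.npz", **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        obj = json.loads((path / "spec.json").read_text())
        spec_text = json.dumps({"classes": obj["classes"], "spec": obj["spec"]}, sort_keys=True)
        if hashlib.sha256(spec_text.encode()).hexdigest() != obj["hash"]:
            raise ValueError(f"{path}: spec hash mismatch; model directory corrupted")
        data = np.load(path / "weights.npz")
        clf = _build(obj["spec"], len(data["mean"]), len(obj["classes"]))
        clf.net.set_params([data[f"p{i}"] for i in range(len(clf.net.get_params()))])
        clf.classes = obj["classes"]
        clf.mean, clf.std = data["mean"], data["std"]
        clf.spec = obj["spec"]
        return clf


def _build(spec: dict, n_bands: int, n_classes: int) -> TrainedClassifier:
    """Reconstruct an untrained classifier skeleton from a spec dict."""
    rng = np.random.default_rng(0)
    if spec["family"] == "global_mlp":
        layers = _mlp_layers(GlobalModelSpec(**{k: _t(v) for k, v in spec["params"].items()}),
                             n_bands, n_classes, rng)
    else:
        layers = _cnn_layers(DisputeModelSpec(**{k: _t(v) for k, v in spec["params"].items()}),
                             n_bands, n_classes, rng)
    return TrainedClassifier(nnet.Network(layers), [], np.zeros(n_bands), np.ones(n_bands), spec)


def _t(v):
    return tuple(v) if isinstance(v, list) else v


def _mlp_layers(spec: GlobalModelSpec, n_bands: int, n_classes: int, rng) -> list:
    h1, h2 = spec.hidden
    return [
        nnet.Dense(n_bands, h1, l2=spec.l2, rng=rng),
        nnet.Activation("relu"),
        nnet.Dropout(spec.dropout),
        nnet.Dense(h1, h2, l2=spec.l2, rng=rng),
        nnet.Activation("relu"),
        nnet.Dropout(spec.dropout),
        nnet.Dense(h2, n_classes, rng=rng),
    ]


def _cnn_layers(spec: DisputeModelSpec, n_bands: int, n_classes: int, rng) -> list:
    conv = nnet.Conv1D(n_bands, spec.n_filters, spec.kernel, spec.stride, rng=rng)
    d1, d2 = spec.dense
    return [
        conv,
        nnet.Activation("selu"),
        nnet.Dense(conv.output_dim, d1, rng=rng),
        nnet.Activation("elu"),
        nnet.Dropout(spec.dropout),
        nnet.Dense(d1, d2, rng=rng),
        nnet.Activation("swish"),
        nnet.Dropout(spec.dropout),
        nnet.Dense(d2, n_classes, rng=rng),
    ]


def _selection_split(block: ModeBlock, frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Fillet-stratified row split: from each fillet, ``frac`` of its rows."""
    val_idx = []
    fillets = block.meta["fillet_id"].to_numpy()
    for fid in np.unique(fillets):
        rows = np.flatnonzero(fillets == fid)
        n_val = max(1, int(round(frac * rows.size))) if rows.size > 1 else 0
        val_idx.extend(rng.choice(rows, size=n_val, replace=False))
    val = np.zeros(block.n_rows, dtype=bool)
    val[np.array(val_idx, dtype=int)] = True
    return np.flatnonzero(~val), np.flatnonzero(val)


def _fit(block: ModeBlock, layers_fn, spec, family: str) -> TrainedClassifier:
    classes = sorted(block.meta["species"].unique())
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    class_index = {c: i for i, c in enumerate(classes)}
    y = block.meta["species"].map(class_index).to_numpy()
    X = block.X
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    tr, va = _selection_split(block, spec.val_fraction, rng)
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    counts[counts == 0] = 1.0
    class_weights = counts.sum() / (len(classes) * counts)  # inverse frequency

    net = nnet.Network(layers_fn(spec, X.shape[1], len(classes), rng))
    history = nnet.train_network(
        net, Xs[tr], y[tr], Xs[va], y[va], class_weights,
        epochs=spec.epochs, patience=spec.patience, batch_size=spec.batch_size,
        lr=spec.lr, seed=spec.seed,
    )
    meta = {"family": family, "params": asdict(spec)}
    return TrainedClassifier(net, classes, mean, std, meta, history)


def train_global_mlp(train, spec: GlobalModelSpec | None = None, mode: str | None = None) -> TrainedClassifier:
    """Fit the global MLP over all species present in one mode of ``train``."""
    spec = spec or GlobalModelSpec()
    block = train.block(mode) if mode else next(iter(train.blocks.values()))
    return _fit(block, _mlp_layers, spec, "global_mlp")


def train_dispute_cnn(train_subset, group_classes: list[str],
                      spec: DisputeModelSpec | None = None, mode: str | None = None) -> TrainedClassifier:
    """Fit a dispute CNN over exactly ``group_classes`` (all must be present)."""
    spec = spec or DisputeModelSpec()
    block = train_subset.block(mode) if mode else next(iter(train_subset.blocks.values()))
    present = set(block.meta["species"].unique())
    missing = sorted(set(group_classes) - present)
    if missing:
        raise ValueError(f"group classes missing from training data: {missing}")
    extra = present - set(group_classes)
    if extra:
        keep = block.meta["species"].isin(set(group_classes)).to_numpy()
        block = block.take(np.flatnonzero(keep))
    return _fit(block, _cnn_layers, spec, "dispute_cnn")


def predict(model: TrainedClassifier, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and probabilities; ties broken toward the lowest class index."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.size == 0:
        return np.array([], dtype=object), np.empty((0, len(model.classes)))
    probs = model.predict_proba(spectra)
    labels = np.array(model.classes, dtype=object)[probs.argmax(axis=1)]
    return labels, probs
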