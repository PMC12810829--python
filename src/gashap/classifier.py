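"""3D CNN case/control classifier and masked-input evaluation.

The architecture is the compact 3D CNN used for whole-volume case/control
discrimination: three convolutional blocks (5**3 then twice 3**3 kernels
with 8/16/32 filters, ReLU, 2x2x2 max-pooling each), a 1024-wide fully
connected layer and a 2-way softmax head, with dropout (keep probability
0.5) at the input and before the final layer.  At an 80**3 input the
flattened feature length is 32000; the spatial path simply scales with the
input, so the same builder serves desk-scale volumes.

Training uses Adadelta (lr 0.05, decay 0.95) on categorical cross-entropy
with batch size 32, early stopping on validation loss (patience 10), and
keeps the checkpoint with the highest validation accuracy.

A deterministic surrogate classifier (thresholded mean intensity over a
voxel set) is provided so that genetic-algorithm fitness plumbing can be
unit-tested without any stochastic training in the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .io import LabeledDataset

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "TrainedClassifier",
    "ConfusionCounts",
    "SurrogateClassifier",
    "build_model",
    "train",
    "masked_accuracy",
]

DEFAULT_BLOCKS: tuple[tuple[int, int], ...] = ((5, 8), (3, 16), (3, 32))


@dataclass
class CNNSpec:
    input_shape: tuple[int, int, int] = (24, 24, 24)
    conv_blocks: tuple[tuple[int, int], ...] = DEFAULT_BLOCKS
    fc_width: int = 1024
    n_classes: int = 2
    dropout_keep: float = 0.5

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.conv_blocks = tuple((int(k), int(f)) for k, f in self.conv_blocks)
        divisor = 2 ** len(self.conv_blocks)
        for dim in self.input_shape:
            if dim % divisor != 0:
                raise ValueError(
                    f"input dim {dim} not divisible by 2^{len(self.conv_blocks)} "
                    f"(one halving per pooling stage)"
                )

    @property
    def spatial_out(self) -> tuple[int, int, int]:
        d = 2 ** len(self.conv_blocks)
        return tuple(s // d for s in self.input_shape)  # type: ignore[return-value]

    @property
    def flat_features(self) -> int:
        """Length of the flattened vector after the last pooling stage."""
        return int(np.prod(self.spatial_out)) * self.conv_blocks[-1][1]


@dataclass
class TrainConfig:
    lr: float = 0.05
    decay: float = 0.95
    batch_size: int = 32
    max_epochs: int = 30
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


def build_model(spec: CNNSpec, rng: np.random.Generator | int | None = 0) -> nn.Sequential:
    """Instantiate the (untrained) network for ``spec``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layers: list[nn.Layer] = [nn.Dropout(spec.dropout_keep)]
    in_ch = 1
    for k, f in spec.conv_blocks:
        layers += [nn.Conv3D(in_ch, f, k, rng), nn.ReLU(), nn.MaxPool3D()]
        in_ch = f
    layers += [
        nn.Flatten(),
        nn.Dense(spec.flat_features, spec.fc_width, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout_keep),
        # zero-init head: initial logits are 0 so optimization starts from the
        # uniform prediction instead of whatever the random features imply
        nn.Dense(spec.fc_width, spec.n_classes, rng, scale=0.0),
    ]
    return nn.Sequential(layers)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for v in (self.TP, self.FP, self.TN, self.FN):
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def accuracy(self) -> float:
        """(TP+TN) / (TP+TN+FP+FN) — the f1 term of the mask fitness."""
        return (self.TP + self.TN) / self.n


class TrainedClassifier:
    """A fitted network exposing probabilities and input gradients."""

    def __init__(self, net: nn.Sequential, spec: CNNSpec, history: pd.DataFrame | None = None):
        self.net = net
        self.spec = spec
        self.history = history if history is not None else pd.DataFrame()

    # -- prediction --------------------------------------------------------

    def _as_batch(self, volumes: np.ndarray) -> np.ndarray:
        volumes = np.asarray(volumes, dtype=np.float32)
        if volumes.ndim == 3:
            volumes = volumes[None]
        if volumes.ndim != 4:
            raise ValueError("expected (n, nx, ny, nz) or a single 3D volume")
        return volumes[:, None]  # add channel axis

    def logits(self, volumes: np.ndarray, batch_size: int = 16) -> np.ndarray:
        x = self._as_batch(volumes)
        outs = [
            self.net.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(volumes))

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        return self.logits(volumes).argmax(axis=1)

    def input_gradient(
        self, volumes: np.ndarray, target_class: np.ndarray | int, batch_size: int = 8
    ) -> np.ndarray:
        """d(logit of target class)/d(input voxel), per sample, dropout off."""
        x = self._as_batch(volumes)
        targets = np.broadcast_to(np.asarray(target_class, dtype=np.int64), (len(x),))
        grads = []
        for i in range(0, len(x), batch_size):
            xb, tb = x[i : i + batch_size], targets[i : i + batch_size]
            logits = self.net.forward(xb, train=False)
            dout = np.zeros_like(logits)
            dout[np.arange(len(xb)), tb] = 1.0
            grads.append(self.net.backward(dout)[:, 0])
        return np.concatenate(grads, axis=0)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "input_shape": self.spec.input_shape,
            "conv_blocks": self.spec.conv_blocks,
            "fc_width": self.spec.fc_width,
            "n_classes": self.spec.n_classes,
            "dropout_keep": self.spec.dropout_keep,
        }
        state = self.net.get_state()
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            history=self.history.to_json(),
            **{f"param_{i}": p for i, p in enumerate(state)},
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            spec = CNNSpec(
                input_shape=tuple(meta["input_shape"]),
                conv_blocks=tuple(tuple(b) for b in meta["conv_blocks"]),
                fc_width=meta["fc_width"],
                n_classes=meta["n_classes"],
                dropout_keep=meta["dropout_keep"],
            )
            net = build_model(spec, rng=0)
            n_params = len(net.parameters())
            net.set_state([archive[f"param_{i}"] for i in range(n_params)])
            from io import StringIO

            history = pd.read_json(StringIO(str(archive["history"])))
        return cls(net=net, spec=spec, history=history)


def _evaluate(net: nn.Sequential, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = np.concatenate(
        [net.forward(x[i : i + 16], train=False) for i in range(0, len(x), 16)]
    )
    loss, _ = nn.softmax_cross_entropy(logits.copy(), y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    model: nn.Sequential | CNNSpec, dataset: LabeledDataset, cfg: TrainConfig
) -> TrainedClassifier:
    """Fit the network, returning the best-validation-accuracy checkpoint.

    Early stopping fires after ``early_stop_patience`` consecutive epochs
    without a validation-loss improvement.  Deterministic for a fixed seed
    under single-threaded execution.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(model, CNNSpec):
        spec = model
        net = build_model(spec, rng)
    else:
        net = model
        spec = _infer_spec(net, dataset)
    xtr, ytr = dataset.subset("train")
    xva, yva = dataset.subset("val")
    if len(ytr) == 0 or len(yva) == 0:
        raise ValueError("training requires nonempty train and val splits")
    xtr = xtr[:, None].astype(np.float32)
    xva = xva[:, None].astype(np.float32)
    opt = nn.Adadelta(net, lr=cfg.lr, rho=cfg.decay)

    best_val_loss = np.inf
    best_val_acc = -np.inf
    best_state = net.get_state()
    since_improve = 0
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(xtr[idx], train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, ytr[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss, val_acc = _evaluate(net, xva, yva)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_state = net.get_state()
        if val_loss < best_val_loss - 1e-12:
            best_val_loss = val_loss
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience:
                break
    net.set_state(best_state)
    return TrainedClassifier(net=net, spec=spec, history=pd.DataFrame(rows))


def _infer_spec(net: nn.Sequential, dataset: LabeledDataset) -> CNNSpec:
    blocks = tuple(
        (layer.k, layer.out_ch) for layer in net.layers if isinstance(layer, nn.Conv3D)
    )
    dense = [layer for layer in net.layers if isinstance(layer, nn.Dense)]
    keep = next(
        (layer.keep for layer in net.layers if isinstance(layer, nn.Dropout)), 1.0
    )
    return CNNSpec(
        input_shape=dataset.volumes[0].shape,
        conv_blocks=blocks or DEFAULT_BLOCKS,
        fc_width=dense[0].params["b"].shape[0] if dense else 1024,
        n_classes=dense[-1].params["b"].shape[0] if dense else 2,
        dropout_keep=keep,
    )


# ---------------------------------------------------------------------------
# masked evaluation


def _mask_array(mask) -> np.ndarray:
    arr = getattr(mask, "mask", mask)
    return np.asarray(arr)


def masked_accuracy(
    clf, volumes: np.ndarray, labels: np.ndarray, mask, fill: float = 0.0
) -> tuple[ConfusionCounts, float]:
    """Accuracy of ``clf`` on volumes with everything outside ``mask`` filled.

    The fill value defaults to 0 — the least-informative constant on
    zero-mean standardized volumes.  Returns the confusion counts and
    f1 = (TP+TN)/(TP+TN+FP+FN).
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    labels = np.asarray(labels)
    m = _mask_array(mask)
    if m.shape != volumes.shape[1:]:
        raise ValueError(f"mask shape {m.shape} != volume shape {volumes.shape[1:]}")
    m = m.astype(np.float32)
    masked = volumes * m + fill * (1.0 - m)
    pred = clf.predict(masked)
    counts = ConfusionCounts(
        TP=int(((pred == 1) & (labels == 1)).sum()),
        FP=int(((pred == 1) & (labels == 0)).sum()),
        TN=int(((pred == 0) & (labels == 0)).sum()),
        FN=int(((pred == 0) & (labels == 1)).sum()),
    )
    return counts, counts.accuracy


# ---------------------------------------------------------------------------
# deterministic surrogate


class SurrogateClassifier:
    """Threshold on the mean intensity over a voxel set.

    ``voxel_set`` restricts the mean to a boolean support (None = whole
    grid).  The decision is ``mean > threshold``; probabilities come from a
    logistic squashing of the margin so the object honours the same
    predict/predict_proba/input_gradient contract as the trained network,
    with zero stochasticity.
    """

    def __init__(
        self,
        voxel_set: np.ndarray | None = None,
        threshold: float = 0.0,
        temperature: float = 0.05,
    ) -> None:
        self.voxel_set = None if voxel_set is None else np.asarray(voxel_set, dtype=bool)
        self.threshold = float(threshold)
        self.temperature = float(temperature)

    def _scores(self, volumes: np.ndarray) -> np.ndarray:
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim == 3:
            volumes = volumes[None]
        if self.voxel_set is None:
            return volumes.reshape(len(volumes), -1).mean(axis=1)
        return volumes[:, self.voxel_set].mean(axis=1)

    def fit_threshold(self, volumes: np.ndarray, labels: np.ndarray) -> "SurrogateClassifier":
        """Set the threshold to the midpoint of the two class-mean scores."""
        s = self._scores(volumes)
        labels = np.asarray(labels)
        self.threshold = float((s[labels == 0].mean() + s[labels == 1].mean()) / 2.0)
        return self

    def logits(self, volumes: np.ndarray) -> np.ndarray:
        z = (self._scores(volumes) - self.threshold) / self.temperature
        return np.column_stack([-z / 2.0, z / 2.0])

    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(volumes))

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        return self.logits(volumes).argmax(axis=1)

    def input_gradient(self, volumes: np.ndarray, target_class) -> np.ndarray:
        volumes = np.asarray(volumes)
        if volumes.ndim == 3:
            volumes = volumes[None]
        shape = volumes.shape[1:]
        support = (
            np.ones(shape, dtype=np.float64) if self.voxel_set is None else self.voxel_set
        ).astype(np.float64)
        base = support / (support.sum() * self.temperature) / 2.0
        targets = np.broadcast_to(np.asarray(target_class, dtype=np.int64), (len(volumes),))
        sign = np.where(targets == 1, 1.0, -1.0)
        return sign[:, None, None, None] * base[None]
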