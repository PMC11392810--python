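"""Genus-level deep classifier for short 16S fragments.

Reads of up to 150 nt are one-hot encoded over (A, C, G, T, N), right-padded
and masked.  The network runs four parallel 1-D convolution branches (kernel
sizes 15/17/19/23) to pick up short motifs, concatenates them, and feeds two
bidirectional LSTM layers that scan the sequence in both directions; a
dropout/dense stack ends in a softmax over genera.  Training uses Adam on
categorical cross-entropy with per-epoch shuffling and early stopping on the
training loss.  The whole model is implemented in numpy (see ``_nn``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from . import _nn

ALPHABET = "ACGTN"
MAX_LEN = 150


@dataclass
class EncodedBatch:
    """One-hot encoded reads: x (n, T, 5), mask (n, T), integer labels."""

    x: np.ndarray
    mask: np.ndarray
    labels: Optional[np.ndarray] = None
    classes: Optional[list[str]] = None

    def __len__(self) -> int:
        return self.x.shape[0]

    def subset(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(
            x=self.x[idx],
            mask=self.mask[idx],
            labels=None if self.labels is None else self.labels[idx],
            classes=self.classes,
        )


def encode(
    sequences: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    classes: Optional[Sequence[str]] = None,
    max_len: int = MAX_LEN,
) -> EncodedBatch:
    """One-hot encode reads with right-padding and a validity mask.

    Channel order is (A, C, G, T, N); padded positions are all-zero and
    masked out.  Characters outside the alphabet raise, naming the read and
    position.
    """
    n = len(sequences)
    x = np.zeros((n, max_len, 5), dtype=np.float32)
    mask = np.zeros((n, max_len), dtype=np.float32)
    lut = {c: i for i, c in enumerate(ALPHABET)}
    for r, seq in enumerate(sequences):
        if len(seq) > max_len:
            raise ValueError(f"read {r}: length {len(seq)} exceeds {max_len}")
        for p, ch in enumerate(seq):
            ci = lut.get(ch)
            if ci is None:
                raise ValueError(f"read {r}, position {p}: invalid character {ch!r}")
            x[r, p, ci] = 1.0
            mask[r, p] = 1.0
    enc_labels = None
    cls: Optional[list[str]] = list(classes) if classes is not None else None
    if labels is not None:
        if cls is None:
            cls = sorted(set(labels))
        index = {c: i for i, c in enumerate(cls)}
        enc_labels = np.array([index[l] for l in labels], dtype=np.int64)
    return EncodedBatch(x=x, mask=mask, labels=enc_labels, classes=cls)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Kernel sizes and dropout rates follow the published architecture; filter
    and unit counts are this package's defaults (the original counts are not
    recoverable from the text).
    """

    n_classes: int = 2
    kernel_sizes: tuple[int, ...] = (15, 17, 19, 23)
    filters: int = 32
    recurrent_units: int = 48
    dense_units: tuple[int, int] = (96, 48)
    dropout_rates: tuple[float, float, float] = (0.5, 0.2, 0.1)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(not (0.0 <= r < 1.0) for r in self.dropout_rates):
            raise ValueError("dropout rates must be in [0, 1)")


@dataclass
class TrainConfig:
    split: float = 0.8
    max_epochs: int = 15
    patience: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split < 1.0):
            raise ValueError("split fraction must be in (0, 1)")


class GenusClassifier:
    """mask -> 4x conv -> concat -> dropout -> 2x BiLSTM -> dense stack -> softmax."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        F = config.filters
        H = config.recurrent_units
        self.convs = [
            _nn.Conv1D(f"conv{k}", k, 5, F, self.params, rng)
            for k in config.kernel_sizes
        ]
        concat_ch = F * len(config.kernel_sizes)
        self.lstm1 = _nn.BiLSTM("lstm1", concat_ch, H, self.params, rng)
        self.lstm2 = _nn.BiLSTM("lstm2", 2 * H, H, self.params, rng)
        d1, d2 = config.dense_units
        self.dense1 = _nn.Dense("dense1", 2 * H, d1, "relu", self.params, rng)
        self.dense2 = _nn.Dense("dense2", d1, d2, "relu", self.params, rng)
        self.dense_out = _nn.Dense("out", d2, config.n_classes, "linear",
                                   self.params, rng)
        self.fitted = False
        self.classes: Optional[list[str]] = None

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _forward(self, x: np.ndarray, mask: np.ndarray, training: bool,
                 rng: Optional[np.random.Generator]) -> tuple[np.ndarray, dict]:
        # trim the shared padded tail for speed; masking makes this a no-op
        # for the outputs
        valid_cols = np.flatnonzero(mask.any(axis=0))
        T_eff = int(valid_cols[-1]) + 1 if valid_cols.size else 1
        x = x[:, :T_eff]
        mask = mask[:, :T_eff]
        caches: dict = {"mask": mask}
        outs = []
        conv_caches = []
        for conv in self.convs:
            y, c = conv.forward(self.params, x)
            y = y * mask[:, :, None]
            conv_caches.append(c)
            outs.append(y)
        h = np.concatenate(outs, axis=2)
        caches["conv"] = conv_caches
        r1, r2, r3 = self.config.dropout_rates
        h, keep1 = _nn.dropout_forward(h, r1, rng, training)
        caches["keep1"] = keep1
        seq1, _, c1 = self.lstm1.forward(self.params, h, mask)
        caches["lstm1"] = c1
        _, last, c2 = self.lstm2.forward(self.params, seq1, mask)
        caches["lstm2"] = c2
        last, keep2 = _nn.dropout_forward(last, r2, rng, training)
        caches["keep2"] = keep2
        a1, cd1 = self.dense1.forward(self.params, last)
        caches["dense1"] = cd1
        a1, keep3 = _nn.dropout_forward(a1, r3, rng, training)
        caches["keep3"] = keep3
        a2, cd2 = self.dense2.forward(self.params, a1)
        caches["dense2"] = cd2
        logits, cdo = self.dense_out.forward(self.params, a2)
        caches["out"] = cdo
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches: dict,
                  grads: dict[str, np.ndarray]) -> None:
        da2 = self.dense_out.backward(self.params, grads, dlogits, caches["out"])
        da1 = self.dense2.backward(self.params, grads, da2, caches["dense2"])
        da1 = _nn.dropout_backward(da1, caches["keep3"])
        dlast = self.dense1.backward(self.params, grads, da1, caches["dense1"])
        dlast = _nn.dropout_backward(dlast, caches["keep2"])
        dseq1 = self.lstm2.backward(self.params, grads, None, dlast,
                                    caches["lstm2"])
        dh = self.lstm1.backward(self.params, grads, dseq1, None,
                                 caches["lstm1"])
        dh = _nn.dropout_backward(dh, caches["keep1"])
        mask = caches["mask"]
        F = self.config.filters
        for i, conv in enumerate(self.convs):
            dy = dh[:, :, i * F : (i + 1) * F] * mask[:, :, None]
            conv.backward(self.params, grads, dy, caches["conv"][i])

    def predict_proba(self, x: np.ndarray, mask: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            logits, _ = self._forward(x[i : i + batch_size],
                                      mask[i : i + batch_size],
                                      training=False, rng=None)
            probs.append(_nn.softmax(logits))
        return np.vstack(probs) if probs else np.zeros((0, self.config.n_classes))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "config": {
                "n_classes": self.config.n_classes,
                "kernel_sizes": list(self.config.kernel_sizes),
                "filters": self.config.filters,
                "recurrent_units": self.config.recurrent_units,
                "dense_units": list(self.config.dense_units),
                "dropout_rates": list(self.config.dropout_rates),
            },
            "classes": self.classes,
            "fitted": self.fitted,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "GenusClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        config = ModelConfig(
            n_classes=cfg["n_classes"],
            kernel_sizes=tuple(cfg["kernel_sizes"]),
            filters=cfg["filters"],
            recurrent_units=cfg["recurrent_units"],
            dense_units=tuple(cfg["dense_units"]),
            dropout_rates=tuple(cfg["dropout_rates"]),
        )
        model = cls(config)
        for k in model.params:
            model.params[k] = data[k]
        model.fitted = meta["fitted"]
        model.classes = meta["classes"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> GenusClassifier:
    """Instantiate the classifier with deterministic initial weights."""
    return GenusClassifier(config, seed=seed)


def train(
    model: GenusClassifier,
    batch: EncodedBatch,
    train_config: Optional[TrainConfig] = None,
) -> pd.DataFrame:
    """Fit the model; returns a per-epoch history (loss, accuracy).

    The data are shuffled every epoch; training stops at ``max_epochs`` or
    when the training loss has not decreased for ``patience`` consecutive
    epochs.  Every class must be present in the training data.
    """
    if train_config is None:
        train_config = TrainConfig()
    if batch.labels is None:
        raise ValueError("training batch must carry labels")
    present = set(np.unique(batch.labels).tolist())
    if present != set(range(model.config.n_classes)):
        missing = sorted(set(range(model.config.n_classes)) - present)
        raise ValueError(f"classes absent from training data: {missing}")

    rng = np.random.default_rng(train_config.seed)
    opt = _nn.Adam(model.params, lr=train_config.learning_rate)
    n = len(batch)
    history = []
    best_loss = np.inf
    stale = 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        total_correct = 0
        for i in range(0, n, train_config.batch_size):
            idx = order[i : i + train_config.batch_size]
            xb, mb, yb = batch.x[idx], batch.mask[idx], batch.labels[idx]
            logits, caches = model._forward(xb, mb, training=True, rng=rng)
            loss, dlogits = _nn.softmax_xent(logits, yb)
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            model._backward(dlogits, caches, grads)
            opt.step(model.params, grads)
            total_loss += loss * len(idx)
            total_correct += int((logits.argmax(axis=1) == yb).sum())
        epoch_loss = total_loss / n
        epoch_acc = total_correct / n
        history.append({"epoch": epoch, "loss": epoch_loss, "accuracy": epoch_acc})
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= train_config.patience:
                break
    model.fitted = True
    model.classes = batch.classes
    return pd.DataFrame(history)


def predict_genus(
    model: GenusClassifier, sequences: Sequence[str]
) -> pd.DataFrame:
    """Per-read (genus, probability) by softmax argmax (ties -> lowest index)."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    batch = encode(sequences)
    probs = model.predict_proba(batch.x, batch.mask)
    idx = probs.argmax(axis=1)
    classes = model.classes or [str(i) for i in range(model.config.n_classes)]
    return pd.DataFrame(
        {
            "genus": [classes[i] for i in idx],
            "probability": probs[np.arange(len(idx)), idx],
        }
    )


def evaluate_model(model: GenusClassifier, batch: EncodedBatch) -> dict:
    """Accuracy, macro F1 and macro one-vs-rest AUROC on a labeled batch."""
    if batch.labels is None:
        raise ValueError("evaluation batch must carry labels")
    probs = model.predict_proba(batch.x, batch.mask)
    pred = probs.argmax(axis=1)
    truth = batch.labels
    accuracy = float((pred == truth).mean())
    macro_f1 = float(f1_score(truth, pred, average="macro",
                              labels=np.arange(model.config.n_classes),
                              zero_division=0))
    if len(np.unique(truth)) < 2:
        auroc = None
    elif model.config.n_classes == 2:
        auroc = float(roc_auc_score(truth, probs[:, 1]))
    else:
        auroc = float(roc_auc_score(truth, probs, multi_class="ovr",
                                    average="macro",
                                    labels=np.arange(model.config.n_classes)))
    return {"accuracy": accuracy, "macro_f1": macro_f1, "auroc": auroc}
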