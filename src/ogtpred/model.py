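"""The convolutional optimal-temperature regressor.

Architecture (fixed topology, tunable widths):

    conv(kernel_size, n_neurons filters, relu) → maxpool(pool_size)
    → conv(kernel_size, n_neurons filters, relu) → maxpool(pool_size)
    → flatten → dense(n_neurons, relu) → dropout
    → dense(n_neurons, relu) → dropout → dense(1, linear)

Trained with Adam (AMSGRAD on) against mean squared error in °C, with
early stopping on validation loss and restoration of the best-validation
weights.  ``grid_search`` tunes kernel size and neuron count by validation
Pearson r.  Labels are regressed in °C directly; an optional z-scoring
switch exists for experimentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ogtpred import _nn
from ogtpred.corpus import ProteinRecord
from ogtpred.encoder import DEFAULT_L_MAX, encode_batch

CHECKPOINT_SCHEMA = "ogtpred-cnn-v1"

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "GridSearchResult",
    "build_model",
    "train",
    "grid_search",
    "min_input_length",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the regressor.

    ``n_neurons`` sets both the convolution filter count and the dense
    widths (a single width scalar is tuned).  Defaults follow the tuned
    optimum of kernel 18 / 256 neurons with dropout 0.3, at most 100
    epochs with batches of 32, Adam with AMSGRAD, pooling window 2,
    learning rate 1e-3 and early-stopping patience 5.
    """

    kernel_size: int = 18
    n_neurons: int = 256
    dropout_rate: float = 0.3
    max_epochs: int = 100
    batch_size: int = 32
    pool_size: int = 2
    learning_rate: float = 0.001
    amsgrad: bool = True
    early_stop_patience: int = 5
    normalise_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.pool_size < 1:
            raise ValueError(f"pool_size must be >= 1, got {self.pool_size}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")


def min_input_length(config: ModelConfig) -> int:
    """Smallest L_max the two conv+pool stages can consume."""
    # invert: L -> (L - k + 1) // pool, needs >= k after first stage, >= 1 after second
    need_after_pool1 = config.kernel_size  # so conv2 is applicable
    need_before_pool1 = need_after_pool1 * config.pool_size
    return need_before_pool1 + config.kernel_size - 1


def build_model(config: ModelConfig, l_max: int = DEFAULT_L_MAX) -> _nn.Sequential:
    """Instantiate the untrained network for inputs of shape (L_max, 20).

    Weight initialisation draws from a generator seeded with
    ``config.seed``, so two builds with the same config are identical.
    """
    if l_max < min_input_length(config):
        raise ValueError(
            f"l_max={l_max} too small for kernel {config.kernel_size} with "
            f"pool {config.pool_size}; need at least {min_input_length(config)}"
        )
    rng = np.random.default_rng(config.seed)
    f = config.n_neurons
    p1 = (l_max - config.kernel_size + 1) // config.pool_size
    p2 = (p1 - config.kernel_size + 1) // config.pool_size
    if p2 < 1:
        raise ValueError(
            f"l_max={l_max} leaves no positions after the second pooling; "
            f"need at least {min_input_length(config)}"
        )
    layers: list[_nn.Layer] = [
        _nn.Conv1D(20, f, config.kernel_size, rng),
        _nn.ReLU(),
        _nn.MaxPool1D(config.pool_size),
        _nn.Conv1D(f, f, config.kernel_size, rng),
        _nn.ReLU(),
        _nn.MaxPool1D(config.pool_size),
        _nn.Flatten(),
        _nn.Dense(p2 * f, f, rng),
        _nn.ReLU(),
        _nn.Dropout(config.dropout_rate, rng),
        _nn.Dense(f, f, rng),
        _nn.ReLU(),
        _nn.Dropout(config.dropout_rate, rng),
        _nn.Dense(f, 1, rng),
    ]
    return _nn.Sequential(layers)


@dataclass
class TrainedModel:
    """A trained regressor: config, weights, and its training history."""

    config: ModelConfig
    l_max: int
    weights: list[np.ndarray]
    training_history: pd.DataFrame
    stopped_epoch: int
    label_mean: float = 0.0
    label_sd: float = 1.0
    _net: _nn.Sequential | None = field(default=None, repr=False, compare=False)

    def _network(self) -> _nn.Sequential:
        if self._net is None:
            self._net = build_model(self.config, self.l_max)
        self._net.set_weights(self.weights)
        return self._net

    def predict(
        self, proteins: Sequence[ProteinRecord], chunk_size: int = 256
    ) -> np.ndarray:
        """Predicted optimal temperature (°C) per protein, input order.

        Dropout is inactive; batching does not change values.
        """
        if len(proteins) == 0:
            return np.zeros(0, dtype=np.float64)
        net = self._network()
        out = np.empty(len(proteins), dtype=np.float64)
        for start in range(0, len(proteins), chunk_size):
            chunk = proteins[start : start + chunk_size]
            x, _ = encode_batch(chunk, self.l_max)
            y = net.forward(x, train=False)[:, 0]
            out[start : start + len(chunk)] = y * self.label_sd + self.label_mean
        if not np.all(np.isfinite(out)):
            raise RuntimeError("model produced non-finite predictions")
        return out

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (compressed array container with an
        embedded schema tag and config)."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": asdict(self.config),
            "l_max": self.l_max,
            "stopped_epoch": self.stopped_epoch,
            "label_mean": self.label_mean,
            "label_sd": self.label_sd,
            "history": self.training_history.to_dict(orient="list"),
        }
        arrays = {f"w{i:03d}": w for i, w in enumerate(self.weights)}
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as payload:
            meta = json.loads(bytes(payload["meta"]).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(
                    f"checkpoint schema {meta.get('schema')!r} does not match "
                    f"{CHECKPOINT_SCHEMA!r}"
                )
            keys = sorted(k for k in payload.files if k.startswith("w"))
            weights = [payload[k] for k in keys]
        return cls(
            config=ModelConfig(**meta["config"]),
            l_max=int(meta["l_max"]),
            weights=weights,
            training_history=pd.DataFrame(meta["history"]),
            stopped_epoch=int(meta["stopped_epoch"]),
            label_mean=float(meta["label_mean"]),
            label_sd=float(meta["label_sd"]),
        )


def _labels_of(proteins: Sequence[ProteinRecord]) -> np.ndarray:
    labels = []
    for p in proteins:
        if p.label_celsius is None:
            raise ValueError(f"protein {p.protein_id!r} has no temperature label")
        labels.append(p.label_celsius)
    return np.asarray(labels, dtype=np.float32)


def train(
    train_proteins: Sequence[ProteinRecord],
    val_proteins: Sequence[ProteinRecord],
    config: ModelConfig | None = None,
    l_max: int = DEFAULT_L_MAX,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the regressor on labelled proteins.

    Minimises MSE (°C²) with Adam/AMSGRAD; stops when validation loss has
    not improved for ``early_stop_patience`` consecutive epochs or at
    ``max_epochs``, and restores the best-validation weights.  Training
    and validation sets must be non-empty and (by construction upstream)
    cluster-disjoint.
    """
    config = config or ModelConfig()
    if len(train_proteins) == 0 or len(val_proteins) == 0:
        raise ValueError("train and validation sets must be non-empty")

    net = build_model(config, l_max)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))

    x_train, _ = encode_batch(train_proteins, l_max)
    y_train = _labels_of(train_proteins)
    x_val, _ = encode_batch(val_proteins, l_max)
    y_val = _labels_of(val_proteins)

    if config.normalise_labels:
        mean, sd = float(y_train.mean()), float(y_train.std())
        sd = sd if sd > 0 else 1.0
    else:
        mean, sd = 0.0, 1.0
    yt = (y_train - mean) / sd
    yv = (y_val - mean) / sd

    optimiser = _nn.Adam(
        net.params(), learning_rate=config.learning_rate, amsgrad=config.amsgrad
    )

    def val_loss() -> float:
        preds = []
        for start in range(0, len(x_val), 512):
            preds.append(net.forward(x_val[start : start + 512], train=False)[:, 0])
        p = np.concatenate(preds)
        return float(np.mean((p - yv) ** 2))

    history: list[dict] = []
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    stale = 0
    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = net.forward(x_train[idx], train=True)
            loss, grad = _nn.mse_loss(pred, yt[idx, None])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting {start}); check learning rate and labels"
                )
            net.backward(grad)
            optimiser.step()
            batch_losses.append(loss)
        vloss = val_loss()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(batch_losses)), "val_loss": vloss}
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {history[-1]['train_loss']:9.3f}  val {vloss:9.3f}")
        if vloss < best_loss - 1e-7:
            best_loss = vloss
            best_weights = net.get_weights()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    return TrainedModel(
        config=config,
        l_max=l_max,
        weights=best_weights,
        training_history=pd.DataFrame(history),
        stopped_epoch=best_epoch,
        label_mean=mean,
        label_sd=sd,
        _net=net,
    )


@dataclass
class GridSearchResult:
    """All (kernel, neurons) pairs tried with their validation Pearson r,
    and the best config (ties → smaller kernel, then fewer neurons)."""

    tried: pd.DataFrame
    best: ModelConfig


def grid_search(
    kernel_candidates: Sequence[int],
    neuron_candidates: Sequence[int],
    train_proteins: Sequence[ProteinRecord],
    val_proteins: Sequence[ProteinRecord],
    template: ModelConfig | None = None,
    l_max: int = DEFAULT_L_MAX,
) -> GridSearchResult:
    """Train one model per (kernel_size, n_neurons) pair on the same split
    and score by validation Pearson r.

    A pair whose training fails is recorded with status ``failed`` and
    skipped; if every pair fails, an error is raised.
    """
    from ogtpred.evaluation import pearson_r  # local import to avoid cycle

    if not kernel_candidates or not neuron_candidates:
        raise ValueError("candidate lists must be non-empty")
    template = template or ModelConfig()
    rows = []
    y_val = _labels_of(val_proteins)
    for k in kernel_candidates:
        for m in neuron_candidates:
            cfg_kwargs = asdict(template)
            cfg_kwargs.update(kernel_size=int(k), n_neurons=int(m))
            cfg = ModelConfig(**cfg_kwargs)
            try:
                fitted = train(train_proteins, val_proteins, cfg, l_max)
                r = pearson_r(fitted.predict(val_proteins), y_val)
                rows.append(
                    {"kernel_size": k, "n_neurons": m, "validation_r": r, "status": "ok"}
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                rows.append(
                    {
                        "kernel_size": k,
                        "n_neurons": m,
                        "validation_r": np.nan,
                        "status": f"failed: {exc}",
                    }
                )
    tried = pd.DataFrame(rows, columns=["kernel_size", "n_neurons", "validation_r", "status"])
    ok = tried[tried.status == "ok"].dropna(subset=["validation_r"])
    if ok.empty:
        raise RuntimeError("grid search failed for every candidate pair")
    best_row = ok.sort_values(
        ["validation_r", "kernel_size", "n_neurons"], ascending=[False, True, True]
    ).iloc[0]
    best_kwargs = asdict(template)
    best_kwargs.update(
        kernel_size=int(best_row.kernel_size), n_neurons=int(best_row.n_neurons)
    )
    return GridSearchResult(tried=tried, best=ModelConfig(**best_kwargs))
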