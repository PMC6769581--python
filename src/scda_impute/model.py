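"""The sparse convolutional denoising autoencoder (SCDA) for genotype
imputation.

The model is a 1-D convolutional hourglass over one-hot genotype channels:
an encoder of same-padded convolutions interleaved with width-2 max-pooling,
a bottleneck, and a decoder with width-2 upsampling, ending in a softmax
over genotype classes at every marker. Missing genotypes enter as all-zero
channel vectors; training minimises the categorical cross-entropy between
the reconstruction and the *uncorrupted* target (the denoising setup), plus
an L1 penalty on every convolutional filter that drives most weights to
zero so the model stays identifiable when markers far outnumber samples.

Imputation is reconstruction: missing entries take the argmax class of the
softmax output while observed entries are passed through unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, ImputationResult, MaskIndex, one_hot
from .nn import Adam, Conv1D, Dropout, Layer, MaxPool1D, ReLU, Sigmoid, Upsample1D, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "SCDAConfig",
    "TrainConfig",
    "SCDAModel",
    "build_model",
    "l1_penalty",
    "reconstruction_loss",
    "train",
    "impute",
    "save_checkpoint",
    "load_checkpoint",
]

_DEPTH_KERNELS = {
    # hidden kernel counts; the final layer always has n_classes kernels
    "seven_layer": (32, 64, 128, 128, 64),
    "five_layer": (32, 64, 32),
}


@dataclass(frozen=True)
class SCDAConfig:
    """Architecture hyperparameters.

    ``kernel_counts`` lists the hidden convolution widths; the output layer
    always has ``n_classes`` kernels with softmax. ``None`` selects the
    default for ``depth_variant``: (32, 64, 128, 128, 64) for the
    seven-layer network (input layer + six convolutions) and (32, 64, 32)
    for the five-layer one.
    """

    kernel_counts: tuple[int, ...] | None = None
    filter_size: int = 5
    l1_lambda: float = 1e-4
    dropout_p: float = 0.25
    pool_size: int = 2
    hidden_activation: str = "relu"
    depth_variant: str = "seven_layer"

    def __post_init__(self) -> None:
        if self.filter_size % 2 == 0 or self.filter_size < 3:
            raise ValueError("filter_size must be odd and >= 3")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be >= 0")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.depth_variant not in _DEPTH_KERNELS:
            raise ValueError(f"unknown depth_variant {self.depth_variant!r}")
        if self.kernel_counts is not None and len(self.kernel_counts) == 0:
            raise ValueError("kernel_counts must be nonempty")
        if self.hidden_activation not in ("relu", "sigmoid"):
            raise ValueError("hidden_activation must be 'relu' or 'sigmoid'")

    @property
    def hidden_kernels(self) -> tuple[int, ...]:
        return (
            tuple(self.kernel_counts)
            if self.kernel_counts is not None
            else _DEPTH_KERNELS[self.depth_variant]
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters for :func:`train`."""

    batch_size: int = 32
    max_epochs: int = 1000
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


class SCDAModel:
    """A built network: layer stack, padding bookkeeping, training history."""

    def __init__(
        self,
        cfg: SCDAConfig,
        n_markers: int,
        n_classes: int,
        layers: list[Layer],
        pad_multiple: int,
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.n_markers = n_markers
        self.n_classes = n_classes
        self.layers = layers
        self.pad_multiple = pad_multiple
        self.rng = rng
        self.history: dict[str, list[float]] = {
            "train_loss": [],
            "val_loss": [],
            "val_accuracy": [],
        }

    @property
    def conv_layers(self) -> list[Conv1D]:
        return [l for l in self.layers if isinstance(l, Conv1D)]

    @property
    def padded_length(self) -> int:
        m = self.pad_multiple
        return ((self.n_markers + m - 1) // m) * m

    def n_parameters(self) -> int:
        return int(sum(p.size for l in self.conv_layers for p in l.params))

    def reseed(self, seed: int) -> None:
        """Reset the dropout RNG (shared by all dropout layers)."""
        new = np.random.default_rng(seed)
        self.rng.bit_generator.state = new.bit_generator.state

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        extra = self.padded_length - x.shape[1]
        if extra:
            x = np.pad(x, ((0, 0), (0, extra), (0, 0)))
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """One-hot input ``(B, n_markers, C)`` to logits of the same shape
        (internal pad to a pooling-compatible length, cropped on output)."""
        h = self._pad_input(x.astype(np.float32, copy=False))
        for layer in self.layers:
            h = layer.forward(h, training)
        return h[:, : self.n_markers, :]

    def backward(self, dlogits: np.ndarray) -> None:
        extra = self.padded_length - dlogits.shape[1]
        d = np.pad(dlogits, ((0, 0), (0, extra), (0, 0))) if extra else dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, gm: GenotypeMatrix, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities, shape ``(n_samples, n_markers, C)``."""
        if gm.n_classes != self.n_classes:
            raise ValueError("n_classes of input does not match model")
        x = one_hot(gm)
        out = np.empty_like(x)
        for lo in range(0, x.shape[0], batch_size):
            hi = min(lo + batch_size, x.shape[0])
            out[lo:hi] = softmax(self.forward_logits(x[lo:hi], training=False))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.conv_layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.conv_layers for p in l.params]
        for p, w in zip(flat, weights, strict=True):
            p[...] = w


def build_model(
    cfg: SCDAConfig, n_markers: int, n_classes: int, seed: int = 0
) -> SCDAModel:
    """Assemble the convolutional hourglass for a given marker count.

    Seven-layer variant: conv(32) → pool → conv(64) → pool → conv(128) →
    conv(128) → upsample → conv(64) → upsample → conv(C, softmax), with
    dropout after each pooling stage. Five-layer variant: conv(32) → pool →
    conv(64) → conv(32) → upsample → conv(C, softmax). All convolutions are
    same-padded with the configured filter size and carry the L1 penalty.
    Input lengths that are not a multiple of the total pooling factor are
    zero-padded internally and cropped on output.
    """
    n_pools = 2 if cfg.depth_variant == "seven_layer" else 1
    pad_multiple = cfg.pool_size**n_pools
    if n_markers < pad_multiple:
        raise ValueError(f"need at least {pad_multiple} markers")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 1)
    act = ReLU if cfg.hidden_activation == "relu" else Sigmoid
    k = cfg.filter_size
    hidden = cfg.hidden_kernels
    layers: list[Layer] = []

    def conv(cin: int, cout: int, with_act: bool = True) -> int:
        layers.append(Conv1D(cin, cout, k, rng))
        if with_act:
            layers.append(act())
        return cout

    if cfg.depth_variant == "seven_layer":
        if len(hidden) != 5:
            raise ValueError("seven_layer needs 5 hidden kernel counts")
        c = conv(n_classes, hidden[0])
        layers.append(MaxPool1D(cfg.pool_size))
        layers.append(Dropout(cfg.dropout_p, drop_rng))
        c = conv(c, hidden[1])
        layers.append(MaxPool1D(cfg.pool_size))
        layers.append(Dropout(cfg.dropout_p, drop_rng))
        c = conv(c, hidden[2])
        c = conv(c, hidden[3])
        layers.append(Upsample1D(cfg.pool_size))
        c = conv(c, hidden[4])
        layers.append(Upsample1D(cfg.pool_size))
        conv(c, n_classes, with_act=False)
    else:
        if len(hidden) != 3:
            raise ValueError("five_layer needs 3 hidden kernel counts")
        c = conv(n_classes, hidden[0])
        layers.append(MaxPool1D(cfg.pool_size))
        layers.append(Dropout(cfg.dropout_p, drop_rng))
        c = conv(c, hidden[1])
        c = conv(c, hidden[2])
        layers.append(Upsample1D(cfg.pool_size))
        conv(c, n_classes, with_act=False)

    return SCDAModel(cfg, n_markers, n_classes, layers, pad_multiple, drop_rng)


def l1_penalty(model: SCDAModel, lam: float) -> float:
    """L1 filter-weight penalty ``lam * sum_m |F_m|_1`` (biases excluded)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(lam * sum(np.abs(l.W).sum() for l in model.conv_layers))


def reconstruction_loss(probabilities: np.ndarray, target: GenotypeMatrix) -> float:
    """Mean categorical cross-entropy over non-missing target entries.

    ``-log p[target class]`` averaged over entries whose target class is
    non-zero; probabilities below 1e-12 are clipped before the log.
    """
    v = target.values
    obs = v > 0
    if not obs.any():
        raise ValueError("target has no observed entries")
    i, j = np.nonzero(obs)
    p = probabilities[i, j, v[i, j] - 1]
    if (p <= 0).any():
        logger.warning("clipping %d nonpositive probabilities", int((p <= 0).sum()))
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


def _epoch_loss_and_acc(
    model: SCDAModel,
    x: np.ndarray,
    y_class: np.ndarray,
    score_mask: np.ndarray | None,
    batch_size: int,
) -> tuple[float, float]:
    """Cross-entropy over non-missing targets plus current L1 penalty;
    accuracy over ``score_mask`` entries (NaN if the mask is empty)."""
    total_nll = 0.0
    total_n = 0
    correct = 0
    scored = 0
    for lo in range(0, x.shape[0], batch_size):
        hi = min(lo + batch_size, x.shape[0])
        p = softmax(model.forward_logits(x[lo:hi], training=False))
        yb = y_class[lo:hi]
        obs = yb > 0
        i, j = np.nonzero(obs)
        pc = np.clip(p[i, j, yb[i, j] - 1], 1e-12, None)
        total_nll += float(-np.log(pc).sum())
        total_n += len(i)
        if score_mask is not None:
            sm = score_mask[lo:hi]
            si, sj = np.nonzero(sm)
            if len(si):
                pred = p[si, sj].argmax(axis=1) + 1
                correct += int((pred == yb[si, sj]).sum())
                scored += len(si)
    nll = total_nll / max(total_n, 1)
    acc = correct / scored if scored else float("nan")
    return nll + l1_penalty(model, model.cfg.l1_lambda), acc


def train(
    model: SCDAModel,
    train_set: tuple[GenotypeMatrix, GenotypeMatrix],
    val_set: tuple[GenotypeMatrix, GenotypeMatrix],
    tcfg: TrainConfig,
) -> SCDAModel:
    """Fit the denoising autoencoder.

    ``train_set`` and ``val_set`` are ``(corrupted, target)`` pairs sharing
    shape. Minimises mean cross-entropy over non-missing target entries
    plus the L1 filter penalty, with Adam minibatches, early stopping on
    validation loss, and restoration of the best-validation weights.
    """
    corr_tr, tgt_tr = train_set
    corr_va, tgt_va = val_set
    if corr_tr.values.shape != tgt_tr.values.shape:
        raise ValueError("corrupted and target training matrices differ in shape")
    if corr_va.values.shape != tgt_va.values.shape:
        raise ValueError("corrupted and target validation matrices differ in shape")

    x_tr = one_hot(corr_tr)
    y_tr = tgt_tr.values
    x_va = one_hot(corr_va)
    y_va = tgt_va.values
    # validation accuracy is scored on entries hidden in the corrupted copy
    va_masked = (corr_va.values == 0) & (y_va > 0)

    model.reseed(tcfg.seed + 1)
    rng = np.random.default_rng(tcfg.seed)
    params = [p for l in model.conv_layers for p in l.params]
    opt = Adam(params, lr=tcfg.learning_rate)
    lam = model.cfg.l1_lambda

    best_val = np.inf
    best_weights = model.get_weights()
    patience_left = tcfg.early_stop_patience
    n = x_tr.shape[0]

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        epoch_nll = 0.0
        epoch_cnt = 0
        for lo in range(0, n, tcfg.batch_size):
            idx = order[lo : lo + tcfg.batch_size]
            xb = x_tr[idx]
            yb = y_tr[idx]
            logits = model.forward_logits(xb, training=True)
            p = softmax(logits)
            obs = yb > 0
            cnt = int(obs.sum())
            if cnt == 0:
                continue
            i, j = np.nonzero(obs)
            pc = np.clip(p[i, j, yb[i, j] - 1], 1e-12, None)
            nll = float(-np.log(pc).sum())
            if not np.isfinite(nll):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {nll}"
                )
            epoch_nll += nll
            epoch_cnt += cnt
            dlogits = p
            dlogits[i, j, yb[i, j] - 1] -= 1.0
            dlogits *= obs[:, :, None].astype(p.dtype) / cnt
            model.backward(dlogits)
            grads = []
            for layer in model.conv_layers:
                gW, gb = layer.grads
                if lam:
                    gW = gW + lam * np.sign(layer.W)
                grads.extend([gW, gb])
            opt.step(grads)

        train_loss = epoch_nll / max(epoch_cnt, 1) + l1_penalty(model, lam)
        val_loss, val_acc = _epoch_loss_and_acc(
            model, x_va, y_va, va_masked, max(tcfg.batch_size, 64)
        )
        model.history["train_loss"].append(train_loss)
        model.history["val_loss"].append(val_loss)
        model.history["val_accuracy"].append(val_acc)
        logger.info(
            "epoch %d train_loss=%.5f val_loss=%.5f val_masked_acc=%.4f",
            epoch,
            train_loss,
            val_loss,
            val_acc,
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = model.get_weights()
            patience_left = tcfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stop at epoch %d", epoch)
                break

    model.set_weights(best_weights)
    return model


def impute(
    model: SCDAModel, corrupted: GenotypeMatrix, mask: MaskIndex | None = None
) -> ImputationResult:
    """Complete a corrupted matrix by reconstruction.

    Observed entries are kept unchanged; each missing entry takes the
    argmax class of the softmax output (ties toward the lowest class
    index).
    """
    if corrupted.n_classes != model.n_classes:
        raise ValueError("n_classes mismatch between input and model")
    if corrupted.n_markers != model.n_markers:
        raise ValueError(
            f"model was built for {model.n_markers} markers, "
            f"got {corrupted.n_markers}"
        )
    proba = model.predict_proba(corrupted)
    completed = corrupted.copy()
    miss = corrupted.values == 0
    if miss.any():
        i, j = np.nonzero(miss)
        completed.values[i, j] = proba[i, j].argmax(axis=1) + 1
    return ImputationResult(completed, probabilities=proba, mask_used=mask)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SCDAModel, path: str | Path) -> None:
    """Serialize architecture, weights and training history to ``.npz``."""
    meta = {
        "cfg": asdict(model.cfg),
        "n_markers": model.n_markers,
        "n_classes": model.n_classes,
        "history": model.history,
    }
    arrays = {
        f"w{i}": w for i, w in enumerate(model.get_weights())
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> SCDAModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_d = meta["cfg"]
        if cfg_d.get("kernel_counts") is not None:
            cfg_d["kernel_counts"] = tuple(cfg_d["kernel_counts"])
        cfg = SCDAConfig(**cfg_d)
        model = build_model(cfg, meta["n_markers"], meta["n_classes"])
        weights = [data[f"w{i}"] for i in range(len(model.get_weights()))]
    model.set_weights(weights)
    model.history = meta["history"]
    return model
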