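"""Eye-state image classification: open/half-open vs. closed.

Eye-region crops are down-sampled to 51x51 grayscale rasters (2601 pixels),
flattened row-major, and classified by one of two small networks:

* ``MLP_1H`` — a feed-forward network with 2601 inputs, one hidden layer of
  10 sigmoid units and a 2-way softmax output, trained full-batch on the
  cross-entropy objective;
* ``STACKED_AE`` — a stacked autoencoder: a first autoencoder is trained to
  reconstruct the pixels through a 100-unit sigmoid code, a second
  autoencoder compresses those codes through 50 units, a softmax head is
  trained on the second-level codes, and the assembled 2601-100-50-2 network
  is fine-tuned end-to-end.

Training uses deterministic full-batch L-BFGS from a seeded initialisation,
so a (data, seed, hyperparameter) triple always reproduces the identical
model.  The module also provides the per-frame "FR" (face recognition)
channel score consumed by the fuzzy fusion stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import optimize
from skimage import transform

__all__ = [
    "EyeLabel",
    "EyeImage",
    "EyeStateModel",
    "ConfusionMatrix",
    "preprocess_image",
    "flatten_row_major",
    "train_mlp",
    "train_stacked_autoencoder",
    "classify_eye_state",
    "evaluate",
    "fr_channel_score",
    "load_image",
    "save_image",
]

TARGET_SHAPE = (51, 51)
N_PIXELS = TARGET_SHAPE[0] * TARGET_SHAPE[1]  # 2601
MLP_HIDDEN = 10
SAE_HIDDEN = (100, 50)
MAX_EPOCHS = 500
LOSS_TOL = 1e-5


class EyeLabel(str, Enum):
    OPEN_OR_HALF = "OPEN_OR_HALF"
    CLOSED = "CLOSED"


class Variant(str, Enum):
    MLP_1H = "MLP_1H"
    STACKED_AE = "STACKED_AE"


#: Output-unit order: index 0 = OPEN_OR_HALF, index 1 = CLOSED.
LABEL_ORDER = (EyeLabel.OPEN_OR_HALF, EyeLabel.CLOSED)


@dataclass
class EyeImage:
    """51x51 grayscale raster with intensities in [0, 1]."""

    raster: np.ndarray
    label: EyeLabel | None = None
    source_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.raster.size and (
            self.raster.min() < -1e-9 or self.raster.max() > 1 + 1e-9
        ):
            raise ValueError("intensities must lie in [0, 1]")


def preprocess_image(
    raw: np.ndarray,
    crop_box: tuple[int, int, int, int] | None = None,
    target: tuple[int, int] = TARGET_SHAPE,
) -> EyeImage:
    """Crop, anti-aliased down-sample to ``target`` and rescale to [0, 1].

    ``crop_box`` is (row0, col0, row1, col1), half-open.  Integer rasters are
    rescaled by their dtype maximum; float rasters with values above 1 by
    their own maximum; float rasters already in [0, 1] are left untouched
    (so a constant image keeps its value).  Upsampling is refused: the
    source (after cropping) must be at least as large as the target in both
    dimensions.
    """
    a = np.asarray(raw)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("raw raster must be a nonempty 2-D array")
    source_size = a.shape
    if crop_box is not None:
        r0, c0, r1, c1 = crop_box
        if not (0 <= r0 < r1 <= a.shape[0] and 0 <= c0 < c1 <= a.shape[1]):
            raise ValueError(f"crop_box {crop_box} outside raster bounds {a.shape}")
        a = a[r0:r1, c0:c1]
    if a.shape[0] < target[0] or a.shape[1] < target[1]:
        raise ValueError(
            f"refusing to upsample: source {a.shape} smaller than target {target}"
        )
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(float) / np.iinfo(raw.dtype).max
    else:
        a = a.astype(float)
        if a.max() > 1.0:
            a = a / a.max()
        a = np.clip(a, 0.0, 1.0)
    if a.shape != target:
        a = transform.resize(
            a, target, order=1, anti_aliasing=True, preserve_range=True
        )
        a = np.clip(a, 0.0, 1.0)
    return EyeImage(raster=a, source_size=source_size)


def flatten_row_major(img: EyeImage | np.ndarray, strict: bool = True) -> np.ndarray:
    """Raster read row by row into a length-2601 vector (when 51x51)."""
    raster = img.raster if isinstance(img, EyeImage) else np.asarray(img)
    if strict and raster.shape != TARGET_SHAPE:
        raise ValueError(f"expected {TARGET_SHAPE} raster, got {raster.shape}")
    return raster.reshape(-1, order="C").astype(float)


# ---------------------------------------------------------------------------
# Network internals: parameter packing, forward/backward passes


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_layers(widths: Sequence[int], rng: np.random.Generator):
    """Glorot-uniform weights, zero biases."""
    layers = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        lim = np.sqrt(6.0 / (n_in + n_out))
        layers.append(
            (rng.uniform(-lim, lim, size=(n_in, n_out)), np.zeros(n_out))
        )
    return layers


def _pack(layers) -> np.ndarray:
    return np.concatenate([p.ravel() for W, b in layers for p in (W, b)])


def _unpack(theta: np.ndarray, widths: Sequence[int]):
    layers, k = [], 0
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        W = theta[k : k + n_in * n_out].reshape(n_in, n_out)
        k += n_in * n_out
        b = theta[k : k + n_out]
        k += n_out
        layers.append((W, b))
    return layers


def _forward(layers, X, hidden="sigmoid", output="softmax"):
    """Activations per layer; hidden layers share one activation."""
    acts = [X]
    for i, (W, b) in enumerate(layers):
        z = acts[-1] @ W + b
        last = i == len(layers) - 1
        kind = output if last else hidden
        if kind == "sigmoid":
            acts.append(_sigmoid(z))
        elif kind == "softmax":
            acts.append(_softmax(z))
        elif kind == "linear":
            acts.append(z)
        else:  # pragma: no cover
            raise ValueError(kind)
    return acts


def _loss_grad(theta, widths, X, T, hidden, output, loss, l2):
    """Objective value and flat gradient for full-batch training.

    ``loss`` is "xent" (with softmax output) or "mse" (with linear output);
    both pair with a delta of (prediction - target) at the top layer.
    """
    layers = _unpack(theta, widths)
    acts = _forward(layers, X, hidden, output)
    Y = acts[-1]
    n = X.shape[0]
    if loss == "xent":
        eps = 1e-12
        value = -np.sum(T * np.log(Y + eps)) / n
    else:
        value = 0.5 * np.sum((Y - T) ** 2) / n
    delta = (Y - T) / n
    grads = []
    for i in range(len(layers) - 1, -1, -1):
        W, _ = layers[i]
        A = acts[i]
        gW = A.T @ delta
        gb = delta.sum(axis=0)
        grads.append((gW, gb))
        if i > 0:
            delta = (delta @ W.T) * acts[i] * (1.0 - acts[i])  # sigmoid'
    grads.reverse()
    if l2 > 0:
        value += 0.5 * l2 * sum(np.sum(W**2) for W, _ in layers)
        grads = [(gW + l2 * W, gb) for (gW, gb), (W, _) in zip(grads, layers)]
    return value, _pack(grads)


def _train(widths, X, T, seed, hidden, output, loss, l2=0.0, maxiter=MAX_EPOCHS):
    rng = np.random.default_rng(seed)
    theta0 = _pack(_init_layers(widths, rng))
    res = optimize.minimize(
        _loss_grad,
        theta0,
        args=(widths, X, T, hidden, output, loss, l2),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": maxiter, "ftol": LOSS_TOL, "gtol": 1e-8},
    )
    return _unpack(res.x, widths), float(res.fun)


# ---------------------------------------------------------------------------
# Public model object


@dataclass
class ConfusionMatrix:
    """2x2 actual-class (rows) x predicted-class (columns) counts.

    Row/column order follows ``LABEL_ORDER`` (open/half first, closed
    second); the diagonal counts correct classifications.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    @property
    def n_errors(self) -> int:
        return self.total - int(np.trace(self.counts))

    def to_csv(self, path) -> None:
        names = [l.value for l in LABEL_ORDER]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df.index.name = "actual\\predicted"
        df.to_csv(path)


@dataclass
class EyeStateModel:
    """A trained eye-state classifier (either network variant).

    ``layers`` holds (weights, bias) per layer from input to output; the
    forward pass applies sigmoid activations at hidden layers and softmax at
    the 2-way output, so the two class scores always sum to one.
    """

    variant: Variant
    widths: tuple[int, ...]
    layers: list
    training_seed: int
    final_loss: float
    history: dict = field(default_factory=dict)

    @property
    def architecture(self) -> tuple[int, ...]:
        return self.widths

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.widths[0]:
            raise ValueError(
                f"input width {X.shape[1]} != model input width {self.widths[0]}"
            )
        return _forward(self.layers, X)[-1]

    def predict(self, imgs: Sequence[EyeImage]) -> list[EyeLabel]:
        X = np.stack([flatten_row_major(im) for im in imgs])
        idx = np.argmax(self.predict_scores(X), axis=1)
        return [LABEL_ORDER[i] for i in idx]

    def summary(self) -> str:
        lines = [
            f"EyeStateModel ({self.variant.value})",
            f"  architecture : {'-'.join(map(str, self.widths))}",
            f"  parameters   : {sum(W.size + b.size for W, b in self.layers)}",
            f"  seed         : {self.training_seed}",
            f"  final loss   : {self.final_loss:.6g}",
        ]
        return "\n".join(lines)

    # -- serialization: JSON metadata + npz weights -------------------------

    def save(self, meta_path, weights_path) -> None:
        meta = {
            "variant": self.variant.value,
            "widths": list(self.widths),
            "training_seed": self.training_seed,
            "final_loss": self.final_loss,
            "weights_file": str(weights_path),
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)
        arrays = {}
        for i, (W, b) in enumerate(self.layers):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(weights_path, **arrays)

    @classmethod
    def load(cls, meta_path) -> "EyeStateModel":
        with open(meta_path) as fh:
            meta = json.load(fh)
        data = np.load(meta["weights_file"])
        n_layers = len(meta["widths"]) - 1
        layers = [(data[f"W{i}"], data[f"b{i}"]) for i in range(n_layers)]
        return cls(
            Variant(meta["variant"]),
            tuple(meta["widths"]),
            layers,
            meta["training_seed"],
            meta["final_loss"],
        )


def _design_matrices(train_set: Sequence[EyeImage]):
    if not train_set:
        raise ValueError("empty training set")
    labels = [im.label for im in train_set]
    if any(l is None for l in labels):
        raise ValueError("all training images must be labeled")
    present = set(labels)
    if len(present) < 2:
        raise ValueError("training set must contain both classes")
    for lab in LABEL_ORDER:
        if labels.count(lab) < 2:
            raise ValueError(f"need >= 2 samples of class {lab.value}")
    X = np.stack([flatten_row_major(im) for im in train_set])
    T = np.zeros((len(train_set), 2))
    for i, lab in enumerate(labels):
        T[i, LABEL_ORDER.index(lab)] = 1.0
    return X, T


def train_mlp(
    train_set: Sequence[EyeImage],
    seed: int = 0,
    hidden: int = MLP_HIDDEN,
    l2: float = 1e-4,
    maxiter: int = MAX_EPOCHS,
) -> EyeStateModel:
    """Train the 2601-10-2 feed-forward classifier.

    Full-batch L-BFGS on the cross-entropy objective with a small L2
    penalty; sigmoid hidden units, softmax output.  Deterministic for a
    fixed (data, seed, hyperparameters) triple.
    """
    X, T = _design_matrices(train_set)
    widths = (X.shape[1], hidden, 2)
    layers, loss = _train(widths, X, T, seed, "sigmoid", "softmax", "xent", l2, maxiter)
    return EyeStateModel(Variant.MLP_1H, widths, layers, seed, loss)


def train_stacked_autoencoder(
    train_set: Sequence[EyeImage],
    seed: int = 0,
    hidden: tuple[int, int] = SAE_HIDDEN,
    l2: float = 1e-4,
    pretrain_iter: int = 60,
    finetune_iter: int = 200,
) -> EyeStateModel:
    """Greedy layer-wise autoencoder pretraining, then end-to-end fine-tune.

    Stage 1 trains a 2601-h1-2601 autoencoder on the pixels; stage 2 trains
    an h1-h2-h1 autoencoder on the first-level codes; stage 3 trains a
    softmax head on the second-level codes; stage 4 fine-tunes the assembled
    2601-h1-h2-2 network on the labels.  The stage-1/2 reconstruction losses
    before and after training are recorded in ``history``.
    """
    X, T = _design_matrices(train_set)
    h1, h2 = hidden
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)

    def _ae(Xin, code_width, s):
        widths = (Xin.shape[1], code_width, Xin.shape[1])
        init = _init_layers(widths, np.random.default_rng(s))
        loss_before, _ = _loss_grad(
            _pack(init), widths, Xin, Xin, "sigmoid", "linear", "mse", 0.0
        )
        layers, loss_after = _train(
            widths, Xin, Xin, s, "sigmoid", "linear", "mse", l2, pretrain_iter
        )
        codes = _sigmoid(Xin @ layers[0][0] + layers[0][1])
        return layers[0], codes, loss_before, loss_after

    enc1, codes1, ae1_before, ae1_after = _ae(X, h1, int(sub_seeds[0]))
    enc2, codes2, ae2_before, ae2_after = _ae(codes1, h2, int(sub_seeds[1]))
    head_widths = (h2, 2)
    head, _ = _train(
        head_widths, codes2, T, int(sub_seeds[2]), "sigmoid", "softmax", "xent", l2,
        pretrain_iter,
    )

    # assemble and fine-tune end-to-end
    widths = (X.shape[1], h1, h2, 2)
    theta0 = _pack([enc1, enc2, head[0]])
    res = optimize.minimize(
        _loss_grad,
        theta0,
        args=(widths, X, T, "sigmoid", "softmax", "xent", l2),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": finetune_iter, "ftol": LOSS_TOL, "gtol": 1e-8},
    )
    history = {
        "ae1_loss_before": ae1_before,
        "ae1_loss_after": ae1_after,
        "ae2_loss_before": ae2_before,
        "ae2_loss_after": ae2_after,
    }
    return EyeStateModel(
        Variant.STACKED_AE, widths, _unpack(res.x, widths), seed, float(res.fun),
        history,
    )


def classify_eye_state(model: EyeStateModel, img: EyeImage) -> dict:
    """Label and normalised confidence for one 51x51 image."""
    if img.raster.shape != TARGET_SHAPE:
        raise ValueError(f"raster must be {TARGET_SHAPE}, got {img.raster.shape}")
    scores = model.predict_scores(flatten_row_major(img))[0]
    i = int(np.argmax(scores))
    return {"label": LABEL_ORDER[i], "confidence": float(scores[i])}


def evaluate(model: EyeStateModel, test_set: Sequence[EyeImage]) -> ConfusionMatrix:
    """Confusion matrix of the model on a labeled test set."""
    if not test_set:
        raise ValueError("empty test set")
    if any(im.label is None for im in test_set):
        raise ValueError("all test images must be labeled")
    preds = model.predict(test_set)
    counts = np.zeros((2, 2), dtype=int)
    for im, pred in zip(test_set, preds):
        counts[LABEL_ORDER.index(im.label), LABEL_ORDER.index(pred)] += 1
    return ConfusionMatrix(counts)


def fr_channel_score(labels: Sequence[EyeLabel]) -> float:
    """Fraction of frames predicted open/half-open within a window.

    This is the unit-interval "FR" (face recognition) input of the fuzzy
    fusion stage: 1 = eyes open throughout, 0 = closed throughout.
    """
    if len(labels) == 0:
        raise ValueError("empty window")
    return float(np.mean([l is EyeLabel.OPEN_OR_HALF for l in labels]))


# ---------------------------------------------------------------------------
# Image / manifest I/O


def load_image(path) -> np.ndarray:
    """Grayscale raster from a PNG/PGM file (uint8)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def save_image(path, raster: np.ndarray) -> None:
    """Write a [0, 1] float raster as 8-bit PNG/PGM."""
    a = np.clip(np.asarray(raster, dtype=float), 0.0, 1.0)
    Image.fromarray((a * 255).round().astype(np.uint8)).save(path)


def read_manifest(path) -> list[tuple[str, EyeLabel]]:
    """Corpus manifest CSV with columns path,label."""
    df = pd.read_csv(path)
    return [(r["path"], EyeLabel(r["label"])) for _, r in df.iterrows()]


def write_manifest(path, entries: Sequence[tuple[str, EyeLabel]]) -> None:
    pd.DataFrame(
        [{"path": p, "label": l.value} for p, l in entries]
    ).to_csv(path, index=False)
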