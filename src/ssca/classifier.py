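"""Feed-forward H/E/C classifier: definition, SGD training, persistence, inference.

The network is a small multilayer perceptron: feature rows are z-scored with
statistics taken from the training split, passed through sigmoid hidden
layers (default 128 x 128) and a 3-way softmax output. Training minimizes
categorical cross-entropy with plain mini-batch stochastic gradient descent.
The model file is a versioned JSON document carrying the weights together
with the feature configuration (window length, feature blocks, CG-hbond
criteria, normalization statistics), so inference always recomputes features
exactly as they were computed at training time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

from .errors import DegenerateTrainingError, ModelFileError, SscaError
from .geometry import WindowConfig, featurize_chain
from .hbond import HbondCriteria, hbond_counts
from .structure_io import CaTrace, SSAssignment, detect_chain_breaks

CLASS_ORDER = "HEC"
MODEL_FORMAT = "ssca-mlp"
MODEL_VERSION = 1


@dataclass(frozen=True)
class NetworkLayout:
    """Layer widths: input, hidden stack, 3-way output."""

    input_width: int
    hidden: tuple[int, ...] = (128, 128)
    output_width: int = 3

    def __post_init__(self):
        if self.input_width < 1 or not self.hidden or any(h < 1 for h in self.hidden):
            raise SscaError("invalid network layout")
        if self.output_width != 3:
            raise SscaError("output layer must have 3 neurons (H, E, C)")
        object.__setattr__(self, "hidden", tuple(self.hidden))

    @property
    def widths(self) -> tuple[int, ...]:
        return (self.input_width, *self.hidden, self.output_width)


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters. Defaults follow the published training protocol."""

    learning_rate: float = 0.01
    epochs: int = 3500
    batch_size: int = 32
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise SscaError("invalid training configuration")
        if not (0 < self.train_fraction < 1):
            raise SscaError("train_fraction must lie in (0, 1)")


@dataclass
class MLPModel:
    """Weights plus everything needed to reproduce the input features."""

    layout: NetworkLayout
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    window_config: WindowConfig
    hbond_criteria: HbondCriteria = field(default_factory=HbondCriteria)

    def copy(self) -> "MLPModel":
        return MLPModel(
            layout=self.layout,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            feature_mean=self.feature_mean.copy(),
            feature_std=self.feature_std.copy(),
            window_config=self.window_config,
            hbond_criteria=self.hbond_criteria,
        )


@dataclass(frozen=True)
class TrainResult:
    model: MLPModel
    loss_history: np.ndarray
    train_indices: np.ndarray
    val_indices: np.ndarray


def init_mlp(
    layout: NetworkLayout,
    seed: int,
    window_config: WindowConfig | None = None,
    hbond_criteria: HbondCriteria = HbondCriteria(),
) -> MLPModel:
    """Fresh model with symmetric scaled-uniform (Glorot) weights; deterministic per seed."""
    if window_config is None:
        window_config = WindowConfig()
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    widths = layout.widths
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(
        layout=layout,
        weights=weights,
        biases=biases,
        feature_mean=np.zeros(layout.input_width),
        feature_std=np.ones(layout.input_width),
        window_config=window_config,
        hbond_criteria=hbond_criteria,
    )


def _forward_pass(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, starting from the standardized input."""
    a = (X - model.feature_mean) / model.feature_std
    acts = [a]
    last = len(model.weights) - 1
    for k, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = acts[-1] @ W + b
        acts.append(softmax(z, axis=1) if k == last else expit(z))
    return acts


def forward(model: MLPModel, features) -> np.ndarray:
    """Class probabilities (pH, pE, pC) for one feature vector or a matrix of them."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.layout.input_width:
        raise SscaError(
            f"feature dimension error: expected {model.layout.input_width}, got {X.shape[1]}"
        )
    probs = _forward_pass(model, X)[-1]
    return probs[0] if single else probs


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(np.sum(probs * onehot, axis=1), 1e-12, None)
    return float(-np.mean(np.log(p)))


def _labels_to_indices(y) -> np.ndarray:
    lut = {c: k for k, c in enumerate(CLASS_ORDER)}
    try:
        return np.array([lut[label] for label in y], dtype=int)
    except KeyError as e:
        raise SscaError(f"unknown class label {e.args[0]!r}") from None


def loss_and_gradients(model: MLPModel, X: np.ndarray, onehot: np.ndarray):
    """Cross-entropy loss and its analytic gradients for one batch."""
    acts = _forward_pass(model, X)
    probs = acts[-1]
    B = X.shape[0]
    delta = (probs - onehot) / B  # softmax + CCE
    grads_W, grads_b = [], []
    for k in range(len(model.weights) - 1, -1, -1):
        grads_W.append(acts[k].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if k > 0:
            a = acts[k]
            delta = (delta @ model.weights[k].T) * a * (1.0 - a)  # sigmoid'
    grads_W.reverse()
    grads_b.reverse()
    return cross_entropy(probs, onehot), grads_W, grads_b


def train(
    model: MLPModel,
    X: np.ndarray,
    y,
    cfg: TrainConfig,
    groups=None,
) -> TrainResult:
    """Mini-batch SGD on categorical cross-entropy.

    Splits the rows into train/validation parts (``cfg.train_fraction``,
    seeded). When ``groups`` is given (one hashable per row, e.g. a chain
    identifier) the split is performed over groups so correlated windows of
    one chain never straddle it. Standardization statistics are computed on
    the training rows only and stored in the returned model. Deterministic
    for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    yi = _labels_to_indices(y)
    if X.shape[0] != yi.shape[0]:
        raise SscaError("X and y disagree in length")
    if np.unique(yi).size < 2:
        raise DegenerateTrainingError("degenerate training set: fewer than two classes")

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    if groups is None:
        perm = rng.permutation(n)
        n_train = max(1, int(round(cfg.train_fraction * n)))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
    else:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise SscaError("groups not aligned to X")
        uniq = np.unique(groups)
        gperm = uniq[rng.permutation(uniq.size)]
        n_gtrain = max(1, int(round(cfg.train_fraction * uniq.size)))
        train_groups = set(gperm[:n_gtrain].tolist())
        mask = np.array([g in train_groups for g in groups])
        train_idx, val_idx = np.nonzero(mask)[0], np.nonzero(~mask)[0]
    if np.unique(yi[train_idx]).size < 2:
        raise DegenerateTrainingError("degenerate training split: fewer than two classes")

    mean = X[train_idx].mean(axis=0)
    std = X[train_idx].std(axis=0)
    std[std == 0] = 1.0

    trained = model.copy()
    trained.feature_mean = mean
    trained.feature_std = std

    onehot = np.eye(3)[yi]
    Xt, Yt = X[train_idx], onehot[train_idx]
    history = np.empty(cfg.epochs)
    lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        order = rng.permutation(Xt.shape[0])
        losses, sizes = [], []
        for s in range(0, Xt.shape[0], cfg.batch_size):
            batch = order[s : s + cfg.batch_size]
            loss, gW, gb = loss_and_gradients(trained, Xt[batch], Yt[batch])
            for W, b, dW, db in zip(trained.weights, trained.biases, gW, gb):
                W -= lr * dW
                b -= lr * db
            losses.append(loss * batch.size)
            sizes.append(batch.size)
        history[epoch] = float(np.sum(losses) / np.sum(sizes))
    return TrainResult(
        model=trained,
        loss_history=history,
        train_indices=train_idx,
        val_indices=val_idx,
    )


def predict_labels(model: MLPModel, X: np.ndarray) -> str:
    """Argmax labels for a feature matrix; ties resolve H > E > C."""
    probs = forward(model, np.atleast_2d(X))
    return "".join(CLASS_ORDER[k] for k in np.argmax(probs, axis=1))


def predict_chain(model: MLPModel, trace: CaTrace) -> SSAssignment:
    """Assign H/E/C to every residue of a trace.

    Features are recomputed with the window configuration and CG-hbond
    criteria stored in the model. Residues without a complete window — the
    (N-1)/2 at each terminus and residues whose window spans a chain break —
    are assigned 'C' with probabilities (0, 0, 1). Equal probabilities break
    toward H > E > C.
    """
    L = len(trace)
    N = model.window_config.n
    labels = np.full(L, "C")
    probs = np.zeros((L, 3))
    probs[:, 2] = 1.0
    if L < N:
        warnings.warn(f"trace of length {L} shorter than window {N}: all-coil assignment")
        return SSAssignment("".join(labels), probs)

    breaks = detect_chain_breaks(trace) if L >= 2 else []
    hb = (
        hbond_counts(trace, model.hbond_criteria)
        if "hbonds" in model.window_config.feature_set and L >= 3
        else None
    )
    X, centers = featurize_chain(trace, hb, model.window_config, breaks=breaks)
    if X.shape[0]:
        p = forward(model, X)
        for row, c in enumerate(centers):
            probs[c] = p[row]
            labels[c] = CLASS_ORDER[int(np.argmax(p[row]))]
    return SSAssignment("".join(labels), probs)


def save_model(model: MLPModel, path) -> None:
    """Write a model as versioned JSON text; round-trips every float exactly."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "layout": {
            "input_width": model.layout.input_width,
            "hidden": list(model.layout.hidden),
            "output_width": model.layout.output_width,
        },
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "feature_mean": model.feature_mean.tolist(),
        "feature_std": model.feature_std.tolist(),
        "window": {"n": model.window_config.n, "feature_set": list(model.window_config.feature_set)},
        "hbond": model.hbond_criteria.to_dict(),
        "feature_names": model.window_config.feature_names(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MLPModel:
    """Read a model file, validating the version tag and internal consistency."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise ModelFileError(f"model file error: {e}") from None
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFileError("model file error: unrecognized format tag")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFileError(f"model file error: unsupported version {doc.get('version')!r}")
    try:
        layout = NetworkLayout(
            input_width=doc["layout"]["input_width"],
            hidden=tuple(doc["layout"]["hidden"]),
            output_width=doc["layout"]["output_width"],
        )
        window = WindowConfig(n=doc["window"]["n"], feature_set=tuple(doc["window"]["feature_set"]))
        criteria = HbondCriteria.from_dict(doc["hbond"])
        weights = [np.array(w, dtype=float) for w in doc["weights"]]
        biases = [np.array(b, dtype=float) for b in doc["biases"]]
        mean = np.array(doc["feature_mean"], dtype=float)
        std = np.array(doc["feature_std"], dtype=float)
    except (KeyError, TypeError, ValueError, SscaError) as e:
        raise ModelFileError(f"model file error: {e}") from None

    widths = layout.widths
    shapes_ok = (
        len(weights) == len(biases) == len(widths) - 1
        and all(w.shape == (widths[k], widths[k + 1]) for k, w in enumerate(weights))
        and all(b.shape == (widths[k + 1],) for k, b in enumerate(biases))
        and mean.shape == std.shape == (layout.input_width,)
    )
    if not shapes_ok:
        raise ModelFileError("model file error: weight shapes inconsistent with layout")
    if layout.input_width != window.width:
        raise ModelFileError("model file error: input width does not match feature configuration")
    if np.any(std <= 0):
        raise ModelFileError("model file error: non-positive feature std")
    return MLPModel(
        layout=layout,
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_std=std,
        window_config=window,
        hbond_criteria=criteria,
    )
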