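"""From-scratch multilayer perceptron gesture classifier.

Every neuron applies a sigmoid to a weighted sum of its inputs,

    y = 1 / (1 + exp(-sum_i w_i z_i)),

with an optional bias implemented as a constant-1 augmented input (on by
default; ``bias=False`` reproduces the literal bias-free neuron, whose
decision surfaces must pass through the origin).  Training is stochastic
backpropagation of the per-sample squared error L = 1/2 * sum_j (y_j - t_j)^2
against one-hot targets: each weight moves by

    dw_ij = eta * delta_j * x_i,

where delta_j is the backpropagated error of neuron j and x_i the signal it
receives.  Samples are shuffled each epoch; training stops early once the
test-set classification error has not improved for ``patience`` consecutive
epochs, and the weights from the best test epoch are restored.

Features are min-max normalized to [0, 1] using bounds computed on the
training set only; the bounds are stored with the model and reapplied at
inference.  Classification is winner-take-all over the output neurons with
ties broken toward the lowest class index.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureWindow, training_set

__all__ = [
    "MlpModel",
    "TrainingRun",
    "init_model",
    "forward",
    "forward_batch",
    "gradients",
    "backprop_step",
    "train",
    "classify",
    "classify_batch",
    "classification_error",
]


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(v, -500.0, 500.0)))


#: Relative test-loss decrease below which an epoch does not count as
#: progress for early stopping (see ``train``).  Zero means any new best
#: loss counts; stopping then fires once the loss stops descending and
#: fluctuates around its floor.
_MIN_DELTA_REL = 0.0


@dataclass
class MlpModel:
    """Layered sigmoid network with per-layer weight matrices.

    ``weights[l]`` has shape ``(layer_sizes[l+1], layer_sizes[l] + 1)`` when
    ``bias`` is set (the last column multiplies a constant 1), otherwise
    ``(layer_sizes[l+1], layer_sizes[l])``.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    bias: bool = True
    norm_lo: np.ndarray | None = None  # training-set feature minima
    norm_hi: np.ndarray | None = None
    classes: np.ndarray | None = None  # output index -> gesture label
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = 1 if self.bias else 0
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("one weight matrix is required per trainable layer")
        for l, w in enumerate(self.weights):
            want = (self.layer_sizes[l + 1], self.layer_sizes[l] + extra)
            if w.shape != want:
                raise ValueError(
                    f"layer {l} weights shaped {w.shape}, expected {want}"
                )

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Apply the stored training-set min-max scaling (identity if unset)."""
        if self.norm_lo is None:
            return x
        span = self.norm_hi - self.norm_lo
        span = np.where(span > 0, span, 1.0)
        return (x - self.norm_lo) / span

    def copy(self) -> "MlpModel":
        return copy.deepcopy(self)


@dataclass
class TrainingRun:
    """Epoch-by-epoch log of one training session."""

    learning_rate: float
    max_epochs: int
    patience: int
    epoch_log: list[tuple[float, float]] = field(default_factory=list)
    stopped_at: int = 0  # number of epochs actually run
    best_epoch: int = 0  # epoch (1-based) whose weights were kept
    stop_reason: str = ""

    @property
    def train_errors(self) -> list[float]:
        return [e for e, _ in self.epoch_log]

    @property
    def test_errors(self) -> list[float]:
        return [e for _, e in self.epoch_log]


def init_model(layer_sizes, seed: int = 0, bias: bool = True) -> MlpModel:
    """Random model with weights uniform on [-0.5, 0.5]."""
    sizes = [int(s) for s in layer_sizes]
    if len(sizes) < 2:
        raise ValueError("layer_sizes needs at least an input and an output layer")
    if any(s < 1 for s in sizes):
        raise ValueError("every layer must have at least one neuron")
    rng = np.random.default_rng(seed)
    extra = 1 if bias else 0
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l] + extra))
        for l in range(len(sizes) - 1)
    ]
    return MlpModel(layer_sizes=sizes, weights=weights, bias=bias)


def _augment(a: np.ndarray, bias: bool) -> np.ndarray:
    return np.concatenate([a, [1.0]]) if bias else a


def forward(model: MlpModel, x) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-layer activations (input first) and the final output vector."""
    a = np.asarray(x, dtype=float)
    if a.shape != (model.n_inputs,):
        raise ValueError(
            f"input shaped {a.shape}, model expects ({model.n_inputs},)"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    activations = [a]
    for w in model.weights:
        a = _sigmoid(w @ _augment(a, model.bias))
        activations.append(a)
    return activations, activations[-1]


def forward_batch(model: MlpModel, x: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over rows of ``x``; returns (n, n_outputs)."""
    a = np.asarray(x, dtype=float)
    for w in model.weights:
        if model.bias:
            a = np.hstack([a, np.ones((a.shape[0], 1))])
        a = _sigmoid(a @ w.T)
    return a


def gradients(
    model: MlpModel, x, target
) -> tuple[list[np.ndarray], float]:
    """Backpropagated gradients of L = 1/2 sum (y - t)^2 w.r.t. each weight
    matrix, plus the loss value itself."""
    t = np.asarray(target, dtype=float)
    if t.shape != (model.n_outputs,):
        raise ValueError(
            f"target shaped {t.shape}, model expects ({model.n_outputs},)"
        )
    if not np.all(np.isfinite(t)):
        raise ValueError("target contains non-finite values")
    activations, y = forward(model, x)
    loss = 0.5 * float(np.sum((y - t) ** 2))
    # delta for the output layer: dL/d(net) = (y - t) * y * (1 - y)
    delta = (y - t) * y * (1.0 - y)
    grads: list[np.ndarray] = [None] * len(model.weights)
    for l in range(len(model.weights) - 1, -1, -1):
        inputs = _augment(activations[l], model.bias)
        grads[l] = np.outer(delta, inputs)
        if l > 0:
            a = activations[l]
            w_in = model.weights[l][:, :-1] if model.bias else model.weights[l]
            delta = (w_in.T @ delta) * a * (1.0 - a)
    return grads, loss


def backprop_step(model: MlpModel, x, target, learning_rate: float) -> float:
    """One stochastic gradient step on a single sample, in place.

    Returns the sample's squared-error loss *before* the update.
    """
    grads, loss = gradients(model, x, target)
    for w, g in zip(model.weights, grads):
        w -= learning_rate * g
    return loss


def _sgd_epoch(
    weights: list[np.ndarray],
    bias: bool,
    x: np.ndarray,
    targets: np.ndarray,
    order: np.ndarray,
    learning_rate: float,
) -> None:
    """One shuffled pass of per-sample updates, in place.

    Numerically equivalent to calling :func:`backprop_step` per sample (same
    maths, fewer temporaries); this is the training hot path.
    """
    n_layers = len(weights)
    for i in order:
        a = x[i]
        acts = [a]
        for w in weights:
            if bias:
                z = w[:, :-1] @ a + w[:, -1]
            else:
                z = w @ a
            a = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
            acts.append(a)
        delta = (a - targets[i]) * a * (1.0 - a)
        for l in range(n_layers - 1, -1, -1):
            w = weights[l]
            prev = acts[l]
            if l > 0:
                w_in = w[:, :-1] if bias else w
                next_delta = (w_in.T @ delta) * prev * (1.0 - prev)
            if bias:
                w[:, :-1] -= learning_rate * np.outer(delta, prev)
                w[:, -1] -= learning_rate * delta
            else:
                w -= learning_rate * np.outer(delta, prev)
            if l > 0:
                delta = next_delta


def _coerce_set(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        x, y = dataset
        return np.asarray(x, dtype=float), np.asarray(y, dtype=int)
    if len(dataset) and isinstance(dataset[0], FeatureWindow):
        return training_set(dataset)
    raise ValueError("dataset must be (X, y) arrays or a list of FeatureWindow")


def train(
    model: MlpModel,
    train_data,
    test_data,
    learning_rate: float = 0.01,
    max_epochs: int = 5000,
    patience: int = 50,
    seed: int = 0,
) -> tuple[TrainingRun, MlpModel]:
    """Epoch training with early stopping on test-set classification error.

    ``train_data``/``test_data`` are either ``(X, y)`` arrays or lists of
    :class:`FeatureWindow` (rest windows dropped).  Returns the training log
    and the model restored to the weights of the best test epoch.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    x_train, y_train = _coerce_set(train_data)
    x_test, y_test = _coerce_set(test_data)
    if x_train.size == 0 or x_test.size == 0:
        raise ValueError("train and test sets must be non-empty")

    classes = np.unique(y_train)
    missing = sorted(set(y_test.tolist()) - set(classes.tolist()))
    if missing:
        raise ValueError(f"test classes absent from training set: {missing}")
    if classes.size != model.n_outputs:
        raise ValueError(
            f"{classes.size} training classes but model has "
            f"{model.n_outputs} output neurons"
        )

    model = model.copy()
    model.classes = classes
    model.norm_lo = x_train.min(axis=0)
    model.norm_hi = x_train.max(axis=0)
    xn_train = model.normalize(x_train)
    xn_test = model.normalize(x_test)

    class_index = {c: i for i, c in enumerate(classes.tolist())}
    targets = np.zeros((len(y_train), model.n_outputs))
    for i, label in enumerate(y_train):
        targets[i, class_index[int(label)]] = 1.0

    # One-hot targets for the test set reuse the training class order.
    test_targets = np.zeros((len(y_test), model.n_outputs))
    for i, label in enumerate(y_test):
        test_targets[i, class_index[int(label)]] = 1.0

    run = TrainingRun(
        learning_rate=learning_rate, max_epochs=max_epochs, patience=patience
    )
    rng = np.random.default_rng(seed)
    best_err = np.inf
    best_loss = np.inf
    best_weights = [w.copy() for w in model.weights]
    since_improve = 0
    for epoch in range(1, max_epochs + 1):
        _sgd_epoch(
            model.weights, model.bias, xn_train, targets,
            rng.permutation(len(xn_train)), learning_rate,
        )
        train_err = _error_rate(model, xn_train, y_train)
        test_err = _error_rate(model, xn_test, y_test)
        test_out = forward_batch(model, xn_test)
        test_loss = 0.5 * float(np.sum((test_out - test_targets) ** 2))
        run.epoch_log.append((train_err, test_err))
        run.stopped_at = epoch
        # The misclassification rate moves in steps of 1/n_test and sits on
        # long plateaus while the continuous loss still descends; treat the
        # epoch as progress if either monitor improved, so that "the error
        # started increasing on the test samples" means both have stalled.
        improved = (
            test_err < best_err
            or test_loss < best_loss * (1.0 - _MIN_DELTA_REL)
        )
        if test_err < best_err:
            best_err = test_err
            best_weights = [w.copy() for w in model.weights]
            run.best_epoch = epoch
        best_loss = min(best_loss, test_loss)
        if improved:
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > patience:
                run.stop_reason = (
                    f"no test improvement for {since_improve} epochs"
                )
                break
    if not run.stop_reason:
        run.stop_reason = f"reached max_epochs={max_epochs}"
    model.weights = best_weights
    model.meta.update(
        learning_rate=learning_rate,
        epochs_run=run.stopped_at,
        best_epoch=run.best_epoch,
        best_test_error=float(best_err),
        stop_reason=run.stop_reason,
    )
    return run, model


def _error_rate(model: MlpModel, x_norm: np.ndarray, y: np.ndarray) -> float:
    """Error on already-normalized features (internal hot path)."""
    out = forward_batch(model, x_norm)
    pred_idx = np.argmax(out, axis=1)
    pred = model.classes[pred_idx] if model.classes is not None else pred_idx
    return float(np.mean(pred != y))


def classify(model: MlpModel, rms_vector) -> int:
    """Winner-take-all class of one feature vector (ties -> lowest index)."""
    x = model.normalize(np.asarray(rms_vector, dtype=float))
    _, out = forward(model, x)
    idx = int(np.argmax(out))
    return int(model.classes[idx]) if model.classes is not None else idx


def classify_batch(model: MlpModel, x: np.ndarray) -> np.ndarray:
    xn = model.normalize(np.asarray(x, dtype=float))
    idx = np.argmax(forward_batch(model, xn), axis=1)
    return model.classes[idx] if model.classes is not None else idx


def classification_error(model: MlpModel, dataset) -> float:
    """Fraction of misclassified windows in a labelled set."""
    x, y = _coerce_set(dataset)
    if len(y) == 0:
        raise ValueError("cannot score an empty set")
    return float(np.mean(classify_batch(model, x) != y))
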