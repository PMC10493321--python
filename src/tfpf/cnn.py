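"""Compact two-layer 3D convolutional classifier and its evaluation harness.

The network maps one C x C x N feature block (N = 3 per-window slices, or
3 x windows in stacked mode) to class probabilities:

    conv1: 3 x 3 x 3 kernel, 50 maps, valid padding, stride 1, ReLU
           -> output volume (C-2) x (C-2) x (N-2) x 50
    conv2: (C-2) x (C-2) x (N-2) kernel, 100 maps, valid, ReLU
           -> the kernel covers conv1's whole output volume, so the layer
              emits exactly one 100-dimensional feature vector
    head:  fully connected 100 -> n_classes, softmax

Training uses softmax cross-entropy with Adam (learning rate 1e-4, batch
size 16, 100 epochs by default), fully seeded: weight initialization and
batch shuffling are pure functions of the seed.

Implemented directly on numpy (im2col convolution + hand-written
backpropagation); the model is small enough that a deep-learning framework
would add nothing but a heavier dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pickle

import numpy as np
from scipy import stats

__all__ = ["ModelConfig", "CNN3D", "FoldResult", "build_model", "train",
           "evaluate_cv", "one_way_anova", "ablate_step_sizes"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the two-layer 3D CNN.

    ``input_shape`` is (C, C, N) with C the channel count and N the feature
    depth; both must be >= 3 for the 3 x 3 x 3 first kernel to fit.
    """

    input_shape: tuple
    n_classes: int = 2
    conv1_kernel: tuple = (3, 3, 3)
    conv1_maps: int = 50
    conv2_maps: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        c1, c2, n = self.input_shape
        if c1 != c2:
            raise ValueError(f"input must be square in the channel axes, got {self.input_shape}")
        if c1 < 3 or n < 3:
            raise ValueError(
                f"input shape {self.input_shape} too small for a 3x3x3 kernel: "
                "need C >= 3 and depth N >= 3 (use stacked mode or more feature slices)"
            )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "input_shape", tuple(int(v) for v in self.input_shape))

    @property
    def conv1_output_shape(self) -> tuple:
        """(C-2, C-2, N-2, conv1_maps) under valid padding, stride 1."""
        c, _, n = self.input_shape
        k = self.conv1_kernel
        return (c - k[0] + 1, c - k[1] + 1, n - k[2] + 1, self.conv1_maps)

    @property
    def conv2_kernel(self) -> tuple:
        """Second kernel = conv1's output spatial volume, (C-2, C-2, N-2)."""
        return self.conv1_output_shape[:3]

    @property
    def feature_dim(self) -> int:
        """Dimension of the pre-classifier representation (conv2 map count)."""
        return self.conv2_maps

    @property
    def n_parameters(self) -> int:
        k = self.conv1_kernel
        p = int(np.prod(self.conv1_output_shape[:3]))
        return (
            self.conv1_maps * (k[0] * k[1] * k[2] + 1)
            + self.conv2_maps * (p * self.conv1_maps + 1)
            + self.n_classes * (self.conv2_maps + 1)
        )


class CNN3D:
    """The two-conv-layer 3D CNN, trained with Adam on cross-entropy."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.conv1_kernel
        fan1 = k[0] * k[1] * k[2]
        p = int(np.prod(config.conv1_output_shape[:3]))
        fan2 = p * config.conv1_maps
        # He-normal initialization (ReLU activations)
        self.W1 = rng.standard_normal((fan1, config.conv1_maps)) * np.sqrt(2.0 / fan1)
        self.b1 = np.zeros(config.conv1_maps)
        self.W2 = rng.standard_normal((fan2, config.conv2_maps)) * np.sqrt(2.0 / fan2)
        self.b2 = np.zeros(config.conv2_maps)
        self.W3 = rng.standard_normal((config.conv2_maps, config.n_classes)) * np.sqrt(
            2.0 / config.conv2_maps
        )
        self.b3 = np.zeros(config.n_classes)
        self._adam_state = None
        self.loss_trace: list = []

    # -- forward ---------------------------------------------------------

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        """(B, C, C, N) -> (B, P, 27) patches for the valid 3x3x3 conv."""
        k = self.config.conv1_kernel
        win = np.lib.stride_tricks.sliding_window_view(X, k, axis=(1, 2, 3))
        B = X.shape[0]
        return win.reshape(B, -1, k[0] * k[1] * k[2])

    def _forward(self, patches: np.ndarray):
        z1 = patches @ self.W1 + self.b1               # (B, P, 50)
        a1 = np.maximum(z1, 0.0)
        flat1 = a1.reshape(patches.shape[0], -1)       # (B, P*50)
        z2 = flat1 @ self.W2 + self.b2                 # (B, 100)
        a2 = np.maximum(z2, 0.0)
        logits = a2 @ self.W3 + self.b3                # (B, K)
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return patches, z1, flat1, z2, a2, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        return self._forward(self._im2col(X))[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def embed(self, X: np.ndarray) -> np.ndarray:
        """The 100-dimensional pre-classifier representation."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        return self._forward(self._im2col(X))[4]

    # -- training --------------------------------------------------------

    def _grads(self, patches: np.ndarray, y: np.ndarray):
        B = patches.shape[0]
        patches, z1, flat1, z2, a2, probs = self._forward(patches)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dW3 = a2.T @ dlogits
        db3 = dlogits.sum(axis=0)
        dz2 = (dlogits @ self.W3.T) * (z2 > 0)
        dW2 = flat1.T @ dz2
        db2 = dz2.sum(axis=0)
        dflat1 = dz2 @ self.W2.T
        dz1 = dflat1.reshape(z1.shape) * (z1 > 0)
        fan1 = self.W1.shape[0]
        dW1 = patches.reshape(-1, fan1).T @ dz1.reshape(-1, self.config.conv1_maps)
        db1 = dz1.sum(axis=(0, 1))
        return loss, (dW1, db1, dW2, db2, dW3, db3)

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
                "scratch": [np.empty_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        bc1 = 1 - beta1 ** st["t"]
        bc2 = 1 - beta2 ** st["t"]
        # in-place updates with one scratch buffer per parameter: the Adam
        # moment bookkeeping is the hot loop, so avoid temporaries
        for m, v, s, p, g in zip(st["m"], st["v"], st["scratch"], params, grads):
            m *= beta1
            np.multiply(g, 1 - beta1, out=s)
            m += s
            v *= beta2
            np.multiply(g, g, out=s)
            s *= 1 - beta2
            v += s
            np.divide(v, bc2, out=s)
            np.sqrt(s, out=s)
            s += eps
            np.divide(m, s, out=s)
            s *= lr / bc1
            p -= s

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int | None = None):
        """Train on samples X (n, C, C, N) with integer labels y.

        Returns the per-epoch mean loss trace (also kept on
        ``self.loss_trace``).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_samples, C, C, N), got {X.shape}")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set covers a single class; need >= 2")
        if not np.issubdtype(y.dtype, np.integer) or y.min() < 0 or y.max() >= self.config.n_classes:
            raise ValueError(
                f"labels must be integers in [0, {self.config.n_classes}), got {classes}"
            )
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 1)
        n = X.shape[0]
        # the im2col patches of a sample never change: extract them once
        patches = np.ascontiguousarray(self._im2col(X))
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self._grads(patches[idx], y[idx])
                self._adam_step(grads, cfg.learning_rate)
                epoch_losses.append(loss)
            self.loss_trace.append(float(np.mean(epoch_losses)))
        return self.loss_trace

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> str:
        state = {"config": self.config, "weights": [self.W1, self.b1, self.W2,
                                                    self.b2, self.W3, self.b3],
                 "loss_trace": self.loss_trace}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)
        return path

    @classmethod
    def load(cls, path: str) -> "CNN3D":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["config"])
        model.W1, model.b1, model.W2, model.b2, model.W3, model.b3 = state["weights"]
        model.loss_trace = state["loss_trace"]
        return model


def build_model(config: ModelConfig) -> CNN3D:
    """Construct (and seed-initialize) the classifier for a config."""
    return CNN3D(config)


def train(model: CNN3D, input_sets: list, labels=None, epochs: int | None = None):
    """Train on a list of :class:`~tfpf.features.InputSet` (or raw arrays).

    Returns ``(model, loss_trace)``.
    """
    if labels is None:
        labels = [s.label for s in input_sets]
    X = np.stack([np.asarray(getattr(s, "values", s), dtype=float) for s in input_sets])
    y = np.asarray(labels, dtype=int)
    trace = model.fit(X, y, epochs=epochs)
    return model, trace


@dataclass(frozen=True)
class FoldResult:
    """Held-out performance of one cross-validation fold."""

    fold_index: int
    train_trial_ids: tuple
    test_trial_ids: tuple
    accuracy: float
    confusion: np.ndarray = field(default=None, repr=False)


def evaluate_cv(input_sets: list, config: ModelConfig | None = None, k: int = 10,
                seed: int = 0, split_unit: str = "trial", epochs: int | None = None):
    """k-fold cross-validation over classifier samples.

    ``split_unit='trial'`` (default) assigns all windows of one trial to the
    same fold, so near-duplicate overlapping windows never leak between
    train and test.  ``split_unit='segment'`` splits at the sample level
    (leaky, provided only for comparison with protocols that window before
    splitting).

    Returns ``(fold_results, mean_accuracy, sd_accuracy)``.
    """
    if split_unit not in ("trial", "segment"):
        raise ValueError("split_unit must be 'trial' or 'segment'")
    labels = np.asarray([int(s.label) for s in input_sets])
    n_classes = int(labels.max()) + 1
    X = np.stack([s.values for s in input_sets])
    if config is None:
        config = ModelConfig(input_shape=X.shape[1:], n_classes=n_classes, seed=seed)

    if split_unit == "trial":
        unit_of = np.asarray([s.trial_id for s in input_sets])
    else:
        unit_of = np.arange(len(input_sets)).astype(str)
    units = np.unique(unit_of)
    if units.size < k:
        raise ValueError(f"{units.size} {split_unit}s cannot be split into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(units.size)
    fold_of_unit = {units[p]: f for f, p in zip(np.arange(units.size) % k, perm)}
    fold_assign = np.asarray([fold_of_unit[u] for u in unit_of])

    results = []
    for f in range(k):
        test_mask = fold_assign == f
        model = CNN3D(
            ModelConfig(**{**config.__dict__, "seed": config.seed + f})
        )
        model.fit(X[~test_mask], labels[~test_mask], epochs=epochs)
        pred = model.predict(X[test_mask])
        truth = labels[test_mask]
        confusion = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(confusion, (truth, pred), 1)
        acc = float(np.trace(confusion)) / max(1, confusion.sum())
        results.append(FoldResult(
            fold_index=f,
            train_trial_ids=tuple(sorted(set(unit_of[~test_mask]))),
            test_trial_ids=tuple(sorted(set(unit_of[test_mask]))),
            accuracy=acc, confusion=confusion,
        ))
    accs = np.asarray([r.accuracy for r in results])
    return results, float(accs.mean()), float(accs.std(ddof=1))


def one_way_anova(groups: list):
    """One-way fixed-effects ANOVA from between/within sums of squares.

    Returns ``(F, p)``.  Identical group means give F = 0, p = 1; zero
    within-group variance with distinct means gives F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p


def ablate_step_sizes(dataset_builder, steps=(0.5, 0.25, 0.125), repeats: int = 3,
                      window_s: float = 2.0, band: tuple = (8.0, 30.0),
                      k: int = 5, epochs: int | None = None, seed: int = 0):
    """Sliding-window step-size ablation.

    For each step size the full pipeline (band-pass -> windows -> TFPF ->
    CNN k-fold CV) is rerun ``repeats`` times with fresh datasets from
    ``dataset_builder(seed)``; smaller steps yield more windows per trial
    and hence more training samples.  Group differences are tested with a
    one-way ANOVA on the per-repeat mean accuracies.

    Returns ``(accuracies, F, p)`` with ``accuracies`` a dict
    ``{step: [mean_cv_accuracy per repeat]}``.
    """
    from .pipeline import trials_to_input_sets

    steps = tuple(steps)
    if len(steps) < 2:
        raise ValueError("need at least 2 step sizes")
    if repeats < 2:
        raise ValueError("need at least 2 repeats per step for the ANOVA")
    accuracies = {s: [] for s in steps}
    for r in range(repeats):
        trials = dataset_builder(seed + r)
        for s in steps:
            samples = trials_to_input_sets(trials, band=band, window_s=window_s,
                                           step_s=s)
            _, mean_acc, _ = evaluate_cv(samples, k=k, seed=seed + r, epochs=epochs)
            accuracies[s].append(mean_acc)
    F, p = one_way_anova([accuracies[s] for s in steps])
    return accuracies, F, p
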