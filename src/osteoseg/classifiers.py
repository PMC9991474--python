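"""The three osteoporosis classifiers: C4.5-style decision tree, Gaussian
naive Bayes, and a two-hidden-layer sigmoid multilayer perceptron.

All three operate on cluster-pixel-count feature vectors.  They are written
from first principles because the exact variants matter here: the tree uses
information gain ratio with midpoint numeric splits and pessimistic-error
pruning (the C4.5/J48 family), and the MLP is trained by per-sample
stochastic backpropagation with momentum — the classical configuration
(learning rate 0.3, momentum 0.2, sigmoid activations).

Class order is fixed as (nonosteoporosis, osteoporosis); prediction ties go
to nonosteoporosis, the conservative screening default.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from osteoseg.features import FeatureTable, FeatureVector

CLASS_ORDER = ("nonosteoporosis", "osteoporosis")


@dataclass(frozen=True)
class TreeConfig:
    """C4.5-style decision-tree settings.

    ``min_leaf`` is the minimum number of training samples per leaf;
    ``confidence`` is the pessimistic-pruning confidence factor (the J48
    convention is 0.25; smaller prunes more aggressively).
    """

    min_leaf: int = 2
    prune: bool = True
    confidence: float = 0.25

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class MlpConfig:
    """Multilayer-perceptron settings: 2 sigmoid hidden layers, SGD with
    momentum.  ``hidden_sizes=None`` defaults to (K, ceil(K/2)) at training
    time.  Inputs are normalized to [0, 1] by dividing each count vector by
    its total (the image pixel count) unless ``normalize_inputs`` is off —
    raw counts up to 120,000 would saturate the sigmoids immediately.
    """

    learning_rate: float = 0.3
    momentum: float = 0.2
    hidden_sizes: tuple[int, int] | None = None
    epochs: int = 500
    seed: int = 0
    normalize_inputs: bool = True
    n_hidden_layers: int = 2
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.hidden_sizes is not None and any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.n_hidden_layers != 2:
            raise ValueError("the architecture is fixed at 2 hidden layers")
        if self.activation != "sigmoid":
            raise ValueError("the activation is fixed to sigmoid")


@dataclass
class TrainedModel:
    """A fitted classifier: kind in {tree, nb, mlp} plus its learned state."""

    kind: str
    parameters: dict
    feature_dim: int
    class_order: tuple[str, str] = CLASS_ORDER


# --------------------------------------------------------------------------
# Decision tree (C4.5 / J48 style)
# --------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.array([int(np.sum(y == 0)), int(np.sum(y == 1))])


def _majority(counts: np.ndarray) -> int:
    # Tie -> class 0 (nonosteoporosis).
    return int(counts[1] > counts[0])


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold) by gain ratio among splits with positive gain.

    Numeric thresholds are midpoints between consecutive distinct sorted
    values; children smaller than ``min_leaf`` are not considered.
    """
    n = len(y)
    parent_h = _entropy(_class_counts(y))
    best = None  # (gain_ratio, gain, feature, threshold)
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], y[order]
        distinct = np.unique(xs)
        if len(distinct) < 2:
            continue
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
        for t in thresholds:
            left = xs <= t
            n_left = int(left.sum())
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            h_left = _entropy(_class_counts(ys[left]))
            h_right = _entropy(_class_counts(ys[~left]))
            gain = parent_h - (n_left * h_left + (n - n_left) * h_right) / n
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([n_left, n - n_left]))
            if split_info <= 0:
                continue
            ratio = gain / split_info
            key = (ratio, gain)
            if best is None or key > (best[0], best[1]):
                best = (ratio, gain, j, float(t))
    return None if best is None else (best[2], best[3])


def _grow(X: np.ndarray, y: np.ndarray, cfg: TreeConfig) -> dict:
    counts = _class_counts(y)
    node = {"n": int(len(y)), "counts": counts.tolist(), "label": _majority(counts)}
    if counts[0] == 0 or counts[1] == 0 or len(y) < 2 * cfg.min_leaf:
        node["leaf"] = True
        return node
    split = _best_split(X, y, cfg.min_leaf)
    if split is None:
        node["leaf"] = True
        return node
    j, t = split
    mask = X[:, j] <= t
    node.update(
        leaf=False,
        feature=int(j),
        threshold=t,
        left=_grow(X[mask], y[mask], cfg),
        right=_grow(X[~mask], y[~mask], cfg),
    )
    return node


def _pessimistic_errors(n: int, e: int, z: float) -> float:
    """Upper confidence bound on the error count (Wilson interval, C4.5 style)."""
    if n == 0:
        return 0.0
    f = e / n
    num = f + z * z / (2 * n) + z * math.sqrt(f * (1 - f) / n + z * z / (4 * n * n))
    return n * num / (1 + z * z / n)


def _prune(node: dict, z: float) -> dict:
    if node["leaf"]:
        return node
    node["left"] = _prune(node["left"], z)
    node["right"] = _prune(node["right"], z)
    subtree_est = _subtree_estimated_errors(node, z)
    counts = np.array(node["counts"])
    leaf_est = _pessimistic_errors(node["n"], int(counts.sum() - counts.max()), z)
    if leaf_est <= subtree_est + 0.1:
        return {"n": node["n"], "counts": node["counts"], "label": node["label"], "leaf": True}
    return node


def _subtree_estimated_errors(node: dict, z: float) -> float:
    if node["leaf"]:
        counts = np.array(node["counts"])
        err = int(counts.sum() - counts.max())
        return _pessimistic_errors(node["n"], err, z)
    return _subtree_estimated_errors(node["left"], z) + _subtree_estimated_errors(node["right"], z)


def _encode_labels(table: FeatureTable) -> np.ndarray:
    labels = table.labels()
    if any(lbl is None for lbl in labels):
        raise ValueError("training table contains unlabeled rows")
    return np.array([CLASS_ORDER.index(lbl) for lbl in labels], dtype=np.int64)


def train_decision_tree(table: FeatureTable, cfg: TreeConfig | None = None) -> TrainedModel:
    """Fit a C4.5-style tree: gain-ratio midpoint splits, optional
    pessimistic pruning.  A single-class table yields a one-leaf tree."""
    cfg = cfg or TreeConfig()
    X = table.matrix()
    y = _encode_labels(table)
    root = _grow(X, y, cfg)
    if cfg.prune:
        z = float(norm.ppf(1.0 - cfg.confidence))
        root = _prune(root, z)
    return TrainedModel(
        kind="tree",
        parameters={"root": root, "config": dataclasses.asdict(cfg)},
        feature_dim=table.K,
    )


def _tree_predict_one(node: dict, x: np.ndarray) -> int:
    while not node["leaf"]:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return int(node["label"])


def tree_depth(model: TrainedModel) -> int:
    """Depth of the fitted tree (a bare leaf has depth 0)."""

    def depth(node: dict) -> int:
        return 0 if node["leaf"] else 1 + max(depth(node["left"]), depth(node["right"]))

    return depth(model.parameters["root"])


# --------------------------------------------------------------------------
# Gaussian naive Bayes
# --------------------------------------------------------------------------

VAR_FLOOR_FACTOR = 1e-9


def train_naive_bayes(table: FeatureTable) -> TrainedModel:
    """Fit Gaussian naive Bayes: class priors by frequency, per-class
    per-feature means and variances.  Variances are floored at 1e-9 times
    the mean overall feature variance so degenerate (constant) clusters do
    not produce singular densities."""
    X = table.matrix()
    y = _encode_labels(table)
    overall_var = float(np.mean(np.var(X, axis=0)))
    floor = max(VAR_FLOOR_FACTOR * overall_var, 1e-12)
    priors, means, variances = [], [], []
    for c in range(2):
        Xc = X[y == c]
        if len(Xc) == 0:
            raise ValueError(f"no training samples for class {CLASS_ORDER[c]!r}")
        priors.append(len(Xc) / len(X))
        means.append(Xc.mean(axis=0))
        variances.append(np.maximum(Xc.var(axis=0), floor))
    return TrainedModel(
        kind="nb",
        parameters={
            "priors": [float(p) for p in priors],
            "means": [m.tolist() for m in means],
            "variances": [v.tolist() for v in variances],
        },
        feature_dim=table.K,
    )


def nb_log_posteriors(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior of each class for one feature vector."""
    p = model.parameters
    out = np.empty(2)
    for c in range(2):
        mu = np.asarray(p["means"][c])
        var = np.asarray(p["variances"][c])
        ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
        out[c] = math.log(p["priors"][c]) + ll
    return out


# --------------------------------------------------------------------------
# Multilayer perceptron
# --------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _mlp_init(layer_sizes: list[int], rng: np.random.Generator):
    weights = [rng.uniform(-0.5, 0.5, size=(layer_sizes[i], layer_sizes[i + 1])) for i in range(len(layer_sizes) - 1)]
    biases = [rng.uniform(-0.5, 0.5, size=layer_sizes[i + 1]) for i in range(len(layer_sizes) - 1)]
    return weights, biases


def mlp_forward(weights, biases, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer (input first, output last); all sigmoid."""
    acts = [np.asarray(x, dtype=np.float64)]
    for W, b in zip(weights, biases):
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def mlp_loss_and_gradients(weights, biases, x: np.ndarray, target: np.ndarray):
    """Half squared error loss and its analytic gradients for one sample."""
    acts = mlp_forward(weights, biases, x)
    y = acts[-1]
    loss = 0.5 * float(np.sum((y - target) ** 2))
    grads_w, grads_b = [None] * len(weights), [None] * len(weights)
    delta = (y - target) * y * (1.0 - y)
    for layer in range(len(weights) - 1, -1, -1):
        grads_w[layer] = np.outer(acts[layer], delta)
        grads_b[layer] = delta.copy()
        if layer > 0:
            a = acts[layer]
            delta = (weights[layer] @ delta) * a * (1.0 - a)
    return loss, grads_w, grads_b


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals


def train_mlp(table: FeatureTable, cfg: MlpConfig | None = None) -> TrainedModel:
    """Train the 2-hidden-layer sigmoid MLP by per-sample backpropagation
    with momentum.  Deterministic for a fixed seed: weight initialization
    and the per-epoch sample shuffles come from one seeded generator."""
    cfg = cfg or MlpConfig()
    X = table.matrix()
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    y = _encode_labels(table)
    if cfg.normalize_inputs:
        X = _normalize_rows(X)
    hidden = cfg.hidden_sizes or (table.K, math.ceil(table.K / 2))
    layer_sizes = [table.K, hidden[0], hidden[1], 2]
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _mlp_init(layer_sizes, rng)
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    targets = np.eye(2)[y]
    n = len(X)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for i in order:
            _, gw, gb = mlp_loss_and_gradients(weights, biases, X[i], targets[i])
            for layer in range(len(weights)):
                vel_w[layer] = cfg.momentum * vel_w[layer] - cfg.learning_rate * gw[layer]
                vel_b[layer] = cfg.momentum * vel_b[layer] - cfg.learning_rate * gb[layer]
                weights[layer] += vel_w[layer]
                biases[layer] += vel_b[layer]
    return TrainedModel(
        kind="mlp",
        parameters={
            "weights": [W.tolist() for W in weights],
            "biases": [b.tolist() for b in biases],
            "layer_sizes": layer_sizes,
            "normalize_inputs": cfg.normalize_inputs,
        },
        feature_dim=table.K,
    )


# --------------------------------------------------------------------------
# Prediction and serialization
# --------------------------------------------------------------------------


def _as_feature_array(x: FeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.counts.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def predict(model: TrainedModel, x: FeatureVector | np.ndarray) -> str:
    """Predict the diagnosis for one feature vector; ties resolve to
    nonosteoporosis."""
    arr = _as_feature_array(x)
    if arr.shape != (model.feature_dim,):
        raise ValueError(
            f"feature dimension mismatch: model expects {model.feature_dim}, got {arr.shape}"
        )
    if model.kind == "tree":
        idx = _tree_predict_one(model.parameters["root"], arr)
    elif model.kind == "nb":
        post = nb_log_posteriors(model, arr)
        idx = int(post[1] > post[0])  # tie -> class 0
    elif model.kind == "mlp":
        p = model.parameters
        xin = arr / arr.sum() if (p["normalize_inputs"] and arr.sum() > 0) else arr
        weights = [np.asarray(W) for W in p["weights"]]
        biases = [np.asarray(b) for b in p["biases"]]
        out = mlp_forward(weights, biases, xin)[-1]
        idx = int(out[1] > out[0])  # tie -> class 0
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return model.class_order[idx]


def predict_table(model: TrainedModel, table: FeatureTable) -> list[str]:
    """Predict every row of a feature table."""
    return [predict(model, row) for row in table.rows]


def save_model(model: TrainedModel, path: str | Path) -> None:
    doc = {
        "kind": model.kind,
        "feature_dim": model.feature_dim,
        "class_order": list(model.class_order),
        "parameters": model.parameters,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    return TrainedModel(
        kind=doc["kind"],
        parameters=doc["parameters"],
        feature_dim=int(doc["feature_dim"]),
        class_order=tuple(doc["class_order"]),
    )
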