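"""Decision tree, naive Bayes, and MLP: training, prediction, serialization."""

import math

import numpy as np
import pytest

from osteoseg.classifiers import (
    MlpConfig,
    TreeConfig,
    load_model,
    mlp_forward,
    mlp_loss_and_gradients,
    nb_log_posteriors,
    predict,
    predict_table,
    save_model,
    train_decision_tree,
    train_mlp,
    train_naive_bayes,
    tree_depth,
)
from osteoseg.features import FeatureTable, FeatureVector

from _oracles import numeric_gradient

NON, OST = "nonosteoporosis", "osteoporosis"


def table(X, labels):
    rows = [
        FeatureVector(counts=np.asarray(x, dtype=np.int64), label=lbl, source_id=str(i))
        for i, (x, lbl) in enumerate(zip(X, labels))
    ]
    return FeatureTable(rows=rows, K=len(X[0]))


# -- decision tree ----------------------------------------------------------


def test_tree_separable_single_split():
    t = table([[1], [2], [9], [10]], [NON, NON, OST, OST])
    model = train_decision_tree(t, TreeConfig(min_leaf=1, prune=False))
    assert tree_depth(model) == 1
    assert predict_table(model, t) == [NON, NON, OST, OST]


def test_tree_single_class_one_leaf():
    t = table([[1], [2], [3]], [OST, OST, OST])
    model = train_decision_tree(t)
    assert tree_depth(model) == 0
    assert predict(model, np.array([999])) == OST


def test_tree_xor_like_needs_depth_two():
    # No single axis-aligned split separates this 2-feature XOR-like layout
    # (slightly asymmetric: a perfectly symmetric XOR has zero information
    # gain on every candidate split, so gain-guarded C4.5 cannot start).
    t = table([[0, 0], [0, 10], [10, 0], [12, 10]], [NON, OST, OST, NON])
    model = train_decision_tree(t, TreeConfig(min_leaf=1, prune=False))
    assert tree_depth(model) >= 2
    assert predict_table(model, t) == [NON, OST, OST, NON]


def test_tree_training_accuracy_100_when_consistent(rng):
    X = rng.integers(0, 100, size=(30, 4))
    # labels from a noiseless rule; duplicate-feature conflicts impossible here
    labels = [OST if x[0] + x[2] > 95 else NON for x in X]
    if len(set(labels)) < 2:
        labels[0] = OST if labels[0] == NON else NON
    t = table(X, labels)
    model = train_decision_tree(t, TreeConfig(min_leaf=1, prune=False))
    assert predict_table(model, t) == t.labels()


def test_tree_pruning_collapses_noise_split():
    # 19 clean samples per class plus one mislabeled point: pessimistic
    # pruning should simplify relative to the unpruned tree's leaf count.
    X = [[i] for i in range(20)] + [[100 + i] for i in range(20)]
    labels = [NON] * 20 + [OST] * 20
    labels[19] = OST  # noise inside the low block
    t = table(X, labels)
    unpruned = train_decision_tree(t, TreeConfig(min_leaf=1, prune=False))
    pruned = train_decision_tree(t, TreeConfig(min_leaf=1, prune=True, confidence=0.25))
    assert tree_depth(pruned) <= tree_depth(unpruned)


def test_tree_deterministic():
    t = table([[3, 1], [4, 5], [9, 2], [6, 8]], [NON, OST, OST, NON])
    a = train_decision_tree(t)
    b = train_decision_tree(t)
    assert a.parameters == b.parameters


# -- naive Bayes ------------------------------------------------------------


def test_nb_separated_classes():
    t = table(
        [[100, 100], [110, 90], [10_000, 10_000], [9_000, 11_000]],
        [NON, NON, OST, OST],
    )
    model = train_naive_bayes(t)
    assert predict(model, np.array([100, 100])) == NON
    assert predict(model, np.array([10_000, 10_000])) == OST


def test_nb_symmetric_tie_goes_to_negative_class():
    # Classes mirrored about 50: the midpoint has equal posteriors.
    t = table([[40], [45], [55], [60]], [NON, NON, OST, OST])
    model = train_naive_bayes(t)
    post = nb_log_posteriors(model, np.array([50.0]))
    assert post[0] == pytest.approx(post[1], abs=1e-9)
    assert predict(model, np.array([50])) == NON


def test_nb_hand_computed_posterior():
    # 2 features, 4 samples: means/variances/posteriors computed by hand.
    t = table([[2, 4], [4, 8], [10, 2], [14, 6]], [NON, NON, OST, OST])
    model = train_naive_bayes(t)
    p = model.parameters
    assert p["priors"] == [0.5, 0.5]
    assert p["means"][0] == [3.0, 6.0]
    assert p["means"][1] == [12.0, 4.0]
    assert p["variances"][0] == [1.0, 4.0]
    assert p["variances"][1] == [4.0, 4.0]
    x = np.array([5.0, 5.0])
    expected = {}
    for c, (mus, vars_) in enumerate(zip(p["means"], p["variances"])):
        ll = math.log(0.5)
        for xv, mu, var in zip(x, mus, vars_):
            ll += -0.5 * (math.log(2 * math.pi * var) + (xv - mu) ** 2 / var)
        expected[c] = ll
    got = nb_log_posteriors(model, x)
    assert got[0] == pytest.approx(expected[0])
    assert got[1] == pytest.approx(expected[1])


def test_nb_shift_invariance(rng):
    """Adding a constant to one feature everywhere shifts both class means
    equally and cannot change any prediction."""
    X = rng.integers(0, 50, size=(20, 3))
    labels = [OST if i % 2 else NON for i in range(20)]
    t1 = table(X, labels)
    X2 = X.copy()
    X2[:, 1] += 1000
    t2 = table(X2, labels)
    m1, m2 = train_naive_bayes(t1), train_naive_bayes(t2)
    queries = rng.integers(0, 50, size=(10, 3)).astype(float)
    for q in queries:
        q2 = q.copy()
        q2[1] += 1000
        assert predict(m1, q) == predict(m2, q2)


def test_nb_degenerate_constant_feature_does_not_crash():
    t = table([[5, 1], [5, 2], [5, 9], [5, 10]], [NON, NON, OST, OST])
    model = train_naive_bayes(t)
    assert predict(model, np.array([5, 1])) == NON


# -- MLP --------------------------------------------------------------------


def test_mlp_learns_linearly_separable_data():
    """Separable data is learnable when training runs to convergence."""
    X = [[10, 90], [20, 80], [15, 85], [80, 20], [90, 10], [85, 15]]
    labels = [NON, NON, NON, OST, OST, OST]
    t = table(X, labels)
    model = train_mlp(t, MlpConfig(epochs=2000, seed=0))
    assert predict_table(model, t) == labels


def test_mlp_zero_learning_rate_keeps_initial_weights():
    t = table([[1, 2], [3, 4]], [NON, OST])
    cfg = MlpConfig(learning_rate=0.0, momentum=0.0, epochs=10, seed=5)
    model = train_mlp(t, cfg)
    rng = np.random.default_rng(5)
    sizes = [2, 2, 1, 2]
    expected_w = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1])) for i in range(3)]
    expected_b = [rng.uniform(-0.5, 0.5, size=sizes[i + 1]) for i in range(3)]
    for W, ew in zip(model.parameters["weights"], expected_w):
        assert np.allclose(W, ew)
    for b, eb in zip(model.parameters["biases"], expected_b):
        assert np.allclose(b, eb)


def test_mlp_deterministic_under_seed():
    t = table([[10, 90], [80, 20], [30, 70], [60, 40]], [NON, OST, NON, OST])
    a = train_mlp(t, MlpConfig(epochs=50, seed=3))
    b = train_mlp(t, MlpConfig(epochs=50, seed=3))
    for Wa, Wb in zip(a.parameters["weights"], b.parameters["weights"]):
        assert np.array_equal(Wa, Wb)
    c = train_mlp(t, MlpConfig(epochs=50, seed=4))
    assert any(
        not np.array_equal(Wa, Wc)
        for Wa, Wc in zip(a.parameters["weights"], c.parameters["weights"])
    )


def test_mlp_gradient_matches_finite_differences():
    """Analytic backprop gradients agree with central differences to 1e-5
    relative error on a tiny network."""
    rng = np.random.default_rng(7)
    sizes = [3, 4, 3, 2]
    weights = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1])) for i in range(3)]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1]) for i in range(3)]
    x = rng.uniform(0, 1, size=3)
    target = np.array([1.0, 0.0])

    loss, gw, gb = mlp_loss_and_gradients(weights, biases, x, target)

    def f():
        return mlp_loss_and_gradients(weights, biases, x, target)[0]

    num_w = numeric_gradient(f, weights)
    num_b = numeric_gradient(f, biases)
    for analytic, numeric in zip(gw + gb, num_w + num_b):
        denom = np.maximum(np.abs(numeric), 1e-8)
        assert np.max(np.abs(analytic - numeric) / denom) < 1e-5


def test_mlp_rejects_nonfinite_features():
    rows = [
        FeatureVector(counts=np.array([1, 2]), label=NON),
        FeatureVector(counts=np.array([3, 4]), label=OST),
    ]
    t = FeatureTable(rows=rows, K=2)
    t.rows[0].counts = t.rows[0].counts.astype(float)  # sneak in a NaN
    t.rows[0].counts[0] = np.nan
    with pytest.raises(ValueError):
        train_mlp(t, MlpConfig(epochs=1))


def test_mlp_input_normalization_bounds():
    t = table([[120_000, 0], [0, 120_000]], [NON, OST])
    model = train_mlp(t, MlpConfig(epochs=5, seed=0))
    assert model.parameters["normalize_inputs"] is True
    weights = [np.asarray(W) for W in model.parameters["weights"]]
    biases = [np.asarray(b) for b in model.parameters["biases"]]
    out = mlp_forward(weights, biases, np.array([0.5, 0.5]))[-1]
    assert np.all((out > 0) & (out < 1))


# -- prediction and serialization -------------------------------------------


def test_predict_dimension_mismatch_names_both_dims():
    t = table([[1, 2], [9, 10]], [NON, OST])
    model = train_naive_bayes(t)
    with pytest.raises(ValueError, match="2"):
        predict(model, np.array([1, 2, 3]))


def test_one_leaf_tree_predicts_everywhere():
    t = table([[1], [2]], [OST, OST])
    model = train_decision_tree(t)
    for v in (0, 50, 10_000):
        assert predict(model, np.array([v])) == OST


@pytest.mark.parametrize("kind", ["tree", "nb", "mlp"])
def test_model_json_roundtrip(tmp_path, kind):
    t = table([[10, 90], [80, 20], [20, 80], [70, 30]], [NON, OST, NON, OST])
    if kind == "tree":
        model = train_decision_tree(t)
    elif kind == "nb":
        model = train_naive_bayes(t)
    else:
        model = train_mlp(t, MlpConfig(epochs=20, seed=1))
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    assert back.kind == model.kind
    assert back.feature_dim == model.feature_dim
    assert predict_table(back, t) == predict_table(model, t)
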