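"""Published clinical benchmark values used as worked-example inputs.

A training-performance table (per segmentation method, classifier, and K in
{8, 10, 12, 15}) and a 42-image test confusion matrix.  These printed
numbers serve as inputs to the metric and aggregation arithmetic; the
expected aggregates below them are the values printed alongside the table.
"""

K_LIST = (8, 10, 12, 15)

# {segmentation: {classifier: {metric: [value at K=8, 10, 12, 15]}}}
TRAINING_TABLE = {
    "kmeans": {
        "tree": {
            "accuracy": [86.67, 88.33, 80, 75],
            "specificity": [83.33, 90, 76.67, 73.33],
            "sensitivity": [90, 86.67, 83.33, 76.67],
        },
        "nb": {
            "accuracy": [75, 83.33, 76.67, 73.33],
            "specificity": [73.33, 80, 80, 66.67],
            "sensitivity": [76.67, 86.67, 73.33, 80],
        },
        "mlp": {
            "accuracy": [88.33, 91.67, 80, 81.67],
            "specificity": [86.67, 90, 76.67, 83.33],
            "sensitivity": [90, 93.33, 83.33, 80],
        },
    },
    "fcm": {
        "tree": {
            "accuracy": [78.33, 75, 63.33, 71.67],
            "specificity": [83.33, 70, 70, 76.67],
            "sensitivity": [73.33, 80, 56.67, 66.67],
        },
        "nb": {
            "accuracy": [80, 70, 73.33, 73.33],
            "specificity": [80, 73.33, 63.33, 70],
            "sensitivity": [80, 66.67, 83.33, 76.67],
        },
        "mlp": {
            "accuracy": [81.67, 68.33, 83.33, 85],
            "specificity": [83.33, 70, 80, 83.33],
            "sensitivity": [80, 66.67, 86.67, 86.67],
        },
    },
}

EXPECTED_AVERAGE = {
    ("kmeans", "tree"): 82.50,
    ("kmeans", "nb"): 77.08,
    ("kmeans", "mlp"): 85.42,
    ("fcm", "tree"): 72.08,
    ("fcm", "nb"): 74.17,
    ("fcm", "mlp"): 79.58,
}

EXPECTED_GLOBAL = {"kmeans": 81.67, "fcm": 75.28}

# Test confusion matrix: rows prediction, columns actual, osteoporosis positive.
TEST_CONFUSION = {"tp": 18, "fn": 2, "fp": 2, "tn": 20}


def table_cells() -> dict:
    """The printed table as {(segmentation, classifier, K, metric): value}."""
    cells = {}
    for seg, classifiers in TRAINING_TABLE.items():
        for clf, metrics in classifiers.items():
            for metric, values in metrics.items():
                for k, v in zip(K_LIST, values):
                    cells[(seg, clf, k, metric)] = float(v)
    return cells
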