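"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit loops and shares no code with
the package, so it can serve as an oracle for the screening and search
stages when paired with the deterministic stub classifiers.
"""

from __future__ import annotations

import numpy as np


def threshold_predict_one(x: float, c0: float, c1: float) -> int:
    """Nearest class-mean rule on one feature; ties go to class 1."""
    return 1 if abs(x - c0) >= abs(x - c1) else 0


def threshold_accuracy(x_train, y_train, x_test, y_test) -> float:
    """Test accuracy of the midpoint-of-class-means cut, by hand."""
    c0_vals = [x for x, y in zip(x_train, y_train) if y == 0]
    c1_vals = [x for x, y in zip(x_train, y_train) if y == 1]
    if not c0_vals or not c1_vals:
        constant = y_train[0]
        return sum(1 for y in y_test if y == constant) / len(y_test)
    c0 = sum(c0_vals) / len(c0_vals)
    c1 = sum(c1_vals) / len(c1_vals)
    correct = 0
    for x, y in zip(x_test, y_test):
        if threshold_predict_one(x, c0, c1) == y:
            correct += 1
    return correct / len(y_test)


def threshold_mf(column, labels, partitions) -> float:
    """Mean holdout accuracy of one CpG under the nearest-mean stub."""
    accs = []
    for train, test in partitions:
        accs.append(
            threshold_accuracy(
                [column[i] for i in train],
                [labels[i] for i in train],
                [column[i] for i in test],
                [labels[i] for i in test],
            )
        )
    return sum(accs) / len(accs)


def majority_accuracy(y_train, y_test) -> float:
    """Majority-class predictor accuracy (training ties go to class 1)."""
    n1 = sum(1 for y in y_train if y == 1)
    n0 = len(y_train) - n1
    majority = 1 if n1 >= n0 else 0
    return sum(1 for y in y_test if y == majority) / len(y_test)


def majority_mf(labels, partitions) -> float:
    accs = []
    for train, test in partitions:
        accs.append(
            majority_accuracy([labels[i] for i in train], [labels[i] for i in test])
        )
    return sum(accs) / len(accs)


def threshold_subset_accuracy(X_train, y_train, X_test, y_test) -> float:
    """Multi-feature nearest class-centroid accuracy, by hand."""
    idx0 = [i for i, y in enumerate(y_train) if y == 0]
    idx1 = [i for i, y in enumerate(y_train) if y == 1]
    if not idx0 or not idx1:
        constant = y_train[0]
        return sum(1 for y in y_test if y == constant) / len(y_test)
    p = len(X_train[0])
    c0 = [sum(X_train[i][j] for i in idx0) / len(idx0) for j in range(p)]
    c1 = [sum(X_train[i][j] for i in idx1) / len(idx1) for j in range(p)]
    correct = 0
    for row, y in zip(X_test, y_test):
        d0 = sum((row[j] - c0[j]) ** 2 for j in range(p)) ** 0.5
        d1 = sum((row[j] - c1[j]) ** 2 for j in range(p)) ** 0.5
        pred = 1 if d0 >= d1 else 0
        if pred == y:
            correct += 1
    return correct / len(y_test)


def threshold_subset_mf(X, labels, cols, partitions) -> float:
    """Mean holdout accuracy of a column subset under the centroid stub."""
    accs = []
    for train, test in partitions:
        X_train = [[X[i][j] for j in cols] for i in train]
        X_test = [[X[i][j] for j in cols] for i in test]
        accs.append(
            threshold_subset_accuracy(
                X_train,
                [labels[i] for i in train],
                X_test,
                [labels[i] for i in test],
            )
        )
    return sum(accs) / len(accs)


def all_balanced_partitions(n_per_class: int):
    """Every way to put exactly half of each class in the training set.

    Samples 0..n-1 are class 0 and n..2n-1 class 1; yields
    (train, test) index tuples for all (n choose n/2)^2 balanced splits.
    """
    from itertools import combinations

    n = n_per_class
    half = n // 2
    for tr0 in combinations(range(n), half):
        for tr1 in combinations(range(n, 2 * n), half):
            train = tuple(sorted(tr0 + tr1))
            test = tuple(i for i in range(2 * n) if i not in train)
            yield np.array(train), np.array(test)
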