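"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration, explicit
loops, closed forms — and shares no code with the package internals.
"""

from itertools import combinations, product

import numpy as np


def lasso_bruteforce(X, y, mu):
    """Global minimizer of ||Xa - y||^2 + mu ||a||_1 by sign-support enumeration.

    Every support/sign pattern yields a candidate from the restricted
    stationarity system 2 X_S^T (X_S a - y) + mu s = 0; sign-consistent
    candidates plus the zero vector are scored and the best kept. Exact
    for generic (full-column-rank-on-support) problems with small p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def objective(a):
        r = X @ a - y
        return float(r @ r + mu * np.abs(a).sum())

    best_alpha = np.zeros(p)
    best_obj = objective(best_alpha)
    for size in range(1, p + 1):
        for support in combinations(range(p), size):
            Xs = X[:, support]
            H = Xs.T @ Xs
            g = Xs.T @ y
            for signs in product((-1.0, 1.0), repeat=size):
                s = np.array(signs)
                try:
                    a_s = np.linalg.solve(H, g - 0.5 * mu * s)
                except np.linalg.LinAlgError:
                    continue
                if np.all(np.sign(a_s) == s):
                    a = np.zeros(p)
                    a[list(support)] = a_s
                    obj = objective(a)
                    if obj < best_obj:
                        best_obj = obj
                        best_alpha = a
    return best_alpha, best_obj


def auc_concordance(y_true, scores):
    """Mann-Whitney AUC: concordant positive/negative pairs, ties count 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def knn_bruteforce(train_X, train_y, test_point, K):
    """KNN vote by explicit (distance, index) sort; returns (label, positive fraction)."""
    train_X = np.asarray(train_X, dtype=float)
    dists = [
        (float(np.linalg.norm(test_point - train_X[i])), i)
        for i in range(train_X.shape[0])
    ]
    dists.sort()  # ties resolved by the lower training index
    votes = [train_y[i] for _, i in dists[:K]]
    frac = sum(votes) / K
    return int(frac > 0.5), frac


def fisher_ratio_loop(scores, labels, eps=1e-12):
    """Direct evaluation of the Fisher ratio for one atom's score sequence.

    scores: s_j(t) over samples t; labels: the samples' classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    grand = scores.mean()
    between = 0.0
    within = 0.0
    for cls in np.unique(labels):
        sc = scores[labels == cls]
        between += (grand - sc.mean()) ** 2
        within += sum((v - sc.mean()) ** 2 for v in sc) / len(sc)
    return between / (within + eps)


def scatter_between_loop(D, labels):
    """sum_c (mean_c - grand)(mean_c - grand)^T by explicit loops (columns = samples)."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    grand = D.mean(axis=1)
    S = np.zeros((D.shape[0], D.shape[0]))
    for cls in np.unique(labels):
        mc = D[:, labels == cls].mean(axis=1)
        d = mc - grand
        S += np.outer(d, d)
    return S


def scatter_within_loop(D, labels):
    """sum_c sum_{i in c} (d_i - mean_c)(d_i - mean_c)^T by explicit loops."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    S = np.zeros((D.shape[0], D.shape[0]))
    for cls in np.unique(labels):
        cols = D[:, labels == cls]
        mc = cols.mean(axis=1)
        for i in range(cols.shape[1]):
            d = cols[:, i] - mc
            S += np.outer(d, d)
    return S
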