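"""Independent brute-force oracles used to check the fast implementations."""

import numpy as np


def brute_auc(scores, pos_mask):
    """All-pairs AUC with half credit for ties (O(n_pos * n_neg))."""
    pos = np.asarray(scores, dtype=float)[pos_mask]
    neg = np.asarray(scores, dtype=float)[~pos_mask]
    diff = pos[:, None] - neg[None, :]
    return (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg))


def brute_youden(scores, pos_mask):
    """Exhaustive threshold search; returns (best_J, threshold, sens, spec).

    Candidates are midpoints between adjacent distinct values plus +/-inf,
    with a cell called positive when score >= threshold. Ties in J are
    broken toward higher sensitivity, then lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cands = np.concatenate(([-np.inf], (uniq[1:] + uniq[:-1]) / 2, [np.inf]))
    best = None
    for t in cands:
        pred = scores >= t
        sens = np.mean(pred[pos_mask])
        spec = np.mean(~pred[~pos_mask])
        j = sens + spec - 1
        key = (-j, -sens, t)
        if best is None or key < best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return sens + spec - 1, t, sens, spec


def brute_bh(p):
    """Step-up Benjamini-Hochberg by direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def logistic_loglik(b0, b1, x, y):
    eta = b0 + b1 * x
    return np.sum(y * eta - np.log1p(np.exp(eta)))


def grid_logistic_1d(x, y, span=8.0, steps=81, refinements=4):
    """Two-parameter logistic MLE by iteratively refined grid search."""
    c0, c1 = 0.0, 0.0
    width = span
    for _ in range(refinements):
        b0s = np.linspace(c0 - width, c0 + width, steps)
        b1s = np.linspace(c1 - width, c1 + width, steps)
        ll = np.array([[logistic_loglik(a, b, x, y) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0s[i], b1s[j]
        width = width / (steps // 8)
    return c0, c1
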