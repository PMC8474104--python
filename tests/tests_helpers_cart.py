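"""Independent exhaustive-split CART reference used by the acceptance suite."""

import numpy as np


def brute_force_cart(X, y, min_node_size=5):
    def gini(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        return 1.0 - sum((np.sum(labels == c) / n) ** 2 for c in (0, 1, 2))

    def grow(idx):
        labels = y[idx]
        node = {"n": len(idx), "counts": [int(np.sum(labels == c)) for c in (0, 1, 2)]}
        if len(idx) < min_node_size or gini(labels) == 0.0:
            return node
        best = None
        for f in range(X.shape[1]):
            vals = sorted(set(X[idx, f]))
            for lo, hi in zip(vals, vals[1:]):
                t = (lo + hi) / 2.0
                left = idx[X[idx, f] <= t]
                right = idx[X[idx, f] > t]
                score = (len(left) * gini(y[left]) + len(right) * gini(y[right])) / len(idx)
                if best is None or score < best[0] - 1e-15:
                    best = (score, f, t, left, right)
        if best is None or best[0] >= gini(labels) - 1e-12:
            return node
        node.update(feature=best[1], threshold=best[2],
                    left=grow(best[3]), right=grow(best[4]))
        return node

    return grow(np.arange(len(y)))


def predict_brute(node, row):
    while "feature" in node:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    return int(np.argmax(node["counts"]))
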