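"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain
Python loops and ``math.log2`` only.
"""

import math


def entropy_direct(counts):
    n = sum(counts)
    return -sum((c / n) * math.log2(c / n) for c in counts if c > 0)


def oracle_best_split(X, y, min_gain=1e-6, min_leaf=1):
    """Exhaustive enumeration of every (feature, midpoint-threshold)
    candidate, maximising gain ratio under the mean-gain guard.

    Returns (feature_index, threshold) or None.  Ties break toward the
    lower feature index, then the lower threshold (enumeration order).
    """
    n, n_feat = X.shape
    k = int(max(y)) + 1
    parent = [int(sum(1 for v in y if v == c)) for c in range(k)]
    h_parent = entropy_direct(parent)

    candidates = []  # (j, thr, gain, split_info) in enumeration order
    for j in range(n_feat):
        vals = sorted(set(float(v) for v in X[:, j]))
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2.0
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            lc = [sum(1 for v in left if v == c) for c in range(k)]
            rc = [sum(1 for v in right if v == c) for c in range(k)]
            gain = (
                h_parent
                - (len(left) / n) * entropy_direct(lc)
                - (len(right) / n) * entropy_direct(rc)
            )
            pl, pr = len(left) / n, len(right) / n
            si = -(pl * math.log2(pl) + pr * math.log2(pr))
            candidates.append((j, thr, gain, si))

    if not candidates:
        return None
    if max(c[2] for c in candidates) < min_gain:
        return None
    positive = [c[2] for c in candidates if c[2] > 0]
    mean_gain = sum(positive) / len(positive)
    best = None
    best_ratio = -math.inf
    for j, thr, gain, si in candidates:
        if gain >= mean_gain and gain >= min_gain:
            ratio = gain / si
            if ratio > best_ratio:
                best_ratio = ratio
                best = (j, thr)
    return best
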