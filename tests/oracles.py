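"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitional formulas with plain Python
loops, deliberately sharing no code with the package implementations.
"""

from __future__ import annotations

import math

import numpy as np


def gi_star_reference(rows, cols, x, scheme="queen", include_self=True):
    """Definitional Gi* z-scores via explicit double loops over patches."""
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)

    def adjacent(i, j):
        dr = abs(rows[i] - rows[j])
        dc = abs(cols[i] - cols[j])
        if i == j:
            return include_self
        if scheme == "queen":
            return max(dr, dc) == 1
        return dr + dc == 1

    z = []
    for i in range(n):
        w_row = [1.0 if adjacent(i, j) else 0.0 for j in range(n)]
        wx = sum(w * v for w, v in zip(w_row, x))
        w_i = sum(w_row)
        u_i = sum(w * w for w in w_row)
        if s == 0:
            z.append(0.0)
            continue
        inner = (n * u_i - w_i * w_i) / (n - 1)
        denom = s * math.sqrt(inner) if inner > 0 else 0.0
        z.append((wx - xbar * w_i) / denom if denom > 0 else 0.0)
    return np.array(z)


def auc_by_pair_counting(probs, labels):
    """AUC as the exhaustive concordant-pair fraction (ties count one half)."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for pp in pos:
        for pn in neg:
            if pp > pn:
                total += 1.0
            elif pp == pn:
                total += 0.5
    return total / (len(pos) * len(neg))


def silhouette_reference(X, labels):
    """Mean silhouette coefficient from its definitional formula."""
    X = np.asarray(X, dtype=float)
    n = len(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    uniq = sorted(set(labels))
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in uniq
            if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def davies_bouldin_reference(X, labels):
    """Davies-Bouldin index: mean over clusters of the worst similarity ratio."""
    X = np.asarray(X, dtype=float)
    uniq = sorted(set(labels))
    cents = {c: X[np.array(labels) == c].mean(axis=0) for c in uniq}
    scatter = {
        c: float(np.mean(np.linalg.norm(X[np.array(labels) == c] - cents[c], axis=1)))
        for c in uniq
    }
    total = 0.0
    for ci in uniq:
        worst = max(
            (scatter[ci] + scatter[cj]) / np.linalg.norm(cents[ci] - cents[cj])
            for cj in uniq
            if cj != ci
        )
        total += worst
    return total / len(uniq)


def calinski_harabasz_reference(X, labels):
    """Calinski-Harabasz index: between/within dispersion ratio."""
    X = np.asarray(X, dtype=float)
    labels = np.array(labels)
    n = len(labels)
    uniq = sorted(set(labels))
    k = len(uniq)
    mean = X.mean(axis=0)
    between = sum(
        (labels == c).sum() * float(((X[labels == c].mean(axis=0) - mean) ** 2).sum())
        for c in uniq
    )
    within = sum(
        float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
        for c in uniq
    )
    return (between / (k - 1)) / (within / (n - k))


def net_benefit_by_counting(probs, labels, threshold):
    """Decision-curve net benefit at one threshold by explicit enumeration."""
    n = len(labels)
    tp = sum(1 for p, y in zip(probs, labels) if p >= threshold and y == 1)
    fp = sum(1 for p, y in zip(probs, labels) if p >= threshold and y == 0)
    return tp / n - (fp / n) * threshold / (1 - threshold)


def join_count_like_pairs(mask_positions, positive):
    """Fraction of rook-adjacent tissue pairs with equal binary labels."""
    pos = {coord: v for coord, v in zip(mask_positions, positive)}
    like = total = 0
    for (r, c), v in pos.items():
        for dr, dc in ((0, 1), (1, 0)):
            other = pos.get((r + dr, c + dc))
            if other is not None:
                total += 1
                like += int(other == v)
    return like / total if total else float("nan")
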