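"""Independent oracles and small generators shared across the test suite."""

from __future__ import annotations

import numpy as np

from geudpred.dvh import CumulativeDVH


def pair_count_auc(scores, labels) -> float:
    """Brute-force tie-corrected AUC: concordant pairs plus half the tied
    pairs over all positive x negative pairs.  O(m*n); the oracle against
    which the rank-based implementation is checked."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    """Exhaustive threshold scan for max J; returns (cutoff, J).

    Candidates are the lowest score (classify-all-positive) and midpoints
    between adjacent distinct scores; rule score >= cutoff; ties in J keep
    the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    u = np.unique(scores)
    candidates = np.concatenate(([u[0]], 0.5 * (u[:-1] + u[1:])))
    best_c, best_j = None, -np.inf
    for c in candidates:
        pred = scores >= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = float(c), float(j)
    return best_c, best_j


def random_cdvh(rng: np.random.Generator, max_edges: int = 40) -> CumulativeDVH:
    """A random valid cumulative DVH ending at zero volume."""
    n_bins = int(rng.integers(2, max_edges))
    width = float(rng.choice([0.5, 1.0, 2.0]))
    edges = width * np.arange(n_bins + 1)
    bins = rng.gamma(1.0, 10.0, size=n_bins)
    bins[rng.random(n_bins) < 0.2] = 0.0  # flat segments
    if bins.sum() == 0:
        bins[0] = 1.0
    vol = np.concatenate((np.cumsum(bins[::-1])[::-1], [0.0]))
    return CumulativeDVH(edges, vol)


def random_scores_labels(rng: np.random.Generator, max_n: int = 30):
    """Random score/label sets with heavy ties and both classes present."""
    n = int(rng.integers(4, max_n + 1))
    if rng.random() < 0.5:
        scores = rng.integers(0, 6, size=n).astype(float)  # many ties
    else:
        scores = np.round(rng.normal(60, 5, size=n), 1)
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1  # guarantee both classes
    return scores, labels
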