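"""Independent brute-force oracles used to check the implementation.

Everything here deliberately avoids the package's own code paths: the
logistic oracle maximizes the exact log-likelihood by dense grid search
plus local refinement, the AUC oracle counts pairs in O(n^2), the
dispersion and stability oracles transcribe the definitions with explicit
loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def loglik(a: float, b: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = a + b * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def profile_over_intercept(b: float, x: np.ndarray, y: np.ndarray) -> float:
    res = minimize_scalar(lambda a: -loglik(a, b, x, y), bracket=(-5.0, 5.0))
    return -res.fun


def grid_search_logistic_slope(x: np.ndarray, y: np.ndarray) -> float:
    """ML slope of logit P(y=1) = a + b x by grid search then refinement."""
    grid = np.arange(-20.0, 20.0 + 1e-9, 0.05)
    values = [profile_over_intercept(b, x, y) for b in grid]
    b0 = grid[int(np.argmax(values))]
    res = minimize_scalar(
        lambda b: -profile_over_intercept(b, x, y),
        bounds=(b0 - 0.1, b0 + 0.1),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def brute_force_auc(scores, labels) -> float:
    """Concordance probability by explicit pair counting, ties = half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def brute_force_top_variance(matrix, k: int) -> set:
    """Top-k genes by sample variance, ties by lexicographic gene id."""
    stats = []
    for gene in matrix.columns:
        v = matrix[gene].to_numpy()
        mean = v.sum() / len(v)
        var = ((v - mean) ** 2).sum() / (len(v) - 1)
        stats.append((-var, str(gene), gene))
    stats.sort()
    return {g for _, _, g in stats[:k]}


def brute_force_spearman(x, y) -> float:
    """Mid-rank Spearman rho as Pearson correlation of ranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def brute_force_stability_m(quantities) -> dict:
    """GeNorm M by direct transcription of the pairwise-variation definition."""
    genes = list(quantities.columns)
    n = quantities.shape[0]
    m = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                math.log2(quantities[j].iloc[s] / quantities[k].iloc[s])
                for s in range(n)
            ]
            mean = sum(ratios) / n
            sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1))
            vs.append(sd)
        m[j] = sum(vs) / len(vs)
    return m
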