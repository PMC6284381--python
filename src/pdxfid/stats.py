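"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["binomial_tail", "poisson_binomial_tail", "pearson_r", "wilcoxon_paired_p"]


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    Stable for small p; P(X >= 0) is 1 by definition.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p))


def poisson_binomial_tail(probs, k: int) -> float:
    """P(X >= k) where X is a sum of independent Bernoulli(p_i).

    Exact dynamic-programming convolution over the success-count
    distribution; O(n^2), intended for n up to a few hundred.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    n = len(probs)
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y)[0])


def wilcoxon_paired_p(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Identical pairs throughout yield p = 1 by convention (there is no
    evidence of a shift when every difference is zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)
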