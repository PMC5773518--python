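"""Small-sample nonparametric statistics used by the panel analyses."""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

__all__ = ["wilcoxon_signed_rank"]


def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided signed-rank p by dynamic programming.

    ``ranks2`` are the |difference| ranks doubled so mid-ranks from ties
    become integers; the null assigns each rank a + sign independently with
    probability 1/2.  Enumerates the distribution of twice the positive-rank
    sum by convolution over the 2^n sign patterns.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_patterns = 2.0 ** len(ranks2)
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(values, mu0: float = 0.0, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank test of ``values`` against ``mu0``.

    Zero differences are dropped (Wilcoxon's rule) and ties mid-ranked.
    The null distribution is enumerated exactly for n <= ``exact_max_n``
    (valid with ties); larger samples use the normal approximation with
    continuity and tie corrections.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        return _exact_two_sided_p(ranks2, int(round(2 * w_plus)))
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    t = tie_counts.astype(float)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / math.sqrt(var)
    return float(min(1.0, 2.0 * (1.0 - _phi(abs(z)))))


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
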