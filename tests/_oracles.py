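"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and the libraries' algorithms)
they validate: the KS oracle enumerates label assignments, the folding
oracle enumerates secondary structures, and the AUC oracle counts
concordant pairs directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_ALLOWED_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def ks_statistic_bruteforce(x, y) -> float:
    """D = sup |ECDF_x - ECDF_y| evaluated at every pooled point."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pts = np.concatenate([x, y])
    d = 0.0
    for p in pts:
        d = max(d, abs(np.mean(x <= p) - np.mean(y <= p)))
    return d


def ks_exact_p_bruteforce(x, y) -> float:
    """Exact permutation p: enumerate all C(nx+ny, nx) group assignments.

    p = fraction of assignments whose D is >= the observed D (the
    observed assignment is included, so p > 0).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sort(np.concatenate([x, y]))
    n = nx + ny
    d_obs = ks_statistic_bruteforce(x, y)
    hits = total = 0
    for xi in combinations(range(n), nx):
        in_x = np.zeros(n, dtype=bool)
        in_x[list(xi)] = True
        # ECDF difference only changes at pooled points, scanned in order
        cx = np.cumsum(in_x) / nx
        cy = np.cumsum(~in_x) / ny
        d = np.max(np.abs(cx - cy))
        total += 1
        if d >= d_obs - 1e-12:
            hits += 1
    return hits / total


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Max pairs over ALL nested structures, by explicit enumeration.

    Recursively generates every pseudoknot-free structure (each position
    unpaired or paired outward with a compatible partner at distance
    > min_loop) and takes the max pair count. Exponential; for short
    sequences only.
    """

    def counts(lo: int, hi: int):
        if hi - lo <= min_loop:
            yield 0
            return
        yield from counts(lo + 1, hi)  # lo unpaired
        for k in range(lo + min_loop + 1, hi):
            if (seq[lo], seq[k]) in _ALLOWED_PAIRS:
                for inner in counts(lo + 1, k):
                    for outer in counts(k + 1, hi):
                        yield 1 + inner + outer

    return max(counts(0, len(seq)))


def auc_concordance(scores, labels) -> float:
    """P(positive outranks negative) by direct pair counting, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total
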