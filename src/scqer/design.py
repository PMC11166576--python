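"""Closed-form design calculations for barcoded reporter libraries.

With reporters integrated at multiplicity-of-integration (MOI) ``k`` drawn
uniformly from a library of ``n`` distinct oBC-CRE-mBC triplets, the chance
that some triplet lands in the same cell twice is the classic birthday
probability. A duplicated triplet is undesirable because the two integrations
are indistinguishable by barcode, conflating their positional effects.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "duplicate_integration_probability",
    "poisson_duplicate_integration_probability",
]


def duplicate_integration_probability(n_triplets: int, moi: int) -> float:
    """Probability that >=1 triplet is integrated more than once in a cell.

    Exact birthday computation for ``moi`` independent uniform draws from a
    library of ``n_triplets`` distinct triplets:

        P(dup) = 1 - prod_{i=0}^{moi-1} (1 - i / n_triplets)

    Parameters
    ----------
    n_triplets : int
        Number of distinct triplets in the integrated library.
    moi : int
        Number of integrations in the cell.

    Returns
    -------
    float
        Per-cell probability of at least one duplicated triplet.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    if moi < 0:
        raise ValueError("moi must be >= 0")
    if moi > n_triplets:
        return 1.0
    i = np.arange(moi, dtype=float)
    # log-space product for numerical stability at large moi
    return float(-np.expm1(np.log1p(-i / n_triplets).sum()))


def poisson_duplicate_integration_probability(
    n_triplets: int, moi_mean: float, zero_truncated: bool = True, kmax: int | None = None
) -> float:
    """Duplicate probability averaged over a (zero-truncated) Poisson MOI.

    Cells receive a Poisson-distributed number of integrations; profiled cells
    carry at least one (zero truncation). The per-cell duplicate probability is
    the birthday probability averaged over that MOI distribution.
    """
    if moi_mean <= 0:
        raise ValueError("moi_mean must be > 0")
    from scipy import stats as sps

    kmax = kmax or int(moi_mean + 12 * np.sqrt(moi_mean) + 12)
    k = np.arange(1 if zero_truncated else 0, kmax + 1)
    w = sps.poisson.pmf(k, moi_mean)
    w /= w.sum()
    p = np.array([duplicate_integration_probability(n_triplets, int(ki)) for ki in k])
    return float(np.dot(w, p))
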