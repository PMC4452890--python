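"""Monte-Carlo power of the co-occurrence test via Fisher's exact test.

The observed counts define a two-binomial alternative: group 1 — the K pool
members associated with GO1 — with success probability p1 = k/K, and group 2
— the remaining N-K — with p2 = (n-k)/(N-K). Each simulation draws the two
counts, forms the 2x2 table and applies Fisher's exact test at level alpha;
power is the rejection fraction over ``n_sims`` simulations (1000 by
default, giving a binomial standard error of at most sqrt(0.25/1000) ~
0.0158). The default is the two-sided test; one-sided alternatives
(``less`` = GO2 depleted among GO1-associated members, the direction a
dissimilar pair shows; ``greater`` = enrichment) are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import hypergeom

from .cooccurrence import CooccurrenceCounts

Alternative = Literal["two-sided", "less", "greater"]


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection fraction over n_sims simulated tables; power*n_sims is integral."""

    power: float
    n_sims: int
    alpha: float
    seed: int
    counts: CooccurrenceCounts
    degenerate: bool = False
    alternative: Alternative = "two-sided"


def fisher_exact_pvalues(
    x1: np.ndarray | int,
    size1: int,
    x2: np.ndarray | int,
    size2: int,
    alternative: Alternative = "two-sided",
) -> np.ndarray:
    """Vectorised Fisher exact p-values for 2x2 tables with fixed group sizes.

    Conditional on the margins, the group-1 count is hypergeometric with
    population size1+size2, size1 draws and x1+x2 successes. One-sided
    p-values are the corresponding CDF/upper tail; the two-sided p-value sums
    every table probability not exceeding the observed one (the convention
    of R's ``fisher.test``).
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=np.int64))
    x2 = np.atleast_1d(np.asarray(x2, dtype=np.int64))
    m = x1 + x2
    pop = size1 + size2
    if alternative == "less":
        return hypergeom.cdf(x1, pop, m, size1)
    if alternative == "greater":
        return hypergeom.sf(x1 - 1, pop, m, size1)
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")

    pvals = np.empty(x1.shape, dtype=float)
    for m_val in np.unique(m):
        idx = m == m_val
        lo = max(0, m_val - size2)
        hi = min(size1, m_val)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, pop, m_val, size1)
        obs = pmf[x1[idx] - lo]
        # relative tolerance guards against ties broken by rounding
        pvals[idx] = (pmf * (pmf[None, :] <= obs[:, None] * (1 + 1e-7))).sum(axis=1)
    return np.minimum(pvals, 1.0)


def fisher_power(
    counts: CooccurrenceCounts,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    alternative: Alternative = "two-sided",
) -> PowerEstimate:
    """Simulated power of Fisher's exact test at the observed design.

    Deterministic given ``seed``; there is no hidden global randomness. A
    degenerate design (p1 = p2 = 0 or 1) still reports its rejection
    fraction but carries ``degenerate=True``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    K, N = counts.K, counts.N
    size2 = N - K
    if K < 1 or size2 < 1:
        raise ValueError("power needs both groups non-empty (K >= 1 and N-K >= 1)")
    p1 = counts.k / K
    p2 = (counts.n - counts.k) / size2
    degenerate = p1 == p2 and p1 in (0.0, 1.0)

    rng = np.random.default_rng(seed)
    x1 = rng.binomial(K, p1, size=n_sims)
    x2 = rng.binomial(size2, p2, size=n_sims)
    pvals = fisher_exact_pvalues(x1, K, x2, size2, alternative=alternative)
    power = float(np.count_nonzero(pvals < alpha)) / n_sims
    return PowerEstimate(
        power=power,
        n_sims=n_sims,
        alpha=alpha,
        seed=seed,
        counts=counts,
        degenerate=degenerate,
        alternative=alternative,
    )
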