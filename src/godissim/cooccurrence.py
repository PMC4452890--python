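"""Low-tail hypergeometric co-occurrence of a GO term pair.

The model: draw the proteins (AP mode) or interactions (IP mode) associated
with GO2 from a pool of size N of which K are associated with GO1; the number
X associated with both then follows a hypergeometric law,

    P(X <= k0) = sum_{k=0..k0} C(K,k) C(N-K, n-k) / C(N,n)

A small low tail means the two terms co-occur far less often than chance —
the terms are functionally *dissimilar* (category ``Dissimilar`` when
``p_low`` falls strictly below the threshold, default 0.05). The pool is
restricted to entities that can express co-occurrence at all: proteins with
at least two distinct direct annotations in the namespace (or one in each
namespace for a cross-ontology pair); in IP mode, edges whose endpoints both
pass that rule. K, n and k are counted over PROPAGATED annotations within
the pool, so a parent term inherits its descendants' proteins (true-path
rule) and K, n <= N always holds.

Jaccard index and Cohen's kappa of the same pooled 2x2 membership table are
reported alongside the probability, so all statistics share one universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.stats import hypergeom

from .annotations import AnnotationTable, eligible_proteins
from .errors import EmptyPoolError, NotAnnotatedError
from .interactome import InteractionNetwork
from .ontology import OntologyGraph

Mode = Literal["AP", "IP"]
Category = Literal["Dissimilar", "NotDissimilar", "NA"]


@dataclass(frozen=True)
class CooccurrenceCounts:
    """The quadruple (N, K, n, k) of the hypergeometric model for one pair.

    N: pool size (eligible proteins in AP mode, eligible edges in IP mode);
    K: pool members associated with GO1; n: with GO2; k: with both.
    Symmetric under swapping the two terms: (N, K, n, k) <-> (N, n, K, k).
    """

    N: int
    K: int
    n: int
    k: int
    mode: Mode = "AP"
    namespaces: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("N", "K", "n", "k"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need K, n in [0, N]: {self}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"need 0 <= k <= min(K, n): {self}")

    def swapped(self) -> "CooccurrenceCounts":
        return CooccurrenceCounts(self.N, self.n, self.K, self.k, self.mode, self.namespaces)


@dataclass
class PairResult:
    """All reported statistics for one (GO1, GO2, mode) query."""

    go1: str
    go2: str
    mode: Mode
    counts: CooccurrenceCounts | None = None
    p_low: float | None = None
    expected: float | None = None
    category: str = "NA"
    jaccard: float | None = None
    kappa: float | None = None
    threshold: float = 0.05
    power: float | None = None
    power_seed: int | None = None
    error: str | None = None


def _resolve_pair(go1: str, go2: str, graph: OntologyGraph) -> tuple[str, str, tuple[str, ...]]:
    t1 = graph.resolve(go1)
    t2 = graph.resolve(go2)
    if graph.terms[t1].obsolete or graph.terms[t2].obsolete:
        obsolete = t1 if graph.terms[t1].obsolete else t2
        raise NotAnnotatedError(f"{obsolete} is obsolete and annotates no current protein")
    if t1 == t2:
        raise ValueError(f"co-occurrence needs two distinct terms, got {go1}/{go2}")
    ns1, ns2 = graph.namespace(t1), graph.namespace(t2)
    namespaces = (ns1,) if ns1 == ns2 else (ns1, ns2)
    return t1, t2, namespaces


def _check_annotated(term: str, table: AnnotationTable) -> None:
    if not table.by_term_full.get(term):
        raise NotAnnotatedError(f"{term} annotates no protein in this species")


def ap_counts(
    go1: str, go2: str, table: AnnotationTable, graph: OntologyGraph
) -> CooccurrenceCounts:
    """Annotation-mode counts: pool members are eligible proteins.

    NA-signalling errors: unknown/obsolete term, a term annotating zero
    proteins in the species, or an empty eligibility pool.
    """
    t1, t2, namespaces = _resolve_pair(go1, go2, graph)
    _check_annotated(t1, table)
    _check_annotated(t2, table)
    pool = eligible_proteins(table, namespaces[0] if len(namespaces) == 1 else namespaces)
    if not pool:
        raise EmptyPoolError(f"no eligible proteins for namespaces {namespaces}")
    set1 = table.by_term_full.get(t1, set()) & pool
    set2 = table.by_term_full.get(t2, set()) & pool
    return CooccurrenceCounts(
        N=len(pool), K=len(set1), n=len(set2), k=len(set1 & set2),
        mode="AP", namespaces=namespaces,
    )


def ip_counts(
    go1: str,
    go2: str,
    table: AnnotationTable,
    network: InteractionNetwork,
    graph: OntologyGraph,
    both_endpoints_eligible: bool = True,
    distinct_endpoints: bool = False,
) -> CooccurrenceCounts:
    """Interaction-mode counts: pool members are eligible network edges.

    An edge enters the pool when both endpoints individually satisfy the
    direct-annotation eligibility rule (set ``both_endpoints_eligible=False``
    for the one-endpoint reading). K counts pool edges with GO1 on at least
    one endpoint (propagated), n likewise for GO2, and k counts edges u–v
    with GO1 on u and GO2 on v for some ordering of the endpoints (with
    ``distinct_endpoints=True``, u and v must supply the two terms from
    genuinely different endpoint/term pairings — an edge counts only if one
    endpoint carries GO1 and the *other* carries GO2). Each edge contributes
    at most once to each count.
    """
    t1, t2, namespaces = _resolve_pair(go1, go2, graph)
    _check_annotated(t1, table)
    _check_annotated(t2, table)
    eligible = eligible_proteins(table, namespaces[0] if len(namespaces) == 1 else namespaces)
    prop = table.propagated
    empty: set[str] = set()

    N = K = n = k = 0
    for u, v in network.graph.edges:
        if both_endpoints_eligible:
            if u not in eligible or v not in eligible:
                continue
        elif u not in eligible and v not in eligible:
            continue
        N += 1
        pu = prop.get(u, empty)
        pv = prop.get(v, empty)
        has1 = t1 in pu or t1 in pv
        has2 = t2 in pu or t2 in pv
        if has1:
            K += 1
        if has2:
            n += 1
        if distinct_endpoints:
            hit = (t1 in pu and t2 in pv) or (t1 in pv and t2 in pu)
        else:
            hit = has1 and has2
        if hit:
            k += 1
    if N == 0:
        raise EmptyPoolError(f"no eligible interactions for namespaces {namespaces}")
    return CooccurrenceCounts(N=N, K=K, n=n, k=k, mode="IP", namespaces=namespaces)


def hypergeom_low_tail(counts: CooccurrenceCounts) -> float:
    """P(X <= k) under the hypergeometric null; symmetric in (K, n)."""
    if counts.N < 1:
        raise ValueError("pool must contain at least one member")
    # canonical argument order makes the (K, n) swap symmetry exact in floats
    lo, hi = sorted((counts.K, counts.n))
    p = float(hypergeom.cdf(counts.k, counts.N, lo, hi))
    return min(max(p, 0.0), 1.0)


def expected_count(counts: CooccurrenceCounts) -> float:
    """Expected number of co-occurrences under independence: K*n/N."""
    if counts.N < 1:
        raise ValueError("pool must contain at least one member")
    return counts.K * counts.n / counts.N


def classify(p_low: float | None, threshold: float = 0.05) -> Category:
    """Dissimilar iff p_low < threshold (strict); ties are NotDissimilar."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if p_low is None:
        return "NA"
    return "Dissimilar" if p_low < threshold else "NotDissimilar"


def jaccard(counts: CooccurrenceCounts) -> float | None:
    """k / (K + n - k); absent when both member sets are empty."""
    denom = counts.K + counts.n - counts.k
    if denom < 1:
        return None
    return counts.k / denom


def cohens_kappa(counts: CooccurrenceCounts) -> float | None:
    """Cohen's kappa of the pooled 2x2 membership table.

    Rows/columns are GO1/GO2 membership: both = k, only-GO1 = K-k,
    only-GO2 = n-k, neither = N-K-n+k. Absent when chance agreement is
    exactly 1 (both margins degenerate).
    """
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    if N < 2:
        raise ValueError("kappa needs a pool of at least two members")
    p_o = (k + (N - K - n + k)) / N
    p_e = (K * n + (N - K) * (N - n)) / (N * N)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def pair_result(
    go1: str,
    go2: str,
    counts: CooccurrenceCounts,
    threshold: float = 0.05,
) -> PairResult:
    """Assemble the full statistics record from one set of counts."""
    p = hypergeom_low_tail(counts)
    return PairResult(
        go1=go1,
        go2=go2,
        mode=counts.mode,
        counts=counts,
        p_low=p,
        expected=expected_count(counts),
        category=classify(p, threshold),
        jaccard=jaccard(counts),
        kappa=cohens_kappa(counts),
        threshold=threshold,
    )
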