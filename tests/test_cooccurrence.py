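"""The hypergeometric co-occurrence model and its companion statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from godissim.annotations import eligible_proteins
from godissim.cooccurrence import (
    CooccurrenceCounts,
    ap_counts,
    classify,
    cohens_kappa,
    expected_count,
    hypergeom_low_tail,
    ip_counts,
    jaccard,
)
from godissim.errors import NASignal


def _c(N, K, n, k, mode="AP"):
    return CooccurrenceCounts(N=N, K=K, n=n, k=k, mode=mode)


def low_tail_oracle(N, K, n, k):
    """Exhaustive enumeration of Eq-style binomial-coefficient sums (exact integers)."""
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k + 1)
              if n - j <= N - K)
    return num / math.comb(N, n)


def test_full_support_is_certain():
    assert hypergeom_low_tail(_c(10, 4, 3, 3)) == pytest.approx(1.0)


def test_zero_overlap_closed_form():
    # P(X=0) = C(6,3)/C(10,3) = 20/120
    assert hypergeom_low_tail(_c(10, 4, 3, 0)) == pytest.approx(20 / 120, abs=1e-12)


def test_worked_example_counts():
    counts = _c(17866, 116, 459, 25)
    assert round(hypergeom_low_tail(counts), 2) == 1.00
    assert expected_count(counts) == pytest.approx(2.98, abs=0.005)
    assert round(expected_count(counts)) == 3
    assert jaccard(counts) == pytest.approx(25 / 550, abs=1e-9)


def test_low_tail_matches_enumeration_exhaustively():
    # every valid (N, K, n, k) with N <= 12, plus spot checks above
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                cdf = hypergeom.cdf(np.arange(min(K, n) + 1), N, K, n)
                for k in range(min(K, n) + 1):
                    assert abs(cdf[k] - low_tail_oracle(N, K, n, k)) < 1e-12


@given(st.integers(1, 30), st.data())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_low_tail_oracle_and_normalization(N, data):
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(0, min(K, n)))
    counts = _c(N, K, n, k)
    assert abs(hypergeom_low_tail(counts) - low_tail_oracle(N, K, n, k)) < 1e-12
    lo, hi = max(0, n - (N - K)), min(K, n)
    total = float(hypergeom.pmf(np.arange(lo, hi + 1), N, K, n).sum())
    assert abs(total - 1.0) < 1e-9
    # symmetry under (K, n) swap
    assert hypergeom_low_tail(counts.swapped()) == pytest.approx(
        hypergeom_low_tail(counts), abs=1e-12
    )


def test_low_tail_monotone_in_k():
    vals = [hypergeom_low_tail(_c(40, 12, 9, k)) for k in range(10)]
    assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("bad", [
    dict(N=10, K=11, n=3, k=0),
    dict(N=10, K=4, n=3, k=4),
    dict(N=10, K=4, n=3, k=-1),
])
def test_invalid_counts_rejected(bad):
    with pytest.raises(ValueError):
        CooccurrenceCounts(mode="AP", **bad)


def test_expected_count_zero_when_K_zero():
    assert expected_count(_c(10, 0, 3, 0)) == 0.0


def test_classification_is_strict_at_threshold():
    assert classify(7.5e-33, 0.05) == "Dissimilar"
    assert classify(0.05, 0.05) == "NotDissimilar"
    assert classify(None, 0.05) == "NA"


def test_jaccard_bounds():
    assert jaccard(_c(10, 4, 3, 0)) == 0.0
    assert jaccard(_c(10, 3, 3, 3)) == 1.0
    assert jaccard(_c(10, 0, 0, 0)) is None


def test_kappa_perfect_agreement():
    assert cohens_kappa(_c(10, 3, 3, 3)) == pytest.approx(1.0)


def test_kappa_matches_sklearn_contingency_oracle():
    sklearn = pytest.importorskip("sklearn.metrics")
    N, K, n, k = 17866, 116, 459, 25
    both, only1, only2 = k, K - k, n - k
    neither = N - K - n + k
    labels1 = [1] * (both + only1) + [0] * (only2 + neither)
    labels2 = [1] * both + [0] * only1 + [1] * only2 + [0] * neither
    ref = sklearn.cohen_kappa_score(labels1, labels2)
    assert cohens_kappa(_c(N, K, n, k)) == pytest.approx(ref, abs=1e-12)


def test_kappa_near_zero_under_independence():
    rng = np.random.default_rng(11)
    N = 4000
    m1 = rng.random(N) < 0.3
    m2 = rng.random(N) < 0.4
    counts = _c(N, int(m1.sum()), int(m2.sum()), int((m1 & m2).sum()))
    assert abs(cohens_kappa(counts)) < 0.05


# ---------------------------------------------------------------------------
# AP / IP counting against brute-force set algebra on the fixture corpus

def _brute_ap(go1, go2, table, graph):
    ns1, ns2 = graph.namespace(go1), graph.namespace(go2)
    pool = eligible_proteins(table, ns1 if ns1 == ns2 else (ns1, ns2))
    s1 = {p for p in pool if go1 in table.propagated[p]}
    s2 = {p for p in pool if go2 in table.propagated[p]}
    return len(pool), len(s1), len(s2), len(s1 & s2)


def _brute_ip(go1, go2, table, network, graph):
    ns1, ns2 = graph.namespace(go1), graph.namespace(go2)
    pool = eligible_proteins(table, ns1 if ns1 == ns2 else (ns1, ns2))
    N = K = n = k = 0
    for u, v in network.graph.edges:
        if u not in pool or v not in pool:
            continue
        N += 1
        h1 = go1 in table.propagated[u] or go1 in table.propagated[v]
        h2 = go2 in table.propagated[u] or go2 in table.propagated[v]
        K += h1
        n += h2
        k += h1 and h2
    return N, K, n, k


def _random_annotated_pairs(table, rng, count):
    terms = sorted(t for t, prots in table.by_term_full.items() if prots)
    pairs = []
    while len(pairs) < count:
        a, b = rng.choice(terms, size=2, replace=False)
        pairs.append((str(a), str(b)))
    return pairs


def test_ap_counts_match_set_algebra(table, graph):
    rng = np.random.default_rng(3)
    for go1, go2 in _random_annotated_pairs(table, rng, 20):
        c = ap_counts(go1, go2, table, graph)
        assert (c.N, c.K, c.n, c.k) == _brute_ap(go1, go2, table, graph)


def test_ip_counts_match_edge_scan(table, network, graph):
    rng = np.random.default_rng(4)
    for go1, go2 in _random_annotated_pairs(table, rng, 20):
        c = ip_counts(go1, go2, table, network, graph)
        assert (c.N, c.K, c.n, c.k) == _brute_ip(go1, go2, table, network, graph)


def test_planted_disjoint_pair_has_zero_overlap(store, ledger):
    (d1, d2), = ledger.planted_dissimilar
    c = ap_counts(d1, d2, store.table, store.graph)
    assert c.k == 0
    assert [c.N, c.K, c.n, c.k] == ledger.planted_counts["AP"][f"{d1}|{d2}"]


def test_parent_child_pair_gives_k_equals_n(store, ledger):
    # choose an is_a child->parent edge where the child annotates someone
    for child, parent, rel in ledger.ontology_edges:
        if rel == "is_a" and ledger.term_direct.get(child) and parent in ledger.term_direct:
            c = ap_counts(parent, child, store.table, store.graph)
            assert c.k == c.n  # every child-annotated protein inherits the parent
            return
    pytest.fail("fixture has no annotated is_a edge")


def test_ip_endpoint_definition(store, ledger):
    # an edge with GO1 on one endpoint only still counts once in K, n and k
    (d1, d2), = ledger.planted_dissimilar
    (s1, s2), = ledger.planted_similar
    c = ip_counts(s1, s2, store.table, store.network, store.graph)
    assert [c.N, c.K, c.n, c.k] == ledger.planted_counts["IP"][f"{s1}|{s2}"]
    c0 = ip_counts(d1, d2, store.table, store.network, store.graph)
    assert c0.k == 0


def test_unannotated_term_signals_na(store, ledger):
    un = ledger.unannotated_terms[0]
    other = ledger.planted_dissimilar[0][0]
    with pytest.raises(NASignal):
        ap_counts(un, other, store.table, store.graph)
    with pytest.raises(NASignal):
        ip_counts(other, un, store.table, store.network, store.graph)


def test_identical_terms_rejected(store):
    t = sorted(store.table.by_term_full)[0]
    with pytest.raises(ValueError):
        ap_counts(t, t, store.table, store.graph)
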