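"""Build a species store from ontology/annotation/interactome inputs and query it.

A :class:`Store` is the in-memory product of :func:`build`: the ontology
graph, the propagated annotation table and the filtered interaction network,
plus the configuration snapshot that produced them. It persists as a
deterministic TSV bundle (sorted rows, byte-identical across rebuilds from
identical inputs) with a ``meta.json`` carrying input digests, pool counts
and the config. Pair statistics are computed lazily at query time; the
quadratic all-pairs table is opt-in.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

from . import cooccurrence as co
from .annotations import AnnotationTable, eligible_proteins, parse_gaf, propagate
from .errors import NASignal, ParseError
from .interactome import (
    DEFAULT_METHOD_WHITELIST,
    DEFAULT_TYPE_WHITELIST,
    InteractionNetwork,
    filter_binary,
    merge_redundant,
    parse_mitab,
    read_mapping,
)
from .ontology import GO_ID_RE, NAMESPACES, OntologyGraph, Term, parse_obo
from .power import fisher_power

QUERY_COLUMNS = (
    "go1", "go2", "mode", "N", "K", "n", "k", "expected",
    "p_low", "category", "jaccard", "kappa", "power", "power_seed",
)


@dataclass(frozen=True)
class BuildConfig:
    """Configuration snapshot attached to every build and query result."""

    taxon: int
    threshold: float = 0.05
    relations: tuple[str, ...] = ("is_a", "part_of")
    method_whitelist: frozenset[str] = DEFAULT_METHOD_WHITELIST
    filter_interaction_type: bool = False
    type_whitelist: frozenset[str] = DEFAULT_TYPE_WHITELIST
    ip_both_endpoints_eligible: bool = True
    ip_distinct_endpoints: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["method_whitelist"] = sorted(self.method_whitelist)
        d["type_whitelist"] = sorted(self.type_whitelist)
        d["relations"] = list(self.relations)
        return d


@dataclass
class Store:
    config: BuildConfig
    graph: OntologyGraph
    table: AnnotationTable
    network: InteractionNetwork
    meta: dict = field(default_factory=dict)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build(
    obo: str,
    gaf: str,
    mitab: str,
    mapping: str | None,
    config: BuildConfig,
    out_dir: str | None = None,
    all_pairs: bool = False,
) -> Store:
    """Run the full construction pipeline and optionally persist the store.

    A GAF that yields no rows for the configured taxon is a hard error (the
    annotation file and the configuration disagree about the species).
    """
    graph = parse_obo(obo, relations=frozenset(config.relations))
    try:
        table = parse_gaf(gaf, taxon=config.taxon)
    except ParseError as exc:
        raise ParseError(f"taxon mismatch or empty GAF for taxon {config.taxon}: {exc}") from exc
    propagate(table, graph)
    records = parse_mitab(mitab)
    network = filter_binary(
        records,
        method_whitelist=config.method_whitelist,
        type_whitelist=config.type_whitelist if config.filter_interaction_type else None,
    )
    if mapping:
        network = merge_redundant(network, read_mapping(mapping))

    meta = {
        "inputs": {
            "obo": _digest(obo),
            "gaf": _digest(gaf),
            "mitab": _digest(mitab),
            "mapping": _digest(mapping) if mapping else None,
        },
        "counts": {
            "terms": len(graph),
            "proteins": len(table.proteins),
            "edges": len(network),
            "pools": {
                ns: len(eligible_proteins(table, ns)) for ns in NAMESPACES
            },
        },
        "config": config.to_dict(),
        "built": datetime.now(timezone.utc).isoformat(),
    }
    store = Store(config=config, graph=graph, table=table, network=network, meta=meta)
    if out_dir is not None:
        save(store, out_dir, all_pairs=all_pairs)
    return store


# ---------------------------------------------------------------------------
# persistence: deterministic TSV bundle

def save(store: Store, out_dir: str, all_pairs: bool = False) -> None:
    os.makedirs(out_dir, exist_ok=True)

    with open(os.path.join(out_dir, "terms.tsv"), "w", encoding="utf-8") as fh:
        fh.write("id\tname\tnamespace\tobsolete\talt_ids\n")
        for tid in sorted(store.graph.terms):
            t = store.graph.terms[tid]
            fh.write(
                f"{t.id}\t{t.name}\t{t.namespace}\t{int(t.obsolete)}\t"
                f"{','.join(sorted(t.alt_ids))}\n"
            )
    with open(os.path.join(out_dir, "ontology_edges.tsv"), "w", encoding="utf-8") as fh:
        fh.write("child\tparent\trelation\n")
        for c, p, r in sorted(store.graph.edges):
            fh.write(f"{c}\t{p}\t{r}\n")
    with open(os.path.join(out_dir, "annotations.tsv"), "w", encoding="utf-8") as fh:
        fh.write("protein\tterm\tevidence\n")
        rows = sorted(
            (prot, term, ev)
            for prot, annots in store.table.direct.items()
            for term, ev in annots
        )
        for prot, term, ev in rows:
            fh.write(f"{prot}\t{term}\t{ev}\n")
    with open(os.path.join(out_dir, "network.tsv"), "w", encoding="utf-8") as fh:
        fh.write("a\tb\tprovenance\n")
        for u, v in sorted(store.network.edges):
            prov = ";".join(sorted(f"{s}|{m}" for s, m in store.network.provenance(u, v)))
            fh.write(f"{u}\t{v}\t{prov}\n")
    with open(os.path.join(out_dir, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(store.meta, fh, indent=1, sort_keys=True)
    if all_pairs:
        results = _all_pair_results(store)
        write_query_tsv(results, os.path.join(out_dir, "pairs.tsv"))


def load(store_dir: str) -> Store:
    """Reconstruct a Store from its TSV bundle."""
    with open(os.path.join(store_dir, "meta.json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg = dict(meta["config"])
    cfg["relations"] = tuple(cfg["relations"])
    cfg["method_whitelist"] = frozenset(cfg["method_whitelist"])
    cfg["type_whitelist"] = frozenset(cfg["type_whitelist"])
    config = BuildConfig(**cfg)

    terms: dict[str, Term] = {}
    with open(os.path.join(store_dir, "terms.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            tid, name, ns, obsolete, alt = line.rstrip("\n").split("\t")
            terms[tid] = Term(tid, name, ns, bool(int(obsolete)),
                              frozenset(alt.split(",")) if alt else frozenset())
    edges: set[tuple[str, str, str]] = set()
    with open(os.path.join(store_dir, "ontology_edges.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            c, p, r = line.rstrip("\n").split("\t")
            edges.add((c, p, r))
    graph = OntologyGraph(terms, edges, relations=frozenset(config.relations))

    table = AnnotationTable(taxon=config.taxon)
    with open(os.path.join(store_dir, "annotations.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            prot, term, ev = line.rstrip("\n").split("\t")
            table.proteins.add(prot)
            table.direct.setdefault(prot, set()).add((term, ev))
            table.by_term_direct.setdefault(term, set()).add(prot)
    propagate(table, graph)

    network = InteractionNetwork()
    with open(os.path.join(store_dir, "network.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            a, b, prov = line.rstrip("\n").split("\t")
            provenance = {
                tuple(entry.split("|", 1)) for entry in prov.split(";") if entry
            }
            network.add_interaction(a, b, provenance or {("", "")})
    return Store(config=config, graph=graph, table=table, network=network, meta=meta)


# ---------------------------------------------------------------------------
# queries

def _one_result(store: Store, go1: str, go2: str, mode: str, threshold: float) -> co.PairResult:
    if not (GO_ID_RE.match(go1) and GO_ID_RE.match(go2)):
        return co.PairResult(go1=go1, go2=go2, mode=mode, category="Error",
                             threshold=threshold, error="malformed GO identifier")
    try:
        if mode == "AP":
            counts = co.ap_counts(go1, go2, store.table, store.graph)
        else:
            counts = co.ip_counts(
                go1, go2, store.table, store.network, store.graph,
                both_endpoints_eligible=store.config.ip_both_endpoints_eligible,
                distinct_endpoints=store.config.ip_distinct_endpoints,
            )
    except NASignal as exc:
        return co.PairResult(go1=go1, go2=go2, mode=mode, category="NA",
                             threshold=threshold, error=str(exc))
    except ValueError as exc:
        return co.PairResult(go1=go1, go2=go2, mode=mode, category="Error",
                             threshold=threshold, error=str(exc))
    return co.pair_result(go1, go2, counts, threshold=threshold)


def query(
    store: Store,
    pairs: list[tuple[str, str]],
    mode: str = "both",
    threshold: float | None = None,
    power_seed: int | None = None,
    power_sims: int = 1000,
) -> list[co.PairResult]:
    """One result row per (pair, mode), in input order.

    NA semantics: a pair in which either term is unknown, obsolete, or
    annotates no protein of the species yields category NA; a syntactically
    invalid GO id yields a per-row Error marker. With ``power_seed`` set, the
    Monte-Carlo power of the one-sided Fisher test is attached to every
    computable row (each row gets a sub-seed derived from the pair index so
    results do not depend on query batching).
    """
    thr = store.config.threshold if threshold is None else threshold
    modes = ("AP", "IP") if mode == "both" else (mode.upper(),)
    results: list[co.PairResult] = []
    for go1, go2 in pairs:
        for m in modes:
            res = _one_result(store, go1, go2, m, thr)
            if power_seed is not None and res.counts is not None:
                c = res.counts
                if c.K >= 1 and c.N - c.K >= 1:
                    sub = (power_seed + 9973 * len(results)) % (2**31)
                    est = fisher_power(c, alpha=thr, n_sims=power_sims, seed=sub)
                    res.power, res.power_seed = est.power, sub
            results.append(res)
    return results


def _format(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_query_tsv(results: list[co.PairResult], path: str) -> None:
    """Fixed-column TSV: go1 go2 mode N K n k expected p_low category jaccard kappa power power_seed."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(QUERY_COLUMNS) + "\n")
        for r in results:
            c = r.counts
            row = [
                r.go1, r.go2, r.mode,
                _format(c.N if c else None), _format(c.K if c else None),
                _format(c.n if c else None), _format(c.k if c else None),
                _format(r.expected), _format(r.p_low),
                "ERROR" if r.category == "Error" else r.category,
                _format(r.jaccard), _format(r.kappa),
                _format(r.power), _format(r.power_seed),
            ]
            fh.write("\t".join(row) + "\n")


def pair_universe(store: Store) -> list[tuple[str, str]]:
    """The stated all-pairs universe: unordered pairs of distinct, non-obsolete
    terms that annotate at least one protein (same- and cross-namespace)."""
    annotated = sorted(t for t, prots in store.table.by_term_full.items() if prots)
    return list(itertools.combinations(annotated, 2))


def _all_pair_results(store: Store) -> list[co.PairResult]:
    pairs = pair_universe(store)
    return query(store, pairs, mode="both")


def summarize(store: Store, mode: str, threshold: float | None = None) -> dict[str, float]:
    """Fractions of Dissimilar / NotDissimilar / NA pairs over the all-pairs universe.

    The two headline fractions need not sum to 1: NA pairs are excluded from
    both but counted in the denominator.
    """
    pairs = pair_universe(store)
    results = query(store, pairs, mode=mode, threshold=threshold)
    n = len(results)
    if n == 0:
        return {"Dissimilar": 0.0, "NotDissimilar": 0.0, "NA": 0.0, "n_pairs": 0}
    tally = {"Dissimilar": 0, "NotDissimilar": 0, "NA": 0}
    for r in results:
        tally[r.category] = tally.get(r.category, 0) + 1
    return {
        "Dissimilar": tally["Dissimilar"] / n,
        "NotDissimilar": tally["NotDissimilar"] / n,
        "NA": tally["NA"] / n,
        "n_pairs": n,
    }
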