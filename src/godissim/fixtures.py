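"""Deterministic generator of small OBO/GAF/MITAB fixture triples.

The generator emits a miniature species: a three-namespace ontology DAG with
multi-parent nodes, a proteome with planted annotation structure, and an
interaction network with module structure aligned to the annotation groups.
Two BP term pairs are planted: a *dissimilar* pair annotating disjoint
protein groups that never interact, and a *similar* pair co-annotating one
group with a co-occurrence lift well above expectation. Deliberate noise
rows (NOT qualifiers, duplicates, isoform suffixes, off-taxon rows, an
obsolete-term annotation, an alt_id row, self-interactions, non-whitelisted
detection methods, records without UniProt cross-references, and redundant
secondary accessions) exercise every filter in the parsing modules.

A machine-readable :class:`FixtureLedger` records the ground truth the files
encode — direct annotation sets, the final edge list, eligibility pool sizes
and the planted pair counts — so tests can compare pipeline output against
generator bookkeeping without re-deriving anything.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

FIXTURE_TAXON = 9999
_NS = ("biological_process", "molecular_function", "cellular_component")
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
_EVIDENCE_CYCLE = ("IEA", "IDA", "ISS", "EXP")

#: Fixture GO ids live in a reserved high range to avoid real-term collisions.
_BASE = 9000000
OBSOLETE_TERM = "GO:9999999"
ALT_ID = "GO:9900001"


def _go(i: int) -> str:
    return f"GO:{_BASE + i:07d}"


@dataclass
class FixtureLedger:
    """Ground truth for one generated fixture triple."""

    seed: int
    taxon: int
    proteins: list[str]
    #: term id -> sorted proteins carrying it as a DIRECT annotation
    term_direct: dict[str, list[str]]
    #: term id -> namespace
    term_namespace: dict[str, str]
    #: ontology edges (child, parent, relation)
    ontology_edges: list[list[str]]
    planted_dissimilar: list[list[str]]
    planted_similar: list[list[str]]
    #: mode -> pool key ("ns" or "ns1|ns2") -> size
    pool_sizes: dict[str, dict[str, int]]
    #: planted pair counts: mode -> "go1|go2" -> [N, K, n, k]
    planted_counts: dict[str, dict[str, list[int]]]
    #: final (post-merge, post-filter) interaction edges, sorted
    edges: list[list[str]]
    #: secondary -> canonical accession mapping emitted to the mapping file
    mapping: dict[str, str] = field(default_factory=dict)
    #: terms present in the ontology but annotating no protein
    unannotated_terms: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureLedger":
        return cls(**json.loads(text))


def _sample_pairs(
    rng: np.random.Generator,
    left: list[str],
    right: list[str] | None,
    count: int,
) -> list[tuple[str, str]]:
    """Sample distinct unordered pairs, within ``left`` or across left/right."""
    if right is None:
        universe = [
            (left[i], left[j]) for i in range(len(left)) for j in range(i + 1, len(left))
        ]
    else:
        universe = [(a, b) for a in left for b in right]
    idx = rng.choice(len(universe), size=count, replace=False)
    return [tuple(sorted(universe[i])) for i in sorted(idx)]


def _closure(term: str, parents: dict[str, set[str]]) -> set[str]:
    out: set[str] = set()
    stack = [term]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def generate(
    seed: int,
    out_dir: str,
    n_terms: int = 30,
    n_proteins: int = 120,
    n_edges: int = 300,
) -> FixtureLedger:
    """Write fixture.obo / fixture.gaf / fixture.mitab / mapping.tsv + ledger.

    Deterministic: the same seed yields byte-identical files. Sizes are kept
    small enough that exhaustive brute-force oracles stay cheap.
    """
    if n_terms < 24 or n_proteins < 60 or n_edges < 60:
        raise ValueError("fixture sizes too small for the planted structure")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    # ---- ontology ------------------------------------------------------
    n_per = n_terms // 3
    ns_terms: dict[str, list[str]] = {}
    term_ns: dict[str, str] = {}
    edges_onto: list[tuple[str, str, str]] = []
    nxt = 1
    for ns in _NS:
        ids = [_go(nxt + i) for i in range(n_per)]
        nxt += n_per
        ns_terms[ns] = ids
        for t in ids:
            term_ns[t] = ns
        root, mids, leaves = ids[0], ids[1:5], ids[5:]
        for m in mids:
            edges_onto.append((m, root, "is_a"))
        for i, leaf in enumerate(leaves):
            edges_onto.append((leaf, mids[i % len(mids)], "is_a"))
        # multi-parent node and a part_of edge on the first two leaves
        edges_onto.append((leaves[0], mids[(1) % len(mids)], "is_a"))
        edges_onto.append((leaves[1], mids[(2) % len(mids)], "part_of"))
    term_ns[OBSOLETE_TERM] = "biological_process"

    bp = ns_terms["biological_process"]
    bp_leaves = bp[5:]
    d1, d2, s1_t, s2_t = bp_leaves[-4], bp_leaves[-3], bp_leaves[-2], bp_leaves[-1]
    bp_fillers = bp[1:5] + [t for t in bp_leaves if t not in {d1, d2, s1_t, s2_t}]

    # ---- protein groups and direct annotations ------------------------
    proteins = [f"P9{i:04d}" for i in range(1, n_proteins + 1)]
    n_grp = max(8, round(0.208 * n_proteins))
    grp_a = proteins[:n_grp]
    grp_b = proteins[n_grp : 2 * n_grp]
    grp_s = proteins[2 * n_grp : 3 * n_grp]
    rest = proteins[3 * n_grp :]
    a80 = round(0.8 * n_grp)
    s1_prots, s2_prots = grp_s[:a80], grp_s[n_grp - a80 :]
    # a few proteins carry only one direct BP term: excluded from the BP pool
    single_bp = rest[-5:]

    direct: dict[str, set[str]] = {p: set() for p in proteins}
    for p in grp_a:
        direct[p] |= {d1, str(rng.choice(bp_fillers))}
    for p in grp_b:
        direct[p] |= {d2, str(rng.choice(bp_fillers))}
    for p in grp_s:
        if p in s1_prots:
            direct[p].add(s1_t)
        if p in s2_prots:
            direct[p].add(s2_t)
        direct[p].add(str(rng.choice(bp_fillers)))
    for p in rest:
        k_fill = 1 if p in single_bp else 2
        for t in rng.choice(bp_fillers, size=k_fill, replace=False):
            direct[p].add(str(t))
    # the last MF leaf is reserved as a never-annotated term (NA semantics)
    unannotated = ns_terms["molecular_function"][-1]
    for p in proteins:
        for t in rng.choice(ns_terms["molecular_function"][1:-1], size=2, replace=False):
            direct[p].add(str(t))
        for t in rng.choice(ns_terms["cellular_component"][1:], size=2, replace=False):
            direct[p].add(str(t))

    # ---- interaction edges (module structure) --------------------------
    frac = n_edges / 300
    n_intra, n_rest_intra, n_bridge = round(60 * frac), round(90 * frac), round(10 * frac)
    edge_list: list[tuple[str, str]] = []
    for grp in (grp_a, grp_b, grp_s):
        edge_list += _sample_pairs(rng, grp, None, n_intra)
    edge_list += _sample_pairs(rng, rest, None, n_rest_intra)
    for grp in (grp_a, grp_b, grp_s):
        edge_list += _sample_pairs(rng, grp, rest, n_bridge)
    edges = sorted(set(edge_list))

    # ---- ledger bookkeeping (generator-side brute force) ---------------
    parents: dict[str, set[str]] = {}
    for c, p, _r in edges_onto:
        parents.setdefault(c, set()).add(p)
    propagated = {p: ts | set().union(*(_closure(t, parents) for t in ts)) for p, ts in direct.items()}

    def eligible(ns_key: tuple[str, ...]) -> set[str]:
        pool = set()
        for p, ts in direct.items():
            if len(ns_key) == 1:
                if sum(1 for t in ts if term_ns[t] == ns_key[0]) >= 2:
                    pool.add(p)
            elif all(any(term_ns[t] == ns for t in ts) for ns in ns_key):
                pool.add(p)
        return pool

    ns_keys: list[tuple[str, ...]] = [(ns,) for ns in _NS] + [
        (_NS[i], _NS[j]) for i in range(3) for j in range(i + 1, 3)
    ]
    pool_sizes: dict[str, dict[str, int]] = {"AP": {}, "IP": {}}
    pools: dict[str, set[str]] = {}
    for key in ns_keys:
        label = "|".join(key)
        pool = eligible(key)
        pools[label] = pool
        pool_sizes["AP"][label] = len(pool)
        pool_sizes["IP"][label] = sum(1 for u, v in edges if u in pool and v in pool)

    def ap_quad(t1: str, t2: str) -> list[int]:
        label = term_ns[t1] if term_ns[t1] == term_ns[t2] else f"{term_ns[t1]}|{term_ns[t2]}"
        pool = pools[label]
        s1 = {p for p in pool if t1 in propagated[p]}
        s2 = {p for p in pool if t2 in propagated[p]}
        return [len(pool), len(s1), len(s2), len(s1 & s2)]

    def ip_quad(t1: str, t2: str) -> list[int]:
        label = term_ns[t1] if term_ns[t1] == term_ns[t2] else f"{term_ns[t1]}|{term_ns[t2]}"
        pool = pools[label]
        N = K = n = k = 0
        for u, v in edges:
            if u not in pool or v not in pool:
                continue
            N += 1
            h1 = t1 in propagated[u] or t1 in propagated[v]
            h2 = t2 in propagated[u] or t2 in propagated[v]
            K += h1
            n += h2
            k += h1 and h2
        return [N, K, n, k]

    planted_dis = [[d1, d2]]
    planted_sim = [[s1_t, s2_t]]
    planted_counts = {
        "AP": {f"{a}|{b}": ap_quad(a, b) for a, b in planted_dis + planted_sim},
        "IP": {f"{a}|{b}": ip_quad(a, b) for a, b in planted_dis + planted_sim},
    }

    # ---- write OBO -----------------------------------------------------
    names = {t: f"fixture term {t[3:]}" for t in term_ns}
    alt_host = sorted(direct[rest[0]] & set(bp_fillers))[0]
    obo_path = os.path.join(out_dir, "fixture.obo")
    with open(obo_path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: godissim-fixture\n")
        for t in sorted(term_ns):
            if t == OBSOLETE_TERM:
                continue
            fh.write(f"\n[Term]\nid: {t}\nname: {names[t]}\nnamespace: {term_ns[t]}\n")
            if t == alt_host:
                fh.write(f"alt_id: {ALT_ID}\n")
            for c, p, r in edges_onto:
                if c == t:
                    if r == "is_a":
                        fh.write(f"is_a: {p} ! {names[p]}\n")
                    else:
                        fh.write(f"relationship: {r} {p} ! {names[p]}\n")
        fh.write(
            f"\n[Term]\nid: {OBSOLETE_TERM}\nname: retired fixture term\n"
            f"namespace: biological_process\nis_obsolete: true\n"
        )

    # ---- write GAF -----------------------------------------------------
    gaf_path = os.path.join(out_dir, "fixture.gaf")
    ev_i = 0

    def gaf_row(acc: str, term: str, qualifier: str = "", taxon: int = FIXTURE_TAXON,
                evidence: str | None = None, col17: str = "") -> str:
        nonlocal ev_i
        if evidence is None:
            evidence = _EVIDENCE_CYCLE[ev_i % len(_EVIDENCE_CYCLE)]
            ev_i += 1
        aspect = _ASPECT[term_ns.get(term, "biological_process")]
        return "\t".join([
            "FIX", acc, acc, qualifier, term, "FIX:0001", evidence, "", aspect,
            "", "", "protein", f"taxon:{taxon}", "20150603", "FIX", "", col17,
        ]) + "\n"

    with open(gaf_path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n!generated by godissim.fixtures\n")
        for p in proteins:
            for t in sorted(direct[p]):
                fh.write(gaf_row(p, t))
        # deliberate noise: duplicates, isoform suffix, NOT rows, off-taxon,
        # an obsolete-term annotation and an alt_id annotation
        for p in (grp_a[0], grp_b[0], grp_s[0]):
            fh.write(gaf_row(p, sorted(direct[p])[0], evidence="TAS"))
        iso_term = sorted(direct[grp_a[0]])[0]
        fh.write(gaf_row(f"{grp_a[0]}-1", iso_term, col17=f"UniProtKB:{grp_a[0]}-1"))
        fh.write(gaf_row(grp_a[0], d2, qualifier="NOT"))
        fh.write(gaf_row(grp_b[0], d1, qualifier="NOT"))
        fh.write(gaf_row(grp_s[0], d1, qualifier="NOT|involved_in"))
        for p in (grp_a[1], grp_b[1], rest[1]):
            fh.write(gaf_row(p, d1, taxon=10090))
        fh.write(gaf_row(rest[2], OBSOLETE_TERM))
        fh.write(gaf_row(rest[0], ALT_ID))

    # ---- write MITAB + mapping -----------------------------------------
    canon = rest[:3]
    mapping = {f"X9{i:04d}": c for i, c in enumerate(canon, start=1)}
    sec_of = {c: s for s, c in mapping.items()}
    substituted: dict[str, int] = {c: 0 for c in canon}

    def mitab_row(a: str, b: str, method: str, source: str, typ: str = "MI:0407",
                  raw_a: str | None = None, raw_b: str | None = None) -> str:
        ida = raw_a if raw_a is not None else f"uniprotkb:{a}"
        idb = raw_b if raw_b is not None else f"uniprotkb:{b}"
        return "\t".join([
            ida, idb, "-", "-", f"godissim:{a}", f"godissim:{b}",
            f'psi-mi:"{method}"(detection)', "-", "pubmed:12345678",
            f"taxid:{FIXTURE_TAXON}", f"taxid:{FIXTURE_TAXON}",
            f'psi-mi:"{typ}"(direct interaction)', f'psi-mi:"{source}"(source)',
            "fixture:1", "-",
        ]) + "\n"

    mitab_path = os.path.join(out_dir, "fixture.mitab")
    with open(mitab_path, "w", encoding="utf-8") as fh:
        fh.write("#ID(s) interactor A\tID(s) interactor B\t...\n")
        for i, (u, v) in enumerate(edges):
            method = "MI:0018" if i % 2 == 0 else "MI:0090"
            source = "MI:0469" if i % 3 else "MI:0463"
            # a few edges are reported under the redundant secondary accession
            a, b = u, v
            if u in sec_of and substituted[u] < 2:
                a = sec_of[u]
                substituted[u] += 1
            elif v in sec_of and substituted[v] < 2:
                b = sec_of[v]
                substituted[v] += 1
            fh.write(mitab_row(a, b, method, source))
        # duplicates in reversed order from a second source database
        for u, v in edges[:10]:
            fh.write(mitab_row(v, u, "MI:0018", "MI:0463"))
        # self-interactions (discarded downstream)
        for p in grp_a[:5]:
            fh.write(mitab_row(p, p, "MI:0018", "MI:0469"))
        # non-whitelisted co-complex method between never-interacting groups
        for u, v in zip(grp_a[:6], grp_b[:6]):
            fh.write(mitab_row(u, v, "MI:0004", "MI:0469"))
        # records without a uniprotkb cross-reference
        fh.write(mitab_row("", "", "MI:0018", "MI:0469",
                           raw_a="genecards:FOO1", raw_b=f"uniprotkb:{grp_a[0]}"))
        fh.write(mitab_row("", "", "MI:0018", "MI:0469",
                           raw_a="genecards:FOO2", raw_b="genecards:FOO3"))
        # secondary-canonical pair that collapses to a self-loop after merging
        fh.write(mitab_row(sorted(mapping)[0], canon[0], "MI:0018", "MI:0469"))

    map_path = os.path.join(out_dir, "mapping.tsv")
    with open(map_path, "w", encoding="utf-8") as fh:
        for sec in sorted(mapping):
            fh.write(f"{sec}\t{mapping[sec]}\n")

    ledger = FixtureLedger(
        seed=seed,
        taxon=FIXTURE_TAXON,
        proteins=proteins,
        term_direct={
            t: sorted(p for p in proteins if t in direct[p])
            for t in sorted(term_ns) if t != OBSOLETE_TERM
        },
        term_namespace=dict(sorted(term_ns.items())),
        ontology_edges=sorted([c, p, r] for c, p, r in edges_onto),
        planted_dissimilar=planted_dis,
        planted_similar=planted_sim,
        pool_sizes=pool_sizes,
        planted_counts=planted_counts,
        edges=[list(e) for e in edges],
        mapping=mapping,
        unannotated_terms=[unannotated],
    )
    with open(os.path.join(out_dir, "ledger.json"), "w", encoding="utf-8") as fh:
        fh.write(ledger.to_json())
    return ledger
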