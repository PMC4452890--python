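"""GAF parsing, annotation propagation and eligibility pools.

Direct annotations are the rows of the GAF file (after policy filters);
propagated annotations add every ancestor of each direct term (true-path
rule). Eligibility — membership in the pool *N* of the hypergeometric model —
is decided on DIRECT annotations only: a protein enters a single-namespace
pool with at least two distinct direct terms in that namespace, and a
cross-ontology pool with at least one direct term in each of the two
namespaces.

Policy: every evidence code is kept (electronic annotations included), rows
with a ``NOT`` qualifier are dropped, duplicate (protein, term) pairs are
collapsed, and isoform suffixes (``P12345-2``) fold into the parent
accession.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import ParseError
from .ontology import GO_ID_RE, OntologyGraph

logger = logging.getLogger(__name__)

_ISOFORM_RE = re.compile(r"-\d+$")


def _canonical_accession(accession: str) -> str:
    return _ISOFORM_RE.sub("", accession)


@dataclass
class AnnotationTable:
    """Per-protein GO annotations, direct and (after :func:`propagate`) inherited."""

    taxon: int
    proteins: set[str] = field(default_factory=set)
    #: protein -> set of (term id, evidence code), exactly as parsed
    direct: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    #: protein -> set of primary term ids after alt_id resolution (propagate fills this)
    direct_resolved: dict[str, set[str]] = field(default_factory=dict)
    #: protein -> direct ∪ all ancestors of direct terms
    propagated: dict[str, set[str]] = field(default_factory=dict)
    #: term -> proteins carrying it directly / after propagation
    by_term_direct: dict[str, set[str]] = field(default_factory=dict)
    by_term_full: dict[str, set[str]] = field(default_factory=dict)
    #: namespace of every term seen after resolution
    term_namespace: dict[str, str] = field(default_factory=dict)

    @property
    def is_propagated(self) -> bool:
        return bool(self.propagated)

    def direct_terms(self, protein: str) -> set[str]:
        """Distinct direct term ids (unresolved) for one protein."""
        return {t for t, _ev in self.direct.get(protein, set())}


def parse_gaf(path: str, taxon: int) -> AnnotationTable:
    """Read a GAF 2.x file, keeping rows of the requested NCBI taxon.

    All evidence codes are retained; ``NOT``-qualified rows are dropped;
    duplicate (protein, term) pairs collapse to the first row seen. Malformed
    rows are skipped with a logged count. Zero usable rows is a hard error —
    it usually means the file belongs to a different taxon.
    """
    taxon_tag = f"taxon:{taxon}"
    table = AnnotationTable(taxon=taxon)
    n_rows = n_malformed = n_not = n_other_taxon = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            n_rows += 1
            cols = line.split("\t")
            if len(cols) < 15:
                n_malformed += 1
                logger.warning("%s:%d: malformed GAF row (%d columns)", path, lineno, len(cols))
                continue
            accession = _canonical_accession(cols[1].strip())
            qualifier = cols[3].strip()
            go_id = cols[4].strip()
            evidence = cols[6].strip()
            taxa = cols[12].strip().split("|")
            if not accession or not GO_ID_RE.match(go_id):
                n_malformed += 1
                logger.warning("%s:%d: malformed GAF row (bad accession or GO id)", path, lineno)
                continue
            if taxon_tag not in taxa:
                n_other_taxon += 1
                continue
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            existing = table.direct.setdefault(accession, set())
            if go_id not in {t for t, _ in existing}:
                existing.add((go_id, evidence))
            table.proteins.add(accession)

    if n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, n_malformed)
    logger.info(
        "%s: %d rows, %d NOT-qualified dropped, %d other-taxon dropped",
        path, n_rows, n_not, n_other_taxon,
    )
    if not table.proteins:
        raise ParseError(
            f"{path}: no usable annotation rows for taxon {taxon} "
            f"({n_rows} rows read, {n_other_taxon} for other taxa)"
        )
    for protein, annots in table.direct.items():
        for term, _ev in annots:
            table.by_term_direct.setdefault(term, set()).add(protein)
    return table


def propagate(table: AnnotationTable, graph: OntologyGraph) -> AnnotationTable:
    """Fill inherited annotations: propagated(p) = direct(p) ∪ ancestors.

    Alt_ids are resolved to primary terms; terms missing from the ontology
    and obsolete terms are dropped with a logged count. Idempotent: the
    operation is recomputed from the direct map every time.
    """
    dropped: set[str] = set()
    table.direct_resolved = {}
    table.propagated = {}
    table.by_term_full = {}
    table.term_namespace = {}
    by_term_direct: dict[str, set[str]] = {}

    for protein, annots in table.direct.items():
        resolved: set[str] = set()
        for term, _ev in annots:
            if term not in graph:
                dropped.add(term)
                continue
            primary = graph.resolve(term)
            if graph.terms[primary].obsolete:
                dropped.add(term)
                continue
            resolved.add(primary)
        full = set(resolved)
        for term in resolved:
            full |= graph.ancestors(term)
        table.direct_resolved[protein] = resolved
        table.propagated[protein] = full
        for term in resolved:
            by_term_direct.setdefault(term, set()).add(protein)
        for term in full:
            table.by_term_full.setdefault(term, set()).add(protein)
            table.term_namespace.setdefault(term, graph.terms[term].namespace)

    table.by_term_direct = by_term_direct
    if dropped:
        logger.warning(
            "dropped %d annotation terms unknown or obsolete in the ontology: %s",
            len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    return table


def eligible_proteins(
    table: AnnotationTable, namespaces: str | tuple[str, str]
) -> set[str]:
    """The pool of the hypergeometric model, from DIRECT annotations only.

    ``namespaces`` is one namespace (proteins with ≥2 distinct direct terms
    in it) or a pair of distinct namespaces (proteins with ≥1 direct term in
    each). Propagated terms never affect eligibility.
    """
    if not table.is_propagated:
        raise ValueError("run propagate() before computing eligibility pools")
    if isinstance(namespaces, str):
        ns_pair = (namespaces, namespaces)
    else:
        ns_pair = tuple(namespaces)  # type: ignore[assignment]
        if len(ns_pair) != 2:
            raise ValueError("namespaces must be one namespace or a pair")
    ns1, ns2 = ns_pair
    pool: set[str] = set()
    for protein, terms in table.direct_resolved.items():
        if ns1 == ns2:
            n_in_ns = sum(1 for t in terms if table.term_namespace.get(t) == ns1)
            if n_in_ns >= 2:
                pool.add(protein)
        else:
            has1 = any(table.term_namespace.get(t) == ns1 for t in terms)
            has2 = any(table.term_namespace.get(t) == ns2 for t in terms)
            if has1 and has2:
                pool.add(protein)
    return pool
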