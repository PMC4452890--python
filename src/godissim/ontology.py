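"""The GO DAG: OBO parsing, alt_id resolution, ancestor queries.

The Gene Ontology is three independent rooted DAGs (biological_process,
molecular_function, cellular_component). Annotation inheritance (the
true-path rule) propagates a protein's terms to all ancestors reachable over
a configured relation set — by default ``is_a`` and ``part_of``, the GO
Consortium's standard propagation relations. ``part_of`` edges that cross
sub-ontologies are never traversed, so ancestor sets stay within one
namespace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import ObsoleteTermError, ParseError, UnknownTermError

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: Relations used for annotation propagation by default.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: Relations we recognise in OBO files; anything else is dropped with a warning.
KNOWN_RELATIONS = frozenset(
    {
        "is_a",
        "part_of",
        "regulates",
        "positively_regulates",
        "negatively_regulates",
        "occurs_in",
        "happens_during",
        "ends_during",
    }
)


@dataclass(frozen=True)
class Term:
    """One ontology term.

    ``alt_ids`` are merged/secondary identifiers that resolve to this term.
    Obsolete terms are retained so lookups can distinguish "obsolete" from
    "unknown", but they take part in no pool and no propagation.
    """

    id: str
    name: str
    namespace: str
    obsolete: bool = False
    alt_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.id):
            raise ValueError(f"malformed GO identifier: {self.id!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r} for {self.id}")


class OntologyGraph:
    """Typed parent edges over GO terms, with ancestor queries.

    Edges point child -> parent and carry a relation label. Ancestor queries
    traverse only the requested relations and never cross namespaces.
    """

    def __init__(
        self,
        terms: dict[str, Term],
        edges: set[tuple[str, str, str]],
        relations: frozenset[str] = DEFAULT_RELATIONS,
    ) -> None:
        for child, parent, _rel in edges:
            if child not in terms or parent not in terms:
                raise ValueError(f"edge endpoint missing from term set: {child}->{parent}")
        self.terms = terms
        self.edges = edges
        self.relations = frozenset(relations)
        self._alt: dict[str, str] = {}
        for term in terms.values():
            for alt in term.alt_ids:
                self._alt[alt] = term.id
        self._graph = nx.MultiDiGraph()
        self._graph.add_nodes_from(terms)
        for child, parent, rel in edges:
            self._graph.add_edge(child, parent, key=rel)
        self._anc_cache: dict[tuple[str, frozenset[str]], frozenset[str]] = {}

    # -- lookups -----------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an id (possibly an alt_id) to its primary term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise UnknownTermError(term_id)

    def get(self, term_id: str) -> Term:
        return self.terms[self.resolve(term_id)]

    def namespace(self, term_id: str) -> str:
        return self.get(term_id).namespace

    @property
    def roots(self) -> dict[str, tuple[str, ...]]:
        """Non-obsolete terms with no parent over the configured relations, per namespace."""
        out: dict[str, list[str]] = {ns: [] for ns in NAMESPACES}
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            has_parent = any(
                rel in self.relations for _, _, rel in self._graph.out_edges(tid, keys=True)
            )
            if not has_parent:
                out[term.namespace].append(tid)
        return {ns: tuple(sorted(ids)) for ns, ids in out.items() if ids}

    # -- traversal ---------------------------------------------------------

    def ancestors(self, term_id: str, relations: frozenset[str] | None = None) -> frozenset[str]:
        """All terms reachable from ``term_id`` over the given relations.

        Excludes the term itself. Cross-namespace edges (e.g. a ``part_of``
        from a BP term into CC) are not traversed, keeping propagation within
        one sub-ontology. Raises :class:`UnknownTermError` for unknown ids and
        :class:`ObsoleteTermError` for obsolete terms.
        """
        primary = self.resolve(term_id)
        term = self.terms[primary]
        if term.obsolete:
            raise ObsoleteTermError(primary)
        rels = self.relations if relations is None else frozenset(relations)
        key = (primary, rels)
        cached = self._anc_cache.get(key)
        if cached is not None:
            return cached
        ns = term.namespace
        seen: set[str] = set()
        stack = [primary]
        while stack:
            node = stack.pop()
            for _, parent, rel in self._graph.out_edges(node, keys=True):
                if rel not in rels:
                    continue
                if self.terms[parent].namespace != ns:
                    continue
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        result = frozenset(seen)
        self._anc_cache[key] = result
        return result

    # -- stats -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt


def _validate_obo_lines(path: str) -> None:
    # Cheap structural pass so malformed stanza lines fail with a line number;
    # the heavy lifting is done by obonet afterwards.
    in_term = False
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("["):
                if not stripped.endswith("]"):
                    raise ParseError(f"{path}: unparseable stanza header at line {lineno}: {line!r}")
                in_term = stripped == "[Term]"
                continue
            if ":" not in stripped:
                where = "term stanza" if in_term else "header"
                raise ParseError(f"{path}: unparseable {where} line {lineno}: {line!r}")


def parse_obo(path: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are retained but flagged; their alt_ids still resolve.
    Edges with relation types outside :data:`KNOWN_RELATIONS` are dropped with
    a logged warning. A structurally broken stanza is a hard
    :class:`ParseError` naming the offending line.
    """
    _validate_obo_lines(path)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise ParseError(f"{path}: {exc}") from exc

    terms: dict[str, Term] = {}
    for tid, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise ParseError(f"{path}: term {tid} has no namespace")
        terms[tid] = Term(
            id=tid,
            name=data.get("name", ""),
            namespace=ns,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            alt_ids=frozenset(data.get("alt_id", [])),
        )

    edges: set[tuple[str, str, str]] = set()
    dropped: set[str] = set()
    for child, parent, rel in raw.edges(keys=True):
        if rel not in KNOWN_RELATIONS:
            dropped.add(rel)
            continue
        edges.add((child, parent, rel))
    if dropped:
        logger.warning("%s: ignoring unknown relation types: %s", path, ", ".join(sorted(dropped)))

    graph = OntologyGraph(terms, edges, relations=relations)
    # GO sub-ontologies are DAGs; a cycle means the file is broken.
    propagation = nx.DiGraph(
        (c, p) for c, p, r in edges if r in graph.relations
    )
    if not nx.is_directed_acyclic_graph(propagation):
        raise ParseError(f"{path}: ontology contains a cycle over {sorted(graph.relations)}")
    return graph
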