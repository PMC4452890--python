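"""High-quality binary PPI network construction from PSI-MITAB input.

The pipeline keeps experimentally verified, direct, binary interactions:
records are filtered on their PSI-MI detection-method identifier against a
configurable whitelist (default: two-hybrid and protein-complementation
families, which probe direct binary contact, excluding co-complex/affinity
purification methods), self-interactions are discarded, and redundant
accessions (e.g. unreviewed entries near-identical to a reviewed one) are
folded into their canonical accession through a user-supplied two-column
mapping, the canonical protein inheriting the secondary one's interactions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx

from .errors import ParseError

logger = logging.getLogger(__name__)

_UNIPROT_XREF_RE = re.compile(r"uniprotkb:([A-Za-z0-9][A-Za-z0-9._-]*)")
_MI_RE = re.compile(r"MI:\d{4}")
_ISOFORM_RE = re.compile(r"-\d+$")

#: Default detection-method whitelist: binary-capable methods only.
#: Two-hybrid family plus protein complementation assays; co-complex methods
#: (affinity chromatography MI:0004, pull down MI:0096, ...) are excluded.
DEFAULT_METHOD_WHITELIST = frozenset(
    {
        "MI:0018",  # two hybrid
        "MI:0397",  # two hybrid array
        "MI:0398",  # two hybrid pooling approach
        "MI:0399",  # two hybrid fragment pooling approach
        "MI:0726",  # reverse two hybrid
        "MI:0727",  # lexa b52 complementation
        "MI:1112",  # two hybrid prey pooling approach
        "MI:1113",  # two hybrid bait and prey pooling approach
        "MI:0090",  # protein complementation assay
        "MI:0112",  # ubiquitin reconstruction
        "MI:0232",  # transcriptional complementation assay
        "MI:0809",  # bimolecular fluorescence complementation
    }
)

#: Interaction types accepted when type filtering is switched on
#: (direct interaction and its common descendants).
DEFAULT_TYPE_WHITELIST = frozenset(
    {
        "MI:0407",  # direct interaction
        "MI:0915",  # physical association
        "MI:0914",  # association
    }
)


@dataclass(frozen=True)
class InteractionRecord:
    """One MITAB row reduced to what the filters need."""

    id_a: str
    id_b: str
    methods: frozenset[str]
    types: frozenset[str]
    sources: frozenset[str]


class InteractionNetwork:
    """Simple undirected graph of canonical accessions.

    Edges are unordered, deduplicated and self-loop free; each edge carries a
    provenance set of (source database id, detection-method PSI-MI id) pairs.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_ordered(u, v) for u, v in self.graph.edges}

    def provenance(self, a: str, b: str) -> set[tuple[str, str]]:
        return self.graph.edges[a, b]["provenance"]

    def add_interaction(self, a: str, b: str, provenance: set[tuple[str, str]]) -> None:
        if a == b:
            return
        u, v = _ordered(a, b)
        if self.graph.has_edge(u, v):
            self.graph.edges[u, v]["provenance"] |= provenance
        else:
            self.graph.add_edge(u, v, provenance=set(provenance))

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _extract_uniprot(*fields: str) -> str | None:
    for f in fields:
        m = _UNIPROT_XREF_RE.search(f)
        if m:
            return _ISOFORM_RE.sub("", m.group(1))
    return None


def parse_mitab(path: str) -> list[InteractionRecord]:
    """Read PSI-MITAB 2.5+ rows, resolving interactors to UniProt accessions.

    Records without a ``uniprotkb:`` cross-reference on both interactors are
    dropped with a logged count, as are malformed lines. Zero surviving
    records is a hard error.
    """
    records: list[InteractionRecord] = []
    n_malformed = n_no_uniprot = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                n_malformed += 1
                logger.warning("%s:%d: malformed MITAB row (%d columns)", path, lineno, len(cols))
                continue
            id_a = _extract_uniprot(cols[0], cols[2])
            id_b = _extract_uniprot(cols[1], cols[3])
            if id_a is None or id_b is None:
                n_no_uniprot += 1
                continue
            methods = frozenset(_MI_RE.findall(cols[6]))
            types = frozenset(_MI_RE.findall(cols[11])) if len(cols) > 11 else frozenset()
            sources = frozenset(_MI_RE.findall(cols[12])) if len(cols) > 12 else frozenset()
            records.append(InteractionRecord(id_a, id_b, methods, types, sources))
    if n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, n_malformed)
    if n_no_uniprot:
        logger.info("%s: dropped %d records without uniprotkb cross-reference", path, n_no_uniprot)
    if not records:
        raise ParseError(f"{path}: no usable interaction records")
    return records


def filter_binary(
    records: list[InteractionRecord],
    method_whitelist: frozenset[str] = DEFAULT_METHOD_WHITELIST,
    type_whitelist: frozenset[str] | None = None,
) -> InteractionNetwork:
    """Keep records whose detection method is whitelisted; build the network.

    Self-interactions are discarded; duplicate pairs (in either order) merge
    into one edge with the union of their provenance. When ``type_whitelist``
    is given, the interaction-type column must also match (older MITAB lacks
    reliable typing, hence off by default).
    """
    if not method_whitelist:
        raise ValueError("method whitelist must be non-empty")
    network = InteractionNetwork()
    for rec in records:
        if not (rec.methods & method_whitelist):
            continue
        if type_whitelist is not None and not (rec.types & type_whitelist):
            continue
        provenance = {
            (src, m) for src in (rec.sources or {""}) for m in (rec.methods & method_whitelist)
        }
        network.add_interaction(rec.id_a, rec.id_b, provenance)
    return network


def read_mapping(path: str) -> dict[str, str]:
    """Two-column TSV: secondary accession -> canonical accession."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[cols[0].strip()] = cols[1].strip()
    return mapping


def merge_redundant(network: InteractionNetwork, mapping: dict[str, str]) -> InteractionNetwork:
    """Rewrite every edge endpoint through the redundancy mapping.

    The canonical protein inherits the secondary protein's interactions.
    Self-loops created by the rewrite are discarded; duplicates merge. A
    mapping in which a target is itself remapped (a chain or cycle) is a hard
    error — the mapping must go straight to canonical accessions.
    """
    for sec, canon in mapping.items():
        if canon in mapping:
            raise ParseError(f"cyclic redundancy mapping: {sec} -> {canon} -> {mapping[canon]}")
    merged = InteractionNetwork()
    for u, v in network.graph.edges:
        mu = mapping.get(u, u)
        mv = mapping.get(v, v)
        if mu == mv:
            continue
        merged.add_interaction(mu, mv, network.graph.edges[u, v]["provenance"])
    return merged


def write_edgelist(network: InteractionNetwork, path: str) -> None:
    """Write the network as a sorted, deterministic two-column TSV."""
    with open(path, "w", encoding="utf-8") as handle:
        for u, v in sorted(network.edges):
            handle.write(f"{u}\t{v}\n")
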