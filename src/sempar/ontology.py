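"""Typed ontology DAG: OBO parsing and ancestor/descendant queries.

The graph stores directed child->parent edges, each labelled with a relation
type and a semantic contribution factor in (0, 1).  Only ``is_a``, ``part_of``
and the ``regulates`` family are retained; everything else is dropped with a
warning.  Measures are always computed within a single namespace, so
cross-namespace edges are removed at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: Default semantic contribution factor per relation type.
DEFAULT_WEIGHTS: dict[str, float] = {
    "is_a": 0.8,
    "part_of": 0.6,
    "regulates": 0.7,
    "positively_regulates": 0.7,
    "negatively_regulates": 0.7,
}

#: Relation types retained when parsing OBO files.
RETAINED_RELATIONS = frozenset(DEFAULT_WEIGHTS)


class OntologyError(ValueError):
    """Raised when an ontology violates a structural requirement."""


def _merge_weights(weights: Optional[Mapping[str, float]]) -> dict[str, float]:
    merged = dict(DEFAULT_WEIGHTS)
    if weights:
        for rel, w in weights.items():
            if not (0.0 < w < 1.0):
                raise ValueError(
                    f"contribution factor for {rel!r} must be in (0, 1), got {w}"
                )
            merged[rel] = w
    return merged


@dataclass
class OntologyGraph:
    """A DAG of terms with typed, weighted child->parent edges.

    Attributes
    ----------
    graph:
        ``networkx.DiGraph`` with edges directed child -> parent, carrying
        ``relation`` (str) and ``weight`` (float) attributes.
    names:
        term id -> human-readable name.
    namespaces:
        term id -> namespace identifier.
    roots:
        namespace -> its unique root term (no outgoing edge).
    alt_ids:
        secondary id -> canonical id.
    weights:
        relation type -> contribution factor used when building the edges.
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        edges: Iterable[tuple[str, str, str]],
        *,
        terms: Optional[Iterable[str]] = None,
        namespace: str = "toy",
        names: Optional[Mapping[str, str]] = None,
        weights: Optional[Mapping[str, float]] = None,
    ) -> "OntologyGraph":
        """Build a single-namespace graph from ``(child, parent, relation)`` triples."""
        merged = _merge_weights(weights)
        g = nx.DiGraph()
        for t in terms or ():
            g.add_node(t)
        for child, parent, rel in edges:
            if rel not in merged:
                raise ValueError(f"unknown relation type {rel!r}")
            _add_edge(g, child, parent, rel, merged[rel])
        namespaces = {t: namespace for t in g.nodes}
        obj = cls(
            graph=g,
            names={t: (names or {}).get(t, t) for t in g.nodes},
            namespaces=namespaces,
            roots={},
            alt_ids={},
            weights=merged,
        )
        obj._validate()
        return obj

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        self.roots = {}
        for t in self.graph.nodes:
            if self.graph.out_degree(t) == 0:
                ns = self.namespaces.get(t, "")
                if ns in self.roots:
                    raise OntologyError(
                        f"namespace {ns!r} has multiple roots: "
                        f"{self.roots[ns]!r} and {t!r}"
                    )
                self.roots[ns] = t

    # -- queries ----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def resolve(self, term: str) -> str:
        """Map a (possibly secondary) id to its canonical id."""
        return self.alt_ids.get(term, term)

    def namespace_of(self, term: str) -> str:
        self._require(term)
        return self.namespaces[term]

    def root_of(self, namespace: str) -> str:
        return self.roots[namespace]

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")

    def ancestors(self, term: str, *, reflexive: bool = False) -> set[str]:
        """All terms reachable from ``term`` via child->parent edges.

        ``term`` itself is excluded unless ``reflexive`` is true.
        """
        self._require(term)
        anc = nx.descendants(self.graph, term)  # edges point child -> parent
        if reflexive:
            anc.add(term)
        return anc

    def descendants(self, term: str, *, reflexive: bool = False) -> set[str]:
        """All terms from which ``term`` is reachable (mirror of :meth:`ancestors`)."""
        self._require(term)
        desc = nx.ancestors(self.graph, term)
        if reflexive:
            desc.add(term)
        return desc

    def parents(self, term: str) -> list[tuple[str, str, float]]:
        """Direct ``(parent, relation, weight)`` triples of ``term``."""
        self._require(term)
        return [
            (p, d["relation"], d["weight"])
            for p, d in self.graph.adj[term].items()
        ]

    def children(self, term: str) -> list[tuple[str, str, float]]:
        """Direct ``(child, relation, weight)`` triples of ``term``."""
        self._require(term)
        return [
            (c, d["relation"], d["weight"])
            for c, d in self.graph.pred[term].items()
        ]


def _add_edge(g: nx.DiGraph, child: str, parent: str, rel: str, w: float) -> None:
    # parallel relations between the same pair keep the strongest factor
    if g.has_edge(child, parent) and g[child][parent]["weight"] >= w:
        return
    g.add_edge(child, parent, relation=rel, weight=w)


# -- OBO parsing ----------------------------------------------------------


def _parse_stanzas(text: str):
    """Yield ``[Term]`` stanzas as lists of ``(tag, value)`` pairs."""
    current: Optional[list[tuple[str, str]]] = None
    in_term = False
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip() if "!" in raw else raw.strip()
        if not line:
            continue
        if line.startswith("["):
            if in_term and current:
                yield current
            in_term = line == "[Term]"
            current = [] if in_term else None
            continue
        if not in_term or ":" not in line:
            continue
        tag, value = line.split(":", 1)
        current.append((tag.strip(), value.strip()))
    if in_term and current:
        yield current


def load_obo(
    path: str,
    namespace_filter: Optional[str] = None,
    *,
    weights: Optional[Mapping[str, float]] = None,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are excluded, ``alt_id`` values are mapped back to their
    canonical id, and only is_a/part_of/regulates-family edges are kept.
    Cross-namespace edges are dropped.

    Parameters
    ----------
    path:
        OBO file path.
    namespace_filter:
        If given, only terms of that namespace are loaded.
    weights:
        Override contribution factors per relation type.

    Raises
    ------
    OSError
        If the file is unreadable.
    OntologyError
        If the parsed graph contains a cycle or a namespace has several roots.
    """
    merged = _merge_weights(weights)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()

    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    raw_edges: list[tuple[str, str, str]] = []
    dropped_relations: set[str] = set()

    for stanza in _parse_stanzas(text):
        tid: Optional[str] = None
        name = ""
        ns = ""
        obsolete = False
        alts: list[str] = []
        edges: list[tuple[str, str]] = []
        for tag, value in stanza:
            if tag == "id":
                tid = value
            elif tag == "name":
                name = value
            elif tag == "namespace":
                ns = value
            elif tag == "is_obsolete":
                obsolete = value.lower() == "true"
            elif tag == "alt_id":
                alts.append(value)
            elif tag == "is_a":
                edges.append(("is_a", value))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) >= 2:
                    rel, target = parts[0], parts[1]
                    if rel in RETAINED_RELATIONS:
                        edges.append((rel, target))
                    else:
                        dropped_relations.add(rel)
        if tid is None or obsolete:
            continue
        names[tid] = name or tid
        namespaces[tid] = ns
        for a in alts:
            alt_ids[a] = tid
        for rel, target in edges:
            raw_edges.append((tid, target, rel))

    if dropped_relations:
        logger.warning(
            "ignored relation types without a contribution factor: %s",
            ", ".join(sorted(dropped_relations)),
        )

    if namespace_filter is not None:
        keep = {t for t, ns in namespaces.items() if ns == namespace_filter}
        names = {t: names[t] for t in keep}
        namespaces = {t: namespaces[t] for t in keep}
        alt_ids = {a: t for a, t in alt_ids.items() if t in keep}

    g = nx.DiGraph()
    g.add_nodes_from(names)
    n_cross = 0
    for child, parent, rel in raw_edges:
        parent = alt_ids.get(parent, parent)
        if child not in names or parent not in names:
            continue
        if namespaces[child] != namespaces[parent]:
            n_cross += 1
            continue
        _add_edge(g, child, parent, rel, merged[rel])
    if n_cross:
        logger.warning("dropped %d cross-namespace edge(s)", n_cross)

    obj = OntologyGraph(
        graph=g,
        names=names,
        namespaces=namespaces,
        roots={},
        alt_ids=alt_ids,
        weights=merged,
    )
    obj._validate()
    return obj
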