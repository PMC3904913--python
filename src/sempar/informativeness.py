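"""Term informativeness I(t): semantic value, information content, or a table.

Three interchangeable backings share one interface so the particularity and
similarity measures never care where the numbers come from:

* ``SemanticValueModel`` — Wang's corpus-free semantic value.  The semantic
  contribution of an ancestor ``t`` to a term ``a`` is the maximum product of
  edge contribution factors over descending paths from ``t`` to ``a``
  (``S_a(a) = 1``); the semantic value of ``a`` is the sum of the
  contributions of ``a`` and all its ancestors.
* ``InformationContentModel`` — ``-log p(t)`` with the annotation-propagated
  frequency ``p`` from an :class:`~sempar.annotations.AnnotationCorpus`.
  No smoothing: a zero frequency is a domain error.
* ``TableModel`` — explicit term -> value lookups for fixtures and for
  replaying externally computed tables.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph


class InformativenessError(ValueError):
    """Raised when informativeness is undefined for a queried term."""


def semantic_contribution(g: OntologyGraph, a: str, t: str) -> float:
    """Semantic contribution S_a(t) of ancestor-or-self ``t`` to ``a``.

    Computed by dynamic programming over the sub-DAG between ``a`` and ``t``:
    ``S_a(a) = 1`` and ``S_a(t) = max over children t' of t on a path to a of
    w(t'->t) * S_a(t')``.
    """
    contrib = semantic_contributions(g, a)
    if t not in contrib:
        raise ValueError(f"{t!r} is not an ancestor-or-self of {a!r}")
    return contrib[t]


def semantic_contributions(g: OntologyGraph, a: str) -> dict[str, float]:
    """S_a(t) for every t in {a} union ancestors(a), in one pass."""
    anc = g.ancestors(a, reflexive=True)
    contrib: dict[str, float] = {a: 1.0}
    # children of t on a path to a are exactly the members of anc below t;
    # iterate bottom-up so each child's value exists before its parents need it
    order = _bottom_up(g, a, anc)
    for t in order:
        if t == a:
            continue
        best = 0.0
        for c, _rel, w in g.children(t):
            if c in contrib:
                best = max(best, w * contrib[c])
        contrib[t] = best
    return contrib


def _bottom_up(g: OntologyGraph, a: str, anc: set[str]) -> list[str]:
    """Members of ``anc`` ordered so every term follows all its descendants."""
    import networkx as nx

    sub = g.graph.subgraph(anc)
    return list(nx.topological_sort(sub))


def semantic_value(g: OntologyGraph, a: str) -> float:
    """Wang semantic value SV(a): sum of S_a(t) over a and all its ancestors."""
    return sum(semantic_contributions(g, a).values())


def information_content(
    c: AnnotationCorpus, t: str, *, base: Optional[float] = None
) -> float:
    """IC(t) = -log p(t) with the corpus's propagated frequency.

    Natural log by default.  ``p(t) = 0`` is a domain error (no smoothing).
    """
    p = c.propagated_frequency(t)
    if p <= 0.0:
        raise InformativenessError(
            f"term {t!r} has zero propagated frequency; IC undefined"
        )
    ic = -math.log(p)
    if base is not None:
        ic /= math.log(base)
    return ic


class InformativenessModel:
    """Common interface: :meth:`value` maps a term id to a nonnegative real."""

    kind: str = "abstract"

    def value(self, term: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def __getitem__(self, term: str) -> float:
        return self.value(term)

    def to_table(self, terms) -> dict[str, float]:
        """Materialize the model on an iterable of terms."""
        return {t: self.value(t) for t in terms}


class SemanticValueModel(InformativenessModel):
    """I(t) = SV(t), cached per term."""

    kind = "semantic_value"

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self._cache: dict[str, float] = {}

    def value(self, term: str) -> float:
        if term not in self._cache:
            if term not in self.graph:
                raise KeyError(f"unknown term {term!r}")
            self._cache[term] = semantic_value(self.graph, term)
        return self._cache[term]


class InformationContentModel(InformativenessModel):
    """I(t) = -log p(t) over a corpus; errors on zero-frequency terms."""

    kind = "information_content"

    def __init__(self, corpus: AnnotationCorpus, *, base: Optional[float] = None):
        self.corpus = corpus
        self.base = base
        self._cache: dict[str, float] = {}

    def value(self, term: str) -> float:
        if term not in self._cache:
            self._cache[term] = information_content(self.corpus, term, base=self.base)
        return self._cache[term]


class TableModel(InformativenessModel):
    """Explicit term -> informativeness lookups.

    ``flagged`` marks filler entries that must never be consulted by a target
    computation; querying one raises so tests fail loudly.
    """

    kind = "table"

    def __init__(self, values: Mapping[str, float], *, flagged: frozenset[str] = frozenset()):
        for t, v in values.items():
            if v < 0:
                raise ValueError(f"informativeness of {t!r} is negative: {v}")
        self.values = dict(values)
        self.flagged = frozenset(flagged)

    def value(self, term: str) -> float:
        if term in self.flagged:
            raise InformativenessError(
                f"term {term!r} only has a filler informativeness value"
            )
        try:
            return self.values[term]
        except KeyError:
            raise KeyError(f"no informativeness value for term {term!r}") from None


def from_table(values: Mapping[str, float], **kwargs) -> TableModel:
    """Build a table-backed model from an explicit mapping."""
    return TableModel(values, **kwargs)


def read_table(path: str) -> TableModel:
    """Read a two-column ``term<TAB>value`` TSV into a table model."""
    values: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            term, val = line.split("\t")
            values[term] = float(val)
    return TableModel(values)


def write_table(model: InformativenessModel, terms, path: str) -> None:
    """Write ``term<TAB>value`` rows (full float precision, sorted by term)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in sorted(terms):
            fh.write(f"{t}\t{model.value(t)!r}\n")
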