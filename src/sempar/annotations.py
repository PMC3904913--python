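"""Gene annotation corpora: GAF/TSV loading, set expansion, term frequencies.

A corpus maps genes to their directly annotated terms in one namespace and
derives propagated term counts (a gene counts toward a term if the term is in
the gene's expanded annotation set), from which information content is built.
Evidence codes are carried through as metadata but never used as weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: GAF aspect code -> GO namespace name.
ASPECT_NAMESPACES = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class AnnotationError(ValueError):
    """Raised when an annotation source yields no usable rows."""


def expand_set(g: OntologyGraph, s: Iterable[str]) -> set[str]:
    """Union of ``s`` with the ancestors of each of its members.

    Extensive, monotone and idempotent; ``expand_set(g, [])`` is empty.
    """
    out: set[str] = set()
    for t in s:
        out.update(g.ancestors(t, reflexive=True))
    return out


@dataclass
class AnnotationCorpus:
    """Direct gene->term annotations plus propagated term frequencies."""

    graph: OntologyGraph
    namespace: str
    gene_terms: dict[str, frozenset[str]]
    #: (gene, term) -> evidence codes seen for that pair; metadata only.
    evidence: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    n_skipped_rows: int = 0
    _propagated: Optional[dict[str, int]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_genes(self) -> int:
        """Number of genes carrying at least one annotation in the namespace."""
        return len(self.gene_terms)

    @property
    def propagated_counts(self) -> dict[str, int]:
        """term -> number of genes annotated to the term or any descendant."""
        if self._propagated is None:
            counts: dict[str, int] = {}
            for terms in self.gene_terms.values():
                for t in expand_set(self.graph, terms):
                    counts[t] = counts.get(t, 0) + 1
            self._propagated = counts
        return self._propagated

    def propagated_frequency(self, term: str) -> float:
        """p(term) = propagated count / number of annotated genes; p(root) = 1."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        if self.n_genes == 0:
            raise AnnotationError("corpus has no annotated genes")
        return self.propagated_counts.get(term, 0) / self.n_genes


def propagated_frequency(c: AnnotationCorpus, g: OntologyGraph, t: str) -> float:
    """Functional alias for :meth:`AnnotationCorpus.propagated_frequency`."""
    return c.propagated_frequency(t)


def _iter_rows(path: str):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_gaf(
    path: str,
    g: OntologyGraph,
    namespace: Optional[str] = None,
    *,
    exclude_not: bool = True,
) -> AnnotationCorpus:
    """Load a GAF 2.x file or a plain two-column ``gene<TAB>term`` TSV.

    Rows whose term is absent from ``g`` (after alt_id resolution) or outside
    the requested namespace are skipped and counted.  ``NOT``-qualified GAF
    rows are dropped when ``exclude_not`` is set.  Evidence codes are kept as
    metadata only.

    Raises
    ------
    AnnotationError
        If no usable rows remain.
    """
    gene_terms: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], set[str]] = {}
    n_skipped = 0
    target_ns = namespace

    for lineno, cols in _iter_rows(path):
        if len(cols) >= 15:  # GAF 2.x
            gene, qualifier, term, ev = cols[1], cols[3], cols[4], cols[6]
        elif len(cols) == 2:  # toy TSV dialect
            gene, term = cols[0], cols[1]
            qualifier, ev = "", ""
        else:
            logger.warning("%s:%d: malformed row skipped", path, lineno)
            n_skipped += 1
            continue
        if exclude_not and "NOT" in qualifier.split("|"):
            n_skipped += 1
            continue
        term = g.resolve(term)
        if term not in g:
            n_skipped += 1
            continue
        if target_ns is not None and g.namespace_of(term) != target_ns:
            n_skipped += 1
            continue
        gene_terms.setdefault(gene, set()).add(term)
        if ev:
            evidence.setdefault((gene, term), set()).add(ev)

    if n_skipped:
        logger.info("%s: skipped %d row(s)", path, n_skipped)
    if not gene_terms:
        raise AnnotationError(f"{path}: no usable annotation rows")

    if target_ns is None:
        namespaces = {g.namespace_of(t) for s in gene_terms.values() for t in s}
        if len(namespaces) > 1:
            raise AnnotationError(
                f"annotations span several namespaces {sorted(namespaces)}; "
                "pass namespace= to select one"
            )
        target_ns = namespaces.pop()

    return AnnotationCorpus(
        graph=g,
        namespace=target_ns,
        gene_terms={k: frozenset(v) for k, v in gene_terms.items()},
        evidence={k: frozenset(v) for k, v in evidence.items()},
        n_skipped_rows=n_skipped,
    )


def corpus_from_mapping(
    g: OntologyGraph, gene_terms: dict[str, Iterable[str]], namespace: Optional[str] = None
) -> AnnotationCorpus:
    """Build a corpus directly from an in-memory gene -> terms mapping."""
    cleaned = {}
    for gene, terms in gene_terms.items():
        ts = frozenset(terms)
        for t in ts:
            if t not in g:
                raise KeyError(f"unknown term {t!r} for gene {gene!r}")
        if ts:
            cleaned[gene] = ts
    if not cleaned:
        raise AnnotationError("mapping contains no annotated genes")
    if namespace is None:
        namespaces = {g.namespace_of(t) for s in cleaned.values() for t in s}
        if len(namespaces) > 1:
            raise AnnotationError(
                f"annotations span several namespaces {sorted(namespaces)}"
            )
        namespace = namespaces.pop()
    return AnnotationCorpus(graph=g, namespace=namespace, gene_terms=cleaned)
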