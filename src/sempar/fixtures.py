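"""Synthetic ontologies, corpora and the orthologs worked-example fixture.

Everything here is deterministic under a seed (numpy's PCG64 generator, which
is specified and portable across platforms) so the rest of the package is
testable without downloading any ontology or annotation release.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotations import AnnotationCorpus, corpus_from_mapping
from .informativeness import TableModel
from .ontology import DEFAULT_WEIGHTS, OntologyGraph


@dataclass
class FixtureSpec:
    """Parameters for random ontology / corpus generation."""

    n_terms: int = 30
    max_parents: int = 2
    #: probabilities over (is_a, part_of, regulates); renormalized if needed.
    relation_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_genes: int = 10
    annotations_per_gene: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        lo, hi = self.annotations_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("annotations_per_gene must be a range 1 <= lo <= hi")
        if any(p < 0 for p in self.relation_mix) or sum(self.relation_mix) <= 0:
            raise ValueError("relation_mix must be nonnegative and sum > 0")


_RELATIONS = ("is_a", "part_of", "regulates")


def _term_id(k: int) -> str:
    return f"T:{k:07d}"


def random_dag(spec: FixtureSpec) -> OntologyGraph:
    """A single-root, connected, acyclic random ontology.

    Term ``k`` draws its parents uniformly from terms ``0..k-1``, so the
    result is acyclic by construction; term 0 is the root.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mix = np.asarray(spec.relation_mix, dtype=float)
    mix = mix / mix.sum()
    edges: list[tuple[str, str, str]] = []
    for k in range(1, spec.n_terms):
        n_parents = int(rng.integers(1, min(spec.max_parents, k) + 1))
        parents = rng.choice(k, size=n_parents, replace=False)
        for p in sorted(int(x) for x in parents):
            rel = _RELATIONS[int(rng.choice(3, p=mix))]
            edges.append((_term_id(k), _term_id(p), rel))
    return OntologyGraph.build(
        edges,
        terms=[_term_id(k) for k in range(spec.n_terms)],
        namespace="toy",
    )


def random_corpus(g: OntologyGraph, spec: FixtureSpec) -> AnnotationCorpus:
    """Genes annotated to uniform samples of non-root terms; seeded."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    namespace = next(iter(g.roots))
    root = g.roots[namespace]
    candidates = sorted(g.terms - {root})
    if not candidates:
        candidates = [root]
    lo, hi = spec.annotations_per_gene
    gene_terms = {}
    for j in range(spec.n_genes):
        n = int(rng.integers(lo, hi + 1))
        n = min(n, len(candidates))
        picks = rng.choice(len(candidates), size=n, replace=False)
        gene_terms[f"G{j:04d}"] = {candidates[int(p)] for p in picks}
    return corpus_from_mapping(g, gene_terms, namespace)


# -- plain-text emitters ---------------------------------------------------


def to_obo(g: OntologyGraph, *, header: str = "format-version: 1.2") -> str:
    """Serialize a graph to OBO text that :func:`~sempar.ontology.load_obo` reparses."""
    lines = [header, ""]
    for t in sorted(g.terms):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: {g.names.get(t, t)}")
        lines.append(f"namespace: {g.namespaces[t]}")
        for parent, rel, _w in sorted(g.parents(t)):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    return "\n".join(lines)


def to_annotation_tsv(corpus: AnnotationCorpus) -> str:
    """Serialize a corpus to the two-column ``gene<TAB>term`` dialect."""
    lines = []
    for gene in sorted(corpus.gene_terms):
        for term in sorted(corpus.gene_terms[gene]):
            lines.append(f"{gene}\t{term}")
    return "\n".join(lines) + "\n"


def make_fixture_files(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Write OBO + annotation TSV + a JSON manifest under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    g = random_dag(spec)
    corpus = random_corpus(g, spec)
    paths = {
        "obo": os.path.join(out_dir, "ontology.obo"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    with open(paths["obo"], "w", encoding="utf-8") as fh:
        fh.write(to_obo(g))
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        fh.write(to_annotation_tsv(corpus))
    manifest = {
        "spec": {
            "n_terms": spec.n_terms,
            "max_parents": spec.max_parents,
            "relation_mix": list(spec.relation_mix),
            "n_genes": spec.n_genes,
            "annotations_per_gene": list(spec.annotations_per_gene),
            "seed": spec.seed,
        },
        "n_terms": len(g),
        "n_edges": g.graph.number_of_edges(),
        "n_genes": corpus.n_genes,
        "root": g.roots["toy"],
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# -- the exportin-5 orthologs worked example -------------------------------

MF_ROOT = "molecular_function"


@dataclass
class OrthologExampleFixture:
    """The molecular-function worked example for three species' annotation sets.

    Informativeness is table-backed with the four published semantic values;
    every other term in the graph is a flagged filler so a computation that
    strays outside the published numbers fails loudly.
    """

    graph: OntologyGraph
    sg_hsa: frozenset[str]
    sg_rno: frozenset[str]
    sg_dme: frozenset[str]
    informativeness: TableModel


def figure1_fixture() -> OrthologExampleFixture:
    """Build the three-species molecular-function comparison fixture.

    The human set is {tRNA binding, protein binding, protein transporter
    activity}; the rat set lacks ``protein binding``; the drosophila set lacks
    ``tRNA binding``.  The table carries the published semantic values
    {tRNA binding: 4.201, binding: 1.8, protein transporter activity: 2.952,
    protein binding: 2.44}.
    """
    edges = [
        ("binding", MF_ROOT, "is_a"),
        ("protein binding", "binding", "is_a"),
        ("nucleic acid binding", "binding", "is_a"),
        ("RNA binding", "nucleic acid binding", "is_a"),
        ("tRNA binding", "RNA binding", "is_a"),
        ("transporter activity", MF_ROOT, "is_a"),
        ("substrate-specific transporter activity", "transporter activity", "is_a"),
        ("protein transporter activity", "substrate-specific transporter activity", "is_a"),
    ]
    g = OntologyGraph.build(edges, namespace="molecular_function")
    published = {
        "tRNA binding": 4.201,
        "binding": 1.8,
        "protein transporter activity": 2.952,
        "protein binding": 2.44,
        # the root contributes only itself: SV = 1 by construction; it is a
        # legitimate (if never winning) candidate in every MICA maximization
        MF_ROOT: 1.0,
    }
    fillers = sorted(g.terms - set(published))
    table = TableModel(
        {**published, **{t: 0.0 for t in fillers}},
        flagged=frozenset(fillers),
    )
    return OrthologExampleFixture(
        graph=g,
        sg_hsa=frozenset(
            {"tRNA binding", "protein binding", "protein transporter activity"}
        ),
        sg_rno=frozenset({"tRNA binding", "protein transporter activity"}),
        sg_dme=frozenset({"protein binding", "protein transporter activity"}),
        informativeness=table,
    )
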