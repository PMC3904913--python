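"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's graph queries: they work on a raw
child -> parents edge mapping and use naive repeated edge-following and
exhaustive enumeration, so they stay independent of the code paths they check.
"""

from __future__ import annotations


def edge_map(graph) -> dict[str, set[str]]:
    """child -> set of parents, extracted from the networkx digraph."""
    out: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent in graph.edges:
        out[child].add(parent)
    return out


def brute_ancestors(parents: dict[str, set[str]], t: str) -> set[str]:
    """Transitive closure by repeated edge-following."""
    seen: set[str] = set()
    frontier = set(parents.get(t, ()))
    while frontier:
        seen |= frontier
        frontier = {
            p for f in frontier for p in parents.get(f, ()) if p not in seen
        }
    return seen


def brute_descendants(parents: dict[str, set[str]], t: str) -> set[str]:
    return {s for s in parents if t in brute_ancestors(parents, s)}


def brute_expand(parents: dict[str, set[str]], s) -> set[str]:
    out = set(s)
    for t in s:
        out |= brute_ancestors(parents, t)
    return out


def brute_mpt(parents: dict[str, set[str]], sg1, sg2) -> set[str]:
    sg1 = set(sg1)
    sg2_star = brute_expand(parents, sg2)
    out = set()
    for t in sg1:
        if t in sg2_star:
            continue
        if any(t in brute_ancestors(parents, u) for u in sg1):
            continue
        out.add(t)
    return out


def brute_mct(parents: dict[str, set[str]], sg1, sg2) -> set[str]:
    s1 = brute_expand(parents, sg1)
    s2 = brute_expand(parents, sg2)
    out = set()
    for t in s1 & s2:
        desc = brute_descendants(parents, t)
        if not (desc & s1) and not (desc & s2):
            out.add(t)
    return out


def brute_mica_info(parents: dict[str, set[str]], info, t: str, sg2) -> float:
    candidates = ({t} | brute_ancestors(parents, t)) & brute_expand(parents, sg2)
    if not candidates:
        return 0.0
    return max(info(a) for a in candidates)


def brute_par(parents: dict[str, set[str]], info, sg1, sg2) -> float:
    """Particularity recomputed from the raw definitions."""
    pi = sum(
        max(0.0, info(t) - brute_mica_info(parents, info, t, sg2))
        for t in brute_mpt(parents, sg1, sg2)
    )
    denom = pi + sum(info(t) for t in brute_mct(parents, sg1, sg2))
    return pi / denom if denom else 0.0


def brute_bma(sim, sg1, sg2) -> float:
    """Best-match average via an explicit double loop."""
    sg1, sg2 = list(sg1), list(sg2)
    best1 = [max(sim(a, b) for b in sg2) for a in sg1]
    best2 = [max(sim(a, b) for a in sg1) for b in sg2]
    return (sum(best1) / len(best1) + sum(best2) / len(best2)) / 2.0


def brute_frequency(parents: dict[str, set[str]], gene_terms, t: str) -> float:
    """Fraction of genes whose expanded annotation set contains ``t``."""
    n = len(gene_terms)
    hits = sum(
        1 for terms in gene_terms.values() if t in brute_expand(parents, terms)
    )
    return hits / n
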