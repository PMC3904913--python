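"""Set-level particularity and similarity of ontology term sets.

Given two direct annotation sets ``sg1`` and ``sg2`` (written ``Sg1``/``Sg2``
below) and an informativeness backing ``I``:

* ``MPT(Sg1, Sg2)`` — terms of Sg1 with no descendant in Sg1 that are absent
  from the expanded set Sg2*.
* ``MCT(Sg1, Sg2)`` — terms of Sg1* ∩ Sg2* with no descendant in Sg1* and
  none in Sg2*.
* ``PI(Sg1, Sg2) = Σ_{t ∈ MPT} [I(t) − I(MICA(t, Sg2))]`` where the MICA is
  the most informative member of ancestors-or-self(t) ∩ Sg2* (0 if none).
* ``Par(Sg1, Sg2) = PI / (PI + Σ_{t ∈ MCT} I(t))`` in [0, 1], non-symmetric.

Plus Wang's semantic-value term similarity and Lin's IC term similarity with
max/avg/best-match-average set combiners, and :func:`compare` assembling the
full ``(Sim, Par12, Par21)`` tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotations import expand_set
from .informativeness import InformativenessModel, semantic_contributions
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

TermSet = frozenset[str]


def _check_same_namespace(g: OntologyGraph, *sets: Iterable[str]) -> None:
    namespaces = {g.namespace_of(t) for s in sets for t in s}
    if len(namespaces) > 1:
        raise ValueError(f"term sets mix namespaces: {sorted(namespaces)}")


def most_particular_terms(
    g: OntologyGraph, sg1: Iterable[str], sg2: Iterable[str]
) -> set[str]:
    """Terms of ``sg1`` with no descendant in ``sg1`` and not in ``sg2``'s expansion.

    The descendant test runs on the *direct* set ``sg1``; the membership test
    runs against ``expand_set(sg2)``.
    """
    sg1, sg2 = set(sg1), set(sg2)
    _check_same_namespace(g, sg1, sg2)
    sg2_star = expand_set(g, sg2)
    return {
        t
        for t in sg1
        if t not in sg2_star and not (g.descendants(t) & sg1)
    }


def most_informative_common_terms(
    g: OntologyGraph, sg1: Iterable[str], sg2: Iterable[str]
) -> set[str]:
    """Members of ``sg1* ∩ sg2*`` with no descendant in either expanded set."""
    sg1, sg2 = set(sg1), set(sg2)
    _check_same_namespace(g, sg1, sg2)
    sg1_star = expand_set(g, sg1)
    sg2_star = expand_set(g, sg2)
    common = sg1_star & sg2_star
    return {
        t
        for t in common
        if not (g.descendants(t) & sg1_star) and not (g.descendants(t) & sg2_star)
    }


def mica_informativeness(
    g: OntologyGraph,
    i: InformativenessModel,
    t: str,
    sg2: Iterable[str],
) -> float:
    """Informativeness of the most informative common ancestor of ``t`` and ``sg2``.

    Maximum of ``I`` over ancestors-or-self(t) ∩ expand_set(sg2); 0.0 when the
    intersection is empty (notably when ``sg2`` is empty).
    """
    candidates = g.ancestors(t, reflexive=True) & expand_set(g, set(sg2))
    if not candidates:
        return 0.0
    return max(i.value(a) for a in candidates)


def mica_term(
    g: OntologyGraph, i: InformativenessModel, t: str, sg2: Iterable[str]
) -> Optional[str]:
    """The MICA term itself (lexicographically smallest on ties), or None."""
    candidates = g.ancestors(t, reflexive=True) & expand_set(g, set(sg2))
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-i.value(a), a))


def particular_informativeness(
    g: OntologyGraph,
    i: InformativenessModel,
    sg1: Iterable[str],
    sg2: Iterable[str],
) -> float:
    """PI(sg1, sg2): summed informativeness of MPT members above their MICAs.

    Each summand is clamped at 0 (a warning is logged if clamping fires) so
    the derived particularity stays within [0, 1].
    """
    sg1, sg2 = set(sg1), set(sg2)
    total = 0.0
    for t in most_particular_terms(g, sg1, sg2):
        d = i.value(t) - mica_informativeness(g, i, t, sg2)
        if d < 0.0:
            logger.warning(
                "negative particular-informativeness summand for %r clamped to 0", t
            )
            d = 0.0
        total += d
    return total


def particularity(
    g: OntologyGraph,
    i: InformativenessModel,
    sg1: Iterable[str],
    sg2: Iterable[str],
) -> float:
    """Par(sg1, sg2) = PI / (PI + Σ I over MCT), in [0, 1].

    Conventions: ``particularity(∅, s) = 0`` for nonempty ``s``;
    ``particularity(s, ∅) = 1`` for nonempty ``s``; both sets empty is an
    error.  A zero denominator with both sets nonempty (all informativeness
    zero) yields 0.0 with a warning.
    """
    sg1, sg2 = set(sg1), set(sg2)
    if not sg1 and not sg2:
        raise ValueError("particularity of two empty sets is undefined")
    if not sg1:
        return 0.0
    pi = particular_informativeness(g, i, sg1, sg2)
    mct_info = sum(
        i.value(t) for t in most_informative_common_terms(g, sg1, sg2)
    )
    denom = pi + mct_info
    if denom == 0.0:
        logger.warning("degenerate particularity: zero total informativeness")
        return 0.0
    return pi / denom


# -- term-level similarity -------------------------------------------------


def wang_term_similarity(g: OntologyGraph, a: str, b: str) -> float:
    """Wang similarity of two terms from their shared semantic contributions.

    ``Σ_{t ∈ T_a ∩ T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b))`` where ``T_x``
    is x plus its ancestors.
    """
    if g.namespace_of(a) != g.namespace_of(b):
        raise ValueError("terms belong to different namespaces")
    sa = semantic_contributions(g, a)
    sb = semantic_contributions(g, b)
    # fixed summation order keeps identity exactly 1 and the value symmetric
    num = sum(sa[t] + sb[t] for t in sorted(sa.keys() & sb.keys()))
    denom = sum(sa[t] for t in sorted(sa)) + sum(sb[t] for t in sorted(sb))
    return min(1.0, num / denom)


def lin_term_similarity(
    g: OntologyGraph, ic: InformativenessModel, a: str, b: str
) -> float:
    """Lin similarity ``2·IC(MICA) / (IC(a) + IC(b))`` with IC-like backing.

    When both terms carry zero informativeness (e.g. the root with itself) the
    value is 1.0 for identical terms and 0.0 otherwise.
    """
    if g.namespace_of(a) != g.namespace_of(b):
        raise ValueError("terms belong to different namespaces")
    denom = ic.value(a) + ic.value(b)
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    mica = mica_informativeness(g, ic, a, {b})
    return 2.0 * mica / denom


def _term_similarity(
    g: OntologyGraph,
    backing: Optional[InformativenessModel],
    a: str,
    b: str,
    method: str,
) -> float:
    if method == "wang":
        return wang_term_similarity(g, a, b)
    if method == "lin":
        if backing is None:
            raise ValueError("lin similarity requires an informativeness backing")
        return lin_term_similarity(g, backing, a, b)
    raise ValueError(f"unknown similarity method {method!r}")


def set_similarity(
    g: OntologyGraph,
    backing: Optional[InformativenessModel],
    sg1: Iterable[str],
    sg2: Iterable[str],
    *,
    method: str = "wang",
    combine: str = "bma",
) -> float:
    """Combine a pairwise term-similarity matrix into a set-level similarity.

    ``combine`` is one of ``bma`` (average of the two directional best-match
    means), ``max`` (matrix maximum) or ``avg`` (matrix mean).  Both sets must
    be nonempty.
    """
    sg1, sg2 = sorted(set(sg1)), sorted(set(sg2))
    if not sg1 or not sg2:
        raise ValueError("set similarity requires two nonempty term sets")
    _check_same_namespace(g, sg1, sg2)
    matrix = [
        [_term_similarity(g, backing, a, b, method) for b in sg2] for a in sg1
    ]
    if combine == "max":
        return max(max(row) for row in matrix)
    if combine == "avg":
        return sum(sum(row) for row in matrix) / (len(sg1) * len(sg2))
    if combine == "bma":
        best12 = sum(max(row) for row in matrix) / len(sg1)
        best21 = sum(
            max(matrix[i][j] for i in range(len(sg1))) for j in range(len(sg2))
        ) / len(sg2)
        return (best12 + best21) / 2.0
    raise ValueError(f"unknown combine strategy {combine!r}")


# -- full comparison -------------------------------------------------------


@dataclass
class TermSetComparison:
    """Everything :func:`compare` derives from one pair of term sets."""

    sg1: TermSet
    sg2: TermSet
    sg1_star: TermSet
    sg2_star: TermSet
    mpt12: TermSet
    mpt21: TermSet
    mct: TermSet
    pi12: float
    pi21: float
    par12: float
    par21: float
    sim: float
    method: str = "wang"
    combine: str = "bma"


def compare(
    g: OntologyGraph,
    backing: InformativenessModel,
    sg1: Iterable[str],
    sg2: Iterable[str],
    *,
    method: str = "wang",
    combine: str = "bma",
) -> TermSetComparison:
    """Full comparison of two nonempty term sets: ``(Sim, Par12, Par21)`` and parts."""
    sg1, sg2 = frozenset(sg1), frozenset(sg2)
    if not sg1 or not sg2:
        raise ValueError("compare requires two nonempty term sets")
    _check_same_namespace(g, sg1, sg2)
    return TermSetComparison(
        sg1=sg1,
        sg2=sg2,
        sg1_star=frozenset(expand_set(g, sg1)),
        sg2_star=frozenset(expand_set(g, sg2)),
        mpt12=frozenset(most_particular_terms(g, sg1, sg2)),
        mpt21=frozenset(most_particular_terms(g, sg2, sg1)),
        mct=frozenset(most_informative_common_terms(g, sg1, sg2)),
        pi12=particular_informativeness(g, backing, sg1, sg2),
        pi21=particular_informativeness(g, backing, sg2, sg1),
        par12=particularity(g, backing, sg1, sg2),
        par21=particularity(g, backing, sg2, sg1),
        sim=set_similarity(g, backing, sg1, sg2, method=method, combine=combine),
        method=method,
        combine=combine,
    )
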