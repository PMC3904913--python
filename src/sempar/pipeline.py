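"""Batch comparisons: pairwise matrices, similarity-bin statistics, profiles.

Reproduces the cohort machinery: all unordered gene pairs with their
``(Sim, Par12, Par21)`` tuple, particularity statistics in 20 similarity bins
of width 0.025 over [0.5, 0.999], and the four-way similarity/particularity
profile classification with annotation-validity accounting.  Output ordering
and float formatting are fixed so reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .annotations import AnnotationCorpus, expand_set
from .informativeness import InformativenessModel
from .measures import compare
from .ontology import OntologyGraph

BIN_LO, BIN_WIDTH, N_BINS, BIN_HI = 0.5, 0.025, 20, 0.999


@dataclass
class PairResult:
    """One unordered gene pair; measure fields are None when invalid."""

    gene1: str
    gene2: str
    namespace: str
    n_annot1: int  # expanded-set size (0 when unannotated)
    n_annot2: int
    valid: bool
    reason: str = ""  # "", "one-unannotated" or "both-unannotated"
    sim: Optional[float] = None
    par12: Optional[float] = None
    par21: Optional[float] = None


@dataclass
class BinStat:
    """Particularity statistics for one similarity bin; empty bins are absent."""

    lo: float
    hi: float
    count: int
    mean: Optional[float]
    sd: Optional[float]
    vmin: Optional[float]
    vmax: Optional[float]


@dataclass
class ProfileCounts:
    """Mutually exclusive similarity/particularity classes over valid pairs."""

    similar_none_particular: int = 0
    similar_one_particular: int = 0
    similar_both_particular: int = 0
    dissimilar: int = 0

    @property
    def total(self) -> int:
        return (
            self.similar_none_particular
            + self.similar_one_particular
            + self.similar_both_particular
            + self.dissimilar
        )


@dataclass
class ValidityCounts:
    two_annotated: int = 0
    one_unannotated: int = 0
    both_unannotated: int = 0


@dataclass
class ProfileSummary:
    bins: list[BinStat]
    profiles: ProfileCounts
    validity: ValidityCounts
    theta_sim: float = 0.5
    theta_par: float = 0.5


def pairwise_matrix(
    g: OntologyGraph,
    backing: InformativenessModel,
    corpus: AnnotationCorpus,
    genes: Sequence[str],
    *,
    method: str = "wang",
    combine: str = "bma",
) -> list[PairResult]:
    """All unordered pairs of ``genes`` in lexicographic order.

    Genes missing from the corpus (or with an empty direct set) make a pair
    invalid rather than raising; both particularity directions are reported.
    """
    if not genes:
        raise ValueError("empty gene list")
    results: list[PairResult] = []
    ordered = sorted(set(genes))
    direct = {gene: corpus.gene_terms.get(gene, frozenset()) for gene in ordered}
    expanded_size = {
        gene: len(expand_set(g, terms)) for gene, terms in direct.items()
    }
    for g1, g2 in combinations(ordered, 2):
        s1, s2 = direct[g1], direct[g2]
        base = dict(
            gene1=g1,
            gene2=g2,
            namespace=corpus.namespace,
            n_annot1=expanded_size[g1],
            n_annot2=expanded_size[g2],
        )
        if not s1 and not s2:
            results.append(PairResult(**base, valid=False, reason="both-unannotated"))
            continue
        if not s1 or not s2:
            results.append(PairResult(**base, valid=False, reason="one-unannotated"))
            continue
        c = compare(g, backing, s1, s2, method=method, combine=combine)
        results.append(
            PairResult(
                **base,
                valid=True,
                sim=c.sim,
                par12=c.par12,
                par21=c.par21,
            )
        )
    return results


def _bin_index(sim: float) -> Optional[int]:
    """Bin of a similarity value, or None outside [0.5, 0.999]."""
    if sim < BIN_LO or sim > BIN_HI:
        return None
    return min(int((sim - BIN_LO) / BIN_WIDTH), N_BINS - 1)


def bin_particularity(
    results: Iterable[PairResult],
    *,
    sd_mode: str = "sample",
    pool_directions: bool = True,
) -> list[BinStat]:
    """Per-bin mean/sd/min/max of particularity over pairs grouped by similarity.

    Both particularity directions are pooled by default; ``pool_directions=False``
    keeps only the larger of the two per pair.  ``sd_mode`` is ``sample``
    (n-1 denominator, 0.0 for singleton bins) or ``population``.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    values: list[list[float]] = [[] for _ in range(N_BINS)]
    for r in results:
        if not r.valid or r.sim is None:
            continue
        k = _bin_index(r.sim)
        if k is None:
            continue
        if pool_directions:
            values[k].extend((r.par12, r.par21))
        else:
            values[k].append(max(r.par12, r.par21))
    bins: list[BinStat] = []
    for k, vals in enumerate(values):
        lo = round(BIN_LO + k * BIN_WIDTH, 3)
        hi = BIN_HI if k == N_BINS - 1 else round(lo + BIN_WIDTH, 3)
        if not vals:
            bins.append(BinStat(lo, hi, 0, None, None, None, None))
            continue
        n = len(vals)
        mean = sum(vals) / n
        ss = sum((v - mean) ** 2 for v in vals)
        if sd_mode == "sample":
            sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
        else:
            sd = math.sqrt(ss / n)
        bins.append(BinStat(lo, hi, n, mean, sd, min(vals), max(vals)))
    return bins


def classify_profiles(
    results: Iterable[PairResult],
    theta_sim: float = 0.5,
    theta_par: float = 0.5,
) -> ProfileCounts:
    """Assign each valid pair to exactly one similarity/particularity class."""
    if not (0.0 < theta_sim < 1.0) or not (0.0 < theta_par < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    counts = ProfileCounts()
    for r in results:
        if not r.valid:
            continue
        if r.sim < theta_sim:
            counts.dissimilar += 1
            continue
        n_par = (r.par12 >= theta_par) + (r.par21 >= theta_par)
        if n_par == 0:
            counts.similar_none_particular += 1
        elif n_par == 1:
            counts.similar_one_particular += 1
        else:
            counts.similar_both_particular += 1
    return counts


def count_validity(results: Iterable[PairResult]) -> ValidityCounts:
    counts = ValidityCounts()
    for r in results:
        if r.valid:
            counts.two_annotated += 1
        elif r.reason == "one-unannotated":
            counts.one_unannotated += 1
        else:
            counts.both_unannotated += 1
    return counts


def summarize(
    results: Sequence[PairResult],
    *,
    theta_sim: float = 0.5,
    theta_par: float = 0.5,
    sd_mode: str = "sample",
) -> ProfileSummary:
    """Bundle bin statistics, profile classes and validity accounting."""
    return ProfileSummary(
        bins=bin_particularity(results, sd_mode=sd_mode),
        profiles=classify_profiles(results, theta_sim, theta_par),
        validity=count_validity(results),
        theta_sim=theta_sim,
        theta_par=theta_par,
    )


# -- plain-text round-trip -------------------------------------------------

MATRIX_COLUMNS = (
    "gene1",
    "gene2",
    "namespace",
    "valid",
    "sim",
    "par12",
    "par21",
    "n_annot1",
    "n_annot2",
    "reason",
)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(x)


def write_matrix_tsv(results: Iterable[PairResult], path: str) -> None:
    """Write pair results with full float precision; byte-stable across runs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MATRIX_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.gene1,
                        r.gene2,
                        r.namespace,
                        "1" if r.valid else "0",
                        _fmt(r.sim),
                        _fmt(r.par12),
                        _fmt(r.par21),
                        str(r.n_annot1),
                        str(r.n_annot2),
                        r.reason,
                    )
                )
                + "\n"
            )


def read_matrix_tsv(path: str) -> list[PairResult]:
    results: list[PairResult] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MATRIX_COLUMNS:
            raise ValueError(f"{path}: unexpected matrix header {header}")
        for raw in fh:
            cols = raw.rstrip("\n").split("\t")
            row = dict(zip(MATRIX_COLUMNS, cols))
            results.append(
                PairResult(
                    gene1=row["gene1"],
                    gene2=row["gene2"],
                    namespace=row["namespace"],
                    valid=row["valid"] == "1",
                    sim=float(row["sim"]) if row["sim"] else None,
                    par12=float(row["par12"]) if row["par12"] else None,
                    par21=float(row["par21"]) if row["par21"] else None,
                    n_annot1=int(row["n_annot1"]),
                    n_annot2=int(row["n_annot2"]),
                    reason=row["reason"],
                )
            )
    return results


def write_bins_tsv(bins: Iterable[BinStat], path: str, *, decimals: int = 3) -> None:
    """Human-readable bin table; empty bins print '-' like the published tables."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("similarity_range\tcount\tmean\tsd\tmin\tmax\n")
        for b in bins:
            if b.count == 0:
                fh.write(f"{b.lo:.3f}-{b.hi:.3f}\t0\t-\t-\t-\t-\n")
            else:
                fh.write(
                    f"{b.lo:.3f}-{b.hi:.3f}\t{b.count}"
                    f"\t{b.mean:.{decimals}f}\t{b.sd:.{decimals}f}"
                    f"\t{b.vmin:.{decimals}f}\t{b.vmax:.{decimals}f}\n"
                )


def write_profiles_tsv(summary: ProfileSummary, path: str) -> None:
    p, v = summary.profiles, summary.validity
    n_valid = p.total
    rows = [
        ("similar_none_particular", p.similar_none_particular),
        ("similar_one_particular", p.similar_one_particular),
        ("similar_both_particular", p.similar_both_particular),
        ("dissimilar", p.dissimilar),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# theta_sim={summary.theta_sim!r}\ttheta_par={summary.theta_par!r}\n")
        fh.write("class\tcount\tpercent_of_valid\n")
        for name, count in rows:
            pct = 100.0 * count / n_valid if n_valid else 0.0
            fh.write(f"{name}\t{count}\t{pct:.3f}\n")
        fh.write(f"valid_two_annotated\t{v.two_annotated}\t-\n")
        fh.write(f"invalid_one_unannotated\t{v.one_unannotated}\t-\n")
        fh.write(f"invalid_both_unannotated\t{v.both_unannotated}\t-\n")
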