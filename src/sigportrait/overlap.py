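"""Hypergeometric overlap of top directional gene lists between signatures.

Implements the A/B/C/D quadrant analysis of two signed signatures, the
congruence score (same-direction agreement), the treatment-reversal score
(its negation), reversed-gene sets, treatment ranking, theoretical
treatment combinations, and generic gene-list over-representation tests.

The universe for every hypergeometric test is the set of genes measured in
*both* signatures being compared.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._log import log_event
from .ingest import SignedScoreTable
from .portrait import Portrait, rank_directional

#: Floor applied to hypergeometric p-values before -log10 (keeps scores finite).
DEFAULT_P_FLOOR = 1e-320

#: Minimum shared-gene count before a comparison is flagged incompatible.
DEFAULT_SHARED_GENE_THRESHOLD = 5000

Signature = Union[SignedScoreTable, Portrait]


@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric over-representation of two gene lists."""

    k: int
    n1: int
    n2: int
    N: int
    p: float
    nlp: float
    common: frozenset[str] = frozenset()


@dataclass(frozen=True)
class QuadrantResult:
    """A/B/C/D top-list overlap counts and their hypergeometric tails.

    A = |up1 & up2|, B = |up1 & down2|, C = |down1 & up2|, D = |down1 & down2|.
    """

    A: int
    B: int
    C: int
    D: int
    pA: float
    pB: float
    pC: float
    pD: float
    nlpA: float
    nlpB: float
    nlpC: float
    nlpD: float
    universe_size: int
    list_sizes: tuple[int, int, int, int]  # |up1|, |down1|, |up2|, |down2|
    compatible: bool = True


@dataclass(frozen=True)
class ReversalSets:
    """Genes of a disease top list moved oppositely (or identically) by a treatment."""

    down_reversed: frozenset[str]  # down in disease, up in treatment (count C)
    up_reversed: frozenset[str]    # up in disease, down in treatment (count B)
    same_direction: frozenset[str]
    quadrants: QuadrantResult | None = None

    @property
    def reversed_genes(self) -> frozenset[str]:
        return self.up_reversed | self.down_reversed

    @property
    def n_reversed(self) -> int:
        return len(self.reversed_genes)


@dataclass(frozen=True)
class CombinedReversal:
    """Union of reversed-gene sets across treatments (inclusion-exclusion consistent)."""

    genes: frozenset[str]
    count: int
    pairwise_intersections: dict[tuple[int, int], int] = field(default_factory=dict)


@dataclass(frozen=True)
class TreatmentScore:
    """One treatment's reversal score against a disease signature."""

    dataset_id: str
    score: float
    quadrants: QuadrantResult
    reversal_total: int       # B + C
    same_direction_total: int  # A + D
    compatible: bool = True


def _signature_genes(sig: Signature) -> set[str]:
    if isinstance(sig, Portrait):
        return sig.genes
    return sig.genes


def _restrict(sig: Signature, genes: set[str]) -> Signature:
    if isinstance(sig, Portrait):
        df = sig.data[sig.data["gene_symbol"].isin(genes)].reset_index(drop=True)
        return Portrait(data=df)
    s = sig.scores
    return SignedScoreTable(sig.study_id, s[s.index.isin(genes)])


def top_lists(signature: Signature, n: int = 1000) -> tuple[list[str], list[str]]:
    """First ``min(n, available)`` genes of each directional ranking.

    Signed-score tables rank by |sign1| within direction; portraits by
    |aggregate_score| (their stored order).  Short lists are logged, never
    padded.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if isinstance(signature, Portrait):
        df = signature.data
        up = df.loc[df["aggregate_score"] > 0, "gene_symbol"].tolist()
        down = df.loc[df["aggregate_score"] < 0, "gene_symbol"].tolist()
    else:
        up, down = rank_directional(signature)
    if len(up) < n or len(down) < n:
        log_event("short_top_list", requested=n, n_up=len(up), n_down=len(down))
    return up[:n], down[:n]


def hypergeom_overlap(
    list1: Iterable[str],
    list2: Iterable[str],
    universe: Iterable[str],
    p_floor: float = DEFAULT_P_FLOOR,
) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists.

    ``p = P(X >= k)`` with X ~ Hypergeometric(N=|universe|, K=|list1|,
    n=|list2|); genes outside the universe are dropped with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    l1 = set(list1)
    l2 = set(list2)
    stray = (l1 | l2) - uni
    if stray:
        warnings.warn(
            f"{len(stray)} list genes not in universe were dropped", stacklevel=2
        )
        l1 &= uni
        l2 &= uni
    common = l1 & l2
    k, K, n, N = len(common), len(l1), len(l2), len(uni)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    nlp = float(-np.log10(max(p, p_floor)))
    return OverlapResult(k=k, n1=K, n2=n, N=N, p=p, nlp=nlp, common=frozenset(common))


def quadrant_analysis(
    sig1: Signature,
    sig2: Signature,
    n: int = 1000,
    shared_gene_threshold: int = DEFAULT_SHARED_GENE_THRESHOLD,
    p_floor: float = DEFAULT_P_FLOOR,
) -> QuadrantResult:
    """A/B/C/D overlap of the two signatures' top-n directional lists.

    The universe is the intersection of genes measured in both signatures;
    both signatures are restricted to it before ranking.  A shared-gene
    count below ``shared_gene_threshold`` sets ``compatible=False`` (and is
    logged) but computation proceeds.
    """
    universe = _signature_genes(sig1) & _signature_genes(sig2)
    if not universe:
        raise ValueError("signatures share no genes")
    compatible = len(universe) >= shared_gene_threshold
    if not compatible:
        log_event(
            "compatibility_warning",
            shared_genes=len(universe),
            threshold=shared_gene_threshold,
        )
    r1 = _restrict(sig1, universe)
    r2 = _restrict(sig2, universe)
    up1, down1 = top_lists(r1, n)
    up2, down2 = top_lists(r2, n)
    oA = hypergeom_overlap(up1, up2, universe, p_floor)
    oB = hypergeom_overlap(up1, down2, universe, p_floor)
    oC = hypergeom_overlap(down1, up2, universe, p_floor)
    oD = hypergeom_overlap(down1, down2, universe, p_floor)
    return QuadrantResult(
        A=oA.k, B=oB.k, C=oC.k, D=oD.k,
        pA=oA.p, pB=oB.p, pC=oC.p, pD=oD.p,
        nlpA=oA.nlp, nlpB=oB.nlp, nlpC=oC.nlp, nlpD=oD.nlp,
        universe_size=len(universe),
        list_sizes=(len(up1), len(down1), len(up2), len(down2)),
        compatible=compatible,
    )


def congruence_score(q: QuadrantResult) -> float:
    """Same-direction agreement: nlpA + nlpD - nlpB - nlpC."""
    return q.nlpA + q.nlpD - q.nlpB - q.nlpC


def treatment_score(q: QuadrantResult) -> float:
    """Reversal score: nlpB + nlpC - nlpA - nlpD.

    Computed as the exact negation of :func:`congruence_score` so the
    identity ``treatment_score == -congruence_score`` holds bit-for-bit.
    """
    return -congruence_score(q)


def reversed_genes(
    disease_sig: Signature,
    treatment_sig: Signature,
    n: int = 1000,
    shared_gene_threshold: int = DEFAULT_SHARED_GENE_THRESHOLD,
    p_floor: float = DEFAULT_P_FLOOR,
) -> ReversalSets:
    """Disease top-list genes the treatment pushes the opposite way.

    ``down_reversed`` = down in disease & up in treatment (quadrant C);
    ``up_reversed`` = up in disease & down in treatment (quadrant B);
    ``same_direction`` = (up1 & up2) | (down1 & down2).
    """
    universe = _signature_genes(disease_sig) & _signature_genes(treatment_sig)
    if not universe:
        raise ValueError("signatures share no genes")
    q = quadrant_analysis(disease_sig, treatment_sig, n, shared_gene_threshold, p_floor)
    r1 = _restrict(disease_sig, universe)
    r2 = _restrict(treatment_sig, universe)
    up1, down1 = (set(x) for x in top_lists(r1, n))
    up2, down2 = (set(x) for x in top_lists(r2, n))
    return ReversalSets(
        down_reversed=frozenset(down1 & up2),
        up_reversed=frozenset(up1 & down2),
        same_direction=frozenset((up1 & up2) | (down1 & down2)),
        quadrants=q,
    )


def combine_treatments(
    reversal_sets: Sequence[ReversalSets | tuple[Iterable[str], Iterable[str]]],
) -> CombinedReversal:
    """Union of reversed genes across treatments scored against one disease.

    Accepts :class:`ReversalSets` or raw ``(up_reversed, down_reversed)``
    pairs; also reports pairwise intersection sizes so inclusion-exclusion
    can be checked against the union count.
    """
    if len(reversal_sets) < 2:
        raise ValueError("combine_treatments needs at least two reversal sets")
    per_treatment: list[frozenset[str]] = []
    for item in reversal_sets:
        if isinstance(item, ReversalSets):
            per_treatment.append(item.reversed_genes)
        else:
            up, down = item
            per_treatment.append(frozenset(up) | frozenset(down))
    combined: frozenset[str] = frozenset().union(*per_treatment)
    pairwise = {
        (i, j): len(per_treatment[i] & per_treatment[j])
        for i in range(len(per_treatment))
        for j in range(i + 1, len(per_treatment))
    }
    return CombinedReversal(
        genes=combined, count=len(combined), pairwise_intersections=pairwise
    )


def rank_treatments(
    disease: Signature,
    treatments: Sequence[SignedScoreTable],
    n: int = 1000,
    shared_gene_threshold: int = DEFAULT_SHARED_GENE_THRESHOLD,
    p_floor: float = DEFAULT_P_FLOOR,
    strict: bool = False,
) -> list[TreatmentScore]:
    """Score every treatment against the disease signature, best first.

    Ordering: score desc, ties by reversal_total desc, then dataset_id.
    ``strict=True`` excludes incompatible treatments (shared genes below
    threshold) instead of merely flagging them.
    """
    results: list[TreatmentScore] = []
    for t in treatments:
        q = quadrant_analysis(disease, t, n, shared_gene_threshold, p_floor)
        if strict and not q.compatible:
            log_event("treatment_excluded_incompatible", dataset_id=t.study_id,
                      shared_genes=q.universe_size)
            continue
        results.append(
            TreatmentScore(
                dataset_id=t.study_id,
                score=treatment_score(q),
                quadrants=q,
                reversal_total=q.B + q.C,
                same_direction_total=q.A + q.D,
                compatible=q.compatible,
            )
        )
    results.sort(key=lambda r: (-r.score, -r.reversal_total, r.dataset_id))
    return results


def treatment_table(scores: Sequence[TreatmentScore]) -> pd.DataFrame:
    """Flatten ranked treatment scores into a writable table."""
    rows = []
    for rank, r in enumerate(scores, start=1):
        q = r.quadrants
        rows.append(
            {
                "rank": rank,
                "dataset_id": r.dataset_id,
                "score": r.score,
                "A": q.A, "B": q.B, "C": q.C, "D": q.D,
                "nlpA": q.nlpA, "nlpB": q.nlpB, "nlpC": q.nlpC, "nlpD": q.nlpD,
                "reversal_total": r.reversal_total,
                "same_direction_total": r.same_direction_total,
                "universe_size": q.universe_size,
                "compatible": r.compatible,
            }
        )
    columns = [
        "rank", "dataset_id", "score", "A", "B", "C", "D",
        "nlpA", "nlpB", "nlpC", "nlpD",
        "reversal_total", "same_direction_total", "universe_size", "compatible",
    ]
    return pd.DataFrame(rows, columns=columns)


def gene_list_overlap(
    list_a: Iterable[str],
    signature_top: Iterable[str],
    universe: Iterable[str],
    p_floor: float = DEFAULT_P_FLOOR,
) -> OverlapResult:
    """Over-representation of an undirected gene list in a signature's top genes."""
    return hypergeom_overlap(list_a, signature_top, universe, p_floor)
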