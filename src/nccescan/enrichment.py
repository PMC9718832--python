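"""Nearest-gene assignment and control-matched term enrichment.

Each conserved composite element is assigned to the gene whose TSS is
nearest to the midpoint of its two motif centers (exact rational
arithmetic; ties go to the lexicographically smallest gene id). The
genes nearest to conserved NCCE form the NCCE+ set; genes nearest to
each control class form control sets built under identical
conservation and synteny filters.

Enrichment of a term in NCCE+ against a control set is a one-sided
Fisher exact test on the 2x2 table over the disjointified sets (genes
in both sets are dropped from both), with Haldane-corrected odds
ratios when a cell is empty and Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .genome_io import GeneModel
from .pairing import SYNTENY_PASS, CompositeElement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    label: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise UsageError(f"gene set {self.label}: duplicate ids")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    count_in_test: int
    count_in_control: int
    test_set_size: int
    control_set_size: int
    odds_ratio: float
    p_value: float
    q_value: float


def nearest_gene(ce: CompositeElement, genes: Sequence[GeneModel]) -> str | None:
    """Gene whose TSS minimizes distance to the composite midpoint.

    The midpoint of the two motif centers is midpoint2/4 bp, so the
    comparison |midpoint2 - 4*tss| is exact in integers. Genes on other
    chromosomes are never considered; none on the chromosome yields
    None with a logged warning (the element stays unassigned).
    """
    candidates = [g for g in genes if g.interval.chrom == ce.chrom]
    if not candidates:
        logger.warning(
            "composite %s: no gene on chromosome %s, left unassigned",
            ce.ce_id, ce.chrom,
        )
        return None
    m2 = ce.midpoint2
    return min(candidates, key=lambda g: (abs(m2 - 4 * g.tss), g.gene_id)).gene_id


def assign_nearest_genes(
    ces: Sequence[CompositeElement], genes: Sequence[GeneModel]
) -> list[CompositeElement]:
    return [replace(ce, nearest_gene_id=nearest_gene(ce, genes)) for ce in ces]


def build_gene_sets(
    ces_by_class: Mapping[str, Sequence[CompositeElement]],
    genes: Sequence[GeneModel],
) -> dict[str, GeneSet]:
    """One deduplicated gene set per composite class. Every class must
    already have passed synteny verification: a gene counts once per
    set however many elements point at it."""
    sets: dict[str, GeneSet] = {}
    for label, ces in ces_by_class.items():
        seen: set[str] = set()
        ordered: list[str] = []
        for ce in ces:
            if ce.synteny_conserved != SYNTENY_PASS:
                raise UsageError(
                    f"composite {ce.ce_id} in class {label} has not passed "
                    "synteny verification"
                )
            gid = ce.nearest_gene_id
            if gid is None:
                gid = nearest_gene(ce, genes)
            if gid is not None and gid not in seen:
                seen.add(gid)
                ordered.append(gid)
        if not ordered:
            logger.warning("class %s produced an empty gene set", label)
        sets[label] = GeneSet(label, tuple(ordered))
    return sets


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich_terms(
    test: GeneSet,
    control: GeneSet,
    term_map: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """One-sided (greater-in-test) exact enrichment of every term
    annotated to at least one gene of test or control, after dropping
    genes present in both sets from both. Results are sorted by
    (q, p, term)."""
    test_ids = set(test.gene_ids)
    control_ids = set(control.gene_ids)
    shared = test_ids & control_ids
    if shared:
        logger.info(
            "enrich %s vs %s: dropping %d genes present in both sets",
            test.label, control.label, len(shared),
        )
    t_set = test_ids - shared
    c_set = control_ids - shared
    if not t_set or not c_set:
        raise UsageError("empty test or control set after disjointification")

    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id]
        a = len(t_set & members)
        c = len(c_set & members)
        if a == 0 and c == 0:
            continue
        b = len(t_set) - a
        d = len(c_set) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term_id, a, c, b, d, float(p)))
    if not rows:
        return []

    qs = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=term_id,
            count_in_test=a,
            count_in_control=c,
            test_set_size=len(t_set),
            control_set_size=len(c_set),
            odds_ratio=_odds_ratio(a, b, c, d),
            p_value=p,
            q_value=float(q),
        )
        for (term_id, a, c, b, d, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def enrichment_rows(results: Sequence[EnrichmentResult], control_label: str) -> list[list]:
    return [
        [
            r.term_id, r.count_in_test, r.count_in_control,
            r.test_set_size, r.control_set_size,
            f"{r.odds_ratio:.6g}", f"{r.p_value:.6g}", f"{r.q_value:.6g}",
            control_label,
        ]
        for r in results
    ]
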