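"""End-to-end orchestration of the composite-element screen.

Stage order is fixed: scan conserved elements for every motif role,
pair hits into composite classes, verify syntenic conservation of
every class through the chains (controls are filtered exactly like the
test class), assign nearest genes, build gene sets and run the
control-matched enrichment. Each stage reports in/kept/dropped counts
so any filter can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enrichment import (
    EnrichmentResult,
    GeneSet,
    assign_nearest_genes,
    build_gene_sets,
    enrich_terms,
)
from .errors import UsageError
from .genome_io import (
    ChainAlignment,
    ConservedElement,
    GeneModel,
    GenomeSequence,
)
from .liftover import filter_conserved, verify_synteny
from .motifs import DEFAULT_MOTIFS, MotifDefinition, MotifHit, scan_in_elements
from .pairing import (
    ALL_CLASSES,
    NCCE,
    CompositeElement,
    SpacingWindow,
    build_all_classes,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    hits_by_role: dict[str, list[MotifHit]]
    ces_by_class: dict[str, list[CompositeElement]]  # synteny-tested
    conserved_by_class: dict[str, list[CompositeElement]]  # pass only, genes assigned
    gene_sets: dict[str, GeneSet]
    enrichment: dict[str, list[EnrichmentResult]]  # keyed by control class
    stage_summaries: list[dict] = field(default_factory=list)


def run_screen(
    query_genome: GenomeSequence,
    elements: Sequence[ConservedElement],
    chains: Sequence[ChainAlignment],
    target_genome: GenomeSequence,
    genes: Sequence[GeneModel],
    term_map: Mapping[str, set[str]],
    motifs: Mapping[str, MotifDefinition] | None = None,
    windows: Mapping[str, SpacingWindow] | None = None,
    min_score: float = 300.0,
) -> ScreenResult:
    motifs = dict(DEFAULT_MOTIFS if motifs is None else motifs)
    summaries: list[dict] = []

    hits_by_role = {
        role: scan_in_elements(query_genome, motifs[role], elements, min_score)
        for role in motifs
    }
    summaries.append(
        {"stage": "scan", "hits": {r: len(h) for r, h in hits_by_role.items()}}
    )

    ces_by_class = build_all_classes(hits_by_role, windows)
    summaries.append(
        {"stage": "pair", "composites": {c: len(v) for c, v in ces_by_class.items()}}
    )

    tested = {
        cls: [verify_synteny(ce, chains, target_genome, motifs) for ce in ces]
        for cls, ces in ces_by_class.items()
    }
    conserved = {cls: filter_conserved(ces) for cls, ces in tested.items()}
    summaries.append(
        {
            "stage": "lift",
            "kept": {c: len(v) for c, v in conserved.items()},
            "dropped": {c: len(tested[c]) - len(v) for c, v in conserved.items()},
        }
    )

    conserved = {
        cls: assign_nearest_genes(ces, genes) for cls, ces in conserved.items()
    }
    # carry assigned gene ids back onto the full tested lists
    for cls, ces in tested.items():
        assigned_by_id = {ce.ce_id: ce for ce in conserved[cls]}
        tested[cls] = [assigned_by_id.get(ce.ce_id, ce) for ce in ces]
    unassigned = sum(
        ce.nearest_gene_id is None for ces in conserved.values() for ce in ces
    )
    summaries.append({"stage": "assign", "unassigned": unassigned})

    gene_sets = build_gene_sets(conserved, genes)
    summaries.append(
        {"stage": "gene-sets", "sizes": {c: len(s.gene_ids) for c, s in gene_sets.items()}}
    )

    enrichment: dict[str, list[EnrichmentResult]] = {}
    test_set = gene_sets[NCCE]
    for cls in ALL_CLASSES:
        if cls == NCCE:
            continue
        try:
            enrichment[cls] = enrich_terms(test_set, gene_sets[cls], term_map)
        except UsageError as exc:
            logger.warning("enrichment vs %s skipped: %s", cls, exc)
            enrichment[cls] = []
    summaries.append(
        {"stage": "enrich", "terms_tested": {c: len(r) for c, r in enrichment.items()}}
    )

    return ScreenResult(
        hits_by_role=hits_by_role,
        ces_by_class=tested,
        conserved_by_class=conserved,
        gene_sets=gene_sets,
        enrichment=enrichment,
        stage_summaries=summaries,
    )
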