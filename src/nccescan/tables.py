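"""Plain-text stage outputs: every pipeline stage reads and writes TSV
or JSON so stages can be diffed, resumed and unit-tested in isolation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrichment import EnrichmentResult, GeneSet
from .errors import FormatError
from .genome_io import Interval
from .motifs import MotifHit
from .pairing import CompositeElement

HITS_HEADER = (
    "chrom", "start", "end", "motif_id", "role", "strand",
    "matched_seq", "element_id",
)

CE_HEADER = (
    "chrom", "ce_id", "class", "element_id",
    "nkx_start", "nkx_end", "nkx_strand", "nkx_motif",
    "partner_start", "partner_end", "partner_strand", "partner_motif",
    "spacing2", "strands_seen", "synteny", "synteny_detail", "nearest_gene",
)


def write_hits(hits_by_role: Mapping[str, Sequence[MotifHit]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HITS_HEADER) + "\n")
        for role in sorted(hits_by_role):
            for h in hits_by_role[role]:
                iv = h.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.motif_id}\t{role}\t"
                    f"{iv.strand}\t{h.matched_sequence}\t{h.container_element_id or '.'}\n"
                )


def read_hits(path: str | Path) -> dict[str, list[MotifHit]]:
    out: dict[str, list[MotifHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(HITS_HEADER):
                raise FormatError(f"{path}:{lineno}: expected {len(HITS_HEADER)} columns")
            chrom, start, end, motif_id, role, strand, seq, el = cols
            out.setdefault(role, []).append(
                MotifHit(
                    motif_id,
                    Interval(chrom, int(start), int(end), strand),
                    seq,
                    None if el == "." else el,
                )
            )
    return out


def write_composites(ces: Iterable[CompositeElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CE_HEADER) + "\n")
        for ce in ces:
            n, p = ce.nkx_hit, ce.partner_hit
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ce.chrom, ce.ce_id, ce.class_label, ce.element_id,
                        n.interval.start, n.interval.end, n.interval.strand, n.motif_id,
                        p.interval.start, p.interval.end, p.interval.strand, p.motif_id,
                        ce.spacing2, ",".join(ce.strands_seen) or ".",
                        ce.synteny_conserved, ce.synteny_detail or ".",
                        ce.nearest_gene_id or ".",
                    )
                )
                + "\n"
            )


def read_composites(path: str | Path) -> list[CompositeElement]:
    ces: list[CompositeElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(CE_HEADER):
                raise FormatError(f"{path}:{lineno}: expected {len(CE_HEADER)} columns")
            (
                chrom, ce_id, cls, el, ns, ne, nstr, nmot,
                ps, pe, pstr, pmot, sp2, seen, synteny, detail, gene,
            ) = cols
            nkx = MotifHit(nmot, Interval(chrom, int(ns), int(ne), nstr), "", el)
            partner = MotifHit(pmot, Interval(chrom, int(ps), int(pe), pstr), "", el)
            ces.append(
                CompositeElement(
                    ce_id=ce_id,
                    nkx_hit=nkx,
                    partner_hit=partner,
                    element_id=el,
                    spacing2=int(sp2),
                    class_label=cls,
                    strands_seen=tuple() if seen == "." else tuple(seen.split(",")),
                    synteny_conserved=synteny,
                    synteny_detail="" if detail == "." else detail,
                    nearest_gene_id=None if gene == "." else gene,
                )
            )
    return ces


def group_by_class(ces: Iterable[CompositeElement]) -> dict[str, list[CompositeElement]]:
    out: dict[str, list[CompositeElement]] = {}
    for ce in ces:
        out.setdefault(ce.class_label, []).append(ce)
    return out


def write_gene_sets(gene_sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {label: list(gs.gene_ids) for label, gs in sorted(gene_sets.items())},
            fh, indent=1,
        )
        fh.write("\n")


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    with open(path) as fh:
        raw = json.load(fh)
    return {label: GeneSet(label, tuple(ids)) for label, ids in raw.items()}


ENRICH_HEADER = (
    "term_id", "count_in_test", "count_in_control", "test_set_size",
    "control_set_size", "odds_ratio", "p_value", "q_value", "control",
)


def write_enrichment(results: Sequence[EnrichmentResult], control_label: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ENRICH_HEADER) + "\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.count_in_test}\t{r.count_in_control}\t"
                f"{r.test_set_size}\t{r.control_set_size}\t{r.odds_ratio:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{control_label}\n"
            )


def read_enrichment(path: str | Path) -> list[EnrichmentResult]:
    out: list[EnrichmentResult] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            out.append(
                EnrichmentResult(
                    term_id=cols[0],
                    count_in_test=int(cols[1]),
                    count_in_control=int(cols[2]),
                    test_set_size=int(cols[3]),
                    control_set_size=int(cols[4]),
                    odds_ratio=float(cols[5]),
                    p_value=float(cols[6]),
                    q_value=float(cols[7]),
                )
            )
    return out
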