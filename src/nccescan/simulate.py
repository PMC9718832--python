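"""Seeded two-genome test-bundle generator with an exact truth manifest.

The generator emulates the inputs of the composite-element screen at
desk scale: a query genome of background sequence with conserved
islands, planted NKX/partner motif pairs at controlled center-to-center
spacings, a target genome derived from the query through an alignment
chain (insertions, deletions, optional whole-chromosome inversion),
gene models with defined TSSs, and a term map with an engineered
enrichment in genes near planted elements.

Chance motif pairs arising in the random background are not rejected
away: after planting, the generator scans its own output with the same
detection rules the screen uses and appends every chance composite to
the truth manifest, so recovery metrics are exact by construction.

A single root seed drives per-component child streams derived from
fixed labels, so adding a component never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataConsistencyError
from .genome_io import (
    ChainAlignment,
    ConservedElement,
    GeneModel,
    GenomeSequence,
    Interval,
    revcomp,
    write_bed,
    write_chain,
    write_fasta,
    write_gene_table,
    write_term_map,
)
from .liftover import map_interval, verify_synteny
from .motifs import (
    DEFAULT_MOTIFS,
    IUPAC,
    MotifDefinition,
    iupac_match,
    scan_in_elements,
)
from .pairing import (
    ALL_CLASSES,
    NCCE,
    SYNTENY_PASS,
    WIDE_CONTROL,
    CompositeElement,
    build_all_classes,
    window_for_class,
)

SCHEMA_VERSION = 1

_STREAM_LABELS = {
    "sequence": 11, "elements": 23, "plants": 37, "chain": 41,
    "mutations": 53, "genes": 67, "terms": 79,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe the standard desk-scale scenario: a 1 Mb query
    genome over two chromosomes, 200 conserved islands whose scores
    span the 300 log-odds threshold, ten planted composites per class,
    no synteny breaking and no decoys.
    """

    seed: int = 42
    genome_length: int = 1_000_000
    chrom_count: int = 2
    element_count: int = 200
    element_length_range: tuple[int, int] = (150, 300)
    score_range: tuple[float, float] = (150.0, 600.0)
    min_conservation_score: float = 300.0
    planted_per_class: dict[str, int] = field(
        default_factory=lambda: {cls: 10 for cls in ALL_CLASSES}
    )
    out_of_window_decoys: int = 0
    below_threshold_decoys: int = 0
    synteny_break_rate: float = 0.0
    indels_per_chrom: int = 3
    indel_length_range: tuple[int, int] = (5, 40)
    invert_last_chrom: bool = True
    gene_count: int = 80
    term_count: int = 15
    enriched_term_prob_near: float = 0.8
    enriched_term_prob_other: float = 0.1
    background_term_prob: float = 0.2
    background_gc: float = 0.42

    def validate(self) -> None:
        if not 0 <= self.synteny_break_rate <= 1:
            raise ConfigError("synteny-break rate must be in [0, 1]")
        for p in (
            self.enriched_term_prob_near,
            self.enriched_term_prob_other,
            self.background_term_prob,
        ):
            if not 0 <= p <= 1:
                raise ConfigError("term probabilities must be in [0, 1]")
        if any(n < 0 for n in self.planted_per_class.values()):
            raise ConfigError("planted counts must be >= 0")
        if self.chrom_count < 1 or self.element_count < 1:
            raise ConfigError("need at least one chromosome and one element")


@dataclass
class Bundle:
    """In-memory synthetic bundle plus its truth manifest."""

    config: SimulationConfig
    query_genome: GenomeSequence
    target_genome: GenomeSequence
    elements: list[ConservedElement]
    chains: list[ChainAlignment]
    genes: list[GeneModel]
    term_map: dict[str, set[str]]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.query_genome, outdir / "query.fa")
        write_fasta(self.target_genome, outdir / "target.fa")
        write_bed(self.elements, outdir / "conserved.bed")
        write_chain(self.chains, outdir / "alignment.chain")
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_term_map(self.term_map, outdir / "terms.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _rng(config: SimulationConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM_LABELS[label]])


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _realize(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        IUPAC[c][rng.integers(len(IUPAC[c]))] for c in consensus
    )


def generate_bundle(config: SimulationConfig, outdir: str | Path | None = None) -> Bundle:
    """Build a complete bundle; byte-identical for identical configs.

    Raises ConfigError before writing anything if the requested
    elements cannot be packed into the genome.
    """
    config.validate()
    motifs = DEFAULT_MOTIFS

    # --- chromosome scaffolds -------------------------------------------
    chrom_len = config.genome_length // config.chrom_count
    chrom_names = [f"chr{i + 1}" for i in range(config.chrom_count)]
    per_chrom_elements = _split_count(config.element_count, config.chrom_count)

    max_el = config.element_length_range[1]
    for n_el in per_chrom_elements:
        if n_el and chrom_len // n_el < max_el + 100:
            raise ConfigError(
                f"cannot pack {n_el} elements of up to {max_el} bp plus "
                f"spacing into a {chrom_len} bp chromosome"
            )

    rng_seq = _rng(config, "sequence")
    query_arrays = {
        name: _random_sequence(rng_seq, chrom_len, config.background_gc)
        for name in chrom_names
    }

    # --- conserved islands ----------------------------------------------
    rng_el = _rng(config, "elements")
    elements: list[ConservedElement] = []
    for name, n_el in zip(chrom_names, per_chrom_elements):
        slot = chrom_len // max(n_el, 1)
        for k in range(n_el):
            length = int(rng_el.integers(*config.element_length_range, endpoint=True))
            lo = k * slot + 50
            hi = (k + 1) * slot - length - 50
            start = int(rng_el.integers(lo, hi + 1))
            score = float(
                np.round(rng_el.uniform(*config.score_range), 1)
            )
            elements.append(
                ConservedElement(
                    Interval(name, start, start + length),
                    score,
                    f"el_{name}_{k:04d}",
                )
            )

    # --- plant composites -----------------------------------------------
    rng_pl = _rng(config, "plants")
    plant_specs: list[tuple[str, bool, bool]] = []  # (class, oow_decoy, subthreshold)
    for cls in ALL_CLASSES:
        plant_specs += [(cls, False, False)] * config.planted_per_class.get(cls, 0)
    plant_specs += [(NCCE, True, False)] * config.out_of_window_decoys
    plant_specs += [(NCCE, False, True)] * config.below_threshold_decoys

    if len(plant_specs) > len(elements):
        raise ConfigError(
            f"{len(plant_specs)} planted composites need distinct host "
            f"elements but only {len(elements)} exist"
        )
    host_order = rng_pl.permutation(len(elements))
    threshold = config.min_conservation_score
    planted: list[dict] = []
    elements_out: list[ConservedElement] = list(elements)

    for spec_i, (cls, oow, subthr) in enumerate(plant_specs):
        host_idx = int(host_order[spec_i])
        el = elements[host_idx]
        # host score: strictly above threshold, or exactly at it for
        # the strict-inequality decoys
        score = (
            threshold
            if subthr
            else float(np.round(rng_pl.uniform(threshold + 1, config.score_range[1]), 1))
        )
        el = ConservedElement(el.interval, score, el.element_id)
        elements_out[host_idx] = el

        nkx_def = motifs["NKX"]
        partner_role = "COUP" if cls in (NCCE, WIDE_CONTROL) else cls
        partner_def = motifs[partner_role]

        if oow:
            w = window_for_class(NCCE)
            spacing = int(w.max_bp) + 1 + int(rng_pl.integers(0, 8))
        else:
            w = window_for_class(cls)
            spacing = int(rng_pl.integers(int(w.min_bp), int(w.max_bp) + 1))

        placement = _place_pair(
            rng_pl, el.interval, nkx_def, partner_def, spacing
        )
        nkx_iv, nkx_strand, part_iv, part_strand = placement

        arr = query_arrays[el.interval.chrom]
        for iv, strand, mdef in (
            (nkx_iv, nkx_strand, nkx_def),
            (part_iv, part_strand, partner_def),
        ):
            inst = _realize(rng_pl, mdef.consensus)
            if strand == "-":
                inst = revcomp(inst)
            arr[iv.start : iv.end] = np.frombuffer(inst.encode(), dtype=np.uint8)

        planted.append(
            {
                "class": cls,
                "chrom": el.interval.chrom,
                "nkx": [nkx_iv.start, nkx_iv.end, nkx_strand],
                "partner": [part_iv.start, part_iv.end, part_strand],
                "spacing_bp": spacing,
                "element_id": el.element_id,
                "out_of_window_decoy": oow,
                "below_threshold_decoy": subthr,
            }
        )

    query_genome = GenomeSequence(
        {name: arr.tobytes().decode() for name, arr in query_arrays.items()}
    )

    # --- target genome + chains -----------------------------------------
    rng_ch = _rng(config, "chain")
    chains: list[ChainAlignment] = []
    target_arrays: dict[str, np.ndarray] = {}
    for ci, name in enumerate(chrom_names):
        invert = config.invert_last_chrom and ci == config.chrom_count - 1
        chain, target_arr = _build_chain(
            rng_ch,
            config,
            name,
            query_arrays[name],
            [e.interval for e in elements_out if e.interval.chrom == name],
            chain_id=ci + 1,
            target_name=f"t_{name}",
            invert=invert,
        )
        chains.append(chain)
        target_arrays[chain.target_chrom] = target_arr

    # --- synteny-breaking mutations --------------------------------------
    rng_mut = _rng(config, "mutations")
    for plant in planted:
        if plant["below_threshold_decoy"]:
            plant["intended_synteny"] = "n/a"
            continue
        breaking = rng_mut.random() < config.synteny_break_rate
        plant["intended_synteny"] = "fail" if breaking else "pass"
        if not breaking:
            continue
        which = "nkx" if rng_mut.random() < 0.5 else "partner"
        s, e, _ = plant[which]
        mdef = (
            motifs["NKX"]
            if which == "nkx"
            else motifs["COUP" if plant["class"] in (NCCE, WIDE_CONTROL) else plant["class"]]
        )
        mi = map_interval(chains, Interval(plant["chrom"], s, e))
        if mi is None:  # planted motif landed on a chain gap: already broken
            continue
        _break_motif(rng_mut, target_arrays[mi.mapped.chrom], mi.mapped, mdef)

    target_genome = GenomeSequence(
        {name: arr.tobytes().decode() for name, arr in target_arrays.items()}
    )

    # --- self-scan: the manifest lists everything detectable -------------
    hits_by_role = {
        role: scan_in_elements(query_genome, motifs[role], elements_out, threshold)
        for role in motifs
    }
    ces_by_class = build_all_classes(hits_by_role)
    tested_by_class = {
        cls: [
            verify_synteny(ce, chains, target_genome, motifs)
            for ce in ces
        ]
        for cls, ces in ces_by_class.items()
    }

    planted_keys = {
        (p["class"], p["chrom"], p["nkx"][0], p["nkx"][1], p["partner"][0], p["partner"][1])
        for p in planted
        if not p["below_threshold_decoy"] and not p["out_of_window_decoy"]
    }

    manifest_composites: list[dict] = []
    for cls in ALL_CLASSES:
        for ce in tested_by_class[cls]:
            key = (
                cls, ce.chrom,
                ce.nkx_hit.interval.start, ce.nkx_hit.interval.end,
                ce.partner_hit.interval.start, ce.partner_hit.interval.end,
            )
            manifest_composites.append(
                {
                    "class": cls,
                    "chrom": ce.chrom,
                    "nkx": [ce.nkx_hit.interval.start, ce.nkx_hit.interval.end],
                    "partner": [ce.partner_hit.interval.start, ce.partner_hit.interval.end],
                    "spacing_bp": ce.spacing_bp,
                    "element_id": ce.element_id,
                    "synteny": ce.synteny_conserved,
                    "planted": key in planted_keys,
                }
            )

    # --- genes ------------------------------------------------------------
    rng_g = _rng(config, "genes")
    genes = _place_genes(rng_g, config, chrom_names, chrom_len, manifest_composites)

    # expected nearest gene per conserved composite: brute-force all-pairs
    tss = {
        g.gene_id: (g.interval.chrom, g.tss) for g in genes
    }
    for mc in manifest_composites:
        if mc["synteny"] != SYNTENY_PASS:
            mc["expected_gene"] = None
            continue
        m2 = (mc["nkx"][0] + mc["nkx"][1] - 1) + (mc["partner"][0] + mc["partner"][1] - 1)
        best = min(
            (
                (abs(m2 - 4 * pos), gid)
                for gid, (chrom, pos) in tss.items()
                if chrom == mc["chrom"]
            ),
            default=None,
        )
        mc["expected_gene"] = best[1] if best else None

    expected_gene_sets: dict[str, list[str]] = {}
    for cls in ALL_CLASSES:
        seen: set[str] = set()
        ordered: list[str] = []
        for mc in manifest_composites:
            if mc["class"] == cls and mc["synteny"] == SYNTENY_PASS:
                gid = mc["expected_gene"]
                if gid and gid not in seen:
                    seen.add(gid)
                    ordered.append(gid)
        expected_gene_sets[cls] = ordered

    # --- term map ---------------------------------------------------------
    rng_t = _rng(config, "terms")
    ncce_genes = set(expected_gene_sets[NCCE])
    term_map: dict[str, set[str]] = {}
    enriched_term = "T000"
    term_map[enriched_term] = {
        g.gene_id
        for g in genes
        if rng_t.random()
        < (
            config.enriched_term_prob_near
            if g.gene_id in ncce_genes
            else config.enriched_term_prob_other
        )
    }
    for k in range(1, config.term_count):
        term_map[f"T{k:03d}"] = {
            g.gene_id for g in genes if rng_t.random() < config.background_term_prob
        }

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "threshold": threshold,
        "composites": manifest_composites,
        "planted": planted,
        "expected_gene_sets": expected_gene_sets,
        "enriched_terms": [enriched_term],
        "class_counts": {
            cls: {
                "detectable": sum(m["class"] == cls for m in manifest_composites),
                "conserved": sum(
                    m["class"] == cls and m["synteny"] == SYNTENY_PASS
                    for m in manifest_composites
                ),
            }
            for cls in ALL_CLASSES
        },
    }

    bundle = Bundle(
        config=config,
        query_genome=query_genome,
        target_genome=target_genome,
        elements=elements_out,
        chains=chains,
        genes=genes,
        term_map=term_map,
        manifest=manifest,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total % parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _place_pair(
    rng: np.random.Generator,
    element: Interval,
    nkx_def: MotifDefinition,
    partner_def: MotifDefinition,
    spacing_bp: int,
):
    """Choose non-overlapping intervals for an NKX/partner pair with the
    requested center-to-center spacing, wholly inside the element."""
    ln, lp = len(nkx_def), len(partner_def)
    # doubled-coordinate geometry: center2 = 2*start + len - 1
    downstream = rng.random() < 0.5
    span_needed = spacing_bp + (ln + lp)  # generous footprint bound
    lo = element.start + 2
    hi = element.end - 2 - span_needed
    if hi < lo:
        raise ConfigError(
            f"element {element.chrom}:{element.start}-{element.end} too short "
            f"for a pair at {spacing_bp} bp spacing"
        )
    nkx_start = int(rng.integers(lo, hi + 1))
    nkx_c2 = 2 * nkx_start + ln - 1
    part_c2 = nkx_c2 + 2 * spacing_bp if downstream else nkx_c2 - 2 * spacing_bp
    part_start = (part_c2 - lp + 1) // 2
    if part_start < element.start + 1 or part_start + lp > element.end - 1:
        # upstream placement fell off the element: flip downstream
        part_c2 = nkx_c2 + 2 * spacing_bp
        part_start = (part_c2 - lp + 1) // 2
    nkx_iv = Interval(element.chrom, nkx_start, nkx_start + ln)
    part_iv = Interval(element.chrom, part_start, part_start + lp)
    nkx_strand = "+" if rng.random() < 0.5 else "-"
    part_strand = "+" if rng.random() < 0.5 else "-"
    return nkx_iv, nkx_strand, part_iv, part_strand


def _build_chain(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom: str,
    query_arr: np.ndarray,
    element_ivs: list[Interval],
    chain_id: int,
    target_name: str,
    invert: bool,
) -> tuple[ChainAlignment, np.ndarray]:
    """Transform one query chromosome into a target chromosome and the
    chain aligning them. Indels land strictly between conserved
    elements so every element maps contiguously; an inverted chromosome
    is stored reverse-complemented with a minus-strand chain."""
    qlen = len(query_arr)
    # candidate indel positions: midpoints of inter-element gaps
    sorted_ivs = sorted(element_ivs, key=lambda iv: iv.start)
    gaps = []
    prev = 0
    for iv in sorted_ivs:
        if iv.start - prev > 200:
            gaps.append((prev + 50, iv.start - 50))
        prev = iv.end
    if qlen - prev > 200:
        gaps.append((prev + 50, qlen - 50))
    n_indels = min(config.indels_per_chrom, len(gaps))
    chosen = sorted(
        rng.choice(len(gaps), size=n_indels, replace=False).tolist()
    )

    events = []  # (query_pos, kind, length)
    for gi in chosen:
        lo, hi = gaps[gi]
        pos = int(rng.integers(lo, hi))
        kind = "del" if rng.random() < 0.5 else "ins"
        length = int(rng.integers(*config.indel_length_range, endpoint=True))
        events.append((pos, kind, length))
    events.sort()

    blocks: list[tuple[int, int, int]] = []
    target_parts: list[np.ndarray] = []
    q = 0
    for pos, kind, length in events:
        size = pos - q
        target_parts.append(query_arr[q:pos])
        if kind == "del":
            blocks.append((size, length, 0))
            q = pos + length
        else:
            blocks.append((size, 0, length))
            target_parts.append(
                _random_sequence(rng, length, config.background_gc)
            )
            q = pos
    target_parts.append(query_arr[q:])
    blocks.append((qlen - q, 0, 0))

    target_arr = np.concatenate(target_parts)
    tlen = len(target_arr)
    chain = ChainAlignment(
        chain_id=chain_id,
        score=float(qlen),
        query_chrom=chrom,
        query_size=qlen,
        query_start=0,
        query_end=qlen,
        target_chrom=target_name,
        target_size=tlen,
        target_strand="-" if invert else "+",
        target_start=0,
        target_end=tlen,
        blocks=tuple(blocks),
    )
    if invert:
        comp = np.empty(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b
        target_arr = comp[target_arr[::-1]]
    return chain, target_arr


def _break_motif(
    rng: np.random.Generator,
    target_arr: np.ndarray,
    mapped: Interval,
    mdef: MotifDefinition,
) -> None:
    """Point-mutate the mapped site so the consensus matches on neither
    target strand."""
    window = target_arr[mapped.start : mapped.end].tobytes().decode()
    positions = rng.permutation(len(window)).tolist()
    for pos in positions:
        for base in "ACGT":
            if base == window[pos]:
                continue
            mutated = window[:pos] + base + window[pos + 1 :]
            if not (
                iupac_match(mdef.consensus, mutated)
                or iupac_match(mdef.consensus, revcomp(mutated))
            ):
                target_arr[mapped.start + pos] = ord(base)
                return
    raise DataConsistencyError(
        f"could not break motif {mdef.motif_id} at "
        f"{mapped.chrom}:{mapped.start}-{mapped.end}"
    )


def _place_genes(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom_names: list[str],
    chrom_len: int,
    manifest_composites: list[dict],
) -> list[GeneModel]:
    """One dedicated gene per conserved composite (TSS within 200 bp of
    the composite midpoint) plus background genes placed well away."""
    genes: list[GeneModel] = []
    taken: dict[str, list[int]] = {name: [] for name in chrom_names}
    gi = 0

    conserved = [m for m in manifest_composites if m["synteny"] == SYNTENY_PASS]
    for mc in conserved:
        mid = (
            (mc["nkx"][0] + mc["nkx"][1] - 1)
            + (mc["partner"][0] + mc["partner"][1] - 1)
        ) // 4
        tss = mid + int(rng.integers(-200, 201))
        tss = max(2100, min(chrom_len - 2100, tss))
        if any(abs(tss - t) < 50 for t in taken[mc["chrom"]]):
            continue  # a neighbouring composite's gene already serves here
        genes.append(_make_gene(rng, gi, mc["chrom"], tss, chrom_len))
        taken[mc["chrom"]].append(tss)
        gi += 1

    composite_mids = {
        name: [
            ((m["nkx"][0] + m["nkx"][1] - 1) + (m["partner"][0] + m["partner"][1] - 1)) // 4
            for m in manifest_composites
            if m["chrom"] == name
        ]
        for name in chrom_names
    }
    attempts = 0
    while gi < config.gene_count and attempts < config.gene_count * 50:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        tss = int(rng.integers(2100, chrom_len - 2100))
        if any(abs(tss - m) < 2000 for m in composite_mids[chrom]):
            continue
        if any(abs(tss - t) < 500 for t in taken[chrom]):
            continue
        genes.append(_make_gene(rng, gi, chrom, tss, chrom_len))
        taken[chrom].append(tss)
        gi += 1

    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def _make_gene(
    rng: np.random.Generator, index: int, chrom: str, tss: int, chrom_len: int
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        iv = Interval(chrom, tss, min(tss + 2000, chrom_len), "+")
    else:
        iv = Interval(chrom, max(tss - 1999, 0), tss + 1, "-")
    gid = f"g{index:04d}"
    return GeneModel(gid, gid.upper(), iv)


# ---------------------------------------------------------------------------
# evaluation against the manifest


def evaluate_against_manifest(
    tested_by_class: Mapping[str, Sequence[CompositeElement]],
    manifest: dict,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    enrichment_by_control: Mapping[str, Sequence] | None = None,
) -> dict:
    """Exact per-stage recovery metrics.

    Composites match the manifest by class and exact motif coordinates.
    Reports detection and conserved-set sensitivity/precision per class,
    a synteny confusion count, gene-assignment accuracy, and the rank of
    each planted enriched term in each control comparison (by q-value).
    """
    metrics: dict = {"classes": {}}
    by_key_manifest = {
        (
            m["class"], m["chrom"],
            m["nkx"][0], m["nkx"][1], m["partner"][0], m["partner"][1],
        ): m
        for m in manifest["composites"]
    }

    for cls in ALL_CLASSES:
        out = list(tested_by_class.get(cls, ()))
        man = [m for m in manifest["composites"] if m["class"] == cls]
        out_keys = {
            (
                cls, ce.chrom,
                ce.nkx_hit.interval.start, ce.nkx_hit.interval.end,
                ce.partner_hit.interval.start, ce.partner_hit.interval.end,
            ): ce
            for ce in out
        }
        man_keys = {
            k for k in by_key_manifest if k[0] == cls
        }
        matched = set(out_keys) & man_keys
        synteny_agree = sum(
            1
            for k in matched
            if out_keys[k].synteny_conserved == by_key_manifest[k]["synteny"]
        )
        metrics["classes"][cls] = {
            "detect_sensitivity": len(matched) / len(man) if man else 1.0,
            "detect_precision": len(matched) / len(out) if out else 1.0,
            "synteny_agreement": synteny_agree / len(matched) if matched else 1.0,
            "conserved_found": sum(
                ce.synteny_conserved == SYNTENY_PASS for ce in out
            ),
            "conserved_expected": sum(
                m["synteny"] == SYNTENY_PASS for m in man
            ),
        }
        cls_m = metrics["classes"][cls]
        exp_cons = {
            k for k in man_keys if by_key_manifest[k]["synteny"] == SYNTENY_PASS
        }
        got_cons = {
            k for k, ce in out_keys.items() if ce.synteny_conserved == SYNTENY_PASS
        }
        inter = exp_cons & got_cons
        cls_m["conserved_sensitivity"] = (
            len(inter) / len(exp_cons) if exp_cons else 1.0
        )
        cls_m["conserved_precision"] = (
            len(inter) / len(got_cons) if got_cons else 1.0
        )

    # gene assignment accuracy over conserved matched composites
    total = correct = 0
    for cls in ALL_CLASSES:
        for ce in tested_by_class.get(cls, ()):
            key = (
                cls, ce.chrom,
                ce.nkx_hit.interval.start, ce.nkx_hit.interval.end,
                ce.partner_hit.interval.start, ce.partner_hit.interval.end,
            )
            m = by_key_manifest.get(key)
            if m is None or m["expected_gene"] is None:
                continue
            total += 1
            if ce.nearest_gene_id == m["expected_gene"]:
                correct += 1
    metrics["gene_assignment_accuracy"] = correct / total if total else 1.0

    if gene_sets is not None:
        metrics["gene_set_match"] = {
            cls: sorted(gene_sets.get(cls, ()))
            == sorted(manifest["expected_gene_sets"].get(cls, ()))
            for cls in ALL_CLASSES
        }

    if enrichment_by_control is not None:
        ranks: dict[str, dict[str, int | None]] = {}
        for control, results in enrichment_by_control.items():
            ranks[control] = {}
            for term in manifest["enriched_terms"]:
                rank = None
                for i, r in enumerate(results, start=1):
                    if r.term_id == term:
                        rank = i
                        break
                ranks[control][term] = rank
        metrics["enriched_term_ranks"] = ranks

    return metrics
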