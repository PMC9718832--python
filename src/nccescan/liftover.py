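"""Chain-based coordinate mapping and syntenic motif verification.

Composite elements found on the query genome count as *conserved* only
when both motif intervals map through the query-to-target alignment
chains onto target sequence that still matches the motif consensus.
Mapping is deliberately strict: an interval must fall entirely within
one ungapped run of alignment blocks (no gap crossing), so mapped
intervals always preserve length. Unmappable is a value, not an error.

When several chains cover an interval the highest-scoring chain wins,
ties broken by lowest chain id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import DataConsistencyError, UsageError
from .genome_io import ChainAlignment, GenomeSequence, Interval, revcomp
from .motifs import MotifDefinition, iupac_match
from .pairing import (
    SYNTENY_FAIL,
    SYNTENY_PASS,
    SYNTENY_UNTESTED,
    CompositeElement,
)


@dataclass(frozen=True)
class MappedInterval:
    source: Interval
    mapped: Interval
    chain_id: int
    strand_flipped: bool
    contiguous: bool = True


def _merged_blocks(chain: ChainAlignment) -> list[tuple[int, int, int]]:
    """Collapse adjacent blocks separated by zero-length gaps into
    single ungapped runs."""
    merged: list[list[int]] = []
    for size, dq, dt in chain.blocks:
        if merged and merged[-1][1] == 0 and merged[-1][2] == 0:
            merged[-1][0] += size
            merged[-1][1], merged[-1][2] = dq, dt
        else:
            merged.append([size, dq, dt])
    return [tuple(b) for b in merged]


def map_interval(
    chains: Sequence[ChainAlignment], iv: Interval
) -> MappedInterval | None:
    """liftOver-style mapping of one query interval.

    Returns the target interval in plus-strand coordinates of the
    target chromosome, or None when the interval is uncovered by any
    chain or crosses an alignment gap in the best covering chain.
    """
    covering = [
        c
        for c in chains
        if c.query_chrom == iv.chrom
        and c.query_start <= iv.start
        and iv.end <= c.query_end
    ]
    if not covering:
        return None
    best = max(covering, key=lambda c: (c.score, -c.chain_id))

    q, t = best.query_start, best.target_start
    for size, dq, dt in _merged_blocks(best):
        if q <= iv.start and iv.end <= q + size:
            off = iv.start - q
            t_lo, t_hi = t + off, t + off + len(iv)
            if best.target_strand == "-":
                mapped = Interval(
                    best.target_chrom,
                    best.target_size - t_hi,
                    best.target_size - t_lo,
                )
                flipped = True
            else:
                mapped = Interval(best.target_chrom, t_lo, t_hi)
                flipped = False
            return MappedInterval(iv, mapped, best.chain_id, flipped)
        q += size + dq
        t += size + dt
    return None


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """The chain mapping target back to query (new query strand +)."""
    n = len(chain.blocks)
    if chain.target_strand == "+":
        blocks = tuple((s, dt, dq) for s, dq, dt in chain.blocks)
        return ChainAlignment(
            chain_id=chain.chain_id,
            score=chain.score,
            query_chrom=chain.target_chrom,
            query_size=chain.target_size,
            query_start=chain.target_start,
            query_end=chain.target_end,
            target_chrom=chain.query_chrom,
            target_size=chain.query_size,
            target_strand="+",
            target_start=chain.query_start,
            target_end=chain.query_end,
            blocks=blocks,
        )
    # minus-strand target: block order reverses so the new query (old
    # target, now on +) ascends; the old query becomes a minus-strand
    # target with coordinates counted from its 3' end.
    sizes = [b[0] for b in chain.blocks]
    gaps_q = [chain.blocks[i][1] for i in range(n - 1)]
    gaps_t = [chain.blocks[i][2] for i in range(n - 1)]
    new_blocks = []
    for i, k in enumerate(reversed(range(n))):
        if i < n - 1:
            # gap between old blocks k-1 and k, roles swapped
            new_blocks.append((sizes[k], gaps_t[k - 1], gaps_q[k - 1]))
        else:
            new_blocks.append((sizes[k], 0, 0))
    return ChainAlignment(
        chain_id=chain.chain_id,
        score=chain.score,
        query_chrom=chain.target_chrom,
        query_size=chain.target_size,
        query_start=chain.target_size - chain.target_end,
        query_end=chain.target_size - chain.target_start,
        target_chrom=chain.query_chrom,
        target_size=chain.query_size,
        target_strand="-",
        target_start=chain.query_size - chain.query_end,
        target_end=chain.query_size - chain.query_start,
        blocks=tuple(new_blocks),
    )


def _motif_by_id(motifs: Mapping[str, MotifDefinition], motif_id: str) -> MotifDefinition:
    for m in motifs.values():
        if m.motif_id == motif_id:
            return m
    raise UsageError(f"no motif definition for hit motif-id {motif_id!r}")


def verify_synteny(
    ce: CompositeElement,
    chains: Sequence[ChainAlignment],
    target_genome: GenomeSequence,
    motifs: Mapping[str, MotifDefinition],
) -> CompositeElement:
    """Test one composite element for syntenic motif conservation.

    Both motif intervals must map contiguously AND the target sequence
    at each mapped position must still match the corresponding
    consensus on either strand (a chain strand flip is expected to
    reverse-complement the site). Query-side coordinates are never
    mutated; the result is a copy with synteny status filled in.
    """
    if ce.synteny_conserved != SYNTENY_UNTESTED:
        raise UsageError(f"composite {ce.ce_id} already tested")

    reasons = []
    for which, hit in (("nkx", ce.nkx_hit), ("partner", ce.partner_hit)):
        mi = map_interval(chains, hit.interval)
        if mi is None:
            reasons.append(f"unmapped-{which}")
            continue
        if mi.mapped.chrom not in target_genome.sequences:
            raise DataConsistencyError(
                f"chain {mi.chain_id} maps to chromosome {mi.mapped.chrom!r} "
                "absent from the target genome"
            )
        target_seq = target_genome.fetch(mi.mapped)
        consensus = _motif_by_id(motifs, hit.motif_id).consensus
        if not (
            iupac_match(consensus, target_seq)
            or iupac_match(consensus, revcomp(target_seq))
        ):
            reasons.append(f"motif-lost-{which}")

    status = SYNTENY_PASS if not reasons else SYNTENY_FAIL
    return replace(ce, synteny_conserved=status, synteny_detail=",".join(reasons))


def filter_conserved(ces: Sequence[CompositeElement]) -> list[CompositeElement]:
    """Pass-only subset, order preserved; untested input is a usage
    error so the pipeline cannot skip verification."""
    for ce in ces:
        if ce.synteny_conserved == SYNTENY_UNTESTED:
            raise UsageError(f"composite {ce.ce_id} has not been synteny-tested")
    return [ce for ce in ces if ce.synteny_conserved == SYNTENY_PASS]
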