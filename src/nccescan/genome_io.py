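"""Readers, writers and the coordinate model shared by every stage.

All in-memory coordinates are 0-based half-open (BED-native), on the
plus strand of the named chromosome. Minus-strand chain coordinates are
stored as given in the file and interpreted only at mapping time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataConsistencyError, FormatError, UsageError

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide or IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise UsageError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GenomeSequence:
    """Uppercase chromosome sequences over {A,C,G,T,N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, iv: Interval) -> str:
        """Plus-strand substring at ``iv``; strand field is ignored."""
        try:
            seq = self.sequences[iv.chrom]
        except KeyError:
            raise UsageError(f"unknown chromosome {iv.chrom!r}") from None
        if iv.end > len(seq):
            raise UsageError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[iv.start : iv.end]


@dataclass(frozen=True)
class ConservedElement:
    """Scored interval from a conservation-element track (strandless)."""

    interval: Interval
    score: float
    element_id: str

    def __post_init__(self) -> None:
        if self.score < 0:
            raise UsageError(f"negative conservation score {self.score}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    interval: Interval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise UsageError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start: interval.start on +, end-1 on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class ChainAlignment:
    """One query-to-target alignment per the UCSC chain model.

    The query genome (the one being lifted FROM, always + strand) is the
    FIRST coordinate triple of the header line; the target is the second
    and may be minus-strand, in which case its coordinates count from
    the 3' end as the UCSC spec prescribes.

    ``blocks`` is a tuple of (size, gap_query, gap_target); the gaps
    follow the block, and the final block has both gaps zero.
    """

    chain_id: int
    score: float
    query_chrom: str
    query_size: int
    query_start: int
    query_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        q_span = sum(b[0] + b[1] for b in self.blocks)
        t_span = sum(b[0] + b[2] for b in self.blocks)
        if q_span != self.query_end - self.query_start:
            raise FormatError(
                f"chain {self.chain_id}: blocks span {q_span} query bases "
                f"but header declares {self.query_end - self.query_start}"
            )
        if t_span != self.target_end - self.target_start:
            raise FormatError(
                f"chain {self.chain_id}: blocks span {t_span} target bases "
                f"but header declares {self.target_end - self.target_start}"
            )
        for size, dq, dt in self.blocks:
            if size <= 0:
                raise FormatError(f"chain {self.chain_id}: block size {size} <= 0")
            if dq < 0 or dt < 0:
                raise FormatError(f"chain {self.chain_id}: negative gap")
        if self.target_strand not in ("+", "-"):
            raise FormatError(f"chain {self.chain_id}: bad target strand")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA; residues are uppercased and U mapped
    to T. Any residue outside {A,C,G,T,N,U} is rejected with its line
    number; duplicate headers are rejected by name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    sequences: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in sequences:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate header {name!r}"
                    )
                current = sequences.setdefault(name, [])
            else:
                if current is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                chunk = line.upper().replace("U", "T")
                bad = set(chunk) - VALID_RESIDUES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal residue(s) "
                        f"{''.join(sorted(bad))!r}"
                    )
                current.append(chunk)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence({name: "".join(parts) for name, parts in sequences.items()})


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed_conserved(path: str | Path) -> list[ConservedElement]:
    """Read a conservation-element BED5+ (chrom, start, end, name, score).

    Intervals are kept verbatim in file order; overlapping elements are
    not merged.
    """
    elements: list[ConservedElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns")
            chrom, start_s, end_s, name, score_s = cols[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            try:
                score = float(score_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            elements.append(
                ConservedElement(Interval(chrom, start, end), score, name)
            )
    return elements


def write_bed(items: Iterable, path: str | Path) -> None:
    """Write BED lines for objects exposing an ``interval`` plus either a
    conserved-element (score/element_id) or motif-hit (motif_id) surface."""
    with open(path, "w") as fh:
        for item in items:
            iv = item.interval
            if hasattr(item, "element_id") and hasattr(item, "score"):
                score = item.score
                score_str = f"{int(score)}" if float(score).is_integer() else f"{score}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.element_id}\t{score_str}\n"
                )
            elif hasattr(item, "motif_id"):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.motif_id}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# chain


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC-dialect chain file.

    The first coordinate triple of each header is the genome being
    lifted FROM (query role here); lines starting with ``#`` are
    comments. Block arithmetic is validated against the header spans.
    """
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (
            _, score, q_chrom, q_size, q_strand, q_start, q_end,
            t_chrom, t_size, t_strand, t_start, t_end, chain_id,
        ) = header
        if q_strand != "+":
            raise FormatError(
                f"chain {chain_id}: query strand must be + (got {q_strand})"
            )
        chains.append(
            ChainAlignment(
                chain_id=int(chain_id),
                score=float(score),
                query_chrom=q_chrom,
                query_size=int(q_size),
                query_start=int(q_start),
                query_end=int(q_end),
                target_chrom=t_chrom,
                target_size=int(t_size),
                target_strand=t_strand,
                target_start=int(t_start),
                target_end=int(t_end),
                blocks=tuple(blocks),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                finish()
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) != 13:
                    raise FormatError(
                        f"{path}:{lineno}: chain header needs 13 fields"
                    )
            else:
                cols = line.split()
                if header is None:
                    raise FormatError(f"{path}:{lineno}: block outside a chain")
                if len(cols) == 3:
                    blocks.append((int(cols[0]), int(cols[1]), int(cols[2])))
                elif len(cols) == 1:
                    blocks.append((int(cols[0]), 0, 0))
                else:
                    raise FormatError(f"{path}:{lineno}: malformed block line")
    finish()
    return chains


def write_chain(chains: Sequence[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# chain dialect: first coordinate triple is the genome lifted FROM "
            "(query); second is the target\n"
        )
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.query_chrom} {c.query_size} + "
                f"{c.query_start} {c.query_end} {c.target_chrom} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for i, (size, dq, dt) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size}\t{dq}\t{dt}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene table / term map / generic TSV


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """TSV of (gene-id, symbol, chrom, start, end, strand)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            gene_id, symbol, chrom, start_s, end_s, strand = cols
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: gene strand must be + or - (got {strand!r})"
                )
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            genes.append(GeneModel(gene_id, symbol, Interval(chrom, start, end, strand)))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n"
            )


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """TSV of (term-id, gene-id), many-to-many; duplicate rows are
    dropped with a logged warning."""
    terms: dict[str, set[str]] = {}
    dupes = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            term, gene = cols
            members = terms.setdefault(term, set())
            if gene in members:
                dupes += 1
            members.add(gene)
    if dupes:
        logger.warning("term map %s: dropped %d duplicate (term, gene) rows", path, dupes)
    return terms


def write_term_map(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")


def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header is not None:
            fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def check_genome_consistency(genome: GenomeSequence, chains: Sequence[ChainAlignment], side: str) -> None:
    """Verify every chromosome a chain names on ``side`` ('query' or
    'target') exists in ``genome`` with the declared size."""
    for c in chains:
        chrom = c.query_chrom if side == "query" else c.target_chrom
        size = c.query_size if side == "query" else c.target_size
        if chrom not in genome.sequences:
            raise DataConsistencyError(
                f"chain {c.chain_id} names {side} chromosome {chrom!r} "
                "absent from the genome"
            )
        if len(genome.sequences[chrom]) != size:
            raise DataConsistencyError(
                f"chain {c.chain_id}: {side} size {size} != sequence length "
                f"{len(genome.sequences[chrom])} for {chrom}"
            )
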