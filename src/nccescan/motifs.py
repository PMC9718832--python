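"""Exact IUPAC consensus scanning on both strands, restricted to
conserved elements.

The screen works with degenerate consensus strings, not weight
matrices: the COUP-TFII nuclear-receptor half-site is GGTC(A/G), the
NKX homeodomain site an AT-rich consensus, and the negative-control
"scrambled" motifs are base permutations of the half-site. Every window
of the genome is tested exactly — a window matches a motif when each
position falls in the IUPAC class, on either the plus strand or via its
reverse complement.

A genomic N never matches any consensus position, including consensus
N: assembly gaps must not produce hits.

Motif centers are carried in doubled coordinates (``center2 = start +
end - 1``) so even-length motifs have exact half-integer centers
without floating point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import FormatError, UsageError
from .genome_io import ConservedElement, GenomeSequence, Interval, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Roles a motif may play in composite-element pairing.
ROLES = ("NKX", "COUP", "SCRAMBLE-1", "SCRAMBLE-2", "SCRAMBLE-3")


@dataclass(frozen=True)
class MotifDefinition:
    motif_id: str
    consensus: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise UsageError(f"unknown motif role {self.role!r}")
        if len(self.consensus) < 4:
            raise UsageError(
                f"motif {self.motif_id}: consensus shorter than 4 bases"
            )
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise UsageError(
                f"motif {self.motif_id}: non-IUPAC symbols {''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


# Built-in definitions. The COUP-TFII half-site and the three scrambled
# permutations are fixed by the screen design; the NKX homeodomain
# consensus has no single canonical form and is configuration-overridable.
DEFAULT_MOTIFS: dict[str, MotifDefinition] = {
    "COUP": MotifDefinition("COUP", "GGTCR", "COUP"),
    "NKX": MotifDefinition("NKX", "TNAAGTG", "NKX"),
    "SCRAMBLE-1": MotifDefinition("SCRAMBLE-1", "GTACS", "SCRAMBLE-1"),
    "SCRAMBLE-2": MotifDefinition("SCRAMBLE-2", "AGTCS", "SCRAMBLE-2"),
    "SCRAMBLE-3": MotifDefinition("SCRAMBLE-3", "TGGAY", "SCRAMBLE-3"),
}


def load_motif_config(path: str | Path) -> dict[str, MotifDefinition]:
    """Read a YAML motif config: a list of {motif-id, role, consensus}
    mappings. Returns motifs keyed by role (one motif per role)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise FormatError(f"{path}: motif config must be a YAML list")
    motifs: dict[str, MotifDefinition] = {}
    for entry in entries:
        try:
            m = MotifDefinition(entry["motif-id"], entry["consensus"], entry["role"])
        except (KeyError, TypeError):
            raise FormatError(
                f"{path}: each entry needs motif-id, role, consensus"
            ) from None
        if m.role in motifs:
            raise FormatError(f"{path}: duplicate role {m.role}")
        motifs[m.role] = m
    return motifs


@dataclass(frozen=True)
class MotifHit:
    """One consensus match; ``matched_sequence`` is always the
    plus-strand genomic substring under the hit."""

    motif_id: str
    interval: Interval
    matched_sequence: str
    container_element_id: str | None = None

    @property
    def center2(self) -> int:
        """Doubled-coordinate center: start + end - 1."""
        return self.interval.start + self.interval.end - 1


def iupac_match(consensus: str, window: str) -> bool:
    """True iff every window position lies in the consensus's IUPAC
    class. A genomic N matches nothing."""
    if len(consensus) != len(window):
        raise UsageError(
            f"consensus length {len(consensus)} != window length {len(window)}"
        )
    for c, w in zip(consensus, window):
        if w not in IUPAC[c]:
            return False
    return True


def _regex(consensus: str) -> re.Pattern:
    # character classes list explicit bases only, so genomic N cannot match
    return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in consensus) + "))")


def scan_sequence(
    genome: GenomeSequence,
    motif: MotifDefinition,
    regions: Sequence[Interval] | None = None,
) -> list[MotifHit]:
    """All matches of ``motif`` on both strands, each fully inside one
    of ``regions`` when given (whole chromosomes otherwise), sorted by
    (chrom, start, strand). A window matching on both strands yields
    two hits.
    """
    fwd = _regex(motif.consensus)
    rc = revcomp(motif.consensus)
    rev = _regex(rc)
    palindromic = rc == motif.consensus

    hits: list[MotifHit] = []

    def scan_window(chrom: str, seq: str, offset: int) -> None:
        for m in fwd.finditer(seq):
            s = offset + m.start()
            hits.append(
                MotifHit(motif.motif_id, Interval(chrom, s, s + len(motif), "+"), m.group(1))
            )
        if palindromic:
            # identical matches on both strands: emit the minus twin of
            # every plus hit rather than rescanning
            for m in fwd.finditer(seq):
                s = offset + m.start()
                hits.append(
                    MotifHit(motif.motif_id, Interval(chrom, s, s + len(motif), "-"), m.group(1))
                )
        else:
            for m in rev.finditer(seq):
                s = offset + m.start()
                hits.append(
                    MotifHit(motif.motif_id, Interval(chrom, s, s + len(motif), "-"), m.group(1))
                )

    if regions is None:
        for chrom, seq in genome.sequences.items():
            scan_window(chrom, seq, 0)
    else:
        for iv in regions:
            scan_window(iv.chrom, genome.fetch(iv), iv.start)

    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    # regions may overlap: a window inside two regions is one hit
    deduped: list[MotifHit] = []
    for h in hits:
        if deduped and deduped[-1] == h:
            continue
        deduped.append(h)
    return deduped


def assign_containers(
    hits: Iterable[MotifHit],
    elements: Sequence[ConservedElement],
    min_score: float = 300.0,
) -> list[MotifHit]:
    """Keep hits fully contained in a conserved element with score
    strictly above ``min_score``; a hit inside k qualifying elements is
    emitted once per container."""
    by_chrom: dict[str, list[ConservedElement]] = {}
    for el in elements:
        if el.score > min_score:
            by_chrom.setdefault(el.interval.chrom, []).append(el)
    out: list[MotifHit] = []
    for h in hits:
        for el in by_chrom.get(h.interval.chrom, ()):
            if el.interval.contains(h.interval):
                out.append(replace(h, container_element_id=el.element_id))
    out.sort(
        key=lambda h: (
            h.interval.chrom, h.interval.start, h.interval.strand,
            h.container_element_id or "",
        )
    )
    return out


def scan_in_elements(
    genome: GenomeSequence,
    motif: MotifDefinition,
    elements: Sequence[ConservedElement],
    min_score: float = 300.0,
) -> list[MotifHit]:
    """Scan only within qualifying conserved elements and attach
    container ids — the screen's standard entry point."""
    qualifying = [el for el in elements if el.score > min_score]
    regions = [el.interval for el in qualifying]
    hits = scan_sequence(genome, motif, regions) if regions else []
    return assign_containers(hits, qualifying, min_score)
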