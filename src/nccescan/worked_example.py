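"""Desk-scale worked example: the mouse Madcam1 promoter composite
element.

``MADCAM1_CE_MOUSE_SYNTHETIC`` is a synthetic reconstruction of the
mouse Madcam1 composite element, built from its described architecture
rather than copied from an assembly: an NKX homeodomain site upstream
of two COUP-TFII half-sites (TGACCC on the plus strand, i.e. GGTCA
matches on the minus strand) spaced seven nucleotides apart. It is a
stand-in sequence for demonstration and testing, not genomic mm10
sequence.

Scanning it with the COUP-TFII half-site consensus GGTCR on both
strands finds exactly the two half-sites, seven nucleotides apart —
the spacing compatible with COUP-TFII homodimer binding; the NKX site
sits 12 bp (center-to-center) from the nearer half-site, inside the
6-16 bp heterodimer window.
"""

from __future__ import annotations

from .genome_io import GenomeSequence
from .motifs import DEFAULT_MOTIFS, MotifHit, scan_sequence

#: synthetic reconstruction (see module docstring)
MADCAM1_CE_MOUSE_SYNTHETIC = (
    "GCTAGCTT"   # flank
    "TCAAGTG"    # NKX homeodomain site
    "ATT"
    "TGACCC"     # COUP-TFII half-site "A" (GGTCA on minus strand)
    "TCTGTT"     # 7-nt spacer (with the trailing C of site A)
    "TGACC"      # COUP-TFII half-site "B"
    "AGGCTAGC"   # flank
)


def scan_madcam1_ce() -> tuple[list[MotifHit], int]:
    """Scan the example element for COUP-TFII half-sites.

    Returns the hits and the nucleotide gap between the two half-site
    footprints (end of the first to start of the second).
    """
    genome = GenomeSequence({"madcam1_ce": MADCAM1_CE_MOUSE_SYNTHETIC})
    hits = scan_sequence(genome, DEFAULT_MOTIFS["COUP"])
    if len(hits) >= 2:
        gap = hits[1].interval.start - hits[0].interval.end
    else:
        gap = -1
    return hits, gap
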