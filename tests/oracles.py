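"""Independent brute-force reference implementations used only by the
test suite. These deliberately avoid the package's own helpers (IUPAC
tables, revcomp, interval arithmetic) so they can disagree with the
implementation under test.
"""

from __future__ import annotations

from math import comb

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_matches(consensus: str, window: str) -> bool:
    return len(consensus) == len(window) and all(
        w in ORACLE_IUPAC[c] for c, w in zip(consensus, window)
    )


def brute_scan(seq: str, consensus: str) -> list[tuple[int, int, str]]:
    """Every (start, end, strand) where the window or its reverse
    complement matches the consensus, testing each window independently."""
    k = len(consensus)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if oracle_matches(consensus, window):
            hits.append((i, i + k, "+"))
        if oracle_matches(consensus, oracle_revcomp(window)):
            hits.append((i, i + k, "-"))
    return sorted(hits)


def brute_pair_keys(
    nkx_hits, partner_hits, min_bp: float, max_bp: float
) -> set[tuple]:
    """Strand-free identities of all valid pairs, by exhaustive
    cross-product with floating-point midpoint spacing."""
    keys = set()
    for n in nkx_hits:
        for p in partner_hits:
            if n.container_element_id != p.container_element_id:
                continue
            if n.interval.chrom != p.interval.chrom:
                continue
            overlap = not (
                n.interval.end <= p.interval.start
                or p.interval.end <= n.interval.start
            )
            if overlap:
                continue
            center_n = (n.interval.start + n.interval.end - 1) / 2
            center_p = (p.interval.start + p.interval.end - 1) / 2
            spacing = abs(center_n - center_p)
            if min_bp <= spacing <= max_bp:
                keys.add(
                    (
                        n.interval.chrom,
                        n.interval.start, n.interval.end,
                        p.interval.start, p.interval.end,
                        n.container_element_id,
                    )
                )
    return keys


def brute_nearest(midpoint_bp: float, chrom: str, genes) -> str | None:
    """All-pairs minimization over TSS distances; ties to smallest id."""
    best = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        tss = g.interval.start if g.interval.strand == "+" else g.interval.end - 1
        d = abs(midpoint_bp - tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    return best[1] if best else None


def expand_chain(chain) -> dict[tuple[str, int], tuple[str, int, bool]]:
    """Per-base query->target map: (chrom, qpos) -> (tchrom, tpos_plus,
    flipped). Built by walking the chain one base at a time."""
    table = {}
    q, t = chain.query_start, chain.target_start
    for size, dq, dt in chain.blocks:
        for i in range(size):
            if chain.target_strand == "-":
                tpos = chain.target_size - 1 - (t + i)
                flipped = True
            else:
                tpos = t + i
                flipped = False
            table[(chain.query_chrom, q + i)] = (chain.target_chrom, tpos, flipped)
        q += size + dq
        t += size + dt
    return table


def brute_map_interval(chain, chrom: str, start: int, end: int):
    """Map [start, end) through the per-base table; None unless every
    base maps and the images are consecutive in one orientation."""
    table = expand_chain(chain)
    images = []
    for pos in range(start, end):
        hit = table.get((chrom, pos))
        if hit is None:
            return None
        images.append(hit)
    tchroms = {h[0] for h in images}
    flips = {h[2] for h in images}
    if len(tchroms) != 1 or len(flips) != 1:
        return None
    positions = [h[1] for h in images]
    flipped = flips.pop()
    step = -1 if flipped else 1
    for a, b in zip(positions, positions[1:]):
        if b - a != step:
            return None
    lo, hi = min(positions), max(positions) + 1
    return (tchroms.pop(), lo, hi, flipped)


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater in test row) exact p by direct enumeration of
    all 2x2 tables with the same margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)
    a_min = max(0, row1 + col1 - n)
    a_max = min(row1, col1)
    p = 0.0
    for k in range(a, a_max + 1):
        p += comb(col1, k) * comb(n - col1, row1 - k) / denom
    # guard: probabilities for all tables must sum to ~1
    total = sum(
        comb(col1, k) * comb(n - col1, row1 - k) / denom
        for k in range(a_min, a_max + 1)
    )
    assert abs(total - 1.0) < 1e-9
    return p
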