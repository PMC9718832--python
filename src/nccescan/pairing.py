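"""Pair homeodomain and partner motif hits into composite elements.

A composite element is an NKX-role hit and a partner hit (COUP-TFII
half-site, or a scrambled control motif) inside the SAME conserved
element, with a center-to-center spacing inside a class window and
non-overlapping footprints. The biological class windows:

* NCCE            — NKX x COUP at 6-16 bp between motif centers, the
                    spacing range compatible with a DNA-templated
                    NKX:COUP-TFII heterodimer;
* WIDE-CONTROL    — NKX x COUP at 30-60 bp, too far apart for an
                    efficient DNA-dependent heterodimer;
* SCRAMBLE-1..3   — NKX x scrambled-motif at 6-16 bp.

Both window bounds are inclusive (`SPACING_BOUNDS_INCLUSIVE`); spacings
are exact rationals carried as doubled integers (spacing2 = 2 x bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .motifs import MotifHit

#: The 6-16 bp and 30-60 bp windows are read as closed ranges.
SPACING_BOUNDS_INCLUSIVE = True

NCCE = "NCCE"
WIDE_CONTROL = "WIDE-CONTROL"
SCRAMBLE_CLASSES = ("SCRAMBLE-1", "SCRAMBLE-2", "SCRAMBLE-3")
ALL_CLASSES = (NCCE, WIDE_CONTROL) + SCRAMBLE_CLASSES

SYNTENY_UNTESTED = "untested"
SYNTENY_PASS = "pass"
SYNTENY_FAIL = "fail"


@dataclass(frozen=True)
class SpacingWindow:
    min_bp: float
    max_bp: float
    label: str

    def __post_init__(self) -> None:
        if not (0 < self.min_bp <= self.max_bp):
            raise UsageError(
                f"invalid spacing window [{self.min_bp}, {self.max_bp}]"
            )

    def contains_spacing2(self, spacing2: int) -> bool:
        """Is spacing2/2 bp inside [min_bp, max_bp] (closed)?"""
        return 2 * self.min_bp <= spacing2 <= 2 * self.max_bp


DEFAULT_WINDOWS: dict[str, SpacingWindow] = {
    NCCE: SpacingWindow(6, 16, NCCE),
    WIDE_CONTROL: SpacingWindow(30, 60, WIDE_CONTROL),
}


def window_for_class(label: str, windows: Mapping[str, SpacingWindow] | None = None) -> SpacingWindow:
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    if label == WIDE_CONTROL:
        return windows[WIDE_CONTROL]
    # NCCE and every scramble class use the heterodimer-compatible window
    w = windows[NCCE]
    return SpacingWindow(w.min_bp, w.max_bp, label) if w.label != label else w


@dataclass(frozen=True)
class CompositeElement:
    ce_id: str
    nkx_hit: MotifHit
    partner_hit: MotifHit
    element_id: str
    spacing2: int
    class_label: str
    strands_seen: tuple[str, ...] = ()
    synteny_conserved: str = SYNTENY_UNTESTED
    synteny_detail: str = ""
    nearest_gene_id: str | None = None

    @property
    def chrom(self) -> str:
        return self.nkx_hit.interval.chrom

    @property
    def spacing_bp(self) -> float:
        return self.spacing2 / 2

    @property
    def span(self) -> tuple[int, int]:
        """Footprint from leftmost hit start to rightmost hit end."""
        return (
            min(self.nkx_hit.interval.start, self.partner_hit.interval.start),
            max(self.nkx_hit.interval.end, self.partner_hit.interval.end),
        )

    @property
    def midpoint2(self) -> int:
        """Doubled midpoint of the two motif centers (= 4 x bp midpoint)."""
        return self.nkx_hit.center2 + self.partner_hit.center2


def center_spacing(hit_a: MotifHit, hit_b: MotifHit) -> int:
    """|center2 difference| — twice the bp distance between motif
    centers; symmetric and translation-invariant."""
    if hit_a.interval.chrom != hit_b.interval.chrom:
        raise UsageError("center spacing across chromosomes is undefined")
    return abs(hit_a.center2 - hit_b.center2)


def _overlap(a: MotifHit, b: MotifHit) -> bool:
    return not (a.interval.end <= b.interval.start or b.interval.end <= a.interval.start)


def make_ce_id(class_label: str, chrom: str, nkx: MotifHit, partner: MotifHit, element_id: str) -> str:
    return (
        f"{class_label}|{chrom}:{nkx.interval.start}-{nkx.interval.end}"
        f"+{partner.interval.start}-{partner.interval.end}|{element_id}"
    )


def pair_hits(
    nkx_hits: Sequence[MotifHit],
    partner_hits: Sequence[MotifHit],
    window: SpacingWindow,
    class_label: str,
) -> list[CompositeElement]:
    """Every (NKX, partner) pair sharing a conserved element, with
    non-overlapping footprints and center spacing inside the window.

    Pairs differing only in hit strand over identical intervals (a
    palindromic double match) collapse to one element; the kept
    representative prefers plus-strand hits and all strand combinations
    seen are recorded.
    """
    if window.label != class_label:
        raise UsageError(
            f"window labelled {window.label!r} used for class {class_label!r}"
        )
    for h in list(nkx_hits) + list(partner_hits):
        if h.container_element_id is None:
            raise UsageError("pairing requires container-element ids on every hit")

    partners_by_el: dict[str, list[MotifHit]] = {}
    for p in partner_hits:
        partners_by_el.setdefault(p.container_element_id, []).append(p)

    # key: strand-free identity of the pair
    chosen: dict[tuple, tuple[MotifHit, MotifHit, set[str]]] = {}
    for nk in nkx_hits:
        for pt in partners_by_el.get(nk.container_element_id, ()):
            if nk.interval.chrom != pt.interval.chrom:
                continue
            if _overlap(nk, pt):
                continue
            sp2 = center_spacing(nk, pt)
            if not window.contains_spacing2(sp2):
                continue
            key = (
                nk.interval.chrom,
                nk.interval.start, nk.interval.end,
                pt.interval.start, pt.interval.end,
                nk.container_element_id,
            )
            combo = nk.interval.strand + pt.interval.strand
            if key in chosen:
                prev_nk, prev_pt, seen = chosen[key]
                seen.add(combo)
                # prefer plus-strand representatives, deterministically
                best_nk = nk if (nk.interval.strand, ) < (prev_nk.interval.strand, ) else prev_nk
                best_pt = pt if (pt.interval.strand, ) < (prev_pt.interval.strand, ) else prev_pt
                chosen[key] = (best_nk, best_pt, seen)
            else:
                chosen[key] = (nk, pt, {combo})

    out = []
    for key in sorted(chosen):
        nk, pt, seen = chosen[key]
        out.append(
            CompositeElement(
                ce_id=make_ce_id(class_label, nk.interval.chrom, nk, pt, nk.container_element_id),
                nkx_hit=nk,
                partner_hit=pt,
                element_id=nk.container_element_id,
                spacing2=center_spacing(nk, pt),
                class_label=class_label,
                strands_seen=tuple(sorted(seen)),
            )
        )
    return out


def build_all_classes(
    hits_by_role: Mapping[str, Sequence[MotifHit]],
    windows: Mapping[str, SpacingWindow] | None = None,
) -> dict[str, list[CompositeElement]]:
    """Build every composite-element class independently:
    NCCE = NKX x COUP at the heterodimer window, WIDE-CONTROL = NKX x
    COUP at the wide window, SCRAMBLE-k = NKX x scramble-k at the
    heterodimer window."""
    for role in ("NKX", "COUP") + SCRAMBLE_CLASSES:
        if role not in hits_by_role:
            raise UsageError(f"missing hit set for role {role!r}")
    nkx = hits_by_role["NKX"]
    out: dict[str, list[CompositeElement]] = {}
    out[NCCE] = pair_hits(nkx, hits_by_role["COUP"], window_for_class(NCCE, windows), NCCE)
    out[WIDE_CONTROL] = pair_hits(
        nkx, hits_by_role["COUP"], window_for_class(WIDE_CONTROL, windows), WIDE_CONTROL
    )
    for sc in SCRAMBLE_CLASSES:
        out[sc] = pair_hits(nkx, hits_by_role[sc], window_for_class(sc, windows), sc)
    return out


def composite_rows(ces: Iterable[CompositeElement]) -> list[list]:
    """Rows for the composite-element report TSV."""
    rows = []
    for ce in ces:
        start, end = ce.span
        rows.append([
            ce.chrom, start, end, ce.ce_id, ce.class_label,
            f"{ce.spacing_bp:g}",
            f"{ce.nkx_hit.interval.start}-{ce.nkx_hit.interval.end}({ce.nkx_hit.interval.strand})",
            f"{ce.partner_hit.interval.start}-{ce.partner_hit.interval.end}({ce.partner_hit.interval.strand})",
            ce.element_id, ce.synteny_conserved, ce.nearest_gene_id or ".",
        ])
    return rows
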