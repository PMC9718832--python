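import numpy as np
import pytest

from nccescan import (
    ChainAlignment,
    DataConsistencyError,
    GenomeSequence,
    Interval,
    UsageError,
    filter_conserved,
    invert_chain,
    map_interval,
    revcomp,
    verify_synteny,
)
from nccescan.motifs import DEFAULT_MOTIFS, MotifHit
from nccescan.pairing import NCCE, CompositeElement, SYNTENY_FAIL, SYNTENY_PASS
from oracles import brute_map_interval


def identity_chain(n=1000, chain_id=1, score=100.0):
    return ChainAlignment(
        chain_id=chain_id, score=score,
        query_chrom="chr1", query_size=n, query_start=0, query_end=n,
        target_chrom="t1", target_size=n, target_strand="+",
        target_start=0, target_end=n, blocks=((n, 0, 0),),
    )


def random_chain(rng, chain_id=1):
    """A random multi-block chain, possibly minus-strand."""
    n_blocks = int(rng.integers(1, 6))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 50))
        dq = int(rng.integers(0, 20)) if i < n_blocks - 1 else 0
        dt = int(rng.integers(0, 20)) if i < n_blocks - 1 else 0
        blocks.append((size, dq, dt))
    q_span = sum(s + dq for s, dq, _ in blocks)
    t_span = sum(s + dt for s, _, dt in blocks)
    q_start = int(rng.integers(0, 50))
    t_start = int(rng.integers(0, 50))
    strand = "-" if rng.random() < 0.5 else "+"
    return ChainAlignment(
        chain_id=chain_id, score=float(rng.integers(1, 1000)),
        query_chrom="chr1", query_size=q_start + q_span + int(rng.integers(0, 30)),
        query_start=q_start, query_end=q_start + q_span,
        target_chrom="t1", target_size=t_start + t_span + int(rng.integers(0, 30)),
        target_strand=strand, target_start=t_start, target_end=t_start + t_span,
        blocks=tuple(blocks),
    )


class TestMapInterval:
    def test_identity_chain_is_identity(self):
        mi = map_interval([identity_chain()], Interval("chr1", 10, 17))
        assert (mi.mapped.start, mi.mapped.end) == (10, 17)
        assert mi.mapped.chrom == "t1"
        assert not mi.strand_flipped

    def test_gap_crossing_returns_none(self):
        chain = ChainAlignment(
            chain_id=1, score=1.0,
            query_chrom="chr1", query_size=100, query_start=0, query_end=100,
            target_chrom="t1", target_size=105, target_strand="+",
            target_start=0, target_end=105,
            blocks=((12, 0, 5), (88, 0, 0)),  # 5-bp target insertion after base 12
        )
        assert map_interval([chain], Interval("chr1", 10, 17)) is None
        # fully inside one block still maps
        assert map_interval([chain], Interval("chr1", 0, 12)) is not None

    def test_uncovered_interval_returns_none(self):
        assert map_interval([identity_chain(100)], Interval("chr1", 95, 105)) is None
        assert map_interval([identity_chain(100)], Interval("chr2", 0, 5)) is None

    def test_zero_gap_blocks_form_one_run(self):
        chain = ChainAlignment(
            chain_id=1, score=1.0,
            query_chrom="chr1", query_size=100, query_start=0, query_end=100,
            target_chrom="t1", target_size=100, target_strand="+",
            target_start=0, target_end=100,
            blocks=((50, 0, 0), (50, 0, 0)),
        )
        mi = map_interval([chain], Interval("chr1", 45, 55))
        assert mi is not None and (mi.mapped.start, mi.mapped.end) == (45, 55)

    def test_highest_score_wins_ties_by_lowest_id(self):
        a = identity_chain(100, chain_id=2, score=10.0)
        shifted = ChainAlignment(
            chain_id=1, score=10.0,
            query_chrom="chr1", query_size=100, query_start=0, query_end=100,
            target_chrom="t2", target_size=200, target_strand="+",
            target_start=100, target_end=200, blocks=((100, 0, 0),),
        )
        mi = map_interval([a, shifted], Interval("chr1", 0, 10))
        assert mi.chain_id == 1 and mi.mapped.chrom == "t2"
        big = identity_chain(100, chain_id=3, score=99.0)
        mi2 = map_interval([a, shifted, big], Interval("chr1", 0, 10))
        assert mi2.chain_id == 3

    def test_matches_per_base_expansion_oracle(self):
        """200 random chains (both strands), many intervals each."""
        rng = np.random.default_rng(9)
        for i in range(200):
            chain = random_chain(rng, chain_id=i + 1)
            for _ in range(20):
                lo = int(rng.integers(0, chain.query_size - 1))
                length = int(rng.integers(1, 15))
                iv = Interval("chr1", lo, min(lo + length, chain.query_size))
                got = map_interval([chain], iv)
                expected = brute_map_interval(chain, "chr1", iv.start, iv.end)
                if chain.query_start <= iv.start and iv.end <= chain.query_end:
                    if got is None:
                        assert expected is None
                    else:
                        assert expected == (
                            got.mapped.chrom, got.mapped.start, got.mapped.end,
                            got.strand_flipped,
                        )
                else:
                    assert got is None  # uncovered by chain span

    def test_length_preserved_for_contiguous_maps(self):
        rng = np.random.default_rng(13)
        checked = 0
        for i in range(100):
            chain = random_chain(rng, chain_id=i + 1)
            for _ in range(10):
                lo = int(rng.integers(chain.query_start, chain.query_end))
                iv = Interval("chr1", lo, min(lo + int(rng.integers(1, 12)), chain.query_end))
                mi = map_interval([chain], iv)
                if mi is not None:
                    assert len(mi.mapped) == len(iv)
                    checked += 1
        assert checked > 50

    def test_inverse_chain_round_trip(self):
        """Mapping through a chain then its inversion is the identity on
        every contiguously mapped interval."""
        rng = np.random.default_rng(17)
        round_trips = 0
        for i in range(150):
            chain = random_chain(rng, chain_id=i + 1)
            inv = invert_chain(chain)
            for _ in range(10):
                lo = int(rng.integers(chain.query_start, chain.query_end))
                iv = Interval("chr1", lo, min(lo + int(rng.integers(1, 10)), chain.query_end))
                mi = map_interval([chain], iv)
                if mi is None:
                    continue
                back = map_interval([inv], mi.mapped)
                assert back is not None
                assert (back.mapped.chrom, back.mapped.start, back.mapped.end) == (
                    iv.chrom, iv.start, iv.end,
                )
                round_trips += 1
        assert round_trips > 100


def _make_ce(nkx_iv, coup_iv, el="e1"):
    nkx = MotifHit("NKX", nkx_iv, "", el)
    coup = MotifHit("COUP", coup_iv, "", el)
    return CompositeElement(
        ce_id="ce1", nkx_hit=nkx, partner_hit=coup, element_id=el,
        spacing2=abs(nkx.center2 - coup.center2), class_label=NCCE,
    )


class TestVerifySynteny:
    def _setup(self):
        q = "T" * 20 + "TCAAGTG" + "AAA" + "GGTCA" + "T" * 20
        query = GenomeSequence({"chr1": q})
        target = GenomeSequence({"t1": q})
        chain = identity_chain(len(q))
        ce = _make_ce(Interval("chr1", 20, 27, "+"), Interval("chr1", 30, 35, "+"))
        return query, target, chain, ce

    def test_exact_copy_passes(self):
        _, target, chain, ce = self._setup()
        out = verify_synteny(ce, [chain], target, DEFAULT_MOTIFS)
        assert out.synteny_conserved == SYNTENY_PASS

    def test_point_mutation_in_target_coup_site_fails(self):
        _, target, chain, ce = self._setup()
        seq = target.sequences["t1"]
        # destroy GGTCA at [30,35): GGTCA -> GGACA
        mutated = seq[:32] + "A" + seq[33:]
        target = GenomeSequence({"t1": mutated})
        out = verify_synteny(ce, [chain], target, DEFAULT_MOTIFS)
        assert out.synteny_conserved == SYNTENY_FAIL
        assert "motif-lost-partner" in out.synteny_detail

    def test_strand_flipped_target_still_passes(self):
        query, target, chain, ce = self._setup()
        n = len(query.sequences["chr1"])
        flipped = GenomeSequence({"t1": revcomp(target.sequences["t1"])})
        minus_chain = ChainAlignment(
            chain_id=1, score=10.0,
            query_chrom="chr1", query_size=n, query_start=0, query_end=n,
            target_chrom="t1", target_size=n, target_strand="-",
            target_start=0, target_end=n, blocks=((n, 0, 0),),
        )
        out = verify_synteny(ce, [minus_chain], flipped, DEFAULT_MOTIFS)
        assert out.synteny_conserved == SYNTENY_PASS

    def test_motif_in_chain_gap_fails(self):
        query, target, _, ce = self._setup()
        n = len(query.sequences["chr1"])
        gappy = ChainAlignment(
            chain_id=1, score=10.0,
            query_chrom="chr1", query_size=n, query_start=0, query_end=n,
            target_chrom="t1", target_size=n + 4, target_strand="+",
            target_start=0, target_end=n + 4,
            blocks=((23, 0, 4), (n - 23, 0, 0)),  # gap splits the NKX site
        )
        out = verify_synteny(ce, [gappy], target, DEFAULT_MOTIFS)
        assert out.synteny_conserved == SYNTENY_FAIL
        assert "unmapped-nkx" in out.synteny_detail

    def test_unknown_target_chromosome_is_data_error(self):
        _, _, chain, ce = self._setup()
        with pytest.raises(DataConsistencyError):
            verify_synteny(ce, [chain], GenomeSequence({"other": "ACGT" * 20}), DEFAULT_MOTIFS)

    def test_already_tested_rejected(self):
        _, target, chain, ce = self._setup()
        tested = verify_synteny(ce, [chain], target, DEFAULT_MOTIFS)
        with pytest.raises(UsageError):
            verify_synteny(tested, [chain], target, DEFAULT_MOTIFS)


class TestFilterConserved:
    def test_pass_only_order_preserved(self):
        _, target, chain, ce = TestVerifySynteny()._setup()
        tested = verify_synteny(ce, [chain], target, DEFAULT_MOTIFS)
        from dataclasses import replace
        failed = replace(tested, ce_id="ce2", synteny_conserved=SYNTENY_FAIL)
        out = filter_conserved([tested, failed, tested])
        assert out == [tested, tested]

    def test_all_fail_gives_empty(self):
        from dataclasses import replace
        _, target, chain, ce = TestVerifySynteny()._setup()
        tested = verify_synteny(ce, [chain], target, DEFAULT_MOTIFS)
        failed = replace(tested, synteny_conserved=SYNTENY_FAIL)
        assert filter_conserved([failed, failed]) == []

    def test_untested_is_usage_error(self):
        _, _, _, ce = TestVerifySynteny()._setup()
        with pytest.raises(UsageError):
            filter_conserved([ce])
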