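import numpy as np
import pytest

from nccescan import (
    GeneModel,
    GeneSet,
    Interval,
    UsageError,
    enrich_terms,
    nearest_gene,
)
from nccescan.enrichment import build_gene_sets
from nccescan.motifs import MotifHit
from nccescan.pairing import NCCE, SYNTENY_PASS, CompositeElement
from oracles import brute_nearest, hypergeom_tail_p


def make_ce(mid_bp, chrom="c", synteny=SYNTENY_PASS, gene=None):
    # two 5-mers straddling the midpoint symmetrically: midpoint2 = 4*mid
    nkx = MotifHit("NKX", Interval(chrom, mid_bp - 7, mid_bp - 2, "+"), "", "e1")
    coup = MotifHit("COUP", Interval(chrom, mid_bp + 3, mid_bp + 8, "+"), "", "e1")
    return CompositeElement(
        ce_id=f"ce{mid_bp}", nkx_hit=nkx, partner_hit=coup, element_id="e1",
        spacing2=abs(nkx.center2 - coup.center2), class_label=NCCE,
        synteny_conserved=synteny, nearest_gene_id=gene,
    )


def gene(gid, tss, chrom="c", strand="+"):
    if strand == "+":
        return GeneModel(gid, gid.upper(), Interval(chrom, tss, tss + 100, "+"))
    return GeneModel(gid, gid.upper(), Interval(chrom, tss - 99, tss + 1, "-"))


class TestNearestGene:
    def test_closer_tss_wins(self):
        genes = [gene("a", 400), gene("b", 700)]
        assert nearest_gene(make_ce(500), genes) == "a"

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [gene("zeta", 400), gene("alpha", 600)]
        assert nearest_gene(make_ce(500), genes) == "alpha"

    def test_other_chromosomes_ignored(self):
        genes = [gene("far", 501, chrom="other"), gene("near", 0)]
        assert nearest_gene(make_ce(500), genes) == "near"

    def test_no_gene_on_chromosome_leaves_unassigned(self, caplog):
        with caplog.at_level("WARNING"):
            assert nearest_gene(make_ce(500), [gene("g", 1, chrom="other")]) is None
        assert any("unassigned" in r.message for r in caplog.records)

    def test_matches_all_pairs_minimization(self):
        """1000 random elements vs 50 random genes, brute-force oracle."""
        rng = np.random.default_rng(7)
        genes = [
            gene(f"g{i:02d}", int(rng.integers(100, 100_000)),
                 chrom="c" if i % 4 else "c2",
                 strand="+-"[int(rng.integers(2))])
            for i in range(50)
        ]
        for _ in range(1000):
            mid = int(rng.integers(100, 100_000))
            chrom = "c" if rng.random() < 0.8 else "c2"
            ce = make_ce(mid, chrom=chrom)
            assert nearest_gene(ce, genes) == brute_nearest(
                ce.midpoint2 / 4, chrom, genes
            )


class TestBuildGeneSets:
    def test_deduplication(self):
        genes = [gene("a", 500), gene("b", 5000)]
        ces = [make_ce(400), make_ce(600), make_ce(5100)]
        sets = build_gene_sets({NCCE: ces}, genes)
        assert sets[NCCE].gene_ids == ("a", "b")

    def test_empty_class_gives_empty_set(self, caplog):
        with caplog.at_level("WARNING"):
            sets = build_gene_sets({NCCE: []}, [gene("a", 5)])
        assert sets[NCCE].gene_ids == ()

    def test_unverified_composite_rejected(self):
        ces = [make_ce(400, synteny="untested")]
        with pytest.raises(UsageError):
            build_gene_sets({NCCE: ces}, [gene("a", 5)])


class TestEnrichTerms:
    def test_p_equals_exact_enumeration(self):
        """The (8,2,2,8) example table and 300 random small universes."""
        test = GeneSet("NCCE", tuple(f"t{i}" for i in range(10)))
        control = GeneSet("WIDE-CONTROL", tuple(f"c{i}" for i in range(10)))
        term_map = {"T1": set(test.gene_ids[:8]) | set(control.gene_ids[:2])}
        (r,) = enrich_terms(test, control, term_map)
        assert r.p_value == pytest.approx(hypergeom_tail_p(8, 2, 2, 8), abs=1e-12)

        rng = np.random.default_rng(21)
        for _ in range(300):
            n1 = int(rng.integers(2, 16))
            n2 = int(rng.integers(2, 16))  # universe <= 30 genes
            test = GeneSet("NCCE", tuple(f"t{i}" for i in range(n1)))
            control = GeneSet("WIDE-CONTROL", tuple(f"c{i}" for i in range(n2)))
            members = {
                g for g in test.gene_ids + control.gene_ids if rng.random() < 0.4
            }
            if not members:
                continue
            (r,) = enrich_terms(test, control, {"T": members})
            a = len(set(test.gene_ids) & members)
            c = len(set(control.gene_ids) & members)
            expected = hypergeom_tail_p(a, n1 - a, c, n2 - c)
            assert r.p_value == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_degenerate_term_in_every_gene(self):
        test = GeneSet("NCCE", ("t1", "t2"))
        control = GeneSet("WIDE-CONTROL", ("c1", "c2"))
        term_map = {"T": {"t1", "t2", "c1", "c2"}}
        (r,) = enrich_terms(test, control, term_map)
        assert r.p_value == pytest.approx(1.0)
        assert np.isfinite(r.odds_ratio)  # Haldane branch, no div-by-zero

    def test_shared_genes_dropped_from_both(self):
        test = GeneSet("NCCE", ("a", "b", "c"))
        control = GeneSet("WIDE-CONTROL", ("c", "d", "e"))
        (r,) = enrich_terms(test, control, {"T": {"a", "d"}})
        assert r.test_set_size == 2 and r.control_set_size == 2

    def test_empty_after_disjointification_is_usage_error(self):
        test = GeneSet("NCCE", ("a",))
        control = GeneSet("WIDE-CONTROL", ("a",))
        with pytest.raises(UsageError):
            enrich_terms(test, control, {"T": {"a"}})

    def test_label_exchange_reverses_direction(self):
        """One-sided p of the swapped comparison equals the opposite
        tail of the original table."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            test = GeneSet("NCCE", tuple(f"t{i}" for i in range(n1)))
            control = GeneSet("WIDE-CONTROL", tuple(f"c{i}" for i in range(n2)))
            members = {
                g for g in test.gene_ids + control.gene_ids if rng.random() < 0.5
            }
            if not members:
                continue
            (fwd,) = enrich_terms(test, control, {"T": members})
            (rev,) = enrich_terms(control, test, {"T": members})
            a = len(set(test.gene_ids) & members)
            c = len(set(control.gene_ids) & members)
            # P(greater in control) = sum of tables with control count >= c
            expected_rev = hypergeom_tail_p(c, n2 - c, a, n1 - a)
            assert rev.p_value == pytest.approx(expected_rev, rel=1e-9, abs=1e-12)
            # the two one-sided tails overlap exactly on the observed table
            point = hypergeom_tail_p(a, n1 - a, c, n2 - c) + expected_rev - 1.0
            assert 0.0 <= point <= 1.0 + 1e-12
            assert fwd.p_value + rev.p_value == pytest.approx(1.0 + point, rel=1e-9)

    def test_bh_qvalues_monotone_step_transform(self):
        rng = np.random.default_rng(41)
        test = GeneSet("NCCE", tuple(f"t{i}" for i in range(20)))
        control = GeneSet("WIDE-CONTROL", tuple(f"c{i}" for i in range(20)))
        term_map = {
            f"T{k}": {
                g for g in test.gene_ids + control.gene_ids if rng.random() < 0.3
            }
            for k in range(12)
        }
        results = enrich_terms(test, control, term_map)
        assert all(0.0 <= r.q_value <= 1.0 for r in results)
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)  # monotone in sorted-p order

    def test_null_type_one_error_calibrated(self):
        """Under random term labels the test's size stays inside the
        exact binomial 99% band around the nominal 0.05. Table margins
        of ~200 per set keep the discrete null dense enough for the
        size to approach nominal."""
        from scipy.stats import binom

        rng = np.random.default_rng(51)
        n = 200
        test = GeneSet("NCCE", tuple(f"t{i}" for i in range(n)))
        control = GeneSet("WIDE-CONTROL", tuple(f"c{i}" for i in range(n)))
        universe = test.gene_ids + control.gene_ids
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            members = {g for g in universe if rng.random() < 0.5}
            (r,) = enrich_terms(test, control, {"T": members})
            hits += r.p_value < 0.05
        lo = binom.ppf(0.005, n_sim, 0.05) / n_sim
        hi = binom.ppf(0.995, n_sim, 0.05) / n_sim
        assert lo <= hits / n_sim <= hi
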