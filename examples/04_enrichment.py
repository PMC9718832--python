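"""Control-matched term enrichment of composite-element genes.

Genes nearest to conserved NKX/COUP composite elements (the test set)
are compared with genes nearest to wide-spacing control pairs using a
one-sided Fisher exact test per term and Benjamini-Hochberg FDR.
"""

from nccescan import GeneSet, enrich_terms

test = GeneSet("NCCE", tuple(f"t{i:02d}" for i in range(20)))
control = GeneSet("WIDE-CONTROL", tuple(f"c{i:02d}" for i in range(20)))
term_map = {
    # strongly enriched in the test set: 14/20 vs 3/20
    "heart-morphogenesis": set(test.gene_ids[:14]) | set(control.gene_ids[:3]),
    # flat background term
    "housekeeping": set(test.gene_ids[5:12]) | set(control.gene_ids[5:13]),
}

for r in enrich_terms(test, control, term_map):
    print(f"{r.term_id:20s} {r.count_in_test:2d}/{r.test_set_size} vs "
          f"{r.count_in_control:2d}/{r.control_set_size}  "
          f"OR={r.odds_ratio:6.2f}  p={r.p_value:.2e}  q={r.q_value:.2e}")
print("-> the planted term dominates with a small q; the flat term does not.")
print("   p is the exact hypergeometric tail for greater membership in the")
print("   test set; q is the BH-adjusted value across all tested terms.")
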