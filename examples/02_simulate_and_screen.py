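"""Generate a synthetic two-genome bundle and run the whole screen.

The generator plants NKX/COUP composite elements (and wide-spacing and
scrambled-motif controls) inside conserved islands of a 1 Mb query
genome, derives a target genome through an alignment chain, and writes
a truth manifest including chance background pairs found by self-scan.
The screen is then scored exactly against that manifest.
"""

import json

from nccescan import (
    SimulationConfig,
    evaluate_against_manifest,
    generate_bundle,
    run_screen,
)

bundle = generate_bundle(SimulationConfig(seed=42))
print("manifest class counts:", json.dumps(bundle.manifest["class_counts"]))

res = run_screen(
    bundle.query_genome, bundle.elements, bundle.chains,
    bundle.target_genome, bundle.genes, bundle.term_map,
)
metrics = evaluate_against_manifest(
    res.ces_by_class, bundle.manifest,
    gene_sets={c: s.gene_ids for c, s in res.gene_sets.items()},
    enrichment_by_control=res.enrichment,
)
for cls, m in metrics["classes"].items():
    print(f"{cls:13s} sensitivity {m['detect_sensitivity']:.2f} "
          f"precision {m['detect_precision']:.2f} "
          f"conserved {m['conserved_found']}/{m['conserved_expected']}")
print(f"gene assignment accuracy: {metrics['gene_assignment_accuracy']:.2f}")
print("-> 1.00 everywhere means the screen recovered every planted and every")
print("   chance composite in the manifest, with no false positives.")
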