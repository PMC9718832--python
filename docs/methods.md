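# Methods

This note records the model implemented by `nccescan`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical and design decisions a user adapting
the screen should know about. It describes the procedure only; empirical
claims about recovery and calibration live in the test suite, which
computes them.

## Model

The unit of interest is a **composite cis-regulatory element**: two
transcription-factor binding motifs inside one conserved genomic element,
close enough for the bound factors to form a cooperative complex. The
prototype pairs an NKX homeodomain site with a COUP-TFII nuclear-receptor
half-site (`GGTCR`); we call such a pair an NCCE. The screen asks, for a
query genome with conservation annotation and a whole-genome alignment to
a second genome:

1. Which conserved elements contain an NKX motif and a partner motif at
   heterodimer-compatible spacing?
2. Which of those composites are syntenically conserved — both motifs
   map through the alignment and still match in the target genome?
3. Are the genes nearest those conserved composites enriched for
   particular annotation terms, relative to spacing and motif-identity
   controls?

### Motif scanning

Motifs are IUPAC consensus strings matched exactly (no mismatches, no
position weights). Both strands are scanned; a minus-strand hit is
reported on plus-strand coordinates with `strand='-'`. The base `N` in
the *genome* matches no consensus symbol, including consensus `N`:
unsequenced bases never create hits. Overlapping occurrences are all
reported. Hits are then assigned to containing conserved elements; an
element qualifies only if its conservation log-odds score is **strictly
greater than 300**, and a hit must be fully contained in the element.

The NKX consensus defaults to `TNAAGTG`. This is a documented stand-in
with the qualitative properties of NK-family homeodomain sites (7-mer,
TAAGT-like core); any study using this package on real genomes should
supply the consensus appropriate to its NKX factor via the YAML motif
config (`load_motif_config`), which overrides any motif by role.

### Pairing geometry

All center arithmetic uses **doubled coordinates** to stay in integers:
for a hit on `[start, end)`, `center2 = start + end − 1` (twice the
fractional midpoint). The center-to-center spacing of two hits in bp is
`|Δcenter2| / 2`; a window `[lo, hi]` in bp is tested as
`2·lo ≤ |Δcenter2| ≤ 2·hi`, both bounds inclusive. Windows:

| class | partner consensus | spacing (bp, inclusive) |
|---|---|---|
| NCCE | `GGTCR` | 6–16 |
| WIDE-CONTROL | `GGTCR` | 30–60 |
| SCRAMBLE-1/2/3 | `GTACS` / `AGTCS` / `TGGAY` | 6–16 |

Pairs must lie in the same conserved element and the two motif footprints
must not overlap. When the same genomic pair is found with the partner
hit on both strands (possible for near-palindromic consensi), the pair is
collapsed to a single plus-strand representative, recording which strands
were seen. The composite midpoint is `midpoint2 = center2(NKX) +
center2(partner)` (four times the fractional midpoint), again exact.

### Synteny verification

Alignment chains follow the UCSC chain format, with the first coordinate
triple describing the genome being lifted *from* (plus strand only) and
the second the genome being lifted *to*; `#` comment lines are accepted.
An interval maps only if a single chain covers it without crossing an
alignment gap (**contiguous mapping** — no approximate lifts); blocks
separated by zero-length gaps on both sides are merged first. When
several chains cover an interval the highest-scoring one wins, ties going
to the lowest chain id. Minus-strand target coordinates are converted
from 3'-anchored chain coordinates to plus-strand coordinates. Chains can
be exactly inverted (`invert_chain`), including the minus-strand case
(block order reversed, gap roles swapped), so target-first chain files
are handled by inversion rather than a second code path.

A composite is **conserved** when both motif intervals map contiguously
and the target sequence under each mapped interval matches the motif's
consensus on *either* strand. Failures are labelled
`unmapped-{nkx,partner}` or `motif-lost-{nkx,partner}` (unmapped takes
precedence; NKX checked first).

### Gene assignment and enrichment

Each conserved composite is assigned the gene with the nearest TSS on the
same chromosome, minimizing the exact integer `|midpoint2 − 4·tss|`
(both sides are four times the fractional distance); ties resolve to the
lexicographically smallest gene id. TSS is the start coordinate on `+`
genes and `end − 1` on `−` genes.

For each annotation term, the NCCE gene set is compared against one
control class's gene set at a time. Genes present in both sets are
removed from both (**disjointification**) so the 2×2 table has
independent margins. The p-value is the one-sided Fisher exact test for
greater membership in the test set (`scipy.stats.fisher_exact`,
`alternative='greater'`); the odds ratio uses a Haldane correction of
+0.5 in every cell when any cell is zero. Benjamini–Hochberg FDR is
applied across terms within one test/control comparison
(`statsmodels fdr_bh`). Results sort by (q, p, term id).

## Synthetic data generator

`generate_bundle(SimulationConfig(...))` produces a complete study in
text formats: query FASTA, conserved-element BED, alignment chain, target
FASTA, gene table, term map, and a JSON truth manifest. The defaults are
the standard study conditions and are never adjusted per-run:

- `seed=42`; every random draw comes from per-purpose child streams of
  `numpy.random.default_rng([seed, stream_label])`, so adding a feature
  does not perturb unrelated draws.
- 1 Mb of ~42% GC background over 2 chromosomes; 200 conserved elements
  of 150–300 bp with scores uniform on [150, 600] (so some elements fall
  below the 300 threshold by design).
- 10 planted composites per class (NCCE, WIDE-CONTROL, three scramble
  classes) inside above-threshold elements; realized IUPAC instances,
  random orientation and strand, spacing drawn uniformly inside each
  class window.
- The target genome is the query transformed by the chain: a few indels
  per chromosome placed in the gaps *between* conserved elements (so
  planted motifs map contiguously), and the last chromosome stored
  reverse-complemented with a minus-strand chain, exercising strand
  logic end to end. `synteny_break_rate` optionally mutates planted
  motifs in the target with single substitutions verified to destroy
  the consensus match on both strands.
- One gene is placed with TSS within ±200 bp of each conserved
  composite's midpoint, plus background genes kept ≥2 kb away; a planted
  term (`T000`) is attached to NCCE-proximal genes with probability 0.8
  and to other genes with probability 0.1.
- The manifest's per-class composite lists come from a **self-scan** of
  the generated data with the screen's own scanner, so chance background
  pairs are part of the truth and precision can legitimately reach 1.0.
  (The scan and pairing primitives themselves are validated against
  independent brute-force oracles in the test suite, so the self-scan is
  not circular at the primitive level.)

What the generator does *not* emulate: realistic conservation scoring
(scores are uniform draws, not alignment-derived), repeat structure or
isochore GC variation, weight-matrix motif degeneracy, chain fragmentation
from rearrangements other than one whole-chromosome inversion, and gene
structure beyond a TSS. Problem sizes (1 Mb, 200 elements, 10 plants per
class) are this package's choice: large enough that all stages have
non-trivial work and chance composites occur, small enough that the full
suite runs in seconds from text fixtures.

## Numerical and design choices

- **Exact integer geometry.** Doubled (centers) and quadrupled
  (midpoints) coordinates remove all floating-point from spacing and
  nearest-gene decisions; ties are deterministic.
- **Strict thresholds.** Score must exceed 300 (a score of exactly 300
  is rejected); spacing bounds are inclusive at 6 and 16 (5 and 17 are
  out). Both are pinned by boundary tests.
- **Contiguous-only mapping.** An interval touching an alignment gap is
  unmappable rather than split or approximately shifted, so conservation
  calls never rest on partial lifts.
- **Exact small-sample inference.** Fisher's exact test rather than a
  chi-square approximation, because gene sets from a screen are small;
  the implementation is cross-checked against direct enumeration of 2×2
  tables with fixed margins.
- **Null-calibration sizing.** The type-I-error calibration test uses
  two random 200-gene sets and a term frequency of 0.5. With 50-gene
  sets the exact test's discreteness pulls its size to ≈0.03, below a
  binomial 99% acceptance band around 0.05 for 1000 simulations; 200+200
  sets make the achievable p-values dense enough that the empirical size
  lands inside the band. This is a property of exact tests, not a tuning
  of the method.
- **Single-direction mapping.** Conservation is assessed by lifting
  query → target only; reciprocal-best mapping is out of scope.
  Target-first chain files are supported by exact chain inversion.
- **Two-set exact test.** Enrichment is test-vs-control with
  disjointified sets, not test-vs-genome-background; the controls are
  the point of the design, since they share the scanning and assignment
  pipeline and differ only in spacing or motif identity.

## Limitations

Consensus matching has no mismatch tolerance and no affinity model, so
motif-strength effects are invisible. Nearest-TSS assignment ignores
TADs, contact data and multi-gene regulation. Enrichment treats genes as
exchangeable and terms as independent beyond BH. The synthetic generator
validates the machinery, not biology: performance on generated bundles
does not predict sensitivity on real genomes, where conservation scores,
motif degeneracy and alignment quality are all harder.
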