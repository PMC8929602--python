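# Methods

## Scope and model

plastovar treats a plastome as a circular string over {A,C,G,T,N} with the
canonical quadripartite architecture: large single-copy region (LSC), small
single-copy region (SSC), and two inverted repeats (IRa/IRb) with IRb the
reverse complement of IRa. All coordinates are 0-based half-open on the
linearized orientation LSC → IRa → SSC → IRb; `canonical_orientation`
rotates (and, if needed, strand-flips) any input into this frame, choosing
between the two valid strands by lexicographic order of the resulting
sequence so the operation is idempotent and invariant to rotation and
reverse complement.

## Dispersion scoring

The variability statistic is the sample standard deviation (n−1
denominator) of each canonical k-mer's count vector across samples.
Design choices, and why:

- **Counts, not frequencies.** Plastomes in one study differ in length by
  well under 1%, so normalization changes nothing material; a
  `normalize=True` flag divides by each sample's total k-mer count for
  inputs where sizes do differ.
- **Absent k-mers count 0.** Absence is the signal: a k-mer lost from a
  subset of samples is precisely a variable site. A k-mer absent from *m*
  of *n* samples (count 1 elsewhere) scores
  `sqrt(m(n−m)/(n(n−1)))` — maximized near m = n/2 (0.522 for n = 12)
  and only 0.289 for a private singleton. This tiered structure is what
  separates shared polymorphisms from sample-private noise.
- **IR copy number doubles the scale.** A k-mer inside an inverted repeat
  has count 2 per sample, so its loss pattern scores exactly twice the
  single-copy equivalent. This is intended: diagnostic IR-hosted repeats
  rank at the top, as they should.
- **Default k = 31** (odd, so no window is its own reverse complement);
  25 and 35 are supported for the congruence comparison.
- **Selection default `top_q:0.01`:** the top 1% of k-mers *with sd > 0*.
  Constant k-mers carry no information, so the quantile is taken over the
  variable set. `top_n:N`, `min_sd:t` (strict), and a progressive halving
  schedule (`progressive_selection`) are available; ties are broken
  lexicographically for determinism.
- **Mapping reference: majority-rule consensus** (`majority_consensus`,
  ties resolved toward the first sample). Mapping against any single
  sample silently loses the ancestral k-mers of whichever regions that
  sample itself is mutated in — the consensus retains the majority state
  everywhere, so high-dispersion ancestral k-mers always map. A specific
  sample may be passed instead.
- **max_gap = 0:** hit footprints `[pos, pos+k)` merge only when they
  overlap or abut, since genuine hypervariable regions produce dense hit
  runs. Each merged region is re-scanned against the reference so every
  exact copy (either strand, wrapping the origin) is reported; a repeat
  reachable from both IR copies is reported once, with both copies listed.

Mapped-and-merged regions are labelled by annotation context (inside a
feature → its name; between features A and B → "A-B intergenic"; spanning a
boundary → the overlapping names joined; no annotation → "unannotated"),
and `rank_features_by_variability` aggregates sd per feature for a
gene-level variability table.

## Shared-k-mer distance and trees

`d(a,b) = −ln(p)/k` with `p = |K_a ∩ K_b| / min(|K_a|,|K_b|)` over distinct
canonical k-mer sets. The min-denominator convention keeps p ≤ 1 and is
isolated in `shared_proportion` so variants can be swapped. Distances use
presence/absence only; abundances feed the dispersion statistic, not the
phylogeny. Disjoint k-mer sets make d undefined: an error by default, or a
flagged cap (default 5.0 in the pipeline) when capping is enabled.

Neighbor joining is the standard Saitou–Nei algorithm with the Q-criterion;
ties are broken by the lexicographically smallest label pair and negative
branch lengths are clamped to 0 with a log notice. The implementation is
cross-checked in the test suite against an independent NJ implementation
and, for 5 taxa, against exhaustive enumeration of all 15 unrooted
topologies under the four-point condition. Bootstrap support resamples
k-mer columns of the presence/absence matrix with replacement and reports
the percentage of replicate NJ trees containing each original split.

## Quadripartite structure detection

Exact 25-mer seeds between the sequence and its reverse complement are
grouped by diagonal; the ten best-supported diagonals are extended from a
central seed by X-drop scoring (match +1, mismatch −6, drop 18, max-scoring
prefix). Only a mismatch later recouped by matches is retained, so on exact
inverted repeats the extension reproduces the maximal exact run — this is
what makes the detector agree with the exhaustive O(L²) oracle — while
isolated substitutions inside genuinely diverged IRs are crossed. A
candidate pair is rejected if its mismatch count exceeds
`max_mismatch_frac × length` (default 0.001; pass 0.0 for exact-only).
The longest disjoint pair wins; self-overlapping palindromic matches are
discarded. `min_ir_len` defaults to 1000 bp, which excludes dispersed
repeats (real plastid IRs are ~25–30 kb) while accepting the scaled
synthetic genomes. The longer inter-IR arc is the LSC; in the degenerate
equal-arc case the lower-GC arc is called LSC (single-copy regions are
GC-poorer than IRs in real plastomes) and the result is flagged. For
circular inputs a half-length rotation is also scanned so IRs spanning the
origin are found; intervals may then wrap (end > L, taken mod L) and the
tiling invariant is checked circularly.

## Simple sequence repeats

Maximal perfect tandem runs of 2–6 bp motifs with length strictly greater
than 20 bp (the configurable `min_len=21` default). A run is reported once,
under its smallest period (computed by the KMP failure function on the full
run — the leading motif alone can have a smaller spurious period, e.g.
ACGTAC); homopolymers are excluded. Motifs are canonicalized as the
lexicographic minimum over all rotations of the motif and of its reverse
complement. Cross-sample comparison matches loci by identical flanking
sequence (default 20 bp both sides): matched loci of unequal length are
length-polymorphic, equal are shared, unmatched are private. Only perfect
repeats are detected; imperfect-repeat scoring (RepeatMasker-style) is out
of scope, so counts on real data will differ from library-based tools.

## Plastid contig selection

Step 1 keeps contigs with depth of coverage at or above the DP median of
the whole assembly (inclusive; even n uses the mean of the central pair) —
chloroplast DNA is over-represented in total-DNA extracts, so plastid
contigs sit above the median. Step 2 aligns each surviving contig against a
plastid reference panel by infix edit-distance alignment (edlib), both
strands, after an exact 15-mer seed prefilter; identity is
`100·(len − dist)/len` and the contig is kept at ≥ 85% over ≥ 100 bp.
An e-value criterion is deliberately not reproduced: with near-identical
organelle references, identity over a minimum length is the operative
filter, and the audit trail (`SelectionResult`) records the reason each
contig was dropped.

## The synthetic-data generator

`generate_backbone` draws LSC and SSC at GC 0.37 and the IR at GC ≈ 0.41
(matching the single-copy/IR GC contrast of real plastomes), sets
IRb = revcomp(IRa), and plants non-overlapping hypervariable windows and
SSR slots. `evolve_population` walks the guide tree (Newick, or a star with
per-leaf branch length `star_branch_length`) applying Jukes–Cantor-like
substitutions (uniform choice among the 3 alternative bases; no indels) at
`background_rate` per site per unit branch length; window sites use
`background_rate × multiplier` absolutely. IRa mutations are mirrored into
IRb so IR identity stays exact, matching assembled plastomes where the IRs
are collapsed during assembly.

Deliberate idealizations, chosen once as the study conditions:

- **IR background substitution is off by default** (`ir_rate_factor = 0`,
  settable to 1). Real plastid IRs are the most conserved plastome regions
  (copy-correction suppresses their substitution rate). Because IR k-mers
  score double (copy 2), even a realistic trickle of IR background
  mutations would dominate the dispersion ranking and bury single-copy
  signal; the default isolates the planted-window signal the recovery
  study is about. Planted IRa windows still mutate and are mirrored.
- **`star_branch_length = 0.25`** with the default rate 0.005/site/unit
  makes a planted-window k-mer's per-sample loss probability
  `1 − (1 − 0.025)^31 ≈ 0.5` — the sd-maximizing loss pattern — while
  background k-mers stay in the low-sd singleton tiers. The value follows
  from that binomial design calculation, not from biology.
- **SSR slots are fixed-width**: each locus occupies
  `len(motif)·(base+jitter) + 24` bp, the array followed by a homopolymer
  pad, so per-sample copy-number jitter changes the run length without
  shifting any other coordinate and every sample shares both flanks of
  every locus. The pad can extend a run by a constant sub-period amount
  (the same for every sample), so length differences between samples equal
  copy-number differences exactly. SSR slots (±25 bp) and the four
  junction-adjacent bases are excluded from point mutation — the former so
  copy number is the only signal at repeat loci, the latter because a
  chance complementary base at an IR junction would genuinely lengthen
  the maximal inverted repeat and shift the true coordinates off the
  planted ones.
- **Hybrids** copy their parent's evolved sequence plus exactly
  `n_private_mutations` substitutions at distinct positions. Inside the
  population simulator these fall in single-copy regions (outside SSR
  slots) so the IR-identity and SSR invariants survive; standalone
  `make_hybrid` draws from the whole sequence.
- **Contig simulation** cuts plastid contigs as substrings of the circle
  (coverage ~ Normal(500, 50)×, floored at 1) and decoys as random DNA at
  GC 0.40 (coverage ~ Normal(20, 5)×), lengths uniform 500–3000 bp.

What the generator does **not** emulate: indels, structural rearrangements
(the SSC-inversion polymorphism of real plastomes), rate heterogeneity
beyond the planted windows, sequencing error, or read-level data. Passing
recovery tests therefore demonstrates the statistic's behavior under its
own model — clean substitutions on an exact quadripartite backbone — not
robustness to assembly artifacts or alignment-scale divergence.

## Problem sizes and determinism

The default desk-scale study uses 12 samples on 15.9 kb genomes
(LSC 8.7 kb, IR 3 kb, SSC 1.2 kb — a 1:10 scale model of the ~160 kb,
87/30/12 kb real architecture), 100 random matrices for the dispersion
oracle, and 100 fixtures ≤ 5 kb for the structure oracle; these sizes keep
the whole analysis in minutes on one core while leaving every ratio
(window/genome, IR/genome, k/window) representative. All randomness flows
from a single seed through named `SeedSequence` streams; identical
(config, seed) give byte-identical FASTA and TSV output, which the
pipeline tests assert.

## Known limitations

- The AAF distance saturates as shared k-mers vanish; beyond roughly 10%
  divergence the min-denominator proportion is no longer tree-additive and
  NJ topology quality degrades. The cap (default 5.0) keeps disjoint pairs
  finite but flags them.
- H-disp calling reports regions on the chosen reference only; variation
  in sequence absent from the reference appears in the unmapped-k-mer list
  rather than as a region.
- IR detection assumes exactly one IR pair; plastomes that have lost an IR
  raise "no quadripartite structure" rather than degrading gracefully.
- Junction grouping compares feature-context 4-tuples only; it exposes,
  but does not further analyze, gene-order differences such as SSC
  inversions.
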