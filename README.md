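# plastovar

Alignment-free discovery of hypervariable plastome regions, plus the
supporting analyses a chloroplast-genome comparison needs: shared-k-mer
distance phylogeny, quadripartite structure and junction characterization,
SSR detection, and plastid contig selection from whole-genome assemblies.

## Who this is for

Plant molecular systematists comparing a handful to a few dozen complete
chloroplast genomes (plastomes) from closely related species — for example a
species complex with suspected hybrids — who want to (1) find the genome
regions most variable across the sample set without building a multiple
alignment, (2) get a quick distance phylogeny, and (3) characterize each
assembly's architecture and repeats. A synthetic plastome-population
generator with exported ground truth makes every stage testable at desk
scale.

## The core statistic: k-mer frequency dispersion (H-disp regions)

Each sample *s* is reduced to counts \(c_s(w)\) of canonical k-mers *w*
(the lexicographic minimum of each length-*k* window and its reverse
complement, default *k* = 31, circular genomes wrap the origin). Across *n*
samples each k-mer is scored by the sample standard deviation of its count
vector,

    sd(w) = sqrt( sum_s (c_s(w) - mean(c(w)))^2 / (n - 1) ),

with absent k-mers counted 0 — so presence/absence *and* copy-number
differences both contribute. The top-dispersion k-mers are exactly mapped to
a reference (by default the majority-rule consensus; both strands, all
occurrences), and overlapping footprints are merged into contiguous
**H-disp regions**, each reported with every exact copy position, its gene
or intergenic context, and its mean sd. Hypervariable coding and intergenic
regions — candidate barcoding markers — surface this way without alignment.

Between-sample distance uses the shared-k-mer (AAF) convention: with
\(p = |K_a \cap K_b| / \min(|K_a|, |K_b|)\) over distinct canonical k-mer
sets, \(d(a,b) = -\ln(p)/k\). Trees come from standard neighbor joining
(Saitou–Nei), with column-bootstrap split support and a congruence check
across k ∈ {25, 31, 35}.

The structure stage finds the plastome's two inverted repeats (IRs) by
seeded reverse-complement matching with X-drop extension, yielding the
LSC / IRa / SSC / IRb partition (LSC = longer single-copy arc), per-region
GC, and the gene context of the four junctions. The repeat stage reports
perfect tandem repeats of 2–6 bp motifs longer than 20 bp and classifies
loci between samples as shared / length-polymorphic / private by flank
matching. The assembly filter reproduces the two-step plastid contig
selection: keep contigs at or above the coverage (DP) median, then require
≥ 85% alignment identity against a plastid reference panel.

## Worked example

Simulate the default study — 12 samples on ~16 kb quadripartite genomes
(a 1:10 scale model of a real ~160 kb plastome) with three planted 60 bp
hypervariable windows at 20× the background substitution rate — then call
H-disp regions against the consensus:

```python
from plastovar.simulate import default_hdisp_simulation, simulate_population
from plastovar.kmer import count_kmers, FrequencyMatrix
from plastovar.hdisp import call_hdisp_regions, majority_consensus

cfg = default_hdisp_simulation(seed=1)
records, truth, backbone = simulate_population(cfg)
print("planted windows:", truth.planted_windows)

freq = FrequencyMatrix.from_tables([count_kmers(r, k=31) for r in records])
ref = majority_consensus(records)
regions, unmapped = call_hdisp_regions(freq, ref, strategy="top_q:0.01")
for r in regions:
    print(f"H-disp {r.start}-{r.end} ({r.length} bp), copies={len(r.copies)}, "
          f"kmers={r.contributing_kmers}, mean_sd={r.mean_sd:.3f}")
```

prints

```
planted windows: [(1365, 1425, 20.0), (5919, 5979, 20.0), (12794, 12854, 20.0)]
H-disp 1359-1409 (50 bp), copies=1, kmers=20, mean_sd=0.518
H-disp 1411-1444 (33 bp), copies=1, kmers=3, mean_sd=0.522
H-disp 5904-6004 (100 bp), copies=1, kmers=43, mean_sd=0.514
H-disp 12781-12860 (79 bp), copies=1, kmers=34, mean_sd=0.513
```

All three planted windows (two in the LSC, one in the SSC) are recovered —
every called region overlaps a planted window and no region falls
elsewhere. `mean_sd ≈ 0.52` is what a k-mer absent from about half of 12
samples scores, the signature of a hypervariable site; a k-mer private to
one sample scores only 0.29, which is why background noise stays below the
selection. A region inside an inverted repeat would report `copies=2` with
one copy per strand, the fingerprint of IR-hosted repeats.

The same analyses are scriptable from the shell:

```bash
plastovar simulate --seed 1 --n-samples 12 --out pop/
plastovar tree pop/samples.fasta --k 31 --out tree.nwk
plastovar hdisp pop/samples.fasta --select top_q:0.01 --out hdisp.tsv
plastovar structure pop/samples.fasta --min-ir 1000
plastovar ssr pop/samples.fasta --out ssrs.tsv
plastovar run --seed 1 --out bundle/     # full pipeline + manifest
```

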