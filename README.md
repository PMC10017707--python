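# depscan

Chromatin-state screening of oncogene dependency across a tumor cell-line
panel.

## The problem

Tumor cell lines differ in how strongly their growth depends on an oncogenic
transcriptional coactivator (here, Yap).  Dependency can be measured
directly by a cell-competition assay — mix knockout (Tm+) and intact (GFP+)
populations 50/50 and follow both by flow cytometry over sequential
passages — and then *explained* by asking which regulatory elements in the
epigenome track that dependency across the panel.  `depscan` implements the
full analysis chain as a tested, reusable library:

1. **Dependency scoring.**  Under exponential growth the log2 odds
   `log2(N_test(t) / N_ref(t))` is linear in time; its OLS slope is the
   log2 relative growth rate (per day) and the dependency score is its
   negation, so lines whose knockout population collapses fastest score
   highest.  A *PTF score* (0–5) counts how many of the five progenitor
   transcription factors Sox2, Sox5, Twist2, Nr2f1, Nr2f2 are highly
   expressed per line; lines split into Low (0–2) and High (3–5) groups.
2. **Signal normalization.**  Trimmed-mean-of-M-values (TMM) scaling
   factors from large-bin fragment counts (1,250 bp bins for TFs,
   10,800 bp for histone marks / BRD4), then counts per million of the
   effective library size.
3. **The Kendall screen.**  Per-antibody master peaks (union-merge of all
   per-sample peak calls) are filtered — detected in ≥ 3 samples, maximal
   normalized count ≥ 10, overlapping the other mark's master peaks — and
   each surviving H3K27ac/BRD4 locus pair is correlated against the
   per-line dependency scores with Kendall's τ-b.  Loci with both
   |τ| > 0.3 and concordant signs are labeled dependency-high (YapD_H) or
   dependency-low (YapD_L).  Rank–rank hypergeometric overlap (RRHO)
   quantifies cross-mark concordance, and ward.D2 clustering of row-scaled
   signal orders the heatmaps.
4. **Chromatin states and super-enhancers.**  Master loci split into
   H3K4me3+ TSS vs H3K4me3− CRE, active (H3K27ac+ and BRD4+) vs inactive,
   a seven-way heatmap partition (p1–p3 / e1–e4), and combinatorial
   Jun/Sox2/Sox5/Twist2 co-binding categories.  Super-enhancers are called
   ROSE-style: stitch CREs within 12.5 kb, rank by total signal, cut off
   where the scaled rank-signal curve climbs steeper than 45°.
5. **TF footprinting.**  Around each motif occurrence, *flank height* =
   flanking signal as fold over local background, *footprint depth* =
   flank minus core height, *relative depth* = depth / flank height.
   Sites split into bound/unbound by a two-component Gaussian mixture on
   per-site depths.

A first-class synthetic-data module (`depscan.synthetic`) generates whole
panels — 19 lines, planted rank-correlated loci at a target effect τ,
planted co-binding structure and super-enhancer clusters, multinomial
competition counts, Poisson insertion profiles with planted protection —
with the ground truth serialized next to every fixture.

## Worked example

```python
from depscan import simulate_competition, relative_growth_rate

ts = simulate_competition(rate_ref=1.0, rate_test=0.2,
                          days=[0, 3, 7, 10, 14],
                          n_cells=10_000, rng=2024, line_id="line07")
score = relative_growth_rate(ts)
```

With a planted rate difference of −0.8 log2/day, the observed FACS counts
and the fit are:

```
days         [0, 3, 7, 10, 14]
Tm+ counts   [5074, 1564, 201, 45, 5]
GFP+ counts  [4926, 8436, 9799, 9955, 9995]
log2 relative growth rate: -0.782 / day (SE 0.008)
dependency score:          +0.782
```

The knockout population's odds halve slightly faster than every 31 h; the
estimate recovers the planted −0.8/day within sampling error, and the
positive dependency score marks this line as strongly Yap-dependent.

The same works end to end from the shell:

```sh
depscan simulate --out demo --n-loci 800 --n-pos 60 --n-neg 60 --seed 1
depscan run-all --input-dir demo --output-dir demo_out --seed 1
# -> pipeline done: 61 YapD_H, 59 YapD_L, 5 SE
```

Of 60 planted loci per direction, the cutoff-0.3 screen recovers 61 and 59
(a planted locus can be missed and a null locus can slip in); all 5
planted super-enhancer clusters are called.  `demo_out/summary.json` holds
the machine-readable stage counts; `screen.tsv`, `yapd_high.bed`,
`state_annotations.tsv`, `superenhancers.bed` and `footprint_*.tsv` hold
the per-locus results.

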