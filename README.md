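# chromaprof

Fragment-size-class footprinting of MNase-digested, cross-linked
ChIP-seq (MNase-X-ChIP), with nucleosome occupancy and CATCH-IT
turnover profiling and RNA polymerase II promoter-escape statistics.

## The problem

Sonication-based ChIP resolves protein positions only to 100–300 bp.
Digesting formaldehyde-cross-linked chromatin with micrococcal nuclease
instead leaves protected fragments whose *length* identifies the
protecting species: sub-nucleosomal fragments of 35–75 bp are direct
footprints of factors such as PolII (~35 bp) and the chromatin
remodeler Chd1 (20–45 bp), while 111–140 bp fragments are
mononucleosomal protections — including nucleosomes crosslinked to a
bound factor. Splitting one paired-end library by fragment size thus
yields a base-pair-resolution factor map and a nucleosome map
simultaneously.

`chromaprof` implements the analysis around this idea for anyone
working with MNase-X-ChIP-style data: size-class selection, midpoint
and span coverage, TSS/TES-anchored metaprofiles and heatmaps, gene
rankings, quintile and sliding-window analyses, CATCH-IT turnover
region averages and difference curves, and per-gene promoter-escape
statistics. A synthetic-data generator encodes the underlying chromatin
model (phased nucleosome arrays with an NDR, factor–nucleosome
crosslinks, activity- and elongation-coupled turnover, and a
dominant-negative remodeler condition) so every stage can be validated
end-to-end against known ground truth on a desk-scale cohort.

## Statistics

For gene *g* with transcription-oriented windows and per-bp normalized
densities d(·):

* stalling index SI(g) = d_total-PolII(−100..+300) / d_Ser2phos(+1 kb..min(+5 kb, end))
* traveling ratio TR(g) = d_total-PolII(−30..+300) / d_total-PolII(+300..end)
* elongation fold-enrichment FE_w(g) = d_Ser2phos(window w) / d_Ser2phos(first 5 kb),
  for consecutive 1-kb genic windows w

Ratios carry a pseudocount (1% of the track's genome-wide mean) in
numerator and denominator. Group comparisons use the two-sample
Kolmogorov–Smirnov test, Welch's t, and Pearson correlation.

## Worked example

Simulate a wild-type cohort, recover the +1 nucleosome entry site from
the mononucleosome metaprofile, and measure the stalling contrast of
the dominant-negative (K510R) condition:

```python
from chromaprof import workflows

out = workflows.recover_plus1_entry(seed=1, n_genes=800, n_fragments=80_000)
print(f"+1 entry recovered: +{out['entry']:.0f} bp (truth +{out['truth']:.0f})")

contrast = workflows.stalling_contrast(seed=1, n_genes=800, n_fragments=80_000)
print(f"median stalling-index ratio (K510R / WT): "
      f"{contrast['median_ratio']:.2f} over {contrast['n']} genes")

corr = workflows.turnover_elongation_correlation(
    seed=1, n_genes=800, n_fragments=80_000, window=200)
print(f"turnover vs elongating PolII trend: r = {corr['r']:.3f} "
      f"({corr['n_windows']} windows)")
```

prints

```
+1 entry recovered: +44 bp (truth +50)
median stalling-index ratio (K510R / WT): 1.87 over 800 genes
turnover vs elongating PolII trend: r = 1.000 (601 windows)
```

The entry site is recovered within a few bp of the generative +50 bp
architecture; the mutant roughly doubles the median stalling index
(PolII accumulates at promoters while elongating PolII drains from
gene bodies); and gene-body turnover tracks elongating-PolII density
almost perfectly in the sliding-window trend.

The same analyses are available from the shell on files
(BED/bedGraph/TSV):

```sh
chromaprof simulate --condition wt   --seed 11 --outdir sim/wt
chromaprof simulate --condition k510r --seed 11 --outdir sim/k510r
chromaprof profiles --genes sim/wt/genes.bed \
    --fragments sim/wt/nucleosome_wt.bed --size-class mono \
    --mode span --outdir out/nuc
chromaprof stalling --genes sim/wt/genes.bed \
    --total sim/wt/total_polii_wt.bed  --ser2 sim/wt/ser2_polii_wt.bed \
    --total-b sim/k510r/total_polii_k510r.bed \
    --ser2-b  sim/k510r/ser2_polii_k510r.bed --outdir out/stalling
```

All outputs are plain TSV/JSON with provenance headers; generative
presets live in `src/chromaprof/presets.yaml`.

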