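# Methods

## Scope and model

`chromaprof` analyses paired-end fragment libraries from MNase-digested,
formaldehyde-cross-linked ChIP (MNase-X-ChIP) together with CATCH-IT
nucleosome-turnover signal. The analysis rests on one organising idea:
fragment length separates molecular species. Sub-nucleosomal fragments
(35–75 bp) are footprints of DNA-bound factors — RNA polymerase II
(~35 bp) and the chromatin remodeler Chd1 (20–45 bp) — while
mononucleosome-sized fragments (111–140 bp) report histone-protected
DNA, including factor–nucleosome crosslink products. Splitting a single
library by size class therefore yields a factor map and a nucleosome
map from the same experiment.

Two reduction modes turn fragments into per-base signal:

* **midpoint counting** for short-fragment footprint profiles — the
  midpoint is the best point estimate of a small protected region, and
  midpoint profiles localize factor peaks most sharply;
* **span counting** for nucleosome occupancy — occupancy is the
  probability that a base is wrapped, so every covered base counts.

Tracks are normalized to fragments per million of the originating
library (per factor / condition / size class), recorded in a provenance
tag so only like-for-like tracks are compared. All gene-anchored
operations are transcription-oriented: increasing offsets point 5'→3'
regardless of strand, and minus-strand rows of anchored matrices are
coordinate-reversed.

## Per-gene transcription statistics

For a gene with TSS-oriented windows, with per-bp means of normalized
signal:

* **stalling index** = (total-PolII density over −100..+300 bp) /
  (Ser2phos-PolII density over +1 kb..min(+5 kb, gene end));
  genes ≤ 1 kb are excluded.
* **traveling ratio** = (total-PolII density over −30..+300 bp) /
  (total-PolII density over +300 bp..gene end); the gene-body window is
  our own choice — the source definition fixes only the promoter
  window — and is configurable.
* **elongation fold-enrichment**: Ser2phos density per consecutive 1-kb
  genic window relative to the gene's mean over its first 5 kb; genes
  < 5 kb are excluded. A uniform track gives 1 in every window.

Densities are per-bp window means, not window sums; for ratios of
fixed-width windows the two differ only by constants, but per-bp means
keep windows of different widths commensurable. Ratios are stabilized
with a pseudocount ε, by default 1% of the genome-wide mean of the
respective track, added to numerator and denominator; records whose
denominator is below ε are flagged `denominator_limited`. Stalled and
processive gene sets are the k highest- and lowest-stalling genes of
the top quintile of PolII promoter occupancy (ties broken by gene id so
the sets are deterministic and disjoint).

Two-sample comparisons use the Kolmogorov–Smirnov test (two-sided,
asymptotic p with effective n = n_a·n_b/(n_a+n_b) — appropriate at the
hundreds-to-thousands of genes per group compared here), Welch's
unequal-variance t-test, and the Pearson correlation, all via
scipy.stats behind the package's own validation layer.

## Synthetic cohort generator

The generator encodes the chromatin architecture the analysis is meant
to detect, so that the entire pipeline can be exercised — and its
estimators validated against known ground truth — at desk scale.

**Gene cohort.** 2,000 non-overlapping genes by default, on 4
chromosomes, lengths log-normal (median 6 kb, σ=0.45, clipped to
3–25 kb), strands random, intergenic gaps 10.5–12 kb so that ±5 kb
analysis flanks never overlap a neighbour. Two independent log-normal
latents drive everything downstream:

* *activity* (σ=1.0): PolII promoter occupancy, long-tailed so the
  activity quintiles span a realistic dynamic range;
* *elongation efficiency* (σ=1.0): sets the odds of a total-PolII event
  residing in the gene body rather than the promoter
  (promoter share q = 1/(1 + 0.4286·e), median share 0.7) and scales
  Ser2phos output. Because one latent feeds both the stalling index and
  the traveling ratio, wild-type stalling indices span orders of
  magnitude and the two metrics are strongly correlated, as observed in
  the data this model emulates.

**Nucleosome architecture.** Per gene: a −1 nucleosome (dyad −170), an
NDR containing the TSS (−96..+50), a +1 nucleosome with entry site
+50 bp from the TSS (dyad at entry+73 = +123), then a phased array at a
190-bp repeat, each dyad jittered once per gene with σ=15 bp.
Occupancies decay by 0.85 per array position. Only the +1 entry (~+50)
and the NDR's existence are constrained by the source observations; the
repeat length, fuzziness, −1 position and decay are this package's own
defaults, exposed in `presets.yaml`. Dyad positions are drawn from a
condition-independent random stream, so wild-type and mutant cohorts
share positions exactly and differ only in occupancy — positioning
unaffected, occupancy reduced (×0.6 promoter-proximal, ×0.8 gene body
under `k510r`).

**Libraries.** Each of the 2×10⁵ fragments per library is, with
probability `background_fraction`=0.05, uniform background; otherwise a
binding event on a gene chosen ∝ activity (promoter factors), ∝
activity × length × elongation (Ser2phos), or ∝ length (nucleosome
libraries). An event yields, with probability `p_x`=0.3, a
mononucleosome-sized fragment (N(130,8) clipped to 111–147 bp) centred
on the nearest realized dyad — the factor crosslinked to its
neighbouring nucleosome — and otherwise a short footprint fragment
(PolII N(35,5) clipped 25–50; Chd1 uniform 20–45) placed by the
factor's placement rule:

| factor, condition | placement of footprint centres |
|---|---|
| total PolII, wt | N(0, 20) at the TSS, promoter share q per gene |
| total PolII, k510r | promoter share min(1.35·q, 0.98); within it, 40% TSS component and 36/16/8% stall components at entry_k + 20 bp of the +1/+2/+3 nucleosomes |
| Ser2phos, wt | 15% early (+300..+1000), 85% body (+1000..end) |
| Ser2phos, k510r | body fraction reduced to 0.48 (elongation lost to early stalling) |
| Chd1, wt | 70% uniform 0..+500, 30% exponential tail (scale 300) beyond |
| K510R-Chd1, genome-average | N(+60, 30) |
| K510R-Chd1, per-nucleosome | entry_k + 50 ± 15 at the +1/+2/+3 nucleosomes (55/28/17%) |

The K510R promoter gain (1.35) and Ser2phos body fraction (0.48) were
chosen so the *designed* genome-wide median stalling-index contrast is
twofold after accounting for what the −100..+300 window actually
captures of the stall components and for the pseudocount; the stall
redistribution applies to every gene, but its per-gene magnitude is
capped at a promoter share of 0.98, which makes already-stalled genes
(high share) the least affected and processive genes the most affected.
Per-library normalization cannot see a uniform per-gene multiplier —
weights renormalize — so the mutant contrast is modelled as
redistribution *within* each library (promoter vs body, early vs late),
which is also how it manifests in normalized sequencing data.

**CATCH-IT.** Dense per-base turnover signal: per gene a promoter level
`basal + slope·min(activity, ceiling)` (wild type; the mutant's slope
is 0, i.e. basal — Chd1-dependent turnover abolished) and a body level
`body_basal + body_coupling·(activity·elongation) + δ` (δ=0.15 only in
the mutant — a constant increment at all elongating-PolII densities),
blended by a Gaussian positional decay (scale 400 bp) centred on the
TSS, plus per-position (σ=0.05) and per-gene (σ=0.04) Gaussian noise
over an intergenic background of 0.05. The signal is dense and
array-resolution-free; probe-level structure of the original promoter
arrays is deliberately not modelled.

**Determinism.** Every output is a pure function of (presets, config,
seed); random streams are split per purpose (layout, latents, dyads,
each factor×condition×placement library, CATCH-IT per condition) via
`numpy.random.SeedSequence`, so e.g. regenerating the nucleosome map
under another condition reproduces identical positions.

## Recovery estimators

* `estimate_plus1_entry`: smooth the mononucleosome span-coverage
  metaprofile with a centred 31-bp moving average, locate the NDR
  minimum nearest the TSS (searched in −150..+100), take the first
  prominent local maximum downstream (≥5% of the profile's dynamic
  range, ≥50 bp from competitors) as the +1 dyad peak, and subtract
  73 bp. Assumes span reduction of 111–140 bp fragments.
* `estimate_peak_offset`: position of the maximum of the 31-bp-smoothed
  profile in a search window; a smoothing plateau resolves to its
  centre, separated ties to the leftmost peak. For peaks near the +1
  nucleosome the search window is +25..+200 bp — the promoter-proximal
  region downstream of the TSS-centred initiation peak, which would
  otherwise dominate the argmax.

## Numerical and degenerate-case choices

* Size-class bounds are inclusive on both ends (natural-language
  ranges).
* Missing track positions count as zero (coverage tracks are dense by
  construction); windows truncated at a chromosome end keep the full
  width as divisor.
* Percent-dynamic-range of a constant profile returns all zeros with a
  warning rather than dividing by zero.
* Ranking ties break lexicographically by gene id; quintile remainders
  go to the highest-occupancy blocks; sliding windows advance one gene
  per step and degenerate to the identity at window 1.
* The Welch t statistic is refused when both samples have zero variance.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis
targets: size-class composition, a phased nucleosome array with an NDR,
factor–nucleosome crosslink contamination, activity- and
elongation-coupled turnover, and the mutant's redistribution contrasts.
It does not model sequence (no MNase sequence bias, GC or mappability
structure), digestion-level kinetics, replicate or batch structure, or
probe-level array noise. Passing recovery tests therefore demonstrates
that the pipeline's estimators are unbiased and correctly oriented on
data with known truth at realistic counting noise — not that they are
robust to every artefact of real sequencing data.

Default problem sizes (2,000 genes, 2×10⁵ fragments per library) are
the package's chosen study scale: large enough that positional
recoveries are reproducible to a few bp across seeds and the
median-contrast estimate is stable, small enough that any workflow runs
in seconds on one CPU. The unit-test fixtures use a 400-gene cohort at
the same per-gene sequencing depth.

## Known limitations

* The stalling and traveling-ratio windows assume genes are spaced
  farther apart than the largest window; the synthetic layout
  guarantees this, real gene annotations require the documented filter
  (drop genes < 2 kb or with a neighbour within 1 kb of TSS/TES).
* The KS p-value is asymptotic; at group sizes below a few dozen genes
  it is conservative.
* `estimate_plus1_entry` presumes an NDR-bearing ("open") promoter
  architecture; on profiles without a pronounced NDR (e.g. the lowest
  Chd1-occupancy class) the minimum search is not meaningful.
* CATCH-IT is treated as dense per-base signal; probe-level resolution
  of array-based turnover measurements is abstracted away.
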