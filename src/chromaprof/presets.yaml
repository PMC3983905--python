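# Generative presets for the synthetic chromatin cohort (version 1).
# Positions are bp, transcription-oriented relative to the TSS unless noted.
version: 1

architecture:
  nucleosome_footprint: 147     # bp wrapped around the octamer
  plus1_entry: 50               # 5' edge of the +1 nucleosome; dyad = entry + 73
  repeat_length: 190            # dyad-to-dyad spacing of the genic array
  fuzz_sd: 15.0                 # per-gene dyad positioning sd
  minus1_dyad: -170
  ndr: [-96, 50]                # nucleosome-depleted region containing the TSS
  occupancy_decay: 0.85         # per-nucleosome decay of array occupancy
  minus1_occupancy: 0.8

footprints:
  total_polii:  {dist: normal,  mean: 35, sd: 5, min_len: 25, max_len: 50}
  ser2_polii:   {dist: normal,  mean: 35, sd: 5, min_len: 25, max_len: 50}
  chd1:         {dist: uniform, mean: null, sd: null, min_len: 20, max_len: 45}
  nucleosome:   {dist: normal,  mean: 130, sd: 8, min_len: 111, max_len: 147}

placements:
  tss_sd: 20                    # total-PolII initiation peak width
  stall_inset: 20               # PolII stall position inside each nucleosome entry
  stall_sd: 15
  stall_weights: [0.40, 0.36, 0.16, 0.08]   # TSS component, then +1/+2/+3 stalls
  chd1_wt_span: 500             # uniform Chd1 coverage over the early gene body
  chd1_wt_body_fraction: 0.30   # events beyond +span, exponential tail
  chd1_wt_tail: 300
  chd1_ga_center: 60            # genome-average K510R-Chd1 peak
  chd1_ga_sd: 30
  chd1_pn_inset: 50             # K510R-Chd1 action site inside each entry
  chd1_pn_sd: 15
  chd1_pn_weights: [0.55, 0.28, 0.17]       # +1/+2/+3 nucleosomes
  ser2_early_window: [300, 1000]
  mono_length: {mean: 130, sd: 8, min_len: 111, max_len: 147}

conditions:
  wt:
    nuc_occ_promoter: 1.0
    nuc_occ_body: 1.0
    promoter_gain: 1.0          # multiplier on each gene's promoter share of PolII
    promoter_share_cap: 0.98
    ser2_body_fraction: 0.85    # share of Ser2phos events placed beyond +1 kb
    turnover:
      basal: 0.20
      slope: 0.50               # promoter turnover per unit PolII activity
      ceiling: 1.70             # activity above which promoter turnover saturates
      body_basal: 0.10
      body_coupling: 0.15       # gene-body turnover per unit elongating density
      delta: 0.0                # constant gene-body increment over wild type
      noise_sd: 0.05
      gene_noise_sd: 0.04
      background_level: 0.05
      decay_scale: 400          # promoter-to-body positional decay (bp)
  k510r:
    nuc_occ_promoter: 0.6
    nuc_occ_body: 0.8
    promoter_gain: 1.35
    promoter_share_cap: 0.98
    ser2_body_fraction: 0.48    # elongation loss to early stalling (designed twofold median index contrast)
    turnover:
      basal: 0.20
      slope: 0.0                # promoter turnover abrogated to basal
      ceiling: 1.70
      body_basal: 0.10
      body_coupling: 0.15
      delta: 0.15               # constant turnover gain throughout the gene body
      noise_sd: 0.05
      gene_noise_sd: 0.04
      background_level: 0.05
      decay_scale: 400

simulation:
  n_genes: 2000
  length_median: 6000
  length_sigma: 0.45
  length_min: 3000
  length_max: 25000
  gap_min: 10500
  gap_max: 12000
  n_chroms: 4
  flank: 6000
  n_fragments: 200000
  p_x: 0.3                      # factor-nucleosome crosslink probability
  background_fraction: 0.05
  activity_sigma: 1.0           # lognormal sd of per-gene PolII promoter activity
  elongation_sigma: 1.0         # lognormal sd of per-gene elongation efficiency (stalling spans decades)
  promoter_body_ratio: 0.4286   # body/promoter PolII odds at unit efficiency (median promoter share 0.7)
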