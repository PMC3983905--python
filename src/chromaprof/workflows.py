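"""End-to-end synthetic-cohort workflows.

Each function simulates a cohort from scratch at the default study
scale (2,000 genes, 2x10^5 fragments per library), runs the relevant
analysis stages, and returns the recovered quantity next to the
generative ground truth.  They are the single source for both the
acceptance checks and command-line reproduction, and are deterministic
in the seed.
"""

from __future__ import annotations

import numpy as np

from .fragment_ops import MONO, SHORT, midpoint_coverage, normalize_rpm, select_size_class, span_coverage
from .metaprofile import WindowSpec, build_anchored_matrix, mean_profile, rank_genes, window_mean
from .stats import pearson_r
from .synthetic import (
    Cohort,
    SimConfig,
    default_architecture,
    default_sim_config,
    estimate_peak_offset,
    estimate_plus1_entry,
    sample_gene_cohort,
    simulate_catchit,
    simulate_library,
)
from .transcription import PROMOTER_WINDOW, classify_stalled_processive, compute_stalling_records, median_stalling_ratio
from .turnover import BODY_TES, catchit_region_mean, turnover_vs_density

__all__ = [
    "PLUS1_SEARCH_WINDOW",
    "recover_plus1_entry",
    "recover_chd1_genome_average_peak",
    "recover_processive_offset",
    "stalling_contrast",
    "turnover_elongation_correlation",
]

#: Search window for factor peaks at the +1 nucleosome: the
#: promoter-proximal region downstream of the TSS-centred initiation peak.
PLUS1_SEARCH_WINDOW = (25, 200)

_FLANK_UP, _FLANK_DOWN = 500, 1000


def _config(seed: int, n_genes: int | None, n_fragments: int | None) -> SimConfig:
    overrides = {}
    if n_genes is not None:
        overrides["n_genes"] = n_genes
    if n_fragments is not None:
        overrides["n_fragments"] = n_fragments
    return default_sim_config(seed, **overrides)


def _rpm_track(cohort: Cohort, factor, condition, placement="default",
               size_class=None, mode="span"):
    lib = simulate_library(factor, condition, cohort, config=cohort.config,
                           placement=placement)
    if size_class is not None:
        lib = select_size_class(lib, size_class)
    reduce = span_coverage if mode == "span" else midpoint_coverage
    return normalize_rpm(reduce(lib, cohort.chrom_sizes), lib.library_size)


def _tss_profile(cohort: Cohort, track, subset=None):
    matrix = build_anchored_matrix(track, cohort.genes, "TSS", _FLANK_UP, _FLANK_DOWN, 1)
    return mean_profile(matrix, subset=subset)


def recover_plus1_entry(seed: int, n_genes: int | None = None,
                        n_fragments: int | None = None) -> dict:
    """+1 nucleosome entry site (bp from TSS) recovered from the
    mononucleosome span-coverage metaprofile of a wild-type cohort."""
    cohort = sample_gene_cohort(_config(seed, n_genes, n_fragments))
    track = _rpm_track(cohort, "nucleosome", "wt", size_class=MONO, mode="span")
    entry = estimate_plus1_entry(_tss_profile(cohort, track))
    return {
        "entry": entry,
        "truth": float(default_architecture().plus1_entry),
        "n": len(cohort.genes),
    }


def recover_chd1_genome_average_peak(seed: int, n_genes: int | None = None,
                                     n_fragments: int | None = None) -> dict:
    """Genome-average short-fragment peak position of K510R-Chd1."""
    cohort = sample_gene_cohort(_config(seed, n_genes, n_fragments))
    track = _rpm_track(cohort, "chd1_k510r", "k510r", placement="genome_average",
                       size_class=SHORT, mode="midpoint")
    peak = estimate_peak_offset(_tss_profile(cohort, track), (-200, 500))
    return {"peak": peak, "n": len(cohort.genes)}


def _processive_set(cohort: Cohort, k: int) -> tuple[list[str], object]:
    """Wild-type stalling analysis -> processive gene ids of the top
    PolII-promoter-occupancy quintile."""
    total_wt = _rpm_track(cohort, "total_polii", "wt")
    ser2_wt = _rpm_track(cohort, "ser2_polii", "wt")
    records = compute_stalling_records(cohort.genes, total_wt, ser2_wt)
    ranking = rank_genes(
        {g.id: window_mean(total_wt, g, PROMOTER_WINDOW) for g in cohort.genes},
        "polii_promoter",
    )
    _, processive = classify_stalled_processive(records, ranking, k=k)
    return processive, records


def recover_processive_offset(seed: int, factor: str, n_genes: int | None = None,
                              n_fragments: int | None = None, k: int = 150) -> dict:
    """Offset (bp) of a factor's short-fragment peak past the +1
    nucleosome entry site at processive genes under the K510R condition.

    ``factor`` is ``"total_polii"`` (PolII stalls ~20 bp inside the
    entry) or ``"chd1_k510r"`` (Chd1 acts ~50 bp inside).  The entry
    site is recovered from the matched wild-type nucleosome library of
    the same cohort, whose dyads are identical across conditions.
    """
    cohort = sample_gene_cohort(_config(seed, n_genes, n_fragments))
    processive, _ = _processive_set(cohort, k)
    placement = "per_nucleosome" if factor == "chd1_k510r" else "default"
    track = _rpm_track(cohort, factor, "k510r", placement=placement,
                       size_class=SHORT, mode="midpoint")
    peak = estimate_peak_offset(
        _tss_profile(cohort, track, subset=processive), PLUS1_SEARCH_WINDOW
    )
    nuc = _rpm_track(cohort, "nucleosome", "wt", size_class=MONO, mode="span")
    entry = estimate_plus1_entry(_tss_profile(cohort, nuc))
    return {
        "peak": peak,
        "entry": entry,
        "offset": peak - entry,
        "n_processive": len(processive),
        "n": len(cohort.genes),
    }


def stalling_contrast(seed: int, n_genes: int | None = None,
                      n_fragments: int | None = None) -> dict:
    """Median per-gene stalling-index ratio K510R / wild type."""
    cohort = sample_gene_cohort(_config(seed, n_genes, n_fragments))
    total_wt = _rpm_track(cohort, "total_polii", "wt")
    ser2_wt = _rpm_track(cohort, "ser2_polii", "wt")
    records_wt = compute_stalling_records(cohort.genes, total_wt, ser2_wt)
    total_k = _rpm_track(cohort, "total_polii", "k510r")
    ser2_k = _rpm_track(cohort, "ser2_polii", "k510r")
    records_k = compute_stalling_records(cohort.genes, total_k, ser2_k)
    out = median_stalling_ratio(records_wt, records_k)
    out["n"] = len(cohort.genes)
    return out


def turnover_elongation_correlation(seed: int, window: int = 500,
                                    n_genes: int | None = None,
                                    n_fragments: int | None = None) -> dict:
    """Pearson r of the sliding-window trend between elongating-PolII
    density (Ser2phos, last 3 kb of the gene body) and CATCH-IT signal
    in the -3 to -0.5 kb TES window, wild-type condition."""
    cohort = sample_gene_cohort(_config(seed, n_genes, n_fragments))
    ser2 = _rpm_track(cohort, "ser2_polii", "wt")
    catchit = simulate_catchit(cohort, "wt", cohort.config)
    region = catchit_region_mean(catchit, cohort.genes, BODY_TES)
    fit = {ra.gene_id for ra in region}
    scores = {
        g.id: window_mean(ser2, g, WindowSpec("TES", -3000, 0))
        for g in cohort.genes
        if g.id in fit
    }
    ranking = rank_genes(scores, "ser2_tes_density")
    trend = turnover_vs_density(ranking, region, window)
    return {
        "r": pearson_r(trend[:, 0], trend[:, 1]),
        "n_windows": len(trend),
        "n": len(cohort.genes),
    }
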