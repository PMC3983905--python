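"""CATCH-IT nucleosome-turnover analysis.

Turnover signal is carried in the same dense per-base representation as
coverage (a SignalTrack), but unlike coverage it may be negative
(log-ratio-like incorporation signal).  The named analysis windows of
the turnover figures are provided as module constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fragment_ops import SignalTrack
from .genomic_io import GeneModel
from .metaprofile import GeneRanking, Profile, WindowSpec, rank_genes, sliding_window_xy, window_mean

logger = logging.getLogger(__name__)

__all__ = [
    "TurnoverTrack",
    "RegionAverage",
    "PROMOTER_PROXIMAL",
    "PROMOTER",
    "PLUS1_REGION",
    "BODY_TSS",
    "BODY_TES",
    "catchit_region_mean",
    "difference_profile",
    "turnover_vs_density",
    "gene_length_stratified",
]

# CATCH-IT signal shares the SignalTrack representation; the alias keeps
# call sites explicit about what kind of signal they carry.
TurnoverTrack = SignalTrack

#: -1 nucleosome through +2 nucleosome around the TSS.
PROMOTER_PROXIMAL = WindowSpec("TSS", -350, 350)
PROMOTER = WindowSpec("TSS", -150, 150)
PLUS1_REGION = WindowSpec("TSS", 0, 150)
#: Gene body measured from the TSS side.
BODY_TSS = WindowSpec("TSS", 1000, 3000)
#: Gene body measured upstream of the TES (transcription-oriented).
BODY_TES = WindowSpec("TES", -3000, -500)


@dataclass
class RegionAverage:
    gene_id: str
    window: WindowSpec
    value: float


def _window_reach(window: WindowSpec) -> int:
    """Minimum gene length for the window to stay inside the gene."""
    s, e = window.start_offset, window.end_offset if window.end_offset is not None else 0
    if window.anchor == "TSS":
        return max(e, 0)
    return max(-s, 0)


def catchit_region_mean(
    track: TurnoverTrack,
    genes: Sequence[GeneModel],
    window: WindowSpec,
    require_fit: bool = True,
) -> list[RegionAverage]:
    """Per-gene mean turnover in a named window.

    Gene-body windows require the gene to be long enough to contain
    them; shorter genes are excluded with a warning (disable with
    ``require_fit=False`` for promoter windows that deliberately span
    the TSS).
    """
    reach = _window_reach(window)
    out, n_short = [], 0
    for gene in genes:
        if require_fit and gene.length < reach:
            n_short += 1
            continue
        out.append(RegionAverage(gene.id, window, window_mean(track, gene, window)))
    if n_short:
        logger.warning("%d genes shorter than %d bp excluded from region average", n_short, reach)
    return out


def difference_profile(profile_a: Profile, profile_b: Profile) -> Profile:
    """Pointwise a - b on identical offset grids."""
    if len(profile_a.offsets) != len(profile_b.offsets) or np.any(
        profile_a.offsets != profile_b.offsets
    ):
        raise ValueError("profiles are on different offset grids")
    return Profile(
        profile_a.offsets.copy(),
        profile_a.values - profile_b.values,
        min(profile_a.n_genes, profile_b.n_genes),
    )


def turnover_vs_density(
    ranking: GeneRanking, region_averages: Sequence[RegionAverage], window: int
) -> np.ndarray:
    """Sliding-window trend of (mean PolII density, mean turnover).

    Genes are taken in ranking order; every ranked gene must have a
    region average.
    """
    y = {ra.gene_id: ra.value for ra in region_averages}
    missing = [g for g in ranking.gene_ids if g not in y]
    if missing:
        raise KeyError(f"no turnover value for ranked genes: {missing[:3]}...")
    return sliding_window_xy(ranking, y, window)


def gene_length_stratified(
    region_averages: Sequence[RegionAverage],
    genes: Sequence[GeneModel],
    window: int,
) -> np.ndarray:
    """Trend of (mean gene length, mean turnover) with genes ranked by length."""
    lengths = {g.id: float(g.length) for g in genes}
    avail = [ra for ra in region_averages if ra.gene_id in lengths]
    if not avail:
        raise ValueError("no region averages overlap the gene cohort")
    ranking = rank_genes({ra.gene_id: lengths[ra.gene_id] for ra in avail}, "gene_length")
    return sliding_window_xy(ranking, {ra.gene_id: ra.value for ra in avail}, window)
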