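"""Per-gene PolII promoter-escape statistics.

The stalling index of a gene is the ratio of total-PolII density at the
promoter (-100..+300 bp around the TSS) to elongating (Ser2phos) PolII
density in the gene body (+1 kb to +5 kb or the gene end).  The related
traveling ratio uses total PolII in both windows (promoter -30..+300,
body +300 bp to gene end).  Both ratios are stabilized with a small
pseudocount (default 1% of each track's genome-wide mean) so genes with
an empty denominator window stay finite; such genes are flagged as
denominator-limited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragment_ops import SignalTrack
from .genomic_io import GeneModel
from .metaprofile import GeneRanking, WindowSpec, quintile_split, window_mean

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "StallingRecord",
    "ElongationProfile",
    "PROMOTER_WINDOW",
    "TR_PROMOTER_WINDOW",
    "stalling_index",
    "compute_stalling_records",
    "traveling_ratio",
    "elongation_fold_enrichment",
    "classify_stalled_processive",
    "median_stalling_ratio",
    "write_stalling_table",
]

#: Total-PolII promoter window for the stalling index.
PROMOTER_WINDOW = WindowSpec("TSS", -100, 300)
#: Total-PolII promoter window for the traveling ratio.
TR_PROMOTER_WINDOW = WindowSpec("TSS", -30, 300)

#: Gene-body window bounds for the stalling index (bp from TSS).
BODY_START = 1000
BODY_END = 5000


@dataclass
class StallingRecord:
    gene_id: str
    d_prom: float
    d_body: float
    stalling_index: float
    traveling_ratio: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ElongationProfile:
    """Cohort fold-enrichment of Ser2phos density in consecutive 1 kb windows.

    Per gene, window *w* is compared with the gene's mean density over
    its first 5 kb; the cohort mean and standard deviation are reported
    per window index.
    """

    window_size: int
    per_gene: dict[str, np.ndarray]
    mean: np.ndarray
    sd: np.ndarray


def _pseudocount(track: SignalTrack, eps: float | None) -> float:
    return 0.01 * track.mean() if eps is None else eps


def stalling_index(
    gene: GeneModel,
    total_polii: SignalTrack,
    ser2: SignalTrack,
    eps_prom: float | None = None,
    eps_body: float | None = None,
) -> StallingRecord:
    """Stalling index of one gene; genes <= 1 kb are rejected.

    ``eps_prom``/``eps_body`` default to 1% of the genome-wide mean of
    the respective track.
    """
    if gene.length <= 1000:
        raise ValueError(f"gene {gene.id}: length {gene.length} <= 1 kb, body window empty")
    ep = _pseudocount(total_polii, eps_prom)
    eb = _pseudocount(ser2, eps_body)
    d_prom = window_mean(total_polii, gene, PROMOTER_WINDOW)
    body = WindowSpec("TSS", BODY_START, min(BODY_END, gene.length))
    d_body = window_mean(ser2, gene, body)
    flags = ["denominator_limited"] if d_body < eb else []
    return StallingRecord(
        gene_id=gene.id,
        d_prom=d_prom,
        d_body=d_body,
        stalling_index=(d_prom + ep) / (d_body + eb),
        flags=flags,
    )


def traveling_ratio(
    gene: GeneModel, total_polii: SignalTrack, eps: float | None = None
) -> float:
    """Promoter (-30..+300) over gene-body (+300..end) total-PolII density."""
    if gene.length <= 300:
        raise ValueError(f"gene {gene.id}: length {gene.length} <= 300 bp, body window empty")
    e = _pseudocount(total_polii, eps)
    prom = window_mean(total_polii, gene, TR_PROMOTER_WINDOW)
    body = window_mean(total_polii, gene, WindowSpec("TSS", 300, None))
    return (prom + e) / (body + e)


def compute_stalling_records(
    genes: Sequence[GeneModel],
    total_polii: SignalTrack,
    ser2: SignalTrack,
    eps_prom: float | None = None,
    eps_body: float | None = None,
    with_traveling_ratio: bool = True,
) -> list[StallingRecord]:
    """Stalling records for a cohort, skipping genes <= 1 kb with a warning."""
    ep = _pseudocount(total_polii, eps_prom)
    eb = _pseudocount(ser2, eps_body)
    records = []
    n_skipped = 0
    for gene in genes:
        if gene.length <= 1000:
            n_skipped += 1
            continue
        rec = stalling_index(gene, total_polii, ser2, ep, eb)
        if with_traveling_ratio:
            rec.traveling_ratio = traveling_ratio(gene, total_polii, ep)
        records.append(rec)
    if n_skipped:
        logger.warning("%d genes <= 1 kb excluded from stalling analysis", n_skipped)
    return records


def elongation_fold_enrichment(
    genes: Sequence[GeneModel],
    ser2: SignalTrack,
    n_windows: int = 10,
    window_size: int = 1000,
    reference_span: int = 5000,
    eps: float | None = None,
) -> ElongationProfile:
    """Ser2phos fold enrichment per 1 kb genic window, relative to the
    mean density over each gene's first 5 kb.

    Genes shorter than ``reference_span`` are excluded; a gene
    contributes window *w* only while the window fits inside the gene.
    A uniform track gives fold enrichment 1 in every window (sd 0).
    """
    e = _pseudocount(ser2, eps)
    per_gene: dict[str, np.ndarray] = {}
    for gene in genes:
        if gene.length < reference_span:
            continue
        ref = window_mean(ser2, gene, WindowSpec("TSS", 0, reference_span))
        k = min(n_windows, gene.length // window_size)
        fe = np.full(n_windows, np.nan)
        for w in range(k):
            m = window_mean(ser2, gene, WindowSpec("TSS", w * window_size, (w + 1) * window_size))
            fe[w] = (m + e) / (ref + e)
        per_gene[gene.id] = fe
    if not per_gene:
        raise ValueError(f"no genes >= {reference_span} bp; cannot compute fold enrichment")
    grid = np.array(list(per_gene.values()))
    counts = np.sum(~np.isnan(grid), axis=0)
    mean = np.full(n_windows, np.nan)
    sd = np.full(n_windows, np.nan)
    for w in np.flatnonzero(counts):
        col = grid[:, w][~np.isnan(grid[:, w])]
        mean[w] = col.mean()
        sd[w] = col.std()
    return ElongationProfile(window_size, per_gene, mean, sd)


def classify_stalled_processive(
    records: Sequence[StallingRecord],
    polii_ranking: GeneRanking,
    k: int = 500,
) -> tuple[list[str], list[str]]:
    """Top-k stalled and top-k processive genes of the highest PolII quintile.

    Within the top quintile of promoter PolII occupancy, the *stalled*
    set is the k genes with the highest stalling index and the
    *processive* set the k with the lowest; ties break by gene id so the
    two sets are always disjoint.
    """
    top = set(quintile_split(polii_ranking).highest)
    pool = [r for r in records if r.gene_id in top]
    if k > len(pool) // 2:
        raise ValueError(f"k={k} exceeds half the top-quintile size ({len(pool)})")
    by_index = sorted(pool, key=lambda r: (-r.stalling_index, r.gene_id))
    stalled = sorted(r.gene_id for r in by_index[:k])
    processive = sorted(r.gene_id for r in by_index[-k:])
    return stalled, processive


def median_stalling_ratio(
    records_a: Sequence[StallingRecord], records_b: Sequence[StallingRecord]
) -> dict[str, float]:
    """Median per-gene stalling-index ratio b/a over shared genes.

    Convention: *a* is the reference (wild type), *b* the perturbed
    condition.  Also reports the ratio of the two medians.
    """
    a = {r.gene_id: r.stalling_index for r in records_a}
    b = {r.gene_id: r.stalling_index for r in records_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared genes between the two record sets")
    ratios = np.array([b[g] / a[g] for g in shared])
    return {
        "median_ratio": float(np.median(ratios)),
        "ratio_of_medians": float(
            np.median([b[g] for g in shared]) / np.median([a[g] for g in shared])
        ),
        "n_genes": len(shared),
    }


def write_stalling_table(records: Sequence[StallingRecord], path, header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in header:
            fh.write(f"# {h}\n")
        fh.write("gene\td_prom\td_body\tstalling_index\ttraveling_ratio\tflags\n")
        for r in records:
            tr = f"{r.traveling_ratio:.6g}" if r.traveling_ratio is not None else "NA"
            fh.write(
                f"{r.gene_id}\t{r.d_prom:.6g}\t{r.d_body:.6g}\t"
                f"{r.stalling_index:.6g}\t{tr}\t{','.join(r.flags) or '.'}\n"
            )
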