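"""Gene-anchored metaprofiles: matrices, averages, rankings, trend curves.

Every operation here is transcription-oriented: for a minus-strand gene
increasing offsets point 5'->3' along the gene, so profiles from both
strands superimpose directly.  Positions absent from a track (or beyond
a chromosome end) contribute 0, because coverage tracks are dense by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fragment_ops import SignalTrack
from .genomic_io import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "AnchoredMatrix",
    "Profile",
    "GeneRanking",
    "QuintileGroups",
    "build_anchored_matrix",
    "mean_profile",
    "percent_dynamic_range",
    "window_mean",
    "rank_genes",
    "quintile_split",
    "sliding_window_xy",
]


@dataclass(frozen=True)
class WindowSpec:
    """A transcription-oriented analysis window.

    ``anchor`` is ``"TSS"`` or ``"TES"``; offsets are bp along the
    direction of transcription, half-open ``[start_offset, end_offset)``.
    ``end_offset=None`` means "to the end of the gene" (resolved per
    gene, only meaningful with a TSS anchor).
    """

    anchor: str
    start_offset: int
    end_offset: int | None

    def __post_init__(self) -> None:
        if self.anchor not in ("TSS", "TES"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.end_offset is not None and not self.start_offset < self.end_offset:
            raise ValueError("window requires start_offset < end_offset")

    def resolve(self, gene: GeneModel) -> tuple[int, int]:
        end = self.end_offset if self.end_offset is not None else gene.length
        return self.start_offset, end


@dataclass
class AnchoredMatrix:
    """Genes x offsets grid of signal around a common anchor.

    ``offsets`` holds the left edge of each bin; row order matches
    ``gene_ids``.  Minus-strand rows are coordinate-reversed so offset
    always increases in the direction of transcription.
    """

    gene_ids: list[str]
    anchor: str
    offsets: np.ndarray
    bin_size: int
    values: np.ndarray  # shape (n_genes, n_bins)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_tsv(self, path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for h in header:
                fh.write(f"# {h}\n")
            fh.write("gene\t" + "\t".join(str(o) for o in self.offsets) + "\n")
            for gid, row in zip(self.gene_ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class Profile:
    """Mean signal per offset, with the number of contributing genes."""

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("profile offsets must be strictly increasing")

    def to_tsv(self, path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for h in header:
                fh.write(f"# {h}\n")
            fh.write("offset\tvalue\n")
            for o, v in zip(self.offsets, self.values):
                fh.write(f"{o}\t{v:.6g}\n")


@dataclass
class GeneRanking:
    """Gene ids ordered by descending score (ties broken by id)."""

    gene_ids: list[str]
    scores: np.ndarray
    score_name: str = "score"

    def score_of(self, gene_id: str) -> float:
        return float(self.scores[self.gene_ids.index(gene_id)])


@dataclass
class QuintileGroups:
    """Five ordered, disjoint gene-id blocks covering the ranking."""

    groups: list[list[str]]

    @property
    def highest(self) -> list[str]:
        return self.groups[0]

    @property
    def lowest(self) -> list[str]:
        return self.groups[-1]


def _gene_window_values(
    track: SignalTrack, gene: GeneModel, anchor: str, start_offset: int, end_offset: int
) -> np.ndarray:
    """Per-base track values over oriented offsets [start, end); out-of-bounds -> 0."""
    a = gene.tss if anchor == "TSS" else gene.tes
    n = end_offset - start_offset
    arr = track.data.get(gene.chrom)
    out = np.zeros(n, dtype=float)
    if arr is None:
        return out
    if gene.strand == "+":
        lo = a + start_offset
        src_lo, src_hi = max(lo, 0), min(lo + n, len(arr))
        if src_hi > src_lo:
            out[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
    else:
        # oriented offset o maps to genomic a - o
        hi = a - start_offset  # genomic position of the first oriented offset
        lo = a - end_offset + 1
        src_lo, src_hi = max(lo, 0), min(hi + 1, len(arr))
        if src_hi > src_lo:
            seg = arr[src_lo:src_hi][::-1]
            # first oriented slot corresponds to genomic hi
            off0 = hi - (src_hi - 1)
            out[off0 : off0 + len(seg)] = seg
    return out


def build_anchored_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    anchor: str = "TSS",
    flank_up: int = 500,
    flank_down: int = 2000,
    bin_size: int = 1,
) -> AnchoredMatrix:
    """Build the genes x offsets signal grid around TSS or TES.

    Row *g*, bin at oriented offset *o* holds the mean track value over
    ``[o, o + bin_size)`` bp from the anchor of *g*.  Flanks must be
    positive multiples of ``bin_size``.
    """
    if flank_up <= 0 or flank_down <= 0:
        raise ValueError("flanks must be positive")
    if flank_up % bin_size or flank_down % bin_size:
        raise ValueError("flanks must be multiples of bin_size")
    n_bins = (flank_up + flank_down) // bin_size
    offsets = np.arange(-flank_up, flank_down, bin_size)
    values = np.empty((len(genes), n_bins), dtype=float)
    for i, gene in enumerate(genes):
        if gene.chrom not in track.data:
            logger.warning("gene %s: chromosome %s absent from track, row set to 0", gene.id, gene.chrom)
            values[i] = 0.0
            continue
        base = _gene_window_values(track, gene, anchor, -flank_up, flank_down)
        values[i] = base.reshape(n_bins, bin_size).mean(axis=1)
    return AnchoredMatrix([g.id for g in genes], anchor, offsets, bin_size, values)


def mean_profile(matrix: AnchoredMatrix, subset: Sequence[str] | None = None) -> Profile:
    """Column-wise mean over all rows or a gene-id subset."""
    if subset is None:
        vals = matrix.values
        n = len(matrix.gene_ids)
    else:
        index = {g: i for i, g in enumerate(matrix.gene_ids)}
        missing = [g for g in subset if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:3]}...")
        rows = [index[g] for g in subset]
        if not rows:
            raise ValueError("empty gene subset")
        vals = matrix.values[rows]
        n = len(rows)
    if n == 0:
        raise ValueError("cannot average an empty matrix")
    return Profile(matrix.offsets.copy(), vals.mean(axis=0), n)


def percent_dynamic_range(profile: Profile) -> Profile:
    """Rescale a profile to percent of its dynamic range: min -> 0, max -> 100."""
    v = profile.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        logger.warning("constant profile: dynamic range is zero, returning all-zero profile")
        return Profile(profile.offsets.copy(), np.zeros_like(v), profile.n_genes)
    return Profile(profile.offsets.copy(), 100.0 * (v - lo) / (hi - lo), profile.n_genes)


def window_mean(track: SignalTrack, gene: GeneModel, window: WindowSpec) -> float:
    """Mean signal over a transcription-oriented window.

    Missing positions (beyond chromosome bounds) count as 0 and the
    divisor is the full window width, so truncation at a chromosome end
    only dilutes the mean.
    """
    s, e = window.resolve(gene)
    if not s < e:
        raise ValueError(f"gene {gene.id}: degenerate window [{s}, {e})")
    vals = _gene_window_values(track, gene, window.anchor, s, e)
    return float(vals.sum() / (e - s))


def rank_genes(scores: Mapping[str, float], score_name: str = "score") -> GeneRanking:
    """Rank genes by descending score; ties broken lexicographically by id."""
    for g, s in scores.items():
        if not np.isfinite(s):
            raise ValueError(f"gene {g}: non-finite score {s}")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    return GeneRanking(order, np.array([scores[g] for g in order], dtype=float), score_name)


def quintile_split(ranking: GeneRanking) -> QuintileGroups:
    """Split a ranking into five contiguous blocks, larger blocks first."""
    n = len(ranking.gene_ids)
    if n < 5:
        raise ValueError(f"need at least 5 genes to split into quintiles, got {n}")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    groups, at = [], 0
    for sz in sizes:
        groups.append(list(ranking.gene_ids[at : at + sz]))
        at += sz
    return QuintileGroups(groups)


def sliding_window_xy(
    ranking: GeneRanking, y: Mapping[str, float], window: int
) -> np.ndarray:
    """Sliding-window trend of (mean score, mean y) along a ranking.

    Windows of ``window`` consecutive ranked genes advance one gene per
    step; returns an array of shape (n - window + 1, 2).  ``window=1``
    degenerates to the identity on (score, y) pairs in rank order.
    """
    n = len(ranking.gene_ids)
    if window < 1:
        raise ValueError("window must be >= 1 gene")
    if window > n:
        raise ValueError(f"window {window} exceeds number of genes {n}")
    yv = np.array([y[g] for g in ranking.gene_ids], dtype=float)
    kernel = np.ones(window) / window
    mx = np.convolve(ranking.scores, kernel, mode="valid")
    my = np.convolve(yv, kernel, mode="valid")
    return np.column_stack([mx, my])
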