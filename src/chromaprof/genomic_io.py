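"""Readers and writers for the interval formats the pipeline touches.

All interval I/O follows the BED convention: 0-based, half-open
``[start, end)``.  Gene anchors are stored internally as the 0-based
position of the 5'-most transcribed base, so a minus-strand gene read
from ``chrom start end name score -`` has ``tss = end - 1`` and
``tes = start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "FragmentSet",
    "ParseError",
    "read_genes",
    "read_fragments",
    "read_bedgraph",
    "write_bedgraph",
    "write_gene_table",
]


class ParseError(ValueError):
    """Raised on a malformed record; the message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a pair of transcription-oriented anchors.

    ``tss`` and ``tes`` are 0-based genomic positions of the first and
    last transcribed base.  Plus-strand genes have ``tss < tes``;
    minus-strand genes have ``tss > tes``.
    """

    id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.id}: plus-strand gene requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.id}: minus-strand gene requires tss > tes")

    @property
    def length(self) -> int:
        """Gene length in bp: |tes - tss| + 1 since both anchors are
        transcribed bases (closed-end), i.e. end - start of the BED record."""
        return abs(self.tes - self.tss) + 1

    def oriented_position(self, anchor: str, offset: int) -> int:
        """Genomic position at a transcription-oriented ``offset`` from ``anchor``.

        Positive offsets always point in the direction of transcription.
        ``anchor`` is ``"TSS"`` or ``"TES"``.
        """
        a = self.tss if anchor == "TSS" else self.tes
        return a + offset if self.strand == "+" else a - offset


@dataclass
class FragmentSet:
    """Paired-end fragment intervals: parallel arrays of chrom/start/end.

    ``library_size`` is the number of fragments and is the denominator
    for counts-per-million normalization regardless of which subset of
    chromosomes overlaps the gene cohort.
    """

    chroms: np.ndarray  # dtype object (str)
    starts: np.ndarray  # int64, 0-based inclusive
    ends: np.ndarray    # int64, exclusive

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(self.starts >= self.ends):
            bad = int(np.argmax(self.starts >= self.ends))
            raise ValueError(f"fragment {bad}: start >= end")

    @property
    def library_size(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "FragmentSet":
        recs = list(records)
        if not recs:
            return cls(np.empty(0, object), np.empty(0, np.int64), np.empty(0, np.int64))
        c, s, e = zip(*recs)
        return cls(np.array(c, object), np.array(s, np.int64), np.array(e, np.int64))


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield i, _fields(line)


def read_genes(path: str | Path, format: str = "bed6") -> list[GeneModel]:
    """Read a gene table in BED6 or BED12 (first six columns used).

    Records with an unknown strand are rejected with a logged warning;
    malformed coordinates raise :class:`ParseError` naming the line.
    """
    if format not in ("bed6", "bed12"):
        raise ValueError(f"unknown gene format {format!r}")
    path = Path(path)
    genes: list[GeneModel] = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise ParseError(f"{path}:{lineno}: expected >=6 columns, got {len(f)}")
        try:
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        strand = f[5]
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        if strand not in ("+", "-"):
            logger.warning("%s:%d: unknown strand %r, record %s skipped", path, lineno, strand, name)
            continue
        if strand == "+":
            genes.append(GeneModel(name, chrom, "+", tss=start, tes=end - 1))
        else:
            genes.append(GeneModel(name, chrom, "-", tss=end - 1, tes=start))
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate gene ids in cohort")
    return genes


def read_fragments(path: str | Path, format: str = "bed3") -> FragmentSet:
    """Read fragments from BED3 or BEDPE.

    BEDPE mate pairs are collapsed to their outer span (min start, max
    end); inter-chromosomal pairs are skipped with a warning.
    """
    if format not in ("bed3", "bedpe"):
        raise ValueError(f"unknown fragment format {format!r}")
    path = Path(path)
    records: list[tuple[str, int, int]] = []
    for lineno, f in _data_lines(path):
        try:
            if format == "bed3":
                chrom, start, end = f[0], int(f[1]), int(f[2])
            else:
                if len(f) < 6:
                    raise ParseError(f"{path}:{lineno}: BEDPE needs >=6 columns")
                c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                if c1 != c2:
                    logger.warning("%s:%d: inter-chromosomal pair skipped", path, lineno)
                    continue
                chrom, start, end = c1, min(s1, s2), max(e1, e2)
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        records.append((chrom, start, end))
    return FragmentSet.from_records(records)


def write_fragments_bed3(frags: FragmentSet, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a FragmentSet as BED3 with optional ``#``-prefixed header lines."""
    with open(path, "w") as fh:
        for h in header:
            fh.write(f"# {h}\n")
        for c, s, e in zip(frags.chroms, frags.starts, frags.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


def write_bedgraph(track, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a SignalTrack as run-length-merged bedGraph.

    Zero-valued runs are written too, so the round trip through
    :func:`read_bedgraph` reproduces the track exactly on every covered
    position.  Requires finite values.
    """
    with open(path, "w") as fh:
        for h in header:
            fh.write(f"# {h}\n")
        for chrom in sorted(track.data):
            values = np.asarray(track.data[chrom], dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: track contains non-finite values")
            if len(values) == 0:
                continue
            # run-length boundaries where the value changes
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.10g}\n")


def read_bedgraph(path: str | Path, normalization: str = "raw"):
    """Read a bedGraph into a dense SignalTrack (positions absent -> 0)."""
    from .fragment_ops import SignalTrack

    spans: dict[str, list[tuple[int, int, float]]] = {}
    path = Path(path)
    for lineno, f in _data_lines(path):
        try:
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        spans.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, runs in spans.items():
        size = max(e for _, e, _ in runs)
        arr = np.zeros(size, dtype=float)
        for s, e, v in runs:
            arr[s:e] = v
        data[chrom] = arr
    return SignalTrack(data=data, normalization=normalization, provenance={"source": str(path)})


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes back out as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tes + 1
            else:
                start, end = g.tes, g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.id}\t0\t{g.strand}\n")
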