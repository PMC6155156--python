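"""Genomic interval data model, interval algebra, and flat-file I/O.

All coordinates are 0-based half-open everywhere in memory; the on-disk
formats handled here (BED, bedGraph, the gene table) use the same
convention, so no conversion happens at the I/O edges.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from math import nan
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "CoverageTrack",
    "BedParseError",
    "EmptyQueryError",
    "StructuralError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_totals",
    "write_totals",
    "read_genes",
    "write_genes",
    "read_fasta",
    "read_chrom_sizes",
    "overlap_count",
    "merge_intervals",
    "enrichment_screen",
    "benjamini_hochberg",
]

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed line in a BED/bedGraph/gene-table file."""


class EmptyQueryError(ValueError):
    """An operation received an empty query set where one is required."""


class StructuralError(ValueError):
    """Two inputs that must share structure (e.g. bin grids) do not."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` with optional annotations."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp shared, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak(GenomicInterval):
    """Interval with enrichment statistics attached."""

    fold_change: float = nan
    fdr: float = nan


@dataclass
class PeakSet:
    """Labeled peak collection for one sample, kept sorted by (chrom, start)."""

    sample_label: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS/TES and ordered disjoint exon blocks.

    ``tss``/``tes`` are point coordinates: the 5' and 3' ends of the
    transcription unit respecting strand. For a minus-strand gene
    ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        lo, hi = self.body
        prev_end = lo
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s}, {e}) in {self.gene_id}")
            if s < prev_end and prev_end != lo:
                raise ValueError(f"exons overlap or unordered in {self.gene_id}")
            if s < lo or e > hi:
                raise ValueError(f"exon [{s}, {e}) outside gene body in {self.gene_id}")
            prev_end = e

    @property
    def body(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter_window(self, flank: int = 1000) -> tuple[int, int]:
        """Symmetric window around the TSS, clipped at zero."""
        return (max(0, self.tss - flank), self.tss + flank)

    @classmethod
    def from_tx(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        tx_start: int,
        tx_end: int,
        exons: Sequence[tuple[int, int]] = (),
    ) -> "GeneModel":
        if tx_start >= tx_end:
            raise ValueError(f"tx_start >= tx_end for {gene_id}")
        if strand == "+":
            tss, tes = tx_start, tx_end
        else:
            tss, tes = tx_end, tx_start
        return cls(gene_id, chrom, strand, tss, tes, tuple(map(tuple, exons)))


@dataclass
class CoverageTrack:
    """Per-chromosome binned counts at a uniform bin width.

    Counts may be fragment-weighted floats; they need not sum to
    ``total_mapped_reads``, which is the declared depth used for RPM
    normalization.
    """

    bin_width: int
    counts: dict[str, np.ndarray]
    total_mapped_reads: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        self.counts = {c: np.asarray(v, dtype=float) for c, v in self.counts.items()}
        for c, v in self.counts.items():
            if v.ndim != 1:
                raise ValueError(f"counts for {c} must be 1-D")
            if np.any(v < 0):
                raise ValueError(f"negative counts on {c}")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.counts)

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chroms == other.chroms
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.total_mapped_reads

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def mean_rpm(self) -> float:
        """Genome-wide mean per-bin coverage in RPM."""
        n_bins = sum(len(v) for v in self.counts.values())
        if n_bins == 0:
            raise ValueError("empty track")
        return self.total_signal() * self.rpm_factor / n_bins

    def mean_rpm_over(self, intervals: Iterable[GenomicInterval]) -> float:
        """Mean per-bin RPM over every bin overlapped by the intervals."""
        total = 0.0
        n = 0
        for iv in intervals:
            if iv.chrom not in self.counts:
                continue
            arr = self.counts[iv.chrom]
            lo = iv.start // self.bin_width
            hi = -(-iv.end // self.bin_width)
            lo, hi = max(0, lo), min(len(arr), hi)
            if hi > lo:
                total += float(arr[lo:hi].sum())
                n += hi - lo
        if n == 0:
            return nan
        return total * self.rpm_factor / n


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns ignored) as 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad score {cols[4]!r}") from exc
            strand = cols[5] if len(cols) > 5 else "."
            try:
                out.append(GenomicInterval(cols[0], start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph + mapped-read sidecar
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write every bin (zeros included) so read/write round-trips exactly."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.counts[chrom]
            w = track.bin_width
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, total_mapped_reads: float, bin_width: int | None = None
) -> CoverageTrack:
    """Read a bedGraph whose intervals all sit on one uniform bin grid."""
    raw: dict[str, dict[int, float]] = {}
    inferred = bin_width
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{lineno}: bad span [{start}, {end})")
            if inferred is None:
                inferred = end - start
            if end - start != inferred or start % inferred:
                raise BedParseError(
                    f"{path}:{lineno}: interval off the {inferred}-bp bin grid"
                )
            raw.setdefault(chrom, {})[start // inferred] = value
    if inferred is None:
        raise BedParseError(f"{path}: empty bedGraph")
    counts = {}
    for chrom, bins in raw.items():
        arr = np.zeros(max(bins) + 1)
        for i, v in bins.items():
            arr[i] = v
        counts[chrom] = arr
    return CoverageTrack(inferred, counts, total_mapped_reads)


def write_totals(totals: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttotal_mapped_reads\n")
        for sample in sorted(totals):
            fh.write(f"{sample}\t{totals[sample]:g}\n")


def read_totals(path: str | Path) -> dict[str, float]:
    totals: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise BedParseError(f"{path}:1: missing sidecar header")
        for line in fh:
            sample, value = line.rstrip("\n").split("\t")
            totals[sample] = float(value)
    return totals


# ---------------------------------------------------------------------------
# Gene table (refFlat-style TSV, 0-based half-open)
# ---------------------------------------------------------------------------

_GENE_HEADER = "gene_id\tchrom\tstrand\ttx_start\ttx_end\texon_starts\texon_ends"


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_GENE_HEADER + "\n")
        for g in genes:
            lo, hi = g.body
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{lo}\t{hi}\t{starts}\t{ends}\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _GENE_HEADER:
            raise BedParseError(f"{path}:1: unexpected gene-table header")
        for lineno, line in enumerate(fh, start=2):
            if _is_comment(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 7:
                raise BedParseError(f"{path}:{lineno}: expected 7 columns")
            try:
                starts = [int(x) for x in cols[5].split(",") if x]
                ends = [int(x) for x in cols[6].split(",") if x]
                genes.append(
                    GeneModel.from_tx(
                        cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]),
                        list(zip(starts, ends)),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader (uppercased sequences, first word of header)."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chrom, size."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise BedParseError(f"{path}:{lineno}: expected chrom and size")
            sizes[cols[0]] = int(cols[1])
    return sizes


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint spans (name/score dropped)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


class IntervalIndex:
    """Sorted disjoint-span index supporting O(log n) any-overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._spans: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._spans.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._spans:
            return False
        starts, ends = self._spans[chrom]
        i = bisect.bisect_right(starts, end - 1) - 1
        return i >= 0 and ends[i] > start

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return self.overlaps(iv.chrom, iv.start, iv.end)


def overlap_count(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[int, float]:
    """Count intervals of ``a`` overlapping (>=1 bp, strand-blind) any of ``b``.

    Returns ``(n_a_hit, n_a_hit / len(a))``. Each ``a`` interval is counted
    at most once regardless of how many ``b`` intervals it touches.
    """
    if len(a) == 0:
        raise EmptyQueryError("overlap_count: empty query set a")
    index = IntervalIndex(b)
    n_hit = sum(1 for iv in a if index.overlaps_interval(iv))
    return n_hit, n_hit / len(a)


# ---------------------------------------------------------------------------
# Enrichment screen (simple stand-in peak caller)
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def enrichment_screen(
    chip: CoverageTrack,
    input_: CoverageTrack,
    fdr_max: float = 0.01,
    fc_min: float = 5.0,
    pseudocount: float = 1.0,
    sample_label: str = "screen",
) -> PeakSet:
    """Per-bin fold-change + Poisson enrichment screen with BH correction.

    Per bin: the input count is scaled to the ChIP depth and floored at
    ``pseudocount``; FC is the ratio of the ChIP count to that floor; the
    p-value is the upper Poisson tail of the ChIP count at lambda equal to
    the floored scaled input. Bins passing both ``fdr < fdr_max`` and
    ``FC > fc_min`` are merged into peaks when adjacent (score and
    fold_change = mean bin FC; fdr = worst merged bin).

    This is a documented simple stand-in for a full peak caller: no
    fragment-model building and no local-lambda correction.
    """
    if not chip.same_grid(input_):
        raise StructuralError("chip and input tracks are not on the same bin grid")
    if not (0 < fdr_max <= 1):
        raise ValueError(f"fdr_max must be in (0, 1], got {fdr_max}")
    if sum(len(v) for v in chip.counts.values()) == 0:
        raise ValueError("zero-length tracks")

    scale = chip.total_mapped_reads / input_.total_mapped_reads
    chroms = chip.chroms
    fc_parts, p_parts = [], []
    for chrom in chroms:
        c = chip.counts[chrom]
        lam = np.maximum(input_.counts[chrom] * scale, pseudocount)
        fc_parts.append(c / lam)
        # P(X >= c) for X ~ Poisson(lam); sf(k-1) == P(X >= k)
        p_parts.append(stats.poisson.sf(np.ceil(c) - 1, lam))
    fc = np.concatenate(fc_parts)
    q = benjamini_hochberg(np.concatenate(p_parts))

    keep = (q < fdr_max) & (fc > fc_min)
    peaks: list[GenomicInterval] = []
    offset = 0
    w = chip.bin_width
    for chrom in chroms:
        n = len(chip.counts[chrom])
        k = keep[offset : offset + n]
        idx = np.flatnonzero(k)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [idx.size - 1]))
            for rs, re in zip(run_starts, run_ends):
                bins = idx[rs : re + 1]
                mean_fc = float(fc[offset + bins].mean())
                worst_q = float(q[offset + bins].max())
                peaks.append(
                    Peak(
                        chrom,
                        int(bins[0]) * w,
                        (int(bins[-1]) + 1) * w,
                        name=f"peak_{len(peaks) + 1}",
                        score=mean_fc,
                        fold_change=mean_fc,
                        fdr=worst_q,
                    )
                )
        offset += n
    return PeakSet(sample_label, peaks)
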