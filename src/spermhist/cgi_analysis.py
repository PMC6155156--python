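"""CpG-island observed/expected statistics and peak/CGI comparisons.

The o/e ratio follows the Gardiner-Garden & Frommer convention:
``oe = N_CpG * L / (N_C * N_G)`` with N bases excluded from all counts and
from L. The rank-sum test is exact (full null enumeration via a count DP)
for small untied samples and falls back to the tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals_io import GenomicInterval, IntervalIndex, PeakSet

__all__ = [
    "CpGIsland",
    "UndefinedOERatioError",
    "compute_oe",
    "wilcoxon_rank_sum",
    "boxplot_stats",
    "cgi_peak_oe_comparison",
    "chromosome_density",
    "read_cgis",
    "write_cgis",
]

_ALPHABET = set("ACGTN")

# untied samples up to this combined size use the exact null distribution
EXACT_LIMIT = 25


class UndefinedOERatioError(ValueError):
    """o/e ratio is undefined when the sequence has no C or no G."""


def compute_oe(sequence: str) -> float:
    """Observed/expected CpG ratio of a sequence (A/C/G/T/N alphabet)."""
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 bp")
    seq = sequence.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    length = len(seq) - seq.count("N")
    if n_c * n_g == 0:
        raise UndefinedOERatioError("sequence contains no C or no G")
    return n_cpg * length / (n_c * n_g)


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    n_cpg: int
    n_c: int
    n_g: int
    length: int
    oe_ratio: float

    def __post_init__(self) -> None:
        if self.n_cpg > min(self.n_c, self.n_g):
            raise ValueError("n_cpg cannot exceed min(n_c, n_g)")
        if self.oe_ratio < 0:
            raise ValueError("oe_ratio must be non-negative")

    @classmethod
    def from_sequence(cls, interval: GenomicInterval, sequence: str) -> "CpGIsland":
        if len(sequence) != len(interval):
            raise ValueError("sequence length does not match interval span")
        seq = sequence.upper()
        return cls(
            interval=interval,
            n_cpg=seq.count("CG"),
            n_c=seq.count("C"),
            n_g=seq.count("G"),
            length=len(interval),
            oe_ratio=compute_oe(sequence),
        )


def write_cgis(cgis: Iterable[CpGIsland], path) -> None:
    """BED6+3 export: extra columns are n_cpg, n_c + n_g, oe."""
    with open(path, "w") as fh:
        for c in cgis:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{c.oe_ratio:.6g}\t"
                f"{iv.strand}\t{c.n_cpg}\t{c.n_c + c.n_g}\t{c.oe_ratio:.6g}\n"
            )


def read_cgis(path) -> list[CpGIsland]:
    """Read the BED6+3 CGI format.

    Only the C+G sum is stored on disk; it is split as evenly as the
    ``n_cpg <= min(n_c, n_g)`` invariant allows.
    """
    out: list[CpGIsland] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns (BED6+3)")
            iv = GenomicInterval(
                cols[0], int(cols[1]), int(cols[2]), cols[5], cols[3], float(cols[4])
            )
            n_cpg, n_cg_sum, oe = int(cols[6]), int(cols[7]), float(cols[8])
            n_c = max(n_cpg, n_cg_sum // 2)
            n_g = max(n_cpg, n_cg_sum - n_c)
            out.append(CpGIsland(iv, n_cpg, n_c, n_g, len(iv), oe))
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_p(w: int, n: int, m: int) -> float:
    """Two-sided exact p-value for rank-sum ``w`` of the smaller-handled
    sample of size ``n`` out of ``N = n + m`` untied observations.

    Uses the classic count DP: f[k][s] = number of k-subsets of {1..N}
    with rank sum s. p = P(|W - mu| >= |w - mu|) under the uniform null.
    """
    total = n + m
    max_s = total * (total + 1) // 2
    f = np.zeros((n + 1, max_s + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):
            f[k, r:] += f[k - 1, : max_s + 1 - r]
    dist = f[n]
    mu = n * (total + 1) / 2
    dev = abs(w - mu)
    sums = np.arange(max_s + 1)
    mass = dist[np.abs(sums - mu) >= dev - 1e-9].sum()
    return float(min(1.0, mass / comb(total, n)))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(rank_sum_of_x, p)``.

    Exact for untied samples with ``len(x) + len(y) <= EXACT_LIMIT``,
    otherwise normal approximation with tie correction and continuity
    correction. Degenerate zero-variance data yields p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n].sum())
    has_ties = np.unique(combined).size < combined.size

    if not has_ties and n + m <= EXACT_LIMIT:
        return w, _exact_ranksum_p(int(round(w)), n, m)

    total = n + m
    mu = n * (total + 1) / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (total * (total - 1))
    var = n * m / 12 * ((total + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    dev = abs(w - mu)
    z = max(0.0, dev - 0.5) / np.sqrt(var)  # continuity correction
    return w, float(min(1.0, 2 * stats.norm.sf(z)))


def boxplot_stats(values: Sequence[float]) -> dict:
    """Median, quartiles, 1.5*IQR whiskers, and outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(o) for o in v[(v < lo_fence) | (v > hi_fence)]),
    }


# ---------------------------------------------------------------------------
# Peak/CGI comparisons
# ---------------------------------------------------------------------------

def _oe_of_overlapping(cgis: Sequence[CpGIsland], peaks: PeakSet) -> np.ndarray:
    index = IntervalIndex(peaks)
    return np.array(
        [c.oe_ratio for c in cgis if index.overlaps_interval(c.interval)], dtype=float
    )


def cgi_peak_oe_comparison(
    cgis: Sequence[CpGIsland],
    peaks_total: PeakSet,
    peaks_hrcs: PeakSet,
) -> dict:
    """Compare o/e distributions of all CGIs vs CGIs under peaks.

    Returns box-plot summaries and pairwise two-sided rank-sum p-values for
    three samples: all CGIs, CGIs overlapping total-sperm peaks, and CGIs
    overlapping histone-retaining-fraction peaks.
    """
    samples = {
        "all_cgis": np.array([c.oe_ratio for c in cgis], dtype=float),
        "total_peak_cgis": _oe_of_overlapping(cgis, peaks_total),
        "hrcs_peak_cgis": _oe_of_overlapping(cgis, peaks_hrcs),
    }
    for label, v in samples.items():
        if v.size == 0:
            raise ValueError(f"empty o/e sample: {label}")
    pvalues = {}
    labels = list(samples)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            _, p = wilcoxon_rank_sum(samples[a], samples[b])
            pvalues[f"{a}_vs_{b}"] = p
    return {
        "boxplots": {k: boxplot_stats(v) for k, v in samples.items()},
        "pvalues": pvalues,
        "counts": {k: int(v.size) for k, v in samples.items()},
    }


def chromosome_density(
    peaks: PeakSet,
    cgis: Iterable[CpGIsland],
    chrom_sizes: dict[str, int],
    oe_min: float = 1.0,
) -> pd.DataFrame:
    """Per-chromosome peak density and high-o/e CGI density (per Mb)."""
    missing = sorted({p.chrom for p in peaks if p.chrom not in chrom_sizes})
    if missing:
        raise KeyError(f"peaks on chromosomes without a declared size: {missing}")
    peak_counts: dict[str, int] = {c: 0 for c in chrom_sizes}
    cgi_counts: dict[str, int] = {c: 0 for c in chrom_sizes}
    for p in peaks:
        peak_counts[p.chrom] += 1
    for c in cgis:
        if c.oe_ratio > oe_min and c.interval.chrom in cgi_counts:
            cgi_counts[c.interval.chrom] += 1
    rows = []
    for chrom in sorted(chrom_sizes):
        mb = chrom_sizes[chrom] / 1e6
        rows.append(
            {
                "chrom": chrom,
                "n_peaks": peak_counts[chrom],
                "peaks_per_mb": peak_counts[chrom] / mb,
                "n_high_oe_cgis": cgi_counts[chrom],
                "high_oe_cgis_per_mb": cgi_counts[chrom] / mb,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
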