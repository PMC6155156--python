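"""Peak-to-gene mapping, sample overlap summaries, and the three-way
target-gene categorization (H / PH / TS).

A gene is a *target* of a sample iff at least one of the sample's peaks
overlaps the gene's promoter window. Category H = genes with a peak in the
purified fraction; PH/TS split the remaining total-sperm targets by the
level of purified-fraction signal under their total-sperm promoter peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    PeakSet,
    overlap_count,
)

__all__ = [
    "percent",
    "peaks_to_genes",
    "gene_overlap_report",
    "overlap_summary",
    "categorize",
    "TargetGeneCatalog",
    "write_catalog",
    "read_catalog",
]


def percent(numerator: int, denominator: int) -> int:
    """Round-half-up integer percentage, the reporting rule used throughout."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be within [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def peaks_to_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_flank: int = 1000,
) -> set[str]:
    """Gene ids whose promoter window is overlapped by >=1 peak."""
    index = IntervalIndex(peaks)
    hits = set()
    for g in genes:
        lo, hi = g.promoter_window(promoter_flank)
        if index.overlaps(g.chrom, lo, hi):
            hits.add(g.gene_id)
    return hits


def gene_overlap_report(genes_a: set[str], genes_b: set[str]) -> dict:
    """Shared-gene summary for one ordered sample pair."""
    if not genes_a:
        raise ValueError("empty gene set for query sample")
    shared = len(genes_a & genes_b)
    return {
        "n": len(genes_a),
        "n_shared": shared,
        "fraction": shared / len(genes_a),
        "pct": percent(shared, len(genes_a)),
    }


def overlap_summary(
    peaks_by_sample: Mapping[str, PeakSet],
    genes: Sequence[GeneModel],
    promoter_flank: int = 1000,
) -> dict:
    """Pairwise peak-level and gene-level overlap report across samples.

    For every ordered pair (a, b): how many of a's peaks overlap any of
    b's, and how many of a's target genes are also targets of b.
    Percentages are rounded to the nearest integer; raw fractions are kept.
    """
    if len(peaks_by_sample) < 2:
        raise ValueError("need at least two samples")
    for label, ps in peaks_by_sample.items():
        if len(ps) == 0:
            raise ValueError(f"empty peak set for sample {label!r}")
    targets = {
        label: peaks_to_genes(ps, genes, promoter_flank)
        for label, ps in peaks_by_sample.items()
    }
    report: dict = {"pairs": {}, "n_peaks": {}, "n_target_genes": {}}
    for label, ps in peaks_by_sample.items():
        report["n_peaks"][label] = len(ps)
        report["n_target_genes"][label] = len(targets[label])
    labels = list(peaks_by_sample)
    for a in labels:
        for b in labels:
            if a == b:
                continue
            n_hit, frac = overlap_count(
                list(peaks_by_sample[a]), list(peaks_by_sample[b])
            )
            pair: dict = {
                "peaks": {
                    "n": len(peaks_by_sample[a]),
                    "n_overlapping": n_hit,
                    "fraction": frac,
                    "pct": percent(n_hit, len(peaks_by_sample[a])),
                }
            }
            if targets[a]:
                pair["genes"] = gene_overlap_report(targets[a], targets[b])
            report["pairs"][f"{a}_vs_{b}"] = pair
    return report


@dataclass
class TargetGeneCatalog:
    """Per-gene categorization result plus the parameters that produced it."""

    table: pd.DataFrame  # index gene_id; columns in_total, in_hrcs, mean_hrcs_rpm, category
    background_rpm: float
    k_background: float

    def category_sizes(self) -> dict[str, int]:
        sizes = self.table["category"].value_counts().to_dict()
        return {c: int(sizes.get(c, 0)) for c in ("H", "PH", "TS")}

    def genes_in(self, category: str) -> set[str]:
        return set(self.table.index[self.table["category"] == category])


def categorize(
    genes_total: set[str],
    genes_hrcs: set[str],
    hrcs_cov: CoverageTrack,
    peaks_total: PeakSet,
    genes: Sequence[GeneModel],
    k_background: float = 2.0,
    promoter_flank: int = 1000,
    method: str = "background",
    signal_quantile: float = 0.75,
) -> TargetGeneCatalog:
    """Split target genes into H / PH / TS.

    H: gene is a purified-fraction target. Otherwise, for total-sperm
    targets, S = mean purified-fraction RPM over the gene's total-sperm
    promoter peak region(s). With ``method='background'`` (default) the
    gene is PH iff ``S >= k_background * B`` where B is the genome-wide
    mean per-bin RPM; with ``method='quantile'`` the cutoff is instead the
    ``signal_quantile``-th quantile of S over all scored genes. Below the
    cutoff the gene is TS.
    """
    if k_background <= 0:
        raise ValueError("k_background must be positive")
    if method not in ("background", "quantile"):
        raise ValueError(f"unknown method {method!r}")

    gene_by_id = {g.gene_id: g for g in genes}
    background = hrcs_cov.mean_rpm()

    rows: list[dict] = []
    for gid in sorted(genes_total | genes_hrcs):
        g = gene_by_id.get(gid)
        mean_rpm = np.nan
        if g is not None and gid in genes_total:
            lo, hi = g.promoter_window(promoter_flank)
            promoter = GenomicInterval(g.chrom, lo, hi)
            regions = [p for p in peaks_total if p.overlaps(promoter)]
            if regions:
                mean_rpm = hrcs_cov.mean_rpm_over(regions)
        rows.append(
            {
                "gene_id": gid,
                "in_total": gid in genes_total,
                "in_hrcs": gid in genes_hrcs,
                "mean_hrcs_rpm": mean_rpm,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")

    if method == "background":
        cutoff = k_background * background
    else:
        scored = table.loc[~table["in_hrcs"], "mean_hrcs_rpm"].dropna()
        cutoff = float(scored.quantile(signal_quantile)) if len(scored) else np.inf

    def _cat(row) -> str:
        if row["in_hrcs"]:
            return "H"
        s = row["mean_hrcs_rpm"]
        return "PH" if (not np.isnan(s) and s >= cutoff) else "TS"

    table["category"] = table.apply(_cat, axis=1)
    table["background_rpm"] = background
    return TargetGeneCatalog(table, background, k_background)


def write_catalog(catalog: TargetGeneCatalog, path) -> None:
    catalog.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_catalog(path) -> TargetGeneCatalog:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    background = float(table["background_rpm"].iloc[0]) if len(table) else float("nan")
    return TargetGeneCatalog(table, background, float("nan"))
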