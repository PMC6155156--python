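"""Region-level DNA-methylation averaging, cross-sample correlation, and
stage-wise expression dynamics per target-gene category."""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals_io import GenomicInterval
from .target_categories import TargetGeneCatalog

__all__ = [
    "MethylationRecord",
    "read_methylation",
    "write_methylation",
    "region_methylation",
    "methylation_correlation",
    "expression_dynamics",
    "read_expression",
    "write_expression",
]


@dataclass(frozen=True)
class MethylationRecord:
    """Counts at one CG site (position of the C on the + strand, 0-based)."""

    chrom: str
    pos: int
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("negative position")
        if not (0 <= self.methylated <= self.total):
            raise ValueError("need 0 <= methylated <= total")

    @property
    def level(self) -> float:
        return self.methylated / self.total if self.total > 0 else np.nan


_METH_HEADER = "chrom\tpos0\tmethylated\ttotal"


def write_methylation(records: Iterable[MethylationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_METH_HEADER + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.methylated}\t{r.total}\n")


def read_methylation(path: str | Path) -> list[MethylationRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _METH_HEADER:
            raise ValueError(f"{path}: unexpected methylation-table header")
        for line in fh:
            chrom, pos, m, t = line.rstrip("\n").split("\t")
            out.append(MethylationRecord(chrom, int(pos), int(m), int(t)))
    return out


def region_methylation(
    records: Sequence[MethylationRecord],
    regions: Sequence[GenomicInterval],
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Unweighted mean CG-site methylation level per region.

    Sites with ``total < min_coverage`` are excluded. Regions with no
    qualifying site get a NaN level; ``n_sites`` reports how many sites
    contributed. Row order follows the input regions.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    by_chrom: dict[str, tuple[list[int], list[float]]] = {}
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if r.total >= min_coverage:
            pos_list, lev_list = by_chrom.setdefault(r.chrom, ([], []))
            pos_list.append(r.pos)
            lev_list.append(r.level)
    rows = []
    for region in regions:
        level, n = np.nan, 0
        if region.chrom in by_chrom:
            pos_list, lev_list = by_chrom[region.chrom]
            lo = bisect.bisect_left(pos_list, region.start)
            hi = bisect.bisect_left(pos_list, region.end)
            n = hi - lo
            if n:
                level = float(np.mean(lev_list[lo:hi]))
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "name": region.name,
                "mean_level": level,
                "n_sites": n,
            }
        )
    return pd.DataFrame(rows)


def methylation_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int]:
    """Pearson r over pairwise-complete region levels; returns (r, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    r = float(np.corrcoef(x[mask], y[mask])[0, 1])
    return r, n


# ---------------------------------------------------------------------------
# Expression dynamics
# ---------------------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (expr.values < 0).any():
        raise ValueError("negative FPKM values in expression table")
    return expr


def expression_dynamics(
    expr: pd.DataFrame,
    catalog: TargetGeneCatalog,
    threshold: float = 10.0,
    condition_stage: str = "oocyte",
    condition_all_genes: bool = True,
) -> pd.DataFrame:
    """Fraction of highly expressed genes (FPKM strictly > threshold) per
    category and stage, restricted to genes above threshold at
    ``condition_stage``.

    Rows: ``all`` plus each category present in the catalog. ``n`` is the
    conditioned-universe size; categories with an empty universe get NaN
    fractions and n = 0.
    """
    if condition_stage not in expr.columns:
        raise KeyError(f"condition stage {condition_stage!r} not in expression table")
    stages = list(expr.columns)
    conditioned = expr.index[expr[condition_stage] > threshold]

    universes: dict[str, pd.Index] = {}
    universes["all"] = conditioned if condition_all_genes else expr.index
    for cat in ("H", "PH", "TS"):
        members = catalog.genes_in(cat) & set(expr.index)
        universes[cat] = conditioned.intersection(sorted(members))

    rows = []
    for label, universe in universes.items():
        row: dict = {"category": label, "n": len(universe)}
        sub = expr.loc[universe]
        for stage in stages:
            row[stage] = (
                float((sub[stage] > threshold).mean()) if len(universe) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
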