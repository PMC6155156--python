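"""Genomic-compartment annotation and peak-distribution tables.

Every base of every chromosome is assigned to exactly one class by painting
classes in increasing precedence order, so the final labels always form a
partition. Precedence (high to low): promoter > exon > intron > upstream >
downstream > intergenic_repeat > intergenic_unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals_io import GenomicInterval, GeneModel, PeakSet

__all__ = [
    "CLASSES",
    "CompartmentAnnotation",
    "build_annotation",
    "peak_compartment_table",
]

# Index doubles as precedence: larger code wins when a peak spans classes.
CLASSES = (
    "intergenic_unique",
    "intergenic_repeat",
    "downstream",
    "upstream",
    "intron",
    "exon",
    "promoter",
)
_CODE = {name: i for i, name in enumerate(CLASSES)}


@dataclass
class CompartmentAnnotation:
    """Per-base class labels (uint8 codes into :data:`CLASSES`)."""

    labels: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def class_of(self, chrom: str, pos: int) -> str:
        return CLASSES[self.labels[chrom][pos]]

    def class_lengths(self) -> dict[str, int]:
        totals = np.zeros(len(CLASSES), dtype=np.int64)
        for arr in self.labels.values():
            totals += np.bincount(arr, minlength=len(CLASSES))
        return {name: int(totals[i]) for i, name in enumerate(CLASSES)}

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def class_fractions(self) -> dict[str, float]:
        g = self.genome_length()
        return {k: v / g for k, v in self.class_lengths().items()}

    def verify_partition(self) -> bool:
        """Label arrays cover each chromosome exactly once by construction;
        this re-checks lengths and code validity."""
        for chrom, size in self.chrom_sizes.items():
            arr = self.labels[chrom]
            if len(arr) != size or arr.max(initial=0) >= len(CLASSES):
                return False
        return True

    def to_bed(self, path) -> None:
        """Run-length-encoded export, class name in the BED name field."""
        with open(path, "w") as fh:
            for chrom in sorted(self.labels):
                arr = self.labels[chrom]
                if len(arr) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(arr)]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{CLASSES[arr[s]]}\t0\t.\n")


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    # windows beyond chromosome bounds are clipped, not errors
    s, e = max(0, start), min(len(arr), end)
    if e > s:
        arr[s:e] = code


def build_annotation(
    genes: Sequence[GeneModel],
    repeats: Iterable[GenomicInterval],
    chrom_sizes: dict[str, int],
    promoter_flank: int = 1000,
    flank_extent: int = 5000,
) -> CompartmentAnnotation:
    """Annotate every base from gene models and repeat intervals.

    promoter = TSS +/- ``promoter_flank``; upstream runs from
    ``flank_extent`` upstream of the TSS to the promoter edge; downstream
    runs ``flank_extent`` past the TES; introns are gene body minus exons;
    the remainder is intergenic, split by repeat overlap.
    """
    labels = {
        chrom: np.zeros(size, dtype=np.uint8) for chrom, size in chrom_sizes.items()
    }
    for g in genes:
        if g.chrom not in labels:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")

    for rep in repeats:
        if rep.chrom in labels:
            _paint(labels[rep.chrom], rep.start, rep.end, _CODE["intergenic_repeat"])

    # low precedence to high; later layers overwrite earlier ones
    for layer in ("downstream", "upstream", "intron", "exon", "promoter"):
        code = _CODE[layer]
        for g in genes:
            arr = labels[g.chrom]
            sign = 1 if g.strand == "+" else -1
            if layer == "downstream":
                lo, hi = sorted((g.tes, g.tes + sign * flank_extent))
                _paint(arr, lo, hi, code)
            elif layer == "upstream":
                lo, hi = sorted((g.tss - sign * flank_extent, g.tss - sign * promoter_flank))
                _paint(arr, lo, hi, code)
            elif layer == "intron":
                _paint(arr, *g.body, code)
            elif layer == "exon":
                for s, e in g.exons:
                    _paint(arr, s, e, code)
            else:  # promoter, strand-symmetric around the TSS
                _paint(arr, g.tss - promoter_flank, g.tss + promoter_flank, code)

    return CompartmentAnnotation(labels, dict(chrom_sizes))


def peak_compartment_table(
    peaks: PeakSet,
    annotation: CompartmentAnnotation,
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Tabulate peak counts per compartment class.

    ``mode='midpoint'`` (default) assigns each peak the class of its
    midpoint base; ``mode='any_overlap'`` assigns the highest-precedence
    class the peak touches. Returns a frame with columns
    count / fraction / genome_fraction / enrichment, one row per class.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    missing = sorted({p.chrom for p in peaks if p.chrom not in annotation.labels})
    if missing:
        raise KeyError(f"peaks on chromosomes absent from annotation: {missing}")

    counts = np.zeros(len(CLASSES), dtype=np.int64)
    for p in peaks:
        arr = annotation.labels[p.chrom]
        if mode == "midpoint":
            code = arr[min(p.midpoint, len(arr) - 1)]
        else:
            s, e = max(0, p.start), min(len(arr), p.end)
            code = arr[s:e].max() if e > s else arr[min(s, len(arr) - 1)]
        counts[code] += 1

    n = len(peaks)
    genome_frac = annotation.class_fractions()
    rows = []
    for i, name in enumerate(CLASSES):
        frac = counts[i] / n if n else np.nan
        gf = genome_frac[name]
        rows.append(
            {
                "class": name,
                "count": int(counts[i]),
                "fraction": frac,
                "genome_fraction": gf,
                "enrichment": frac / gf if gf > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")
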