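"""TSS-anchored coverage matrices, profile curves, and heatmap export.

Matrix values are RPM-normalized per-bin counts in a fixed window centered
on each anchor. Minus-strand rows are column-reversed so column 0 is
always the 5'-most (upstream) end of the window in transcript orientation.
Anchors whose window runs off a chromosome end are zero-padded and
flagged, never dropped, so row sets stay identical across samples.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .intervals_io import CoverageTrack

__all__ = ["Anchor", "TssMatrix", "build_tss_matrix", "profile_curve", "export_heatmap_matrix"]


class Anchor(NamedTuple):
    name: str
    chrom: str
    pos: int
    strand: str


@dataclass
class TssMatrix:
    values: np.ndarray            # (n_rows, n_bins), RPM
    row_ids: list[str]
    offsets: np.ndarray           # 5'->3' bin-start offsets in bp from anchor
    padded: np.ndarray            # bool per row: window clipped at a chrom edge
    bin_width: int
    window: int
    sample_label: str = ""
    anchor_type: str = "tss"

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.offsets)


def build_tss_matrix(
    cov: CoverageTrack,
    anchors: Sequence[Anchor],
    window: int = 3000,
    bin_width: int = 50,
    sample_label: str = "",
) -> TssMatrix:
    """Collect RPM coverage in ``window`` bp centered on each anchor.

    The window start is snapped down to the coverage grid; ``bin_width``
    must be a multiple of the coverage track's own bin width.
    """
    if window % bin_width:
        raise ValueError(f"window {window} not divisible by bin width {bin_width}")
    if bin_width % cov.bin_width:
        raise ValueError(
            f"matrix bin width {bin_width} incompatible with coverage grid {cov.bin_width}"
        )
    n_bins = window // bin_width
    agg = bin_width // cov.bin_width
    half = window // 2

    values = np.zeros((len(anchors), n_bins))
    padded = np.zeros(len(anchors), dtype=bool)
    factor = cov.rpm_factor
    for i, a in enumerate(anchors):
        arr = cov.counts.get(a.chrom)
        if arr is None:
            padded[i] = True
            continue
        g0 = (a.pos - half) // cov.bin_width
        g1 = g0 + n_bins * agg
        lo, hi = max(0, g0), min(len(arr), g1)
        row = np.zeros(n_bins * agg)
        if hi > lo:
            row[lo - g0 : hi - g0] = arr[lo:hi]
        if g0 < 0 or g1 > len(arr):
            padded[i] = True
        binned = row.reshape(n_bins, agg).sum(axis=1) * factor
        if a.strand == "-":
            binned = binned[::-1]
        values[i] = binned

    offsets = np.arange(-half, half, bin_width)
    return TssMatrix(
        values=values,
        row_ids=[a.name for a in anchors],
        offsets=offsets,
        padded=padded,
        bin_width=bin_width,
        window=window,
        sample_label=sample_label,
    )


def profile_curve(matrix: TssMatrix) -> pd.Series:
    """Per-bin column means (the average profile over all rows)."""
    if len(matrix) == 0:
        raise ValueError("empty matrix")
    return pd.Series(matrix.values.mean(axis=0), index=matrix.offsets, name="mean_rpm")


def export_heatmap_matrix(
    matrix: TssMatrix,
    row_order: str | Sequence[str] = "mean_desc",
    path=None,
) -> pd.DataFrame:
    """Deterministically ordered dense matrix, optionally written as TSV.

    ``row_order`` is either ``'mean_desc'`` (descending row mean, ties
    broken by row id) or an explicit list of row ids. Paths ending in
    ``.gz`` are gzip-compressed.
    """
    frame = matrix.to_frame()
    if isinstance(row_order, str):
        if row_order != "mean_desc":
            raise ValueError(f"unknown row ordering rule {row_order!r}")
        means = frame.mean(axis=1)
        order = sorted(frame.index, key=lambda rid: (-means[rid], rid))
    else:
        missing = set(row_order) - set(frame.index)
        if missing:
            raise KeyError(f"row ids not in matrix: {sorted(missing)}")
        order = list(row_order)
    frame = frame.loc[order]
    if path is not None:
        path = str(path)
        if path.endswith(".gz"):
            with gzip.open(path, "wt") as fh:
                frame.to_csv(fh, sep="\t")
        else:
            frame.to_csv(path, sep="\t")
    return frame
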