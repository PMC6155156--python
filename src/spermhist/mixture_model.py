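"""Two-population contamination mixture model.

Bulk histone signal of a mixed sperm sample is modeled per cell as
``R = (1 - f) + f * (h_un / h_c)`` where ``f`` is the contaminating-cell
fraction, and ``h_un / h_c`` the per-cell histone-content ratio of the
contaminating vs the purified population. ``R`` is the bulk(total) /
bulk(purified) ratio measured on equal cell numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureSpec",
    "NonIdentifiableError",
    "InconsistentMeasurementError",
    "forward_ratio",
    "invert_ratio",
    "recover_from_noisy",
    "sensitivity_to_fraction",
]


class NonIdentifiableError(ValueError):
    """The per-cell ratio cannot be inferred (f = 0)."""


class InconsistentMeasurementError(ValueError):
    """Observed bulk ratio below the f-implied lower bound (R < 1 - f)."""


@dataclass(frozen=True)
class MixtureSpec:
    """Contamination fraction and per-cell histone contents."""

    f: float
    h_c: float = 1.0
    h_un: float = 41.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.h_c <= 0:
            raise ValueError("h_c must be positive")
        if self.h_un < 0:
            raise ValueError("h_un must be non-negative")

    @property
    def ratio(self) -> float:
        return self.h_un / self.h_c

    @property
    def bulk_ratio(self) -> float:
        return forward_ratio(self.f, self.ratio)


def forward_ratio(f: float, h_un_over_h_c: float) -> float:
    """Bulk(total)/bulk(purified) ratio of the mixture."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"f must be in [0, 1], got {f}")
    if h_un_over_h_c < 0:
        raise ValueError("per-cell ratio must be non-negative")
    return (1.0 - f) + f * h_un_over_h_c


def invert_ratio(f: float, R: float) -> tuple[float, float]:
    """Recover ``(h_un/h_c, contamination_share)`` from f and the bulk ratio.

    ``contamination_share`` is the fraction of bulk histone signal derived
    from the contaminating population: ``f * ratio / R``.
    """
    if f == 0:
        raise NonIdentifiableError("f = 0: per-cell ratio is not identifiable")
    if not (0.0 < f <= 1.0):
        raise ValueError(f"f must be in (0, 1], got {f}")
    if R < (1.0 - f) - 1e-12:
        raise InconsistentMeasurementError(
            f"R = {R} below lower bound 1 - f = {1.0 - f}"
        )
    ratio = (R - (1.0 - f)) / f
    share = f * ratio / R if R > 0 else 0.0
    return ratio, share


def recover_from_noisy(
    replicate_ratios: Sequence[float],
    f: float,
    n_bootstrap: int = 1000,
    ci: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Point estimate and percentile bootstrap interval for the per-cell
    ratio from replicate bulk-ratio measurements.

    Deterministic under ``seed``. Raises if fewer than 3 replicates or if
    the mean replicate ratio is inconsistent with ``f``.
    """
    rs = np.asarray(replicate_ratios, dtype=float)
    if rs.size < 3:
        raise ValueError(f"need >= 3 replicates, got {rs.size}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ratio, share = invert_ratio(f, float(rs.mean()))

    idx = rng.integers(0, rs.size, size=(n_bootstrap, rs.size))
    boot_means = rs[idx].mean(axis=1)
    boot_ratios = (boot_means - (1.0 - f)) / f  # raw formula; may dip below 0
    alpha = (1.0 - ci) / 2
    lo, hi = np.quantile(boot_ratios, [alpha, 1.0 - alpha])
    return {
        "ratio": ratio,
        "contamination_share": share,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_replicates": int(rs.size),
        "n_bootstrap": int(n_bootstrap),
        "mean_R": float(rs.mean()),
    }


def sensitivity_to_fraction(
    R: float, f_values: Sequence[float] = (0.05, 0.075, 0.10, 0.125, 0.15)
) -> pd.DataFrame:
    """Inferred per-cell ratio and contamination share across plausible f."""
    rows = []
    for f in f_values:
        ratio, share = invert_ratio(f, R)
        rows.append({"f": f, "ratio": ratio, "contamination_share": share})
    return pd.DataFrame(rows).set_index("f")
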