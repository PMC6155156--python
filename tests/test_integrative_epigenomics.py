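import numpy as np
import pandas as pd
import pytest

from spermhist.integrative_epigenomics import (
    MethylationRecord,
    expression_dynamics,
    methylation_correlation,
    read_expression,
    read_methylation,
    region_methylation,
    write_expression,
    write_methylation,
)
from spermhist.intervals_io import GenomicInterval
from spermhist.target_categories import TargetGeneCatalog


class TestMethylationRecord:
    def test_level(self):
        assert MethylationRecord("chr1", 10, 3, 4).level == pytest.approx(0.75)

    def test_invalid(self):
        with pytest.raises(ValueError):
            MethylationRecord("chr1", 10, 5, 4)

    def test_round_trip(self, tmp_path):
        records = [MethylationRecord("chr1", 5, 1, 10), MethylationRecord("chr2", 9, 0, 3)]
        path = tmp_path / "meth.tsv"
        write_methylation(records, path)
        assert read_methylation(path) == records


class TestRegionMethylation:
    def test_single_site_identity(self):
        records = [MethylationRecord("chr1", 50, 8, 10)]
        out = region_methylation(records, [GenomicInterval("chr1", 0, 100)])
        assert out["mean_level"].iloc[0] == pytest.approx(0.8)

    def test_unweighted_mean(self):
        records = [
            MethylationRecord("chr1", 10, 10, 10),   # 1.0
            MethylationRecord("chr1", 20, 5, 10),    # 0.5
            MethylationRecord("chr1", 30, 0, 10),    # 0.0
        ]
        out = region_methylation(records, [GenomicInterval("chr1", 0, 100)])
        assert out["mean_level"].iloc[0] == pytest.approx(0.5)

    def test_min_coverage_excludes_site(self):
        # 4-site toy: one site below min coverage must drop out of the mean
        records = [
            MethylationRecord("chr1", 10, 9, 10),
            MethylationRecord("chr1", 20, 0, 10),
            MethylationRecord("chr1", 30, 3, 3),   # excluded at min_coverage=5
            MethylationRecord("chr1", 200, 5, 10), # outside region
        ]
        out = region_methylation(
            records, [GenomicInterval("chr1", 0, 100)], min_coverage=5
        )
        assert out["n_sites"].iloc[0] == 2
        assert out["mean_level"].iloc[0] == pytest.approx((0.9 + 0.0) / 2)

    def test_empty_region_reported_missing(self):
        out = region_methylation([], [GenomicInterval("chr1", 0, 100)])
        assert np.isnan(out["mean_level"].iloc[0]) and out["n_sites"].iloc[0] == 0

    def test_order_invariance(self, rng):
        records = [
            MethylationRecord("chr1", int(p), int(m), 10)
            for p, m in zip(rng.integers(0, 1000, 50), rng.integers(0, 11, 50))
        ]
        regions = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 500, 1000)]
        a = region_methylation(records, regions)["mean_level"]
        b = region_methylation(records[::-1], regions)["mean_level"]
        pd.testing.assert_series_equal(a, b)

    def test_levels_in_unit_interval(self, default_dataset):
        ds = default_dataset
        out = region_methylation(
            ds.methylation["hrcs"], list(ds.peaks["hrcs"])
        )
        levels = out["mean_level"].dropna()
        assert ((levels >= 0) & (levels <= 1)).all()
        # peak-bearing promoter CGIs were planted hypomethylated
        assert levels.mean() < 0.4

    def test_bad_min_coverage(self):
        with pytest.raises(ValueError):
            region_methylation([], [], min_coverage=0)


class TestMethylationCorrelation:
    def test_identity(self):
        x = [0.1, 0.5, 0.9, 0.3]
        r, n = methylation_correlation(x, x)
        assert r == pytest.approx(1.0) and n == 4

    def test_anti(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        r, _ = methylation_correlation(x, -x + 1)
        assert r == pytest.approx(-1.0)

    def test_direct_formula_oracle(self, rng):
        x = rng.random(100)
        y = x * 0.5 + rng.random(100)
        r, n = methylation_correlation(x, y)
        # independent covariance-formula computation
        ref = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(ref, abs=1e-12) and n == 100

    def test_nan_dropped_pairwise(self):
        x = [0.1, np.nan, 0.5, 0.9]
        y = [0.2, 0.3, np.nan, 0.8]
        with pytest.raises(ValueError):  # only 2 complete pairs remain
            methylation_correlation(x, y)

    def test_scale_shift_invariance(self, rng):
        x, y = rng.random(30), rng.random(30)
        r1, _ = methylation_correlation(x, y)
        r2, _ = methylation_correlation(3 * x + 1, 0.5 * y - 2)
        assert r1 == pytest.approx(r2)

    def test_planted_samples_correlate(self, default_dataset):
        ds = default_dataset
        regions = list(ds.peaks["hrcs"])
        a = region_methylation(ds.methylation["hrcs"], regions)["mean_level"]
        b = region_methylation(ds.methylation["swimup"], regions)["mean_level"]
        r, _ = methylation_correlation(a, b)
        assert r > 0.6


def _catalog(mapping):
    table = pd.DataFrame(
        {"category": pd.Series(mapping), "in_total": True, "in_hrcs": False,
         "mean_hrcs_rpm": 0.0, "background_rpm": 1.0}
    )
    table.index.name = "gene_id"
    return TargetGeneCatalog(table, 1.0, 2.0)


class TestExpressionDynamics:
    def test_hand_counted_fraction(self):
        # oocyte-conditioned genes with stage FPKMs {12, 9, 30, 10}: strict
        # threshold 10 passes 12 and 30 only -> 2/4
        expr = pd.DataFrame(
            {"oocyte": [20.0, 20.0, 20.0, 20.0], "late": [12.0, 9.0, 30.0, 10.0]},
            index=["a", "b", "c", "d"],
        )
        catalog = _catalog({g: "TS" for g in expr.index})
        dyn = expression_dynamics(expr, catalog, threshold=10.0, condition_stage="oocyte")
        assert dyn.loc["TS", "late"] == pytest.approx(0.5)
        assert dyn.loc["TS", "oocyte"] == pytest.approx(1.0)

    def test_all_zero_reported_missing(self):
        expr = pd.DataFrame({"oocyte": [0.0, 0.0], "late": [0.0, 0.0]}, index=["a", "b"])
        dyn = expression_dynamics(expr, _catalog({"a": "TS", "b": "TS"}))
        assert dyn.loc["all", "n"] == 0
        assert np.isnan(dyn.loc["all", "late"])

    def test_threshold_monotonicity(self, rng):
        # condition stage far above any tested threshold -> fixed universe,
        # so raising the threshold can never raise a fraction
        n = 40
        expr = pd.DataFrame(
            {
                "oocyte": np.full(n, 1e6),
                "mid": rng.lognormal(2.5, 1.0, n),
                "late": rng.lognormal(1.5, 1.0, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        catalog = _catalog({g: "TS" for g in expr.index})
        prev = None
        for thr in (5.0, 10.0, 20.0, 40.0):
            dyn = expression_dynamics(expr, catalog, threshold=thr)
            frac = dyn.loc["TS", ["mid", "late"]].to_numpy(dtype=float)
            assert ((frac >= 0) & (frac <= 1)).all()
            if prev is not None:
                assert (frac <= prev + 1e-12).all()
            prev = frac

    def test_planted_suppression(self, default_dataset):
        ds = default_dataset
        catalog = _catalog(
            {g: c for g, c in ds.truth["gene_categories"].items() if c != "none"}
        )
        dyn = expression_dynamics(ds.expression, catalog, threshold=10.0,
                                  condition_stage="oocyte")
        last = ds.config.stages[-1]
        assert dyn.loc["H", "oocyte"] > 0.9
        assert dyn.loc["H", last] < 0.1
        assert dyn.loc["TS", last] > dyn.loc["H", last]

    def test_missing_condition_stage(self):
        expr = pd.DataFrame({"late": [1.0]}, index=["a"])
        with pytest.raises(KeyError):
            expression_dynamics(expr, _catalog({"a": "TS"}), condition_stage="oocyte")

    def test_expression_round_trip(self, tmp_path, default_dataset):
        path = tmp_path / "expr.tsv"
        write_expression(default_dataset.expression, path)
        back = read_expression(path)
        assert list(back.columns) == list(default_dataset.expression.columns)
        np.testing.assert_allclose(
            back.to_numpy(), default_dataset.expression.to_numpy(), rtol=1e-5
        )
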