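"""Trends, detrending, epoch anomalies, maps, stratification, hinge fits."""

import numpy as np
import pytest
import xarray as xr

from jetcurve import diagnostics as dg
from jetcurve import synthio


def as_field(values, n_lat, n_lon):
    t = values.shape[0]
    return xr.DataArray(values.reshape(t, n_lat, n_lon),
                        dims=("time", "lat", "lon"),
                        coords={"time": np.arange(t),
                                "lat": np.arange(n_lat, dtype=float),
                                "lon": np.arange(n_lon, dtype=float)})


class TestLinearTrend:
    def test_exact_line(self):
        res = dg.linear_trend(2.0 * np.arange(30) + 5.0)
        assert res.slope == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(0.0)
        assert res.ci_low <= res.slope <= res.ci_high

    def test_constant_series_flagged_degenerate(self):
        res = dg.linear_trend(np.full(10, 4.0))
        assert res.degenerate and res.slope == 0.0 and np.isnan(res.pvalue)

    def test_ar1_adjustment_inflates_uncertainty(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=200)
        y = np.empty_like(e)
        y[0] = e[0]
        for i in range(1, e.size):  # strongly red series
            y[i] = 0.8 * y[i - 1] + e[i]
        plain = dg.linear_trend(y)
        adj = dg.linear_trend(y, ar1_adjust=True)
        assert adj.stderr > plain.stderr
        assert adj.ci_high - adj.ci_low > plain.ci_high - plain.ci_low

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            dg.linear_trend([1.0, 2.0])


class TestDetrend:
    def test_pure_line_goes_to_zero(self):
        out = dg.detrend(3.0 * np.arange(20) - 7.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_time_and_idempotent(self):
        rng = np.random.default_rng(1)
        y = 0.5 * np.arange(50) + rng.normal(size=50)
        r = dg.detrend(y)
        t = np.arange(50.0)
        assert abs(np.dot(r, t - t.mean())) < 1e-8
        assert abs(r.mean()) < 1e-10
        np.testing.assert_allclose(dg.detrend(r), r, atol=1e-10)


class TestEpochAnomalies:
    def test_constant_series_zero_anomalies(self):
        years = np.arange(1979, 2024)
        out = dg.epoch_anomalies(np.full(years.size, 2.0), years)
        assert all(v == 0.0 for v in out.values())

    def test_step_reversal_detected(self):
        """An index stepping -a to +a at 2000 shows opposite epoch anomalies."""
        years = np.arange(1990, 2010)
        a = 1.5
        series = np.where(years < 2000, -a, a)
        out = dg.epoch_anomalies(series, years,
                                 epochs=((1990, 1999), (2000, 2009)))
        assert out[(1990, 1999)] == pytest.approx(-a)
        assert out[(2000, 2009)] == pytest.approx(a)

    def test_whole_record_epoch_is_zero(self):
        years = np.arange(2000, 2020)
        rng = np.random.default_rng(2)
        series = rng.normal(size=years.size)
        out = dg.epoch_anomalies(series, years, epochs=((2000, 2019),))
        assert out[(2000, 2019)] == pytest.approx(0.0, abs=1e-12)

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError, match="no data"):
            dg.epoch_anomalies([1.0, 2.0], [2000, 2001],
                               epochs=((1900, 1950),))


class TestCorrelationMap:
    def test_proportional_cell_has_unit_correlation(self):
        rng = np.random.default_rng(3)
        idx = rng.normal(size=40)
        cmap = dg.correlate_index_field(as_field(3.0 * idx[:, None], 1, 1), idx)
        assert cmap.r.values.item() == pytest.approx(1.0)
        assert bool(cmap.significant.values.item())

    def test_trend_only_coupling_vanishes_after_detrending(self):
        """Cells co-trending with the index decorrelate once detrended."""
        rng = np.random.default_rng(4)
        n = 60
        trend = np.arange(n, dtype=float)
        idx = trend + rng.normal(0, 1.0, n)
        cells = trend[:, None] + rng.normal(0, 1.0, (n, 9))
        raw = dg.correlate_index_field(as_field(cells, 3, 3), idx)
        det = dg.correlate_index_field(as_field(cells, 3, 3), idx,
                                       detrend_first=True)
        assert np.abs(raw.r.values).min() > 0.9
        assert np.abs(det.r.values).max() < 0.35

    def test_affine_index_rescaling_leaves_map_unchanged(self):
        rng = np.random.default_rng(5)
        idx = rng.normal(size=30)
        field = as_field(rng.normal(size=(30, 12)), 3, 4)
        a = dg.correlate_index_field(field, idx)
        b = dg.correlate_index_field(field, 10.0 * idx - 4.0)
        np.testing.assert_allclose(a.r.values, b.r.values, atol=1e-12)

    def test_missing_cells_use_pairwise_overlap(self):
        rng = np.random.default_rng(6)
        idx = rng.normal(size=30)
        vals = 2.0 * idx[:, None] + rng.normal(0, 0.1, (30, 4))
        vals[:15, 0] = np.nan        # half record missing in one cell
        vals[:28, 1] = np.nan        # too few points in another
        cmap = dg.correlate_index_field(as_field(vals, 2, 2), idx)
        r = cmap.r.values.ravel()
        assert r[0] > 0.9 and np.isnan(r[1]) and (r[2:] > 0.9).all()
        assert cmap.n.values.ravel().tolist() == [15, 2, 30, 30]

    def test_short_overlap_rejected(self):
        with pytest.raises(ValueError, match="3 common"):
            dg.correlate_index_field(as_field(np.ones((2, 1)), 1, 1),
                                     [1.0, 2.0])

    def test_fdr_mask_is_no_looser_than_percell(self):
        rng = np.random.default_rng(7)
        idx = rng.normal(size=35)
        field = as_field(rng.normal(size=(35, 100)), 10, 10)
        plain = dg.correlate_index_field(field, idx)
        fdr = dg.correlate_index_field(field, idx, fdr=True)
        assert fdr.significant.values.sum() <= plain.significant.values.sum()


class TestRegressionMap:
    def test_unstandardized_slope_recovered(self):
        rng = np.random.default_rng(8)
        idx = rng.normal(size=40)
        rmap = dg.regress_index_field(as_field(2.0 * idx[:, None], 1, 1), idx,
                                      standardize=False)
        assert rmap.coef.values.item() == pytest.approx(2.0)

    def test_standardized_mode_invariant_to_index_scaling(self):
        rng = np.random.default_rng(9)
        idx = rng.normal(size=40)
        field = as_field(rng.normal(size=(40, 8)), 2, 4)
        a = dg.regress_index_field(field, idx)
        b = dg.regress_index_field(field, 10.0 * idx)
        np.testing.assert_allclose(a.coef.values, b.coef.values, atol=1e-12)

    def test_uncoupled_cells_yield_null_coefficients(self):
        rng = np.random.default_rng(10)
        idx = rng.normal(size=45)
        field = as_field(rng.normal(size=(45, 400)), 20, 20)
        rmap = dg.regress_index_field(field, idx)
        frac_sig = rmap.significant.values.mean()
        assert abs(rmap.coef.values.mean()) < 0.2
        assert frac_sig < 0.12  # ~5% nominal for independent cells

    def test_zero_variance_index_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            dg.regress_index_field(as_field(np.ones((10, 1)), 1, 1),
                                   np.ones(10))


class TestLanduseStratification:
    def make_maps(self, coeff_managed, coeff_natural, seed=0):
        """Field with weaker coupling in managed cells, per generator truth."""
        rng = np.random.default_rng(seed)
        idx = rng.normal(size=45)
        n_lat = n_lon = 12
        managed = np.zeros((n_lat, n_lon), dtype=bool)
        managed[:, : n_lon // 2] = True
        coeff = np.where(managed, coeff_managed, coeff_natural)
        vals = coeff.ravel()[None, :] * idx[:, None] + rng.normal(
            0, 1.0, (45, n_lat * n_lon))
        cmap = dg.correlate_index_field(as_field(vals, n_lat, n_lon), idx)
        mf = xr.DataArray(managed.astype(float), dims=("lat", "lon"))
        nf = xr.DataArray(1.0 - managed, dims=("lat", "lon"))
        return cmap, mf, nf

    def test_weaker_managed_coupling_detected(self):
        cmap, mf, nf = self.make_maps(0.3, 1.5)
        out = dg.stratify_by_landuse(cmap, mf, nf)
        assert out.mean_abs_r_managed < out.mean_abs_r_natural
        assert out.pvalue < 0.05

    def test_equal_coupling_not_significant(self):
        cmap, mf, nf = self.make_maps(1.0, 1.0, seed=3)
        out = dg.stratify_by_landuse(cmap, mf, nf)
        assert out.pvalue > 0.05

    def test_empty_class_rejected(self):
        cmap, mf, _ = self.make_maps(1.0, 1.0)
        all_managed = xr.ones_like(mf)
        none = xr.zeros_like(mf)
        with pytest.raises(ValueError, match="empty land-use class"):
            dg.stratify_by_landuse(cmap, all_managed, none)

    def test_fractions_validated(self):
        cmap, mf, nf = self.make_maps(1.0, 1.0)
        with pytest.raises(ValueError, match="fractions"):
            dg.stratify_by_landuse(cmap, mf + 2.0, nf)


class TestBinnedResponse:
    def test_hinge_recovered_near_true_breakpoint(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(10.0, 28.0, 5000)
        y = 5.0 * np.minimum(x, 19.0) + rng.normal(0, 1.0, x.size)
        rc = dg.binned_response(y, x, n_bins=18)
        assert rc.breakpoint_identified
        assert abs(rc.breakpoint - 19.0) <= 1.0  # within one bin
        assert rc.slope_below == pytest.approx(5.0, abs=0.2)
        assert rc.slope_above == pytest.approx(0.0, abs=0.2)

    def test_pure_line_not_identified(self):
        x = np.linspace(0, 10, 200)
        rc = dg.binned_response(3.0 * x + 1.0, x, n_bins=8)
        assert not rc.breakpoint_identified
        assert rc.slope_below == rc.slope_above == pytest.approx(3.0)
        assert np.isnan(rc.breakpoint)

    def test_constant_response_has_zero_slopes(self):
        x = np.linspace(0, 10, 200)
        rc = dg.binned_response(np.full_like(x, 2.0), x, n_bins=8)
        assert rc.slope_below == rc.slope_above == pytest.approx(0.0)

    def test_degenerate_driver_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dg.binned_response(np.arange(100.0), np.ones(100), n_bins=4)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="paired samples"):
            dg.binned_response(np.arange(10.0), np.arange(10.0), n_bins=4)
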