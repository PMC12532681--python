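"""Weighted trend engine: kernel, bandwidths, local fits, CV, surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twr
from twr.covariates import CenteredResponse
from twr.coordinates import ThematicCoordinates
from twr.twr_core import TwrError, _wls_line, _weight_matrix


def make_design(coords_by_station, obs_rows, window=(2012, 2023), time_coding="station_mean"):
    """coords_by_station: {sid: (c1, c2)}; obs_rows: (sid, year, y)."""
    cdf = pd.DataFrame(coords_by_station, index=["c1", "c2"]).T
    cdf.index.name = "station_id"
    coords = ThematicCoordinates(coords=cdf, source="test")
    data = pd.DataFrame(obs_rows, columns=["station_id", "year", "value"])
    resp = CenteredResponse(
        data=data, station_means=pd.Series(dtype=float), variable="pH", window=window
    )
    return twr.build_design(coords, resp, time_coding=time_coding)


def random_design(rng, n_stations=20, noise=0.1, slope=None):
    coords = {f"S{i:03d}": tuple(rng.normal(size=2)) for i in range(n_stations)}
    rows = []
    for sid, (c1, c2) in coords.items():
        years = sorted(rng.choice(range(2012, 2024), size=rng.integers(2, 4), replace=False))
        b = slope if slope is not None else rng.normal(0, 0.03)
        tbar = np.mean(years)
        for y in years:
            rows.append((sid, int(y), b * (y - tbar) + noise * rng.normal()))
    return make_design(coords, rows)


class TestBisquareWeight:
    def test_kernel_maximum_at_zero_distance(self):
        assert twr.bisquare_weight(0.0, 2.0) == 1.0

    def test_zero_at_and_beyond_bandwidth(self):
        assert twr.bisquare_weight(2.0, 2.0) == 0.0
        assert twr.bisquare_weight(5.0, 2.0) == 0.0

    def test_half_bandwidth_value(self):
        assert twr.bisquare_weight(1.0, 2.0) == pytest.approx(0.5625)

    def test_non_positive_bandwidth_rejected(self):
        with pytest.raises(TwrError):
            twr.bisquare_weight(1.0, 0.0)

    @given(
        st.floats(0.0, 10.0),
        st.floats(0.01, 10.0),
        st.floats(0.01, 100.0),
    )
    def test_monotone_and_rescale_invariant(self, d, b, scale):
        w = twr.bisquare_weight(d, b)
        assert 0.0 <= w <= 1.0
        assert twr.bisquare_weight(scale * d, scale * b) == pytest.approx(w, abs=1e-12)
        assert twr.bisquare_weight(d * 1.01, b) <= w + 1e-15


class TestAdaptiveBandwidth:
    coords = np.array([[0.0], [1.0], [2.0], [5.0]])

    def test_sorted_distance_enumeration(self):
        assert twr.adaptive_bandwidth(self.coords, target=0, k=3) == 2.0

    def test_k_equals_n_gives_max_distance(self):
        assert twr.adaptive_bandwidth(self.coords, target=0, k=4) == 5.0

    def test_self_included_at_distance_zero(self):
        assert twr.adaptive_bandwidth(self.coords, target=0, k=1) == 0.0

    def test_k_above_n_is_error(self):
        with pytest.raises(TwrError):
            twr.adaptive_bandwidth(self.coords, target=0, k=5)


class TestLocalFit:
    def test_uniform_weights_reduce_to_ols(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=30)
        y = 0.02 * t + rng.normal(0, 0.1, 30)
        W = np.ones((1, 30))
        slope, intercept, r2, sw, degen = _wls_line(W, t, y)
        b_ols, a_ols = np.polyfit(t, y, 1)
        assert slope[0] == pytest.approx(b_ols, abs=1e-10)
        assert intercept[0] == pytest.approx(a_ols, abs=1e-10)
        assert not degen[0] and sw[0] == 30

    def test_noiseless_line_recovered_exactly(self):
        rows = [("A", y, 0.03 * (y - 2017.5)) for y in (2013, 2016, 2019, 2022)]
        rows += [("B", y, 0.03 * (y - 2017.5)) for y in (2014, 2022)]
        design = make_design({"A": (0, 0), "B": (1, 0)}, rows, time_coding="window_midpoint")
        fit = twr.local_fit(design, "A", twr.KernelSpec(k=6))
        assert fit["slope_per_year"] == pytest.approx(0.03, abs=1e-12)
        assert fit["local_r2"] == pytest.approx(1.0, abs=1e-10)
        assert fit["flag"] == "ok"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_weighted_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng, n_stations=rng.integers(5, 18))
        k = int(rng.integers(4, design.n_rows + 1))
        sid = design.station_coords.index[rng.integers(len(design.station_coords))]
        fit = twr.local_fit(design, sid, twr.KernelSpec(k=k))
        # independent dense solve of (X'WX) beta = X'W y
        target = design.station_coords.loc[sid].to_numpy(dtype=float)
        d = np.linalg.norm(design.row_coords - target, axis=1)
        b = np.sort(d)[k - 1]
        w = np.where(d < b, (1 - (d / b) ** 2) ** 2, 0.0)
        X = np.column_stack([np.ones(design.n_rows), design.rows["t"]])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * design.rows["y"]))
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit["slope_per_year"] == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_window_flagged_not_raised(self):
        rows = [("A", 2015, 0.0), ("B", 2015, 0.1), ("C", 2015, -0.1), ("C", 2020, 0.2)]
        design = make_design(
            {"A": (0, 0), "B": (0.1, 0), "C": (9.0, 0)}, rows, time_coding="window_midpoint"
        )
        fit = twr.local_fit(design, "A", twr.KernelSpec(k=3))
        assert fit["flag"] == "degenerate" and np.isnan(fit["slope_per_year"])

    def test_local_r2_within_unit_interval(self):
        rng = np.random.default_rng(11)
        design = random_design(rng, n_stations=25, noise=0.3)
        surface = twr.fit_trend_surface(design, k=12)
        ok = surface.table[surface.table["flag"] == "ok"]
        assert ((ok["local_r2"] >= 0) & (ok["local_r2"] <= 1)).all()


class TestCvBandwidth:
    def test_single_k_grid_returned_as_is(self):
        rng = np.random.default_rng(3)
        design = random_design(rng, n_stations=15)
        k, trace = twr.cv_bandwidth(design, k_grid=[8])
        assert k == 8 and len(trace) == 1 and np.isfinite(trace["cv_score"]).all()

    def test_noiseless_global_trend_fits_perfectly_at_any_k(self):
        rng = np.random.default_rng(4)
        design = random_design(rng, n_stations=20, noise=0.0, slope=0.03)
        grid = [6, 10, 20, design.n_rows]
        k, trace = twr.cv_bandwidth(design, k_grid=grid)
        # every window reproduces the global line: scores are all ~0
        assert (trace["cv_score"].to_numpy() < 1e-20).all()

    def test_noisy_global_trend_prefers_max_k(self):
        """With a spatially constant slope, smoothing has no bias, so the
        widest window wins leave-one-out CV."""
        rng = np.random.default_rng(14)
        design = random_design(rng, n_stations=40, noise=0.2, slope=0.03)
        grid = [6, 15, 40, design.n_rows]
        k, trace = twr.cv_bandwidth(design, k_grid=grid)
        assert k == max(grid), trace.to_string()

    def test_tie_breaks_to_smallest_k(self):
        rng = np.random.default_rng(4)
        design = random_design(rng, n_stations=20, noise=0.0, slope=0.03)
        k, trace = twr.cv_bandwidth(design, k_grid=[design.n_rows, 20])
        # both fits are exact, scores tie at ~0 -> smallest k wins
        assert k == 20

    def test_station_level_unit_excludes_own_rows(self):
        rng = np.random.default_rng(9)
        design = random_design(rng, n_stations=15)
        k_obs, trace_obs = twr.cv_bandwidth(design, k_grid=[10], cv_unit="observation")
        k_st, trace_st = twr.cv_bandwidth(design, k_grid=[10], cv_unit="station")
        assert trace_st["cv_score"][0] != trace_obs["cv_score"][0]


class TestTrendSurface:
    def test_constant_slope_recovered_everywhere(self):
        rng = np.random.default_rng(6)
        design = random_design(rng, n_stations=30, noise=0.0, slope=0.02)
        surface = twr.fit_trend_surface(design, k=10)
        assert surface.table["slope_per_year"].to_numpy() == pytest.approx(
            np.full(30, 0.02), abs=1e-10
        )

    def test_geographic_coordinates_identical_to_engine(self, small_survey):
        """The GWR special case is the same engine fed easting/northing."""
        panel, _ = small_survey
        resp = twr.center_response(panel)
        geo = twr.geographic_coordinates(panel.attributes)
        assert geo.source == "geographic"
        manual = ThematicCoordinates(coords=geo.coords.copy(), source="manual")
        s_geo = twr.fit_trend_surface(twr.build_design(geo, resp), k=20)
        s_man = twr.fit_trend_surface(twr.build_design(manual, resp), k=20)
        pd.testing.assert_frame_equal(s_geo.table, s_man.table)

    def test_station_permutation_invariance(self):
        rng = np.random.default_rng(8)
        design = random_design(rng, n_stations=18, noise=0.2)
        # rebuild with shuffled input row order
        perm = rng.permutation(design.n_rows)
        rows = list(
            design.rows.iloc[perm][["station_id", "year", "y"]].itertuples(index=False)
        )
        coords = {
            sid: tuple(design.station_coords.loc[sid])
            for sid in rng.permutation(design.station_coords.index)
        }
        shuffled = make_design(coords, rows)
        a = twr.fit_trend_surface(design, k=9).table
        b = twr.fit_trend_surface(shuffled, k=9).table
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_time_shift_equivariance(self):
        """Slope per year is unchanged when all years shift by a constant."""
        rng = np.random.default_rng(12)
        coords = {f"S{i}": tuple(rng.normal(size=2)) for i in range(12)}
        rows = []
        for sid in coords:
            years = sorted(rng.choice(range(2012, 2024), size=2, replace=False))
            for y in years:
                rows.append((sid, int(y), rng.normal(0, 0.2)))
        d1 = make_design(coords, rows, window=(2012, 2023), time_coding="window_midpoint")
        shifted = [(sid, y + 7, v) for sid, y, v in rows]
        d2 = make_design(coords, shifted, window=(2019, 2030), time_coding="window_midpoint")
        s1 = twr.fit_trend_surface(d1, k=8).table
        s2 = twr.fit_trend_surface(d2, k=8).table
        assert s1["slope_per_year"].to_numpy() == pytest.approx(
            s2["slope_per_year"].to_numpy(), abs=1e-10
        )

    def test_cv_trace_recorded_with_chosen_k(self):
        rng = np.random.default_rng(13)
        design = random_design(rng, n_stations=20, noise=0.1)
        surface = twr.fit_trend_surface(design, k_grid=[6, 12, 24])
        assert surface.cv_trace is not None and len(surface.cv_trace) == 3
        best = surface.cv_trace.loc[surface.cv_trace["cv_score"].idxmin(), "k"]
        assert surface.k == best


class TestDefaultKGrid:
    def test_spans_ten_to_n(self):
        grid = twr.default_k_grid(500)
        assert grid[0] == 10 and grid[-1] == 500 and len(grid) <= 12
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_too_few_rows_is_error(self):
        with pytest.raises(TwrError):
            twr.default_k_grid(5)
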