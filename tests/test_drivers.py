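import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import nestcam as nc
from nestcam.drivers import EARTH_RADIUS_KM, load_ssmus


class TestPrecip:
    def test_counts_magnitude_two_and_up(self):
        scores = [
            nc.PrecipScore(dt.date(2015, 1, 1), "rain", 1),
            nc.PrecipScore(dt.date(2015, 1, 2), "rain", 2),
            nc.PrecipScore(dt.date(2015, 1, 3), "snow", 3),
            nc.PrecipScore(dt.date(2015, 1, 4), "rain", 1),
            nc.PrecipScore(dt.date(2015, 1, 5), "snow", 2),
        ]
        assert nc.count_precip_events(scores) == 3

    def test_empty_and_light_only(self):
        assert nc.count_precip_events([]) == 0
        light = [nc.PrecipScore(dt.date(2015, 1, d), k, 1)
                 for d, k in ((1, "rain"), (2, "snow"))]
        assert nc.count_precip_events(light) == 0

    def test_invalid_magnitude_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            nc.PrecipScore(dt.date(2015, 1, 1), "rain", 4)
        df = pd.DataFrame({"date": ["2015-01-01"], "kind": ["snow"],
                           "magnitude": [0]})
        with pytest.raises(ValueError):
            nc.count_precip_events(df)


def _square_around(lon0, lat0, half_km, lon_shift_km=0.0):
    """Approximate planar square in lon/lat near (lon0, lat0)."""
    km_per_deg_lat = np.pi * EARTH_RADIUS_KM / 180.0
    km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(lat0))
    cx = lon0 + lon_shift_km / km_per_deg_lon
    dlat = half_km / km_per_deg_lat
    dlon = half_km / km_per_deg_lon
    return Polygon([
        (cx - dlon, lat0 - dlat), (cx + dlon, lat0 - dlat),
        (cx + dlon, lat0 + dlat), (cx - dlon, lat0 + dlat),
    ])


SITE = (-60.0, -63.0)  # Antarctic Peninsula neighborhood


class TestKrill:
    def test_buffer_inside_single_ssmu(self):
        poly = _square_around(*SITE, half_km=600)
        catch = {(2014, m): 100.0 for m in range(3, 13)}
        ssmu = nc.SsmuCatch("A", poly, catch)
        got = nc.krill_buffer_catch(SITE, [ssmu], season_end_year=2015)
        assert got == pytest.approx(1000.0, rel=1e-6)

    def test_half_half_split_is_weighted_average(self):
        # two huge half-plane-like squares meeting on the site meridian
        left = _square_around(*SITE, half_km=2000, lon_shift_km=-2000)
        right = _square_around(*SITE, half_km=2000, lon_shift_km=2000)
        a = nc.SsmuCatch("L", left, {(2014, 6): 1000.0})
        b = nc.SsmuCatch("R", right, {(2014, 6): 2000.0})
        w = nc.buffer_weights(SITE, [a, b])
        assert w["L"] == pytest.approx(0.5, abs=1e-3)
        assert w["R"] == pytest.approx(0.5, abs=1e-3)
        got = nc.krill_buffer_catch(SITE, [a, b], season_end_year=2015)
        assert got == pytest.approx(1500.0, rel=1e-2)

    def test_weights_sum_below_one_with_partial_cover(self):
        poly = _square_around(*SITE, half_km=100)  # smaller than the buffer
        w = nc.buffer_weights(SITE, [nc.SsmuCatch("A", poly, {})])
        assert 0 < w["A"] < 1

    def test_zero_overlap_warns_and_returns_zero(self):
        far = _square_around(0.0, 0.0, half_km=100)
        with pytest.warns(UserWarning, match="zero SSMU overlap"):
            got = nc.krill_buffer_catch(
                SITE, [nc.SsmuCatch("A", far, {(2014, 6): 500.0})],
                season_end_year=2015)
        assert got == 0.0

    def test_window_is_march_through_january(self):
        months = nc.krill_window_months(2015)
        assert len(months) == 11
        assert months[0] == (2014, 3)
        assert months[-1] == (2015, 1)

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid"):
            nc.SsmuCatch("X", bowtie, {})

    def test_load_ssmus_from_geojson(self):
        poly = _square_around(*SITE, half_km=300)
        gj = {"type": "FeatureCollection", "features": [{
            "type": "Feature", "properties": {"ssmu_id": "A"},
            "geometry": json.loads(
                json.dumps(poly.__geo_interface__)),
        }]}
        catch = pd.DataFrame({"ssmu_id": ["A"], "year": [2014],
                              "month": [6], "tonnes": [123.0]})
        ssmus = load_ssmus(gj, catch)
        assert ssmus[0].window_total([(2014, 6)]) == 123.0


class TestTourism:
    LAY = dt.date(2014, 11, 16)
    CRECHE = dt.date(2015, 1, 15)

    def _visits(self, rows):
        return pd.DataFrame(rows, columns=["date", "visitors"])

    def test_outside_window_ignored(self):
        v = self._visits([(dt.date(2014, 10, 1), 100),
                          (dt.date(2015, 2, 1), 50)])
        assert nc.tourism_window_count(v, self.LAY, self.CRECHE) == 0

    def test_boundaries_inclusive(self):
        v = self._visits([(self.LAY, 120)])
        assert nc.tourism_window_count(v, self.LAY, self.CRECHE) == 120
        v = self._visits([(self.CRECHE, 7)])
        assert nc.tourism_window_count(v, self.LAY, self.CRECHE) == 7

    def test_mixed_window(self):
        v = self._visits([(self.LAY, 50), (dt.date(2014, 12, 15), 70),
                          (dt.date(2015, 1, 20), 30)])
        assert nc.tourism_window_count(v, self.LAY, self.CRECHE) == 120


def _table(x, bs_obs, sigma_bs):
    return pd.DataFrame({
        "site_year": range(len(x)), "precip_events": x,
        "bs_obs": bs_obs, "sigma_bs": sigma_bs,
    })


class TestDriverRegression:
    def test_noiseless_limit_recovers_slope(self):
        x = np.arange(10, dtype=float)
        tab = _table(x, 0.5 + 0.1 * x, np.full(10, 1e-8))
        reg = nc.fit_driver_regression(tab, "precipitation", rng_seed=0,
                                       n_warmup=500, n_samples=1500)
        assert np.median(reg.flat("beta")) == pytest.approx(0.1, abs=1e-3)

    def test_fixed_sigma_zero_error_matches_conjugate_posterior(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 25)
        sigma = 0.3
        y = 1.0 - 0.05 * x + rng.normal(0, sigma, 25)
        tab = _table(x, y, np.zeros(25))
        reg = nc.fit_driver_regression(tab, "precipitation", rng_seed=1,
                                       sigma_fixed=sigma,
                                       n_warmup=500, n_samples=2500)
        X = np.c_[np.ones(25), x]
        lam = X.T @ X / sigma**2 + np.diag([1 / 100, 1 / 100])
        cov = np.linalg.inv(lam)
        mean = cov @ (X.T @ y / sigma**2)
        beta = reg.flat("beta")
        mc_se = beta.std() / np.sqrt(len(beta) / 20)  # conservative ESS
        assert beta.mean() == pytest.approx(mean[1], abs=4 * mc_se + 1e-4)
        assert beta.std() == pytest.approx(np.sqrt(cov[1, 1]), rel=0.1)

    def test_widening_known_errors_never_narrows_interval(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 20)
        y = 1.0 + 0.05 * x + rng.normal(0, 0.1, 20)
        widths = []
        for s in (0.01, 0.3):
            tab = _table(x, y, np.full(20, s))
            reg = nc.fit_driver_regression(tab, "precipitation", rng_seed=3,
                                           n_warmup=500, n_samples=1500)
            b = reg.flat("beta")
            widths.append(np.quantile(b, 0.975) - np.quantile(b, 0.025))
        assert widths[1] >= widths[0]

    def test_krill_log_transform_and_offset(self):
        rows = [{"site_id": "s", "year_id": str(i), "bs_obs": 1.0,
                 "sigma_bs": 0.1, "precip_events": 0,
                 "krill_catch": c, "tourists": 0}
                for i, c in enumerate([0.0, 10.0, 100.0])]
        tab = nc.build_driver_table(rows)
        assert tab.attrs["krill_log_offset"] == pytest.approx(5.0)
        np.testing.assert_allclose(
            tab["log_krill_catch"], np.log(np.array([0, 10, 100.0]) + 5.0))

    def test_all_zero_krill_errors_at_the_krill_fit(self):
        rows = [{"site_id": "s", "year_id": str(i), "bs_obs": 1.0,
                 "sigma_bs": 0.1, "precip_events": i, "krill_catch": 0.0,
                 "tourists": 0} for i in range(4)]
        tab = nc.build_driver_table(rows)
        assert tab.attrs["krill_log_offset"] is None
        with pytest.raises(ValueError, match="offset"):
            nc.fit_driver_regression(tab, "krill")
        # other covariates remain usable
        nc.fit_driver_regression(tab, "precipitation", n_chains=1,
                                 n_warmup=50, n_samples=50)

    def test_too_few_points_rejected(self):
        tab = _table(np.arange(2.0), np.ones(2), np.full(2, 0.1))
        with pytest.raises(ValueError, match="at least 3"):
            nc.fit_driver_regression(tab, "precipitation")

    def test_unknown_covariate_rejected(self):
        tab = _table(np.arange(5.0), np.ones(5), np.full(5, 0.1))
        with pytest.raises(KeyError):
            nc.fit_driver_regression(tab, "moon_phase")


class TestEventOverlay:
    def test_no_events(self):
        out = nc.event_overlay_export(np.linspace(40, 20, 60),
                                      np.ones(60))
        assert out["event_magnitude"].isna().all()
        assert list(out["day"]) == list(range(1, 61))

    def test_event_day_flagged(self):
        scores = pd.DataFrame({"day": [43], "kind": ["snow"],
                               "magnitude": [3]})
        out = nc.event_overlay_export(np.linspace(40, 20, 60), np.ones(60),
                                      precip_scores=scores)
        flagged = out[out["event_magnitude"].notna()]
        assert list(flagged["day"]) == [43]
        assert flagged.iloc[0]["event_kind"] == "snow"

    def test_dates_resolved_against_lay_date(self):
        lay = dt.date(2014, 11, 16)
        scores = pd.DataFrame({"date": [dt.date(2014, 11, 26)],
                               "kind": ["rain"], "magnitude": [2],
                               "day": [np.nan]})
        out = nc.event_overlay_export(np.linspace(40, 20, 60), np.ones(60),
                                      precip_scores=scores, lay_date=lay)
        assert out.loc[9, "event_magnitude"] == 2  # day 10
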