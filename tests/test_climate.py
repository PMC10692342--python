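"""Heat-load covariate construction: THI, station assignment, windows, PC1."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatnorm import climate
from heatnorm.climate import (
    PC1_SCALE,
    THI_SCALE,
    ScalingSpec,
    WEEK_WINDOWS,
    assign_nearest_station,
    haversine_km,
    pc1_daily_thi,
    scale_covariate,
    thi_hourly,
    weekly_window_means,
)


class TestThi:
    @pytest.mark.parametrize(
        "t, rh, expected",
        [
            (25.0, 50.0, 71.775),          # hand-evaluated formula
            (130.0 / 9.0, 0.0, 58.0),      # (1.8T−26)=0 kills the humidity term
            (130.0 / 9.0, 87.0, 58.0),
            (0.0, 100.0, 32.0),            # (0.55−0.0055·100)=0
        ],
    )
    def test_values(self, t, rh, expected):
        assert thi_hourly(t, rh) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="temperature"):
            thi_hourly(70.0, 50.0)
        with pytest.raises(ValueError, match="humidity"):
            thi_hourly(20.0, 120.0)

    def test_monotonicity(self):
        """THI rises with T (RH < 100); its RH-sensitivity flips sign at
        1.8T = 26 °C."""
        t = np.linspace(-20, 40, 61)
        for rh in (0.0, 50.0, 99.0):
            d = np.diff(thi_hourly(t, np.full_like(t, rh)))
            assert np.all(d > 0)
        rh = np.linspace(0, 100, 51)
        hot, cold = 20.0, 5.0  # above / below 130/9 ≈ 14.44 °C
        assert np.all(np.diff(thi_hourly(np.full_like(rh, hot), rh)) > 0)
        assert np.all(np.diff(thi_hourly(np.full_like(rh, cold), rh)) < 0)


class TestHaversine:
    def test_identity_and_antipode(self):
        assert haversine_km(51.0, 10.0, 51.0, 10.0) == 0.0
        assert haversine_km(0, 0, 0, 180) == pytest.approx(np.pi * 6371.0, rel=1e-12)

    def test_one_degree_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(2 * np.pi * 6371.0 / 360.0, abs=1e-2)

    def test_symmetry(self, rng):
        a = rng.uniform([-80, -170], [80, 170], size=(5, 2))
        b = rng.uniform([-80, -170], [80, 170], size=(5, 2))
        d1 = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestNearestStation:
    def test_single_station_and_colocated(self):
        herds = pd.DataFrame({"id": ["h1", "h2"], "lat": [52.0, 53.0], "lon": [11.0, 12.0]})
        stations = pd.DataFrame({"id": ["s1"], "lat": [52.5], "lon": [11.5]})
        m = assign_nearest_station(herds, stations)
        assert set(m["station_id"]) == {"s1"}
        stations2 = pd.DataFrame({"id": ["s1", "s2"], "lat": [50.0, 53.0], "lon": [10.0, 12.0]})
        m2 = assign_nearest_station(herds, stations2)
        assert m2.loc[m2["herd_id"] == "h2", "station_id"].item() == "s2"
        assert m2.loc[m2["herd_id"] == "h2", "distance_km"].item() == 0.0

    def test_matches_brute_force(self, rng):
        herds = pd.DataFrame({"id": [f"h{i}" for i in range(7)],
                              "lat": rng.uniform(50, 54, 7), "lon": rng.uniform(8, 14, 7)})
        stations = pd.DataFrame({"id": [f"s{i}" for i in range(4)],
                                 "lat": rng.uniform(50, 54, 4), "lon": rng.uniform(8, 14, 4)})
        m = assign_nearest_station(herds, stations)
        for _, row in herds.iterrows():
            dists = {s["id"]: haversine_km(row["lat"], row["lon"], s["lat"], s["lon"])
                     for _, s in stations.iterrows()}
            best = min(sorted(dists), key=lambda k: dists[k])
            assert m.loc[m["herd_id"] == row["id"], "station_id"].item() == best

    def test_empty_stations(self):
        herds = pd.DataFrame({"id": ["h"], "lat": [52.0], "lon": [11.0]})
        with pytest.raises(ValueError, match="station"):
            assign_nearest_station(herds, herds.iloc[:0])


def _daily_frame(values, station="s1", start="2010-01-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({"station_id": station, "date": dates, "thi": values})


class TestWeeklyWindows:
    def test_window_definitions(self):
        # WK1 is the printed 0–7 d range (eight days); the rest are 7 days
        assert WEEK_WINDOWS[1] == (0, 7)
        assert WEEK_WINDOWS[2] == (8, 14)
        assert WEEK_WINDOWS[12] == (78, 84)

    def test_constant_series(self):
        daily = _daily_frame(np.full(120, 55.0))
        calves = pd.DataFrame({"calf_id": ["c"], "herd_id": ["h"],
                               "birth_date": [pd.Timestamp("2010-04-25")]})
        hs = pd.DataFrame({"herd_id": ["h"], "station_id": ["s1"]})
        wk = weekly_window_means(daily, calves, hs)
        for k in range(1, 13):
            assert wk[f"wk{k}"].item() == pytest.approx(55.0)

    def test_offset_series_wk2(self):
        # daily THI equal to the day offset → WK2 mean = mean(8..14) = 11
        n = 120
        birth = pd.Timestamp("2010-04-25")
        dates = pd.date_range(birth - pd.Timedelta(days=n - 1), periods=n, freq="D")
        offsets = (birth - dates).days
        daily = pd.DataFrame({"station_id": "s1", "date": dates, "thi": offsets.astype(float)})
        calves = pd.DataFrame({"calf_id": ["c"], "herd_id": ["h"], "birth_date": [birth]})
        hs = pd.DataFrame({"herd_id": ["h"], "station_id": ["s1"]})
        wk = weekly_window_means(daily, calves, hs)
        assert wk["wk2"].item() == pytest.approx(11.0)
        assert wk["wk1"].item() == pytest.approx(3.5)  # mean of 0..7

    def test_matches_loop_oracle(self, rng):
        n = 200
        start = pd.Timestamp("2011-01-01")
        vals = rng.uniform(10, 75, n)
        daily = _daily_frame(vals, start=start)
        births = start + pd.to_timedelta(rng.integers(90, n - 1, 20), unit="D")
        calves = pd.DataFrame({"calf_id": [f"c{i}" for i in range(20)],
                               "herd_id": "h", "birth_date": births})
        hs = pd.DataFrame({"herd_id": ["h"], "station_id": ["s1"]})
        wk = weekly_window_means(daily, calves, hs)
        series = {start + pd.Timedelta(days=i): vals[i] for i in range(n)}
        for i, b in enumerate(births):
            for k, (lo, hi) in WEEK_WINDOWS.items():
                expect = np.mean([series[b - pd.Timedelta(days=o)] for o in range(lo, hi + 1)])
                assert wk.loc[i, f"wk{k}"] == pytest.approx(expect, abs=1e-10)

    def test_insufficient_coverage_missing(self):
        daily = _daily_frame(np.full(30, 50.0))  # only 30 days of weather
        calves = pd.DataFrame({"calf_id": ["c"], "herd_id": ["h"],
                               "birth_date": [pd.Timestamp("2010-01-25")]})
        hs = pd.DataFrame({"herd_id": ["h"], "station_id": ["s1"]})
        wk = weekly_window_means(daily, calves, hs)
        assert np.isnan(wk["wk12"].item())  # offsets 78–84 have no data
        assert wk["wk1"].item() == pytest.approx(50.0)


class TestPc1:
    def test_identical_rows_zero_scores(self):
        m = np.tile(np.linspace(40, 60, 8), (5, 1))
        scores, ok = pc1_daily_thi(m, method="covariance")
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)
        assert ok.all()

    def test_rank_one_structure(self, rng):
        level = np.array([30.0, 40.0, 50.0, 60.0, 70.0])
        m = level[:, None] * np.ones((1, 10))
        scores, _ = pc1_daily_thi(m, method="covariance")
        # proportional to the centred level, positive for hot rows
        np.testing.assert_allclose(scores, (level - level.mean()) * np.sqrt(10), atol=1e-8)

    def test_matches_eigendecomposition(self, rng):
        m = rng.uniform(20, 70, size=(5, 4))
        scores, _ = pc1_daily_thi(m, method="covariance")
        xc = m - m.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(xc, rowvar=False))
        lead = v[:, np.argmax(w)]
        expect = xc @ lead
        if np.corrcoef(expect, m.mean(axis=1))[0, 1] < 0:
            expect = -expect
        np.testing.assert_allclose(scores, expect, atol=1e-10)

    def test_correlation_method_matches_standardised_eigen(self, rng):
        m = rng.uniform(20, 70, size=(20, 6))
        scores, _ = pc1_daily_thi(m)  # default: correlation
        z = (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)
        w, v = np.linalg.eigh(np.corrcoef(z, rowvar=False))
        expect = z @ v[:, np.argmax(w)]
        if np.corrcoef(expect, m.mean(axis=1))[0, 1] < 0:
            expect = -expect
        np.testing.assert_allclose(scores, expect, atol=1e-8)

    def test_incomplete_rows_dropped(self, rng):
        m = rng.uniform(20, 70, size=(6, 5))
        m[2, 3] = np.nan
        scores, ok = pc1_daily_thi(m)
        assert not ok[2] and np.isnan(scores[2])
        assert ok.sum() == 5

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="2 complete rows"):
            pc1_daily_thi(np.array([[1.0, 2.0]]))


class TestScaling:
    @pytest.mark.parametrize(
        "value, spec, expected",
        [
            (17.0, THI_SCALE, -1.0),
            (72.0, THI_SCALE, 1.0),
            (44.5, THI_SCALE, 0.0),   # thermoneutral midpoint
            (-2.0, PC1_SCALE, 0.0),   # PC1 midpoint with anchors (−15, 11)
            (10.0, THI_SCALE, -1.0),  # below the anchor: clamped
            (74.28, THI_SCALE, 1.0),  # above the anchor: clamped
        ],
    )
    def test_anchors_and_clamping(self, value, spec, expected):
        assert scale_covariate(value, spec) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=17.0, max_value=72.0))
    @settings(max_examples=50, derandomize=True)
    def test_roundtrip_inside_anchors(self, v):
        s = scale_covariate(v, THI_SCALE)
        back = THI_SCALE.min_val + (s + 1.0) / 2.0 * (THI_SCALE.max_val - THI_SCALE.min_val)
        assert back == pytest.approx(v, abs=1e-9)
        assert -1.0 <= s <= 1.0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ScalingSpec(5.0, 5.0)


def test_build_covariates_end_to_end(tiny_dataset):
    cov = tiny_dataset.covariates
    scaled = cov[[f"s_wk{k}" for k in range(1, 13)] + ["s_pc1"]].to_numpy()
    assert np.nanmin(scaled) >= -1.0 and np.nanmax(scaled) <= 1.0
    assert len(cov) == len(tiny_dataset.population.calves)
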