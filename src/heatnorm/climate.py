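"""Prenatal heat-load covariates from hourly weather.

Hourly dry-bulb temperature T (°C) and relative humidity RH (%) are combined
into the livestock temperature-humidity index

    THI = (1.8·T + 32) − (0.55 − 0.0055·RH) · (1.8·T − 26),

daily THI is the mean of a calendar day's hourly values, and each calf's
prenatal heat load is summarised as (a) mean THI over twelve weekly windows
counted backwards from the birth date and (b) the first principal component
of the daily THI over the last 56 days of gestation.  Both are affinely
rescaled to [−1, 1] so that reaction-norm slopes are expressed per unit of a
bounded gradient.

Window convention: day offset 0 is the birth date.  WK1 covers offsets 0–7
inclusive (eight days — the printed range is asymmetric and is kept as such);
WK2..WK12 cover the seven-day ranges 8–14, 15–21, ..., 78–84.  The PC1 window
covers offsets 0–55 (56 daily values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScalingSpec",
    "THI_SCALE",
    "PC1_SCALE",
    "WEEK_WINDOWS",
    "PC1_WINDOW_DAYS",
    "thi_hourly",
    "haversine_km",
    "assign_nearest_station",
    "daily_thi",
    "weekly_window_means",
    "gestation_daily_matrix",
    "pc1_daily_thi",
    "scale_covariate",
    "build_covariates",
]

EARTH_RADIUS_KM = 6371.0

#: day-offset windows before birth; WK1 is 0–7 inclusive (8 days), the rest 7 days
WEEK_WINDOWS = {1: (0, 7)} | {k: (7 * (k - 1) + 1, 7 * k) for k in range(2, 13)}

#: PC1 uses the last 56 days of gestation: offsets 0..55
PC1_WINDOW_DAYS = 56

#: minimum fraction of window days with a daily THI for the window mean to count
WINDOW_COVERAGE = 0.8


@dataclass(frozen=True)
class ScalingSpec:
    """Anchors of the affine map onto [−1, 1]; values outside are clamped."""

    min_val: float
    max_val: float

    def __post_init__(self) -> None:
        if not self.max_val > self.min_val:
            raise ValueError(f"max_val must exceed min_val, got {self}")


THI_SCALE = ScalingSpec(17.0, 72.0)
PC1_SCALE = ScalingSpec(-15.0, 11.0)


def thi_hourly(temp_c, rh_pct):
    """Temperature-humidity index of one (or an array of) hourly record(s).

    Raises ``ValueError`` if any temperature is outside [−50, 60] °C or any
    relative humidity outside [0, 100] %.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    bad_t = (t < -50) | (t > 60) | np.isnan(t)
    bad_rh = (rh < 0) | (rh > 100) | np.isnan(rh)
    if np.any(bad_t):
        idx = np.argwhere(np.atleast_1d(bad_t)).ravel()[:5]
        raise ValueError(f"temperature out of [-50, 60] °C at record(s) {idx.tolist()}")
    if np.any(bad_rh):
        idx = np.argwhere(np.atleast_1d(bad_rh)).ravel()[:5]
        raise ValueError(f"relative humidity out of [0, 100] %% at record(s) {idx.tolist()}")
    out = (1.8 * t + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)
    return out if out.ndim else float(out)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (spherical Earth, radius 6371.0 km)."""
    for name, v, lim in (("lat", lat1, 90), ("lon", lon1, 180), ("lat", lat2, 90), ("lon", lon2, 180)):
        if np.any(np.abs(np.asarray(v, dtype=float)) > lim):
            raise ValueError(f"|{name}| exceeds {lim} degrees")
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def assign_nearest_station(herds: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Map each herd to its nearest weather station.

    Parameters
    ----------
    herds, stations : DataFrames with columns ``id``, ``lat``, ``lon``.

    Returns a DataFrame (herd_id, station_id, distance_km); ties on distance
    are broken by the lexicographically smallest station id.
    """
    if len(stations) == 0:
        raise ValueError("no weather stations supplied")
    st = stations.sort_values("id", kind="stable").reset_index(drop=True)
    dist = haversine_km(
        np.asarray(herds["lat"], dtype=float)[:, None],
        np.asarray(herds["lon"], dtype=float)[:, None],
        np.asarray(st["lat"], dtype=float)[None, :],
        np.asarray(st["lon"], dtype=float)[None, :],
    )
    nearest = np.argmin(dist, axis=1)  # argmin takes the first minimum = lowest id after sort
    return pd.DataFrame(
        {
            "herd_id": herds["id"].to_numpy(),
            "station_id": st["id"].to_numpy()[nearest],
            "distance_km": dist[np.arange(len(herds)), nearest],
        }
    )


def daily_thi(weather: pd.DataFrame) -> pd.DataFrame:
    """Collapse hourly weather to daily mean THI per station.

    ``weather`` needs columns station_id, timestamp (datetime-like), temp_c,
    rh_pct.  Duplicate (station, timestamp) pairs are rejected.
    """
    w = weather.copy()
    w["timestamp"] = pd.to_datetime(w["timestamp"])
    if w.duplicated(["station_id", "timestamp"]).any():
        raise ValueError("duplicate (station_id, timestamp) hourly records")
    w["thi"] = thi_hourly(w["temp_c"].to_numpy(), w["rh_pct"].to_numpy())
    w["date"] = w["timestamp"].dt.normalize()
    out = w.groupby(["station_id", "date"], as_index=False)["thi"].mean()
    return out


class _StationSeries:
    """Daily THI of one station on a contiguous date grid (NaN where absent)."""

    def __init__(self, dates: pd.Series, values: np.ndarray):
        self.start = dates.min()
        n = (dates.max() - self.start).days + 1
        self.values = np.full(n, np.nan)
        self.values[(dates - self.start).dt.days.to_numpy()] = values

    def gather(self, day_index: np.ndarray) -> np.ndarray:
        """Values at integer day offsets from self.start; NaN outside range."""
        out = np.full(day_index.shape, np.nan)
        ok = (day_index >= 0) & (day_index < len(self.values))
        out[ok] = self.values[day_index[ok]]
        return out


def _station_series(daily: pd.DataFrame) -> dict:
    return {
        sid: _StationSeries(g["date"].reset_index(drop=True), g["thi"].to_numpy())
        for sid, g in daily.groupby("station_id")
    }


def _calf_window_matrix(daily, calves, herd_station, offsets):
    """Daily THI at the given day offsets before each calf's birth date.

    Returns (calf_ids, matrix) with NaN for days without weather.
    """
    series = _station_series(daily)
    hs = dict(zip(herd_station["herd_id"], herd_station["station_id"]))
    missing = set(calves["herd_id"]) - set(hs)
    if missing:
        raise ValueError(f"no station assigned for herd(s) {sorted(missing)[:5]}")
    birth = pd.to_datetime(calves["birth_date"]).dt.normalize()
    mat = np.full((len(calves), len(offsets)), np.nan)
    sid_per_calf = calves["herd_id"].map(hs)
    for sid, rows in pd.Series(np.arange(len(calves))).groupby(sid_per_calf.to_numpy()):
        s = series.get(sid)
        if s is None:
            continue
        idx = rows.to_numpy()
        day0 = (birth.iloc[idx] - s.start).dt.days.to_numpy()
        mat[idx] = s.gather(day0[:, None] - offsets[None, :])
    return calves["calf_id"].to_numpy(), mat


def weekly_window_means(daily, calves, herd_station, coverage=WINDOW_COVERAGE):
    """Mean daily THI over WK1..WK12 before birth for each calf.

    A window with daily coverage below ``coverage`` is reported as NaN.
    Returns a DataFrame (calf_id, wk1..wk12).
    """
    offsets = np.arange(85)
    calf_ids, mat = _calf_window_matrix(daily, calves, herd_station, offsets)
    out = {"calf_id": calf_ids}
    for k, (lo, hi) in WEEK_WINDOWS.items():
        win = mat[:, lo : hi + 1]
        cnt = np.sum(~np.isnan(win), axis=1)
        frac = cnt / win.shape[1]
        m = np.where(cnt > 0, np.nansum(win, axis=1) / np.maximum(cnt, 1), np.nan)
        m[frac < coverage] = np.nan
        out[f"wk{k}"] = m
    return pd.DataFrame(out)


def gestation_daily_matrix(daily, calves, herd_station, n_days=PC1_WINDOW_DAYS):
    """Calves × day-offset (0..n_days−1) matrix of daily THI (NaN where missing)."""
    offsets = np.arange(n_days)
    calf_ids, mat = _calf_window_matrix(daily, calves, herd_station, offsets)
    return calf_ids, mat


def pc1_daily_thi(matrix: np.ndarray, method: str = "correlation"):
    """First-principal-component scores of the daily late-gestation THI.

    Columns are day offsets; rows are calves.  Rows with any missing day are
    dropped (mask returned).  ``method="correlation"`` standardises columns
    first (the default: its score scale matches the fixed PC1 anchors);
    ``"covariance"`` centres only.  The eigenvector sign is fixed so that
    scores correlate positively with the row-mean THI ("high PC1 = hot").

    Returns (scores, complete_row_mask).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (calves × days)")
    ok = ~np.isnan(x).any(axis=1)
    xc = x[ok]
    if xc.shape[0] < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    xc = xc - xc.mean(axis=0)
    if method == "correlation":
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    elif method != "covariance":
        raise ValueError(f"unknown PCA method {method!r}")
    # SVD of the centred (optionally standardised) matrix; scores on the unit
    # right-singular vector, consistent with eigendecomposition of the
    # covariance/correlation matrix.
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = xc @ vt[0]
    rm = x[ok].mean(axis=1)
    if len(scores) > 1 and np.ptp(rm) > 0:
        c = np.corrcoef(scores, rm)[0, 1] if scores.std() > 0 else 0.0
        if c < 0:
            scores = -scores
    full = np.full(x.shape[0], np.nan)
    full[ok] = scores
    return full, ok


def scale_covariate(value, spec: ScalingSpec):
    """Affine map onto [−1, 1] with clamping outside the anchors."""
    v = np.asarray(value, dtype=float)
    s = -1.0 + 2.0 * (v - spec.min_val) / (spec.max_val - spec.min_val)
    s = np.clip(s, -1.0, 1.0)
    return s if s.ndim else float(s)


def build_covariates(
    weather: pd.DataFrame,
    stations: pd.DataFrame,
    herds: pd.DataFrame,
    calves: pd.DataFrame,
    thi_scale: ScalingSpec = THI_SCALE,
    pc1_scale: ScalingSpec = PC1_SCALE,
    pca_method: str = "correlation",
) -> pd.DataFrame:
    """End-to-end covariate table for a calving table.

    Returns a DataFrame with wk1..wk12, pc1 and their scaled versions
    (s_wk1..s_wk12, s_pc1), one row per calf.
    """
    d = daily_thi(weather)
    hs = assign_nearest_station(herds, stations)
    wk = weekly_window_means(d, calves, hs)
    calf_ids, mat = gestation_daily_matrix(d, calves, hs)
    scores, _ = pc1_daily_thi(mat, method=pca_method)
    wk["pc1"] = scores
    for k in range(1, 13):
        wk[f"s_wk{k}"] = scale_covariate(wk[f"wk{k}"].to_numpy(), thi_scale)
    wk["s_pc1"] = scale_covariate(wk["pc1"].to_numpy(), pc1_scale)
    return wk
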