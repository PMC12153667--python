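"""Raw tri-axial acceleration to ODBA, activity, bouts, and night summaries.

Overall dynamic body acceleration (ODBA) is the L1 norm of the dynamic
(gravity-removed) component of the three acceleration channels:

    ODBA = |A_x| + |A_y| + |A_z|

where each ``A_c`` is the difference between the mean and the midpoint
((max + min) / 2) of channel ``c`` over a short non-overlapping window
(default 2 s), divided by the counts-per-g scale of the logger (default
2**14).  Subtracting the within-window midpoint removes the static/gravity
component, so a motionless logger scores exactly zero.

Resolutions stack as: window (2 s) -> minute (mean of member windows) ->
hour (sum of member windows).  Minute-averaged ODBA above a calibrated
threshold (0.28 g by default) defines *active* minutes; an hour is active
when strictly more than 30 of its minutes are active; nights (noon-to-noon)
accumulate total ODBA and active minutes and are categorized by bout
structure (one unbroken bout vs. activity resumed after a >= 60 min gap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ephemeris import NightWindow, assign_nights, night_weather_average
from .weather import WeatherSeries

DEFAULT_COUNTS_PER_G = 2**14
DEFAULT_THRESHOLD = 0.28     # g, minute-averaged ODBA activity cut
ACTIVE_MINUTES_PER_HOUR = 30  # hour is active when strictly more than this
BOUT_GAP_MINUTES = 60        # inactive run ending a bout

__all__ = [
    "DEFAULT_COUNTS_PER_G",
    "DEFAULT_THRESHOLD",
    "TriaxialSeries",
    "OdbaSeries",
    "NightRecord",
    "ThresholdScan",
    "compute_window_odba",
    "aggregate",
    "classify_hour",
    "categorize_bouts",
    "nightly_summary",
    "threshold_sensitivity",
    "filter_deployment_days",
    "night_records_frame",
    "read_logger_csv",
]


@dataclass
class TriaxialSeries:
    """Raw logger record for one deployment.

    ``samples`` columns: ``timestamp`` (datetime), ``ax``, ``ay``, ``az``
    (integer counts).  Timestamps must be strictly increasing.
    """

    individual_id: str
    samples: pd.DataFrame
    counts_per_g: float = DEFAULT_COUNTS_PER_G

    def __post_init__(self):
        need = {"timestamp", "ax", "ay", "az"}
        if not need.issubset(self.samples.columns):
            raise ValueError(f"samples must have columns {sorted(need)}")
        ts = pd.to_datetime(self.samples["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        for c in ("ax", "ay", "az"):
            vals = self.samples[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"channel {c} has non-finite values")

    def to_csv(self, path) -> None:
        out = self.samples.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        out.to_csv(path, index=False)


@dataclass
class OdbaSeries:
    """ODBA at window, minute, and hour resolution for one deployment."""

    individual_id: str
    window: pd.DataFrame   # window_start, odba
    minute: pd.DataFrame   # minute_start, odba (mean of windows), n_windows, complete
    hourly: pd.DataFrame   # hour_start, odba (sum of windows), n_windows, complete


@dataclass
class NightRecord:
    individual_id: str
    night_id: object                 # date of the starting noon
    total_odba: float
    active_minutes: int
    bout_category: str               # single_bout | gap_resumed | other
    n_bouts: int
    complete: bool
    night_weather: dict | None = None

    def __post_init__(self):
        if not 0 <= self.active_minutes <= 1440:
            raise ValueError("active_minutes outside [0, 1440]")
        if self.total_odba < 0:
            raise ValueError("total_odba negative")


@dataclass
class ThresholdScan:
    """Sensitivity-analysis table over candidate activity thresholds."""

    table: pd.DataFrame     # threshold, active_minutes, n_bouts, between_class_var
    recommended: float | None


def compute_window_odba(series: TriaxialSeries, window_s: float = 2.0) -> pd.DataFrame:
    """Per-window ODBA from raw counts.

    Windows tile forward from the first sample, non-overlapping; a partial
    trailing window (fewer samples than the modal count) is dropped.
    Returns a DataFrame with ``window_start`` and ``odba`` (g units).
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    if len(series.samples) == 0:
        raise ValueError("empty series")
    df = series.samples
    ts = pd.to_datetime(df["timestamp"])
    t0 = ts.iloc[0]
    idx = ((ts - t0).dt.total_seconds() // window_s).astype(int)

    g = df.groupby(idx.values)
    mean = g[["ax", "ay", "az"]].mean()
    mx = g[["ax", "ay", "az"]].max()
    mn = g[["ax", "ay", "az"]].min()
    counts = g.size()
    dyn = (mean - (mx + mn) / 2.0) / series.counts_per_g
    odba = dyn.abs().sum(axis=1)

    # drop partial trailing window (fewer samples than the full windows)
    if len(counts) > 1 and counts.iloc[-1] < counts.iloc[:-1].max():
        odba = odba.iloc[:-1]
        counts = counts.iloc[:-1]
    window_start = t0 + pd.to_timedelta(odba.index * window_s, unit="s")
    return pd.DataFrame({"window_start": window_start.values, "odba": odba.values})


def aggregate(window_odba: pd.DataFrame, window_s: float = 2.0, individual_id: str = "") -> OdbaSeries:
    """Roll window ODBA up to minutes (mean) and hours (sum).

    Partial minutes/hours at the series edges — fewer member windows than a
    full minute/hour holds — are flagged ``complete=False`` so modeling can
    exclude them.
    """
    if len(window_odba) == 0:
        raise ValueError("empty window series")
    w = window_odba.copy()
    w["window_start"] = pd.to_datetime(w["window_start"])

    per_min = 60.0 / window_s
    per_hour = 3600.0 / window_s

    minute_key = w["window_start"].dt.floor("min")
    gm = w.groupby(minute_key)["odba"]
    minute = pd.DataFrame({
        "minute_start": gm.mean().index,
        "odba": gm.mean().values,
        "n_windows": gm.size().values,
    })
    minute["complete"] = minute["n_windows"] >= per_min

    hour_key = w["window_start"].dt.floor("h")
    gh = w.groupby(hour_key)["odba"]
    hourly = pd.DataFrame({
        "hour_start": gh.sum().index,
        "odba": gh.sum().values,
        "n_windows": gh.size().values,
    })
    hourly["complete"] = hourly["n_windows"] >= per_hour

    return OdbaSeries(individual_id=individual_id, window=w, minute=minute, hourly=hourly)


def classify_hour(minute_odba: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Binary hourly activity from minute-averaged ODBA.

    An hour is *active* when strictly more than 30 of its minutes have
    minute ODBA strictly above ``threshold``.  Hours with fewer than 60
    minutes of data are flagged ``complete=False`` (excluded from modeling).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    m = minute_odba.copy()
    m["minute_start"] = pd.to_datetime(m["minute_start"])
    key = m["minute_start"].dt.floor("h")
    above = m["odba"] > threshold
    g = pd.DataFrame({"hour_start": key, "above": above}).groupby("hour_start")["above"]
    out = pd.DataFrame({
        "hour_start": g.sum().index,
        "minutes_above": g.sum().astype(int).values,
        "n_minutes": g.size().values,
    })
    out["active"] = out["minutes_above"] > ACTIVE_MINUTES_PER_HOUR
    out["complete"] = out["n_minutes"] >= 60
    return out


def categorize_bouts(active: Sequence[bool], gap_minutes: int = BOUT_GAP_MINUTES) -> tuple[str, int]:
    """Categorize one night's minute-resolution activity sequence.

    Returns ``(category, n_bouts)`` where a *bout* is a maximal run of
    active minutes separated from the next by >= ``gap_minutes`` inactive
    minutes (shorter pauses do not break a bout):

    - ``single_bout``: activity with no interior inactive gap >= gap_minutes
    - ``gap_resumed``: activity, then >= gap_minutes inactive, then renewed
      activity
    - ``other``: no activity at all
    """
    a = np.asarray(active, dtype=bool)
    idx = np.flatnonzero(a)
    if idx.size == 0:
        return "other", 0
    gaps = np.diff(idx) - 1           # inactive minutes between successive active ones
    n_bouts = 1 + int(np.sum(gaps >= gap_minutes))
    if n_bouts == 1:
        return "single_bout", 1
    return "gap_resumed", n_bouts


def nightly_summary(
    odba: OdbaSeries,
    nights: Iterable[NightWindow],
    threshold: float = DEFAULT_THRESHOLD,
    weather: WeatherSeries | None = None,
) -> list[NightRecord]:
    """Summarize each noon-to-noon night: total ODBA, active minutes, bouts.

    ``total_odba`` sums hourly ODBA over the night window; active minutes
    count minute ODBA strictly above ``threshold``.  Nights whose hourly
    coverage is incomplete (fewer than 24 complete hours) are flagged.
    When ``weather`` is given, sunset-to-sunrise covariate averages are
    attached.
    """
    minute = odba.minute.copy()
    minute["minute_start"] = pd.to_datetime(minute["minute_start"])
    hourly = odba.hourly.copy()
    hourly["hour_start"] = pd.to_datetime(hourly["hour_start"])

    records = []
    for win in nights:
        msel = minute[(minute["minute_start"] >= win.start) & (minute["minute_start"] < win.end)]
        hsel = hourly[(hourly["hour_start"] >= win.start) & (hourly["hour_start"] < win.end)]
        active = (msel["odba"] > threshold).to_numpy()
        category, n_bouts = categorize_bouts(active)
        complete = bool((hsel["complete"]).sum() >= 24)
        nw = night_weather_average(weather, win) if weather is not None else None
        records.append(
            NightRecord(
                individual_id=odba.individual_id,
                night_id=win.night_id,
                total_odba=float(hsel["odba"].sum()),
                active_minutes=int(active.sum()),
                bout_category=category,
                n_bouts=n_bouts,
                complete=complete,
                night_weather=nw,
            )
        )
    return records


def threshold_sensitivity(minute_odba: pd.DataFrame | Sequence[float],
                          candidates: Sequence[float]) -> ThresholdScan:
    """Scan candidate activity thresholds over a minute-ODBA series.

    For each candidate: total active minutes, number of bouts induced, and
    the between-class variance of log minute-ODBA split at the candidate
    (an Otsu-style statistic).  The recommended threshold maximizes the
    between-class variance; a constant series yields no recommendation.
    """
    if isinstance(minute_odba, pd.DataFrame):
        values = minute_odba["odba"].to_numpy(dtype=float)
    else:
        values = np.asarray(minute_odba, dtype=float)
    candidates = np.asarray(sorted(candidates), dtype=float)
    if candidates.size < 2:
        raise ValueError("need at least 2 candidate thresholds")
    logv = np.log(values + 1e-6)

    rows = []
    for t in candidates:
        above = values > t
        n1 = int(above.sum())
        w1 = n1 / values.size
        w0 = 1.0 - w1
        if 0 < n1 < values.size:
            mu0 = logv[~above].mean()
            mu1 = logv[above].mean()
            bcv = w0 * w1 * (mu1 - mu0) ** 2
        else:
            bcv = 0.0
        _, n_bouts = categorize_bouts(above)
        rows.append({"threshold": t, "active_minutes": n1, "n_bouts": n_bouts,
                     "between_class_var": bcv})
    table = pd.DataFrame(rows)
    if np.unique(values).size < 2 or table["between_class_var"].max() <= 0:
        return ThresholdScan(table=table, recommended=None)
    best = table.loc[table["between_class_var"].idxmax(), "threshold"]
    return ThresholdScan(table=table, recommended=float(best))


def filter_deployment_days(
    frame: pd.DataFrame,
    deployment_start,
    deployment_end,
    timestamp_col: str = "hour_start",
) -> pd.DataFrame:
    """Drop the first and last deployment days (noon-to-noon units).

    Activity is depressed on the release day, and the capture time on the
    final day is uncertain, so the night containing the deployment start
    and the night containing the deployment end are both removed.  A
    deployment of <= 2 days therefore yields an empty (warned) result.
    """
    deployment_start = pd.Timestamp(deployment_start)
    deployment_end = pd.Timestamp(deployment_end)
    ts = pd.to_datetime(frame[timestamp_col])
    night = pd.Series(assign_nights(ts), index=frame.index)
    first_night = assign_nights(pd.Series([deployment_start])).iloc[0]
    last_night = assign_nights(pd.Series([deployment_end])).iloc[0]
    keep = (night > first_night) & (night < last_night)
    out = frame[keep].copy()
    if len(out) == 0:
        warnings.warn("deployment too short: no complete analysis days remain", stacklevel=2)
    return out


def night_records_frame(records: Iterable[NightRecord]) -> pd.DataFrame:
    """Tidy one-row-per-night table (weather columns flattened) for export."""
    rows = []
    for r in records:
        row = {"individual_id": r.individual_id, "night_id": r.night_id,
               "total_odba": r.total_odba, "active_minutes": r.active_minutes,
               "bout_category": r.bout_category, "n_bouts": r.n_bouts,
               "complete": r.complete}
        if r.night_weather:
            row.update({k: v for k, v in r.night_weather.items() if k != "night_id"})
        rows.append(row)
    return pd.DataFrame(rows)


def read_logger_csv(path, individual_id: str = "", counts_per_g: float = DEFAULT_COUNTS_PER_G) -> TriaxialSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return TriaxialSeries(individual_id=individual_id, samples=df, counts_per_g=counts_per_g)
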