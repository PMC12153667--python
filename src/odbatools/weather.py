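"""Hourly meteorology handling and body-condition index.

The pipeline's covariates are the seven hourly weather metrics commonly
recorded at woodland meteorological stations: air temperature (``Temp``,
degC), total rainfall (``Rain``, mm), wind speed (``Wind``, m/s), relative
humidity (``RH``, %), soil moisture (``SoilM``, %), and soil temperature at
10 and 30 cm depth (``SoilT10``, ``SoilT30``, degC).  A :class:`WeatherSeries`
is a thin validated wrapper around a tidy hourly DataFrame.

Continuous covariates are z-standardized within season before modeling;
the mean/SD used are retained in a :class:`StandardizationRecord` so that
predictions can be expressed back on natural scales.  Pairs of covariates
that are strongly correlated within a season (soil temperature tracks air
temperature, for example) are screened out of joint model subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WEATHER_COVARIATES = ["Temp", "Rain", "Wind", "RH", "SoilM", "SoilT10", "SoilT30"]

__all__ = [
    "WEATHER_COVARIATES",
    "WeatherSeries",
    "StandardizationRecord",
    "TraitRecord",
    "compute_bci",
    "standardize",
    "back_transform",
    "collinearity_screen",
    "long_term_anomaly",
    "read_weather_csv",
    "read_traits_csv",
]


class WeatherSeries:
    """Hourly weather records with validated schema.

    Parameters
    ----------
    frame
        DataFrame with a ``hour_start`` datetime column plus the seven
        covariate columns in :data:`WEATHER_COVARIATES`.  Missing hours are
        permitted (explicit gaps); duplicated or unordered hours are not.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ["hour_start", *WEATHER_COVARIATES] if c not in frame.columns]
        if missing:
            raise ValueError(f"weather frame missing columns: {missing}")
        frame = frame.copy()
        frame["hour_start"] = pd.to_datetime(frame["hour_start"])
        if frame["hour_start"].duplicated().any():
            raise ValueError("duplicate hour_start values")
        if not frame["hour_start"].is_monotonic_increasing:
            frame = frame.sort_values("hour_start").reset_index(drop=True)
        if (frame["Rain"] < 0).any():
            raise ValueError("negative rainfall")
        if ((frame["RH"] < 0) | (frame["RH"] > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.frame["hour_start"].iloc[0], self.frame["hour_start"].iloc[-1]

    def covers(self, start, end) -> bool:
        """True when every whole hour in [start, end) is present."""
        want = pd.date_range(pd.Timestamp(start).ceil("h"), pd.Timestamp(end), freq="h", inclusive="left")
        have = pd.DatetimeIndex(self.frame["hour_start"])
        return want.isin(have).all()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class StandardizationRecord:
    """Mean/SD (sample SD, n-1) used for each covariate's z-transform."""

    season: str
    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, name: str, x):
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z):
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]


@dataclass
class TraitRecord:
    individual_id: str
    sex: str
    age: float
    mass: float            # kg
    length: float          # cm
    bci: float = field(default=np.nan)
    lactating: bool | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.length <= 1:
            raise ValueError("length must exceed 1 (log-length positive)")
        if np.isnan(self.bci):
            self.bci = compute_bci(self.mass, self.length)


def compute_bci(mass: float, length: float) -> float:
    """Body-condition index: ln(mass) / ln(length).

    Mass in kg, length in cm.  A dimensionless proxy for fat reserves:
    heavier animals at a given skeletal length score higher.
    """
    mass = float(mass)
    length = float(length)
    if mass <= 0:
        raise ValueError("mass must be positive")
    if length <= 1:
        raise ValueError("length must exceed 1 cm")
    return float(np.log(mass) / np.log(length))


def standardize(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    season: str = "",
) -> tuple[pd.DataFrame, StandardizationRecord]:
    """Z-transform covariates to mean 0, SD 1 (sample SD, ddof=1).

    Returns the transformed copy and the record needed to invert the
    transform.  Quadratic model terms are formed downstream as z**2, i.e.
    after standardization.  Constant covariates are rejected by name.
    """
    out = frame.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in covariates:
        x = np.asarray(frame[name], dtype=float)
        if np.unique(x[~np.isnan(x)]).size < 2:
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if sd <= 0:
            raise ValueError(f"covariate {name!r} has zero SD")
        out[name] = (x - mu) / sd
        means[name] = mu
        sds[name] = sd
    return out, StandardizationRecord(season=season, means=means, sds=sds)


def back_transform(record: StandardizationRecord, name: str, z):
    """Inverse of :func:`standardize` for one covariate."""
    return record.inverse(name, z)


def collinearity_screen(
    frame: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    r_threshold: float = 0.7,
) -> list[tuple[str, str]]:
    """List covariate pairs with |Pearson r| >= ``r_threshold``.

    Downstream all-subsets selection never places both members of a listed
    pair in the same candidate model.  Pairs are returned in canonical
    (sorted) order; the relation is symmetric.
    """
    if covariates is None:
        covariates = [c for c in WEATHER_COVARIATES if c in frame.columns]
    if len(frame) < 3:
        raise ValueError("need at least 3 observations to screen collinearity")
    corr = frame[list(covariates)].corr(method="pearson")
    forbidden: list[tuple[str, str]] = []
    for i, a in enumerate(covariates):
        for b in covariates[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= r_threshold:
                forbidden.append(tuple(sorted((a, b))))
    return forbidden


def long_term_anomaly(
    period_values: Iterable[float],
    long_term_mean: float,
    long_term_sd: float,
) -> dict[str, float]:
    """Standardized departure of a study period from the long-term climate.

    Returns ``z`` = (period mean - long-term mean) / long-term SD together
    with a two-sided one-sample t-test of the period values against the
    long-term mean.
    """
    x = np.asarray(list(period_values), dtype=float)
    if long_term_sd <= 0:
        raise ValueError("long-term SD must be positive")
    z = (float(np.mean(x)) - long_term_mean) / long_term_sd
    tstat, p = stats.ttest_1samp(x, popmean=long_term_mean)
    return {"z": float(z), "t": float(tstat), "p": float(p), "n": int(x.size)}


def read_weather_csv(path) -> WeatherSeries:
    return WeatherSeries(pd.read_csv(path, parse_dates=["hour_start"]))


def read_traits_csv(path) -> list[TraitRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TraitRecord(
                individual_id=str(row.individual_id),
                sex=str(row.sex),
                age=float(row.age),
                mass=float(row.mass),
                length=float(row.length),
            )
        )
    return records
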