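"""Tabular I/O, m-array construction, and covariate summarization.

All tables are comma-separated UTF-8 with a header row and ``NA`` as the
missing-value token.  Encounter histories are stored flat, one row per
individual: ``id, sex, age_first, h0..h{T-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_CLASSES,
    GROUPS,
    MISSING_TOKEN,
    SD_DDOF,
    SEASON_WINDOWS,
    SEXES,
)

__all__ = [
    "EncounterData",
    "MArraySet",
    "build_marray",
    "summarize_weather_window",
    "effort_corrected_winter_count",
    "detrend_series",
    "zscore",
    "read_encounters",
    "write_encounters",
    "read_table",
    "write_table",
]


@dataclass
class EncounterData:
    """Individual capture/resight histories with sex and age at first capture.

    Parameters
    ----------
    ids : array of str or int, shape (n,)
    sex : array of {'f', 'm'}, shape (n,)
    age_first : array of {'juvenile', 'adult'}, shape (n,)
        Age class at first capture.
    histories : int array, shape (n, T)
        0/1 detections over the T annual occasions.
    """

    ids: np.ndarray
    sex: np.ndarray
    age_first: np.ndarray
    histories: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sex = np.asarray(self.sex)
        self.age_first = np.asarray(self.age_first)
        self.histories = np.asarray(self.histories, dtype=np.int64)
        if self.histories.ndim != 2:
            raise ValueError("histories must be 2-D (individuals x occasions)")
        n = self.histories.shape[0]
        if not (len(self.ids) == len(self.sex) == len(self.age_first) == n):
            raise ValueError("field lengths disagree")
        if not np.isin(self.sex, SEXES).all():
            raise ValueError("sex must be 'f' or 'm'")
        if not np.isin(self.age_first, AGE_CLASSES).all():
            raise ValueError("age_first must be 'juvenile' or 'adult'")
        if not np.isin(self.histories, (0, 1)).all():
            raise ValueError("histories must be 0/1")
        if n and not (self.histories.sum(axis=1) >= 1).all():
            raise ValueError("every individual must be detected at least once")

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    @property
    def first_occasion(self) -> np.ndarray:
        return np.argmax(self.histories == 1, axis=1)


@dataclass
class MArraySet:
    """Age/sex-specific m-arrays: the sufficient statistic of the CJS model.

    For each group, ``m[g]`` has one row per release occasion i = 0..T-2.
    Column j-1 (j = 1..T-1) counts individuals released at i and first
    recaptured at occasion j; the final column counts those never seen again.
    ``releases[g][i]`` is the row total.
    """

    m: dict[str, np.ndarray] = field(default_factory=dict)
    releases: dict[str, np.ndarray] = field(default_factory=dict)
    n_occasions: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if not (self.m[g].sum(axis=1) == self.releases[g]).all():
                raise ValueError(f"m-array rows of group {g} do not sum to releases")
            if (self.m[g] < 0).any():
                raise ValueError("negative m-array entry")


def build_marray(enc: EncounterData) -> MArraySet:
    """Convert encounter histories into the four age/sex-specific m-arrays.

    An individual marked as a juvenile contributes its first transition
    (release at marking, first recapture) to the juvenile m-array of its sex
    and every later transition to the adult m-array; individuals marked as
    adults contribute only to the adult m-array.
    """
    T = enc.n_occasions
    out = MArraySet(n_occasions=T)
    for g in GROUPS:
        out.m[g] = np.zeros((T - 1, T), dtype=np.int64)
        out.releases[g] = np.zeros(T - 1, dtype=np.int64)

    first = enc.first_occasion
    for i in range(len(enc.ids)):
        occs = np.flatnonzero(enc.histories[i])
        if occs[0] != first[i]:  # pragma: no cover - defensive
            raise ValueError("detection before first occasion")
        sex = enc.sex[i]
        juvenile_release = enc.age_first[i] == "juvenile"
        for k in range(len(occs)):
            rel = occs[k]
            if rel == T - 1:
                break  # a release at the final occasion carries no information
            group = f"juv_{sex}" if (juvenile_release and k == 0) else f"ad_{sex}"
            out.releases[group][rel] += 1
            if k + 1 < len(occs):
                recap = occs[k + 1]
                out.m[group][rel, recap - 1] += 1
            else:
                out.m[group][rel, T - 1] += 1
    out.validate()
    return out


def _window_mask(dates: pd.Series, window: str, year: int) -> pd.Series:
    (m0, d0), (m1, d1) = SEASON_WINDOWS[window]
    start = pd.Timestamp(year=year, month=m0, day=d0)
    end_year = year + 1 if (m1, d1) < (m0, d0) else year
    end = pd.Timestamp(year=end_year, month=m1, day=d1)
    return (dates >= start) & (dates <= end)


def summarize_weather_window(
    daily: pd.DataFrame, window: str, years: range | list[int]
) -> pd.DataFrame:
    """Annual unweighted means of daily station weather within a seasonal window.

    ``daily`` must have columns ``station, date, tmean_c, prcp_mm``.  The mean
    is taken flat over all station-days in the window.  The winter window runs
    01 Nov–31 Mar and is indexed to the year in which it starts (the breeding
    season preceding that winter).  An empty window yields NaN with a warning.
    """
    if window not in SEASON_WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    rows = []
    for y in years:
        sel = daily.loc[_window_mask(daily["date"], window, y)]
        if sel.empty:
            warnings.warn(f"no station-days for window {window} in year {y}")
            rows.append((y, np.nan, np.nan))
        else:
            rows.append((y, sel["tmean_c"].mean(), sel["prcp_mm"].mean()))
    return pd.DataFrame(rows, columns=["year", f"{window}_temp", f"{window}_prcp"])


def effort_corrected_winter_count(winter_counts: pd.DataFrame) -> pd.Series:
    """Pooled birds-per-hour winter abundance index, per year.

    ``winter_counts`` has columns ``year, route, count, hours``.  Counts are
    summed over routes and divided by total survey hours (pooled ratio, not a
    mean of per-route ratios).
    """
    grouped = winter_counts.groupby("year").agg(count=("count", "sum"), hours=("hours", "sum"))
    if (grouped["hours"] <= 0).any():
        bad = grouped.index[grouped["hours"] <= 0].tolist()
        raise ValueError(f"zero total survey hours in year(s) {bad}")
    out = grouped["count"] / grouped["hours"]
    out.name = "winter_density"
    return out


def detrend_series(y: pd.Series | np.ndarray) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of ``y`` on its index.

    Missing values are ignored in the fit and propagate as NaN.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(len(y), dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values to de-trend")
    slope, intercept = np.polyfit(t[ok], y[ok], 1)
    resid = y - (intercept + slope * t)
    resid[~ok] = np.nan
    return resid


def zscore(y: pd.Series | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, SD 1 (population SD); returns (z, mean, sd).

    Constant series are rejected rather than silently zeroed.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    mean = float(y[ok].mean())
    sd = float(y[ok].std(ddof=SD_DDOF))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant series")
    return (y - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# CSV round-trips


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)


def write_encounters(enc: EncounterData, path) -> None:
    T = enc.n_occasions
    df = pd.DataFrame({"id": enc.ids, "sex": enc.sex, "age_first": enc.age_first})
    for t in range(T):
        df[f"h{t}"] = enc.histories[:, t]
    write_table(df, path)


def read_encounters(path) -> EncounterData:
    df = read_table(path)
    hcols = [c for c in df.columns if c.startswith("h")]
    hcols.sort(key=lambda c: int(c[1:]))
    return EncounterData(
        ids=df["id"].to_numpy(),
        sex=df["sex"].to_numpy(),
        age_first=df["age_first"].to_numpy(),
        histories=df[hcols].to_numpy(),
    )
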