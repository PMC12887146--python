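"""Temperature-humidity index (THI) computation, attachment and classing.

The THI combines dry-bulb temperature T (degrees C) and relative humidity
RH (%) into a single heat-load descriptor::

    THI = 1.8 T + 32 - (0.55 - 0.0055 RH) (1.8 T - 26)

Weather stations report T and RH at three standardised observation times
(09:00, 15:00, 21:00).  The THI assigned to a test-day record is the
arithmetic mean of the daily THI over a 6-day window (the test day and the
five preceding days), then discretised to the nearest even integer and
clamped into the 11 classes 60, 62, ..., 80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: standardised observation times required for a daily THI
OBSERVATION_TIMES = ("09:00", "15:00", "21:00")

THI_CLASS_MIN = 60
THI_CLASS_MAX = 80
#: the 11 even-integer THI classes
THI_CLASSES = tuple(range(THI_CLASS_MIN, THI_CLASS_MAX + 1, 2))


def compute_thi(temp_c, rel_humidity):
    """THI from dry-bulb temperature (deg C) and relative humidity (%).

    Vectorised; raises ``ValueError`` if any RH is outside [0, 100].
    At RH = 100 the correction term vanishes and THI = 1.8 T + 32.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must be in [0, 100]")
    thi = 1.8 * t + 32.0 - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


def daily_thi(weather: pd.DataFrame, require_times: bool = True) -> pd.DataFrame:
    """Average the per-observation THI into one value per station and day.

    ``weather`` needs columns ``station, date, time, temp_c, rel_humidity``;
    each (station, date) must carry all three standardised observation times.

    Returns a frame with columns ``station, date, thi``.
    """
    w = weather.copy()
    missing = {"station", "date", "time", "temp_c", "rel_humidity"} - set(w.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    w["date"] = pd.to_datetime(w["date"])
    if require_times:
        counts = w.groupby(["station", "date"])["time"].nunique()
        bad = counts[counts < len(OBSERVATION_TIMES)]
        if len(bad):
            gaps = ", ".join(f"{s}@{d.date()}" for s, d in bad.index[:5])
            raise ValueError(
                f"missing observation times for {len(bad)} station-days (e.g. {gaps})"
            )
    w["thi"] = compute_thi(w["temp_c"].to_numpy(), w["rel_humidity"].to_numpy())
    out = w.groupby(["station", "date"], as_index=False)["thi"].mean()
    return out


@dataclass
class ThiAssignment:
    """Per-record THI attachment: the 6 daily values and their mean."""

    record_index: np.ndarray
    daily_values: np.ndarray  # (n_records, window)
    thi: np.ndarray
    thi_class: np.ndarray


def attach_thi(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    herd_station: dict | pd.DataFrame,
    window: int = 6,
) -> tuple[pd.DataFrame, ThiAssignment]:
    """Attach the windowed-average THI (and its class) to each test-day record.

    The THI for a record is the mean of the daily THI at the herd's reference
    station over the test date and the ``window - 1`` preceding days.  Every
    day in the window must be present in ``weather``; otherwise an error is
    raised naming the gaps.

    Parameters
    ----------
    records : frame with columns ``herd, date`` (plus anything else).
    weather : raw weather table (see :func:`daily_thi`) or a pre-averaged
        frame with columns ``station, date, thi``.
    herd_station : mapping herd -> station id, or a two-column frame
        ``herd, station``.

    Returns the records with ``thi`` and ``thi_class`` columns added, plus
    the :class:`ThiAssignment` detail.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(herd_station, pd.DataFrame):
        herd_station = dict(zip(herd_station["herd"], herd_station["station"]))
    daily = weather if "thi" in weather.columns else daily_thi(weather)
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])

    series = {
        st: grp.set_index("date")["thi"].sort_index()
        for st, grp in daily.groupby("station")
    }

    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    n = len(rec)
    vals = np.full((n, window), np.nan)
    herds = rec["herd"].to_numpy()
    stations = np.array([herd_station.get(h) for h in herds], dtype=object)
    unknown = [h for h, s in zip(herds, stations) if s is None or s not in series]
    if unknown:
        raise ValueError(f"no reference station for herd {unknown[0]!r}")
    dates = rec["date"].to_numpy()
    for st in pd.unique(stations):
        sel = stations == st
        s = series[st]
        for lag in range(window):
            days = pd.DatetimeIndex(dates[sel]) - pd.Timedelta(days=window - 1 - lag)
            vals[sel, lag] = s.reindex(days).to_numpy()
    if np.isnan(vals).any():
        bad = pd.DatetimeIndex(
            np.concatenate(
                [
                    (pd.DatetimeIndex(dates) - pd.Timedelta(days=window - 1 - lag))[
                        np.isnan(vals[:, lag])
                    ]
                    for lag in range(window)
                ]
            )
        )
        gaps = sorted({str(d.date()) for d in bad})
        raise ValueError(f"daily THI missing for {len(gaps)} day(s): {gaps[:10]}")
    thi = vals.mean(axis=1)
    cls = thi_class(thi)
    rec["thi"] = thi
    rec["thi_class"] = cls
    assignment = ThiAssignment(
        record_index=np.asarray(rec.index), daily_values=vals, thi=thi, thi_class=cls
    )
    return rec, assignment


def thi_class(thi):
    """Round a THI to the nearest multiple of 2 and clamp into [60, 80].

    Ties at odd integers round half up (61 -> 62).  Values below 60 (above
    80) fall into the open-ended first (last) class.
    """
    x = np.asarray(thi, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("THI values must be finite")
    cls = 2.0 * np.floor(x / 2.0 + 0.5)
    cls = np.clip(cls, THI_CLASS_MIN, THI_CLASS_MAX)
    out = cls.astype(int)
    if out.ndim == 0:
        return int(out)
    return out
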