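"""Registry records and the period-analysis dataset.

Period analysis estimates survival from the person-time falling inside a
recent calendar window: everybody under follow-up at any point in the window
contributes, with delayed entry (left truncation) at the time they enter the
window.  This keeps the estimates close to the experience of recently
diagnosed patients while still borrowing long-term follow-up from earlier
diagnoses.

Registry rows are plain pandas DataFrames with the columns in
:data:`REGISTRY_COLUMNS`; the prepared dataset wraps the frame together with
entry/exit times on the time-since-diagnosis scale.

Conventions: dates are decimal years; the window upper end is *exclusive*
(a window ``[2007.0, 2014.0)`` means "under follow-up between 1 January 2007
and 31 December 2013"); same-day (zero follow-up) records are nudged to one
day (1/365.25 y) before clipping, since registries code same-day deaths and
zero-length intervals carry no likelihood information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REGISTRY_COLUMNS",
    "PeriodData",
    "read_registry",
    "first_tumour_filter",
    "make_period_dataset",
]

log = logging.getLogger(__name__)

#: canonical registry CSV columns
REGISTRY_COLUMNS = ("id", "cancer", "sex", "dep", "age_dx", "date_dx", "date_exit", "event")

_SAME_DAY = 1.0 / 365.25


def _validate_registry(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry frame missing columns: {missing}")
    df = df.copy()
    df["dep"] = df["dep"].astype(int)
    if not df["dep"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("deprivation must be a quintile in 1..5")
    if (df["age_dx"] < 0).any():
        raise ValueError("age at diagnosis must be >= 0")
    if (df["date_exit"] < df["date_dx"]).any():
        bad = df[df["date_exit"] < df["date_dx"]].iloc[0]
        raise ValueError(f"exit before diagnosis for id {bad['id']!r}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return df


def read_registry(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a registry CSV with columns ``id,cancer,sex,dep,age_dx,date_dx,date_exit,event``."""
    return _validate_registry(pd.read_csv(path, delimiter=delimiter))


def first_tumour_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (id, cancer type), only the earliest-diagnosed record.

    Ties on the diagnosis date break deterministically by input row order.
    """
    if len(records) == 0:
        return records.copy()
    records = records.reset_index(drop=True)
    order = records.sort_values(
        ["id", "cancer", "date_dx"], kind="stable"
    ).drop_duplicates(subset=["id", "cancer"], keep="first")
    return order.sort_index().reset_index(drop=True)


@dataclass
class PeriodData:
    """A left-truncated view of registry records for one analysis window.

    ``frame`` carries the retained registry rows plus columns ``t0`` (entry),
    ``t`` (exit) and ``d`` (event indicator after window censoring), all on
    the time-since-diagnosis scale.
    """

    frame: pd.DataFrame
    window: tuple[float, float]
    n_excluded: int = 0
    n_zero_length: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["d"].sum())

    def subset(self, cancer: str | None = None, sex: str | None = None) -> "PeriodData":
        f = self.frame
        if cancer is not None:
            f = f[f["cancer"] == cancer]
        if sex is not None:
            f = f[f["sex"] == sex]
        return PeriodData(f.reset_index(drop=True), self.window,
                          self.n_excluded, self.n_zero_length)


def make_period_dataset(
    records: pd.DataFrame,
    w_start: float = 2007.0,
    w_end: float = 2014.0,
) -> PeriodData:
    """Build the period-analysis dataset for the window ``[w_start, w_end)``.

    Excluded are records whose follow-up ended on or before the window opened
    and records diagnosed at or after the window closed.  Exits after the
    window are censored at ``w_end``.  Entry is delayed to the window start
    for pre-window diagnoses: ``t0 = max(0, w_start - date_dx)``.
    """
    if w_end <= w_start:
        raise ValueError(f"window end {w_end} must exceed start {w_start}")
    df = _validate_registry(records)

    exit_date = df["date_exit"].to_numpy(dtype=float).copy()
    dx = df["date_dx"].to_numpy(dtype=float)
    same_day = exit_date == dx
    exit_date[same_day] = dx[same_day] + _SAME_DAY

    keep = (exit_date > w_start) & (dx < w_end)
    n_excluded = int((~keep).sum())

    d = df["event"].to_numpy(dtype=int).copy()
    d[exit_date > w_end] = 0  # alive at window close as far as the window knows
    t0 = np.maximum(0.0, w_start - dx)
    t = np.minimum(exit_date, w_end) - dx

    positive = t > t0
    n_zero = int((keep & ~positive).sum())
    if n_zero:
        log.info("dropping %d zero-length rows after window clipping", n_zero)
    keep &= positive

    out = df.loc[keep].reset_index(drop=True)
    out["t0"] = t0[keep]
    out["t"] = t[keep]
    out["d"] = d[keep]
    return PeriodData(out, (float(w_start), float(w_end)), n_excluded, n_zero)
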