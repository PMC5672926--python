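"""Population life tables: expected (background) hazard and survival.

Relative-survival work needs, for every patient profile, the mortality the
general population of the same sex, deprivation quintile, age and calendar
year experiences.  These expected rates come as a rectangular table of annual
rates h*(sex, dep, age, year).  This module reads and validates such tables
and turns them into the three quantities the rest of the package consumes:

* ``expected_hazard``  — h* at a time since diagnosis, with the attained age
  capped at the oldest tabulated age and the attained calendar year clamped
  to the tabulated range (beyond the last year the last year's rates are
  reused, a constant-future assumption);
* ``expected_survival`` — S*(t) = exp(-∫ h*), evaluated *exactly* as a
  piecewise-exponential product over the segments on which attained age and
  attained year are both constant;
* ``expected_life_remaining`` — E* = ∫ S*(t) dt, again exact per segment.

Dates are decimal calendar years throughout (2007.0 = 1 January 2007) and
attained age uses ``floor(age_at_diagnosis + t)``, the usual rate-table
semantics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Profile",
    "LifeTable",
    "LifeTableError",
    "RaggedTableError",
    "read_life_table",
]

_REQUIRED_COLUMNS = ("sex", "dep", "age", "year", "rate")


class LifeTableError(ValueError):
    """Malformed life-table input."""


class RaggedTableError(LifeTableError):
    """A (sex, dep, age, year) combination is missing from the table."""


@dataclass(frozen=True)
class Profile:
    """One covariate pattern for which predictions are made.

    ``age_at_diagnosis`` may be continuous; ``deprivation`` runs from 1
    (least deprived) to 5 (most deprived); ``diagnosis_date`` is a decimal
    calendar year.
    """

    age_at_diagnosis: float
    sex: str
    deprivation: int
    diagnosis_date: float

    def __post_init__(self) -> None:
        if self.age_at_diagnosis < 0:
            raise ValueError("age_at_diagnosis must be >= 0")
        if self.deprivation not in (1, 2, 3, 4, 5):
            raise ValueError("deprivation must be a quintile in 1..5")


class LifeTable:
    """Annual mortality rates indexed by (sex, deprivation, age, year).

    Rates are hazards (events per person-year), not probabilities; a value
    slightly above 1 is legal at extreme ages.  The table must be complete
    over sexes x deprivation quintiles 1..5 x ages 0..age_cap x the year
    range; ragged input is rejected.  Attained ages above ``age_cap`` reuse
    the ``age_cap`` row and attained years outside the range are clamped.
    """

    def __init__(
        self,
        rates: np.ndarray,
        sexes: tuple[str, ...],
        min_year: int,
        *,
        age_min: int = 0,
    ) -> None:
        rates = np.asarray(rates, dtype=float)
        if rates.ndim != 4:
            raise LifeTableError("rates must have shape (sex, dep, age, year)")
        if rates.shape[1] != 5:
            raise LifeTableError("expected 5 deprivation quintiles")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise LifeTableError("all rates must be finite and >= 0")
        if age_min != 0:
            raise LifeTableError("tables must start at age 0")
        self._rates = rates
        self.sexes = tuple(sexes)
        self._sex_index = {s: i for i, s in enumerate(self.sexes)}
        self.min_year = int(min_year)
        self.age_cap = rates.shape[2] - 1
        self.max_year = self.min_year + rates.shape[3] - 1
        if self.age_cap < 99:
            raise LifeTableError(
                f"table must tabulate ages up to at least 99 (got {self.age_cap})"
            )

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        """Build a table from a long-format frame with columns sex, dep, age, year, rate."""
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise LifeTableError(f"missing required columns: {missing}")
        df = df.copy()
        df["dep"] = df["dep"].astype(int)
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["rate"] = df["rate"].astype(float)

        dup = df.duplicated(subset=["sex", "dep", "age", "year"])
        if dup.any():
            row = df[dup].iloc[0]
            raise LifeTableError(
                "duplicate life-table key "
                f"(sex={row['sex']!r}, dep={row['dep']}, age={row['age']}, year={row['year']})"
            )
        if (df["rate"] < 0).any():
            row = df[df["rate"] < 0].iloc[0]
            raise LifeTableError(
                f"negative rate {row['rate']} at (sex={row['sex']!r}, dep={row['dep']}, "
                f"age={row['age']}, year={row['year']})"
            )

        sexes = tuple(sorted(df["sex"].astype(str).unique()))
        deps = np.arange(1, 6)
        if set(df["dep"]) != set(deps):
            raise RaggedTableError(
                f"deprivation quintiles present: {sorted(set(df['dep']))}, expected 1..5"
            )
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        if ages[0] != 0:
            raise LifeTableError("table must start at age 0")
        years = np.arange(df["year"].min(), df["year"].max() + 1)

        expected = len(sexes) * 5 * len(ages) * len(years)
        if len(df) != expected:
            # locate the first missing key for a useful message
            full = pd.MultiIndex.from_product(
                [sexes, deps, ages, years], names=["sex", "dep", "age", "year"]
            )
            have = pd.MultiIndex.from_frame(df[["sex", "dep", "age", "year"]].astype(
                {"sex": str}))
            miss = full.difference(have)
            if len(miss) == 0:
                raise LifeTableError("row count inconsistent with key grid")
            first = miss[0]
            raise RaggedTableError(
                f"ragged table: first missing key (sex={first[0]!r}, dep={first[1]}, "
                f"age={first[2]}, year={first[3]}); {len(miss)} keys missing in total"
            )

        rates = np.empty((len(sexes), 5, len(ages), len(years)))
        sex_idx = df["sex"].astype(str).map({s: i for i, s in enumerate(sexes)}).to_numpy()
        rates[sex_idx, df["dep"].to_numpy() - 1,
              df["age"].to_numpy() - ages[0],
              df["year"].to_numpy() - years[0]] = df["rate"].to_numpy()
        return cls(rates, sexes, int(years[0]))

    @classmethod
    def read_csv(cls, path, *, delimiter: str = ",") -> "LifeTable":
        df = pd.read_csv(path, delimiter=delimiter)
        return cls.from_frame(df)

    @classmethod
    def constant(
        cls,
        rate: float,
        *,
        sexes: tuple[str, ...] = ("F", "M"),
        age_cap: int = 99,
        years: tuple[int, int] = (1981, 2015),
    ) -> "LifeTable":
        """A table with the same rate everywhere — handy for closed-form checks."""
        shape = (len(sexes), 5, age_cap + 1, years[1] - years[0] + 1)
        return cls(np.full(shape, float(rate)), sexes, years[0])

    def to_frame(self) -> pd.DataFrame:
        sx, dp, ag, yr = np.meshgrid(
            np.arange(len(self.sexes)), np.arange(1, 6),
            np.arange(self.age_cap + 1),
            np.arange(self.min_year, self.max_year + 1), indexing="ij",
        )
        return pd.DataFrame({
            "sex": np.asarray(self.sexes)[sx.ravel()],
            "dep": dp.ravel(), "age": ag.ravel(), "year": yr.ravel(),
            "rate": self._rates.ravel(),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # ------------------------------------------------------------------
    # lookups
    # ------------------------------------------------------------------
    def _sex(self, sex: str) -> int:
        try:
            return self._sex_index[sex]
        except KeyError:
            raise KeyError(f"sex {sex!r} not in table (has {self.sexes})") from None

    def rate_at(self, sex: str, dep: int, age, year) -> np.ndarray:
        """Rate rows with age capped at ``age_cap`` and year clamped to range."""
        age = np.minimum(np.asarray(age, dtype=int), self.age_cap)
        year = np.clip(np.asarray(year, dtype=int), self.min_year, self.max_year)
        return self._rates[self._sex(sex), dep - 1, age, year - self.min_year]

    def expected_hazard(self, profile: Profile, t) -> np.ndarray | float:
        """h* at time ``t`` (years) since diagnosis for ``profile``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        age = np.floor(profile.age_at_diagnosis + t)
        year = np.floor(profile.diagnosis_date + t)
        out = self.rate_at(profile.sex, profile.deprivation, age, year)
        return float(out) if out.ndim == 0 else out

    # ------------------------------------------------------------------
    # piecewise-exponential machinery
    # ------------------------------------------------------------------
    def segments(self, profile: Profile, tau: float):
        """Breakpoints and rates of the piecewise-constant expected hazard.

        Returns ``(bounds, rates)`` with ``bounds`` of length m+1 starting at
        0 and ending at ``tau``, and ``rates[i]`` the constant hazard on
        ``[bounds[i], bounds[i+1])``.  Breaks occur at every integer attained
        age and every 1 January.
        """
        if tau <= 0:
            raise ValueError("tau must be > 0")
        a0 = profile.age_at_diagnosis
        y0 = profile.diagnosis_date
        eps = 1e-9
        first_age = np.floor(a0 + eps) + 1.0 - a0
        first_year = np.floor(y0 + eps) + 1.0 - y0
        age_b = np.arange(first_age, tau, 1.0)
        year_b = np.arange(first_year, tau, 1.0)
        bounds = np.unique(np.concatenate([[0.0, tau], age_b, year_b]))
        bounds = bounds[(bounds >= 0.0) & (bounds <= tau)]
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        rates = self.rate_at(
            profile.sex, profile.deprivation,
            np.floor(a0 + mids), np.floor(y0 + mids),
        )
        return bounds, rates

    def expected_survival(self, profile: Profile, t) -> np.ndarray | float:
        """S*(t): exact piecewise-exponential expected survival."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        if t_arr.size == 0:
            return t_arr
        tmax = float(t_arr.max())
        if tmax == 0.0:
            out = np.ones_like(t_arr)
        else:
            bounds, rates = self.segments(profile, tmax)
            cumhaz = np.concatenate([[0.0], np.cumsum(rates * np.diff(bounds))])
            idx = np.clip(np.searchsorted(bounds, t_arr, side="right") - 1, 0, len(rates) - 1)
            H = cumhaz[idx] + rates[idx] * (t_arr - bounds[idx])
            out = np.exp(-H)
        if np.ndim(t) == 0:
            return float(out[0])
        return out

    def expected_life_remaining(
        self, profile: Profile, tau: float | None = None, *, tail: float = 20.0
    ) -> float:
        """E* = ∫0^tau S*(t) dt, exact per piecewise-exponential segment.

        ``tau`` defaults to running past the oldest tabulated age plus a
        ``tail`` of years so the integral is insensitive to the cap.
        """
        if tau is None:
            tau = self.age_cap + 1.0 - profile.age_at_diagnosis + tail
        if tau <= 0:
            raise ValueError("tau must be > 0")
        bounds, rates = self.segments(profile, float(tau))
        widths = np.diff(bounds)
        seg_haz = rates * widths
        entry_surv = np.exp(-np.concatenate([[0.0], np.cumsum(seg_haz[:-1])]))
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(
                rates > 0,
                entry_surv * -np.expm1(-seg_haz) / np.where(rates > 0, rates, 1.0),
                entry_surv * widths,
            )
        return float(contrib.sum())


def read_life_table(path, dialect: dict | None = None) -> LifeTable:
    """Read and validate a delimited life table.

    ``dialect`` may override ``delimiter`` and map non-standard column names,
    e.g. ``{"delimiter": "\\t", "columns": {"imd_quintile": "dep"}}``.
    """
    dialect = dialect or {}
    df = pd.read_csv(path, delimiter=dialect.get("delimiter", ","))
    renames = dialect.get("columns")
    if renames:
        df = df.rename(columns=renames)
    return LifeTable.from_frame(df)
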