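"""Age standardisation and population totals.

Loss in expectation of life is strongly age-dependent, so group summaries
are weighted averages of age-specific estimates.  The default is *internal*
standardisation: weights proportional to the age distribution of each
deprivation group's own diagnoses in the reference year (2013), so each
group's summary reflects its own case mix.  External schemes (the pooled
2013 age distribution across groups, or custom bands such as the
International Cancer Survival Standard, supplied as a CSV) are available for
sensitivity analyses.

Totals scale the average up to the population: total life years lost =
number of patients diagnosed in the reference year x mean LEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectancy import LifeExpectancyResult, age_profile, loss_in_expectation
from .lifetables import LifeTable, Profile

__all__ = [
    "WeightScheme",
    "StandardizedSummary",
    "internal_weights",
    "pooled_weights",
    "custom_weights",
    "read_weights_csv",
    "standardized_average",
    "total_years_lost",
    "summary_table",
]


@dataclass(frozen=True)
class WeightScheme:
    """Normalised weights over age strata.

    ``weights`` maps a stratum key to its weight.  Keys are single years of
    age (int) by default; custom banded schemes use ``(lo, hi)`` tuples with
    ``hi`` exclusive.  Weights are normalised to sum to one on construction.
    """

    kind: str
    weights: dict
    reference_year: int = 2013

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weight scheme has no strata")
        vals = np.asarray(list(self.weights.values()), dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("weights must be finite and >= 0")
        total = vals.sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        object.__setattr__(
            self, "weights",
            {k: float(v) / total for k, v in self.weights.items()},
        )

    @property
    def strata(self) -> list:
        return sorted(self.weights)

    def evaluation_age(self, stratum) -> float:
        """The age at which to evaluate age-specific estimates for a stratum."""
        if isinstance(stratum, tuple):
            lo, hi = stratum
            return 0.5 * (lo + hi)
        return float(stratum)


def _cohort(records: pd.DataFrame, year: int) -> pd.DataFrame:
    dx_year = np.floor(records["date_dx"].to_numpy(dtype=float)).astype(int)
    return records.loc[dx_year == year]


def internal_weights(records: pd.DataFrame, dep: int, year: int = 2013) -> WeightScheme:
    """Weights from the age distribution of one deprivation group's ``year`` diagnoses."""
    sub = _cohort(records, year)
    sub = sub.loc[sub["dep"].astype(int) == dep]
    if len(sub) == 0:
        raise ValueError(f"no {year} diagnoses in deprivation group {dep}")
    counts = np.floor(sub["age_dx"].to_numpy(dtype=float)).astype(int)
    uniq, n = np.unique(counts, return_counts=True)
    return WeightScheme("internal", dict(zip(uniq.tolist(), n.tolist())), year)


def pooled_weights(records: pd.DataFrame, year: int = 2013) -> WeightScheme:
    """Weights from the ``year`` age distribution pooled over all deprivation groups."""
    sub = _cohort(records, year)
    if len(sub) == 0:
        raise ValueError(f"no {year} diagnoses in the cohort")
    counts = np.floor(sub["age_dx"].to_numpy(dtype=float)).astype(int)
    uniq, n = np.unique(counts, return_counts=True)
    return WeightScheme("external_pooled", dict(zip(uniq.tolist(), n.tolist())), year)


def custom_weights(bands: dict, year: int = 2013) -> WeightScheme:
    """External weights over arbitrary ``(lo, hi)`` age bands (hi exclusive)."""
    return WeightScheme("external_custom", dict(bands), year)


def read_weights_csv(path, year: int = 2013) -> WeightScheme:
    """Read banded weights from a CSV with columns ``lo,hi,weight``."""
    df = pd.read_csv(path)
    missing = {"lo", "hi", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"weight CSV missing columns: {sorted(missing)}")
    bands = {(float(r.lo), float(r.hi)): float(r.weight) for r in df.itertuples()}
    return custom_weights(bands, year)


def standardized_average(
    results_by_stratum: dict,
    scheme: WeightScheme,
    *,
    pll_mode: str = "mean_of_ratios",
) -> tuple[float, float]:
    """Weighted mean LEL and PLL over age strata.

    ``results_by_stratum`` maps each stratum key of ``scheme`` to a
    :class:`~lifelost.expectancy.LifeExpectancyResult`.  ``pll_mode``
    chooses between the weighted mean of age-specific PLL ratios
    (``"mean_of_ratios"``, the default) and the ratio of weighted means
    sum(w*LEL)/sum(w*E*) (``"ratio_of_means"``).
    """
    have = set(results_by_stratum)
    want = set(scheme.weights)
    if have != want:
        raise ValueError(
            "strata mismatch between results and weights; "
            f"symmetric difference: {sorted(have ^ want, key=str)}")
    if pll_mode not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown pll_mode {pll_mode!r}")
    mean_lel = sum(w * results_by_stratum[k].lel for k, w in scheme.weights.items())
    if pll_mode == "mean_of_ratios":
        mean_pll = sum(w * results_by_stratum[k].pll for k, w in scheme.weights.items())
    else:
        mean_estar = sum(w * results_by_stratum[k].e_star
                         for k, w in scheme.weights.items())
        mean_pll = mean_lel / mean_estar
    return float(mean_lel), float(mean_pll)


def total_years_lost(n_patients: float, mean_lel: float) -> float:
    """Total life years lost for an annual cohort: count x average LEL."""
    if n_patients < 0:
        raise ValueError("patient count must be >= 0")
    return float(n_patients) * float(mean_lel)


@dataclass(frozen=True)
class StandardizedSummary:
    """One summary row: cancer x sex x deprivation group."""

    cancer: str
    sex: str
    deprivation: int
    mean_lel: float
    mean_pll: float
    n_ref_year: int
    total_years_lost: float


def _scheme_for(records, dep, weights, year):
    if isinstance(weights, WeightScheme):
        return weights
    if weights == "internal":
        return internal_weights(records, dep, year)
    if weights == "pooled":
        return pooled_weights(records, year)
    raise ValueError(f"unknown weight scheme {weights!r}")


def summary_table(
    models: dict,
    table: LifeTable,
    cohort: pd.DataFrame,
    *,
    weights="internal",
    year: int = 2013,
    dx_year: float | None = None,
    tau: float | None = None,
    average: str = "by-age",
    pll_mode: str = "mean_of_ratios",
    order: int = 15,
) -> pd.DataFrame:
    """Standardised means and totals per cancer x sex x deprivation group.

    ``models`` maps ``(cancer, sex)`` to fitted results; ``cohort`` is the
    registry frame the reference-year counts and weights come from.
    ``average="per-patient"`` evaluates the loss at every reference-year
    patient's exact age instead of single-year strata.  Raises if a
    (cancer, sex) stratum present in the cohort has no model; deprivation
    groups with no reference-year diagnoses are omitted (blank, not zero)
    unless an explicit external :class:`WeightScheme` is supplied.
    """
    if dx_year is None:
        dx_year = float(year)
    rows = []
    strata = cohort[["cancer", "sex"]].drop_duplicates().itertuples(index=False)
    for cancer, sex in sorted(strata):
        if (cancer, sex) not in models:
            raise ValueError(f"no fitted model for stratum ({cancer!r}, {sex!r})")
        res = models[(cancer, sex)]
        sub = cohort[(cohort["cancer"] == cancer) & (cohort["sex"] == sex)]
        ref = _cohort(sub, year)
        for dep in (1, 2, 3, 4, 5):
            n_ref = int((ref["dep"].astype(int) == dep).sum())
            if n_ref == 0 and not isinstance(weights, WeightScheme):
                continue  # group absent from the reference year: no row
            if average == "per-patient":
                ages = ref.loc[ref["dep"].astype(int) == dep, "age_dx"].to_numpy(float)
                if len(ages) == 0:
                    raise ValueError(f"no {year} diagnoses in deprivation group {dep}")
                lels, plls = [], []
                for a in ages:
                    r = loss_in_expectation(
                        res, table, Profile(float(a), sex, dep, dx_year),
                        tau, order=order)
                    lels.append(r.lel)
                    plls.append(r.pll)
                mean_lel = float(np.mean(lels))
                mean_pll = float(np.mean(plls))
            elif average == "by-age":
                scheme = _scheme_for(sub, dep, weights, year)
                eval_ages = [scheme.evaluation_age(k) for k in scheme.strata]
                profile_results = age_profile(
                    res, table, eval_ages, sex, dep, dx_year, tau, order=order)
                by_stratum = dict(zip(scheme.strata, profile_results))
                mean_lel, mean_pll = standardized_average(
                    by_stratum, scheme, pll_mode=pll_mode)
            else:
                raise ValueError(f"unknown averaging mode {average!r}")
            rows.append(StandardizedSummary(
                cancer=cancer, sex=sex, deprivation=dep,
                mean_lel=mean_lel, mean_pll=mean_pll,
                n_ref_year=n_ref,
                total_years_lost=total_years_lost(n_ref, mean_lel),
            ))
    return pd.DataFrame([r.__dict__ for r in rows])
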