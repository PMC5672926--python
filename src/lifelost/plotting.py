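"""Optional matplotlib figures; CSV output remains the canonical artifact.

Two figure styles mirror the usual presentation of these analyses: loss in
expectation of life (and the general-population expected-life curve) across
age at diagnosis for selected deprivation groups, and the population totals
as count x mean bar panels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_age_profile", "plot_totals"]


def plot_age_profile(profiles_by_dep: dict, ax=None, *, measure: str = "lel"):
    """Plot LEL (or PLL) across age at diagnosis, one line per group.

    ``profiles_by_dep`` maps a deprivation label to a list of
    :class:`~lifelost.expectancy.LifeExpectancyResult`.  For ``measure="lel"``
    a dashed line shows expected remaining life E* of the first group.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, results in profiles_by_dep.items():
        ages = [r.profile.age_at_diagnosis for r in results]
        if measure == "lel":
            ax.plot(ages, [r.lel for r in results], label=f"dep {label}")
        elif measure == "pll":
            ax.plot(ages, [100 * r.pll for r in results], label=f"dep {label}")
        else:
            raise ValueError(f"unknown measure {measure!r}")
    if measure == "lel":
        first = next(iter(profiles_by_dep.values()))
        ax.plot([r.profile.age_at_diagnosis for r in first],
                [r.e_star for r in first], "k--", label="expected (no cancer)")
        ax.set_ylabel("loss in expectation of life (years)")
    else:
        ax.set_ylabel("proportion of life lost (%)")
    ax.set_xlabel("age at diagnosis (years)")
    ax.legend()
    return ax


def plot_totals(summary, axes=None):
    """Three-panel bar figure: 2013 counts, mean LEL, and total years lost.

    ``summary`` is the frame produced by
    :func:`~lifelost.standardize.summary_table` for one cancer and sex.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 4))
    deps = summary["deprivation"].to_numpy()
    panels = [("n_ref_year", "patients diagnosed (reference year)"),
              ("mean_lel", "mean loss in expectation of life (y)"),
              ("total_years_lost", "total life years lost")]
    for ax, (col, title) in zip(np.ravel(axes), panels):
        ax.bar(deps, summary[col].to_numpy())
        ax.set_xlabel("deprivation quintile")
        ax.set_title(title, fontsize=9)
    return axes
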