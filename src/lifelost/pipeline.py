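"""Config-driven pipeline: simulate -> prepare -> fit -> predict -> standardise.

The pipeline is the scripted equivalent of the full analysis: it takes a
YAML (or dict) configuration, runs each stage with logging, and leaves a
deterministic artifact directory — fitted model JSONs, the full-precision
summary CSV, presentation tables, and a run log.  A state marker records
completed stages so a partially failed run can resume.

Rounding happens only at presentation: the summary CSV is full precision
and the totals in the presentation table are recomputed from unrounded
means, so multiplying a *printed* group size by a *printed* 2-dp mean will
disagree with the printed total by up to ~0.1% — that is expected, not a
bug.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lifetables import LifeTable, read_life_table
from .model import FitConfig, FlexParamRelSurv
from .period import first_tumour_filter, make_period_dataset, read_registry
from .simulate import (
    default_scenario,
    exponential_scenario,
    make_life_table,
    reversal_scenario,
    simulate_registry,
)
from .standardize import read_weights_csv, summary_table

__all__ = ["PipelineConfigError", "validate_config", "run_pipeline", "render_tables"]

log = logging.getLogger(__name__)

_SCENARIOS = {
    "default": default_scenario,
    "exponential": exponential_scenario,
    "reversal": reversal_scenario,
}

_DEFAULTS = {
    "seed": 20130101,
    "scenario": "default",
    "registry": None,
    "lifetable": None,
    "window": [2007.0, 2014.0],
    "fit": {},
    "weights": "internal",
    "reference_year": 2013,
    "dx_year": None,
    "tau": None,
    "quad_order": 15,
    "average": "by-age",
    "pll_mode": "mean_of_ratios",
    "plots": False,
    "log_level": "INFO",
}


class PipelineConfigError(ValueError):
    """The pipeline configuration failed schema validation."""


def validate_config(config: dict | str | Path) -> dict:
    """Normalise and schema-check a pipeline configuration before any work."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineConfigError("configuration must be a mapping")
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise PipelineConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = {**_DEFAULTS, **config}

    if cfg["registry"] is not None and cfg["lifetable"] is None:
        raise PipelineConfigError(
            "a registry path requires a lifetable path (no scenario to tabulate)")
    if cfg["registry"] is None and cfg["scenario"] not in _SCENARIOS:
        raise PipelineConfigError(
            f"unknown scenario {cfg['scenario']!r}; choose from {sorted(_SCENARIOS)}")
    w = cfg["window"]
    if (not isinstance(w, (list, tuple)) or len(w) != 2
            or float(w[1]) <= float(w[0])):
        raise PipelineConfigError("window must be [start, end] with end > start")
    if not isinstance(cfg["fit"], dict):
        raise PipelineConfigError("fit must be a mapping of FitConfig fields")
    try:
        fit_kwargs = dict(cfg["fit"])
        if "td" in fit_kwargs:
            fit_kwargs["td"] = tuple(fit_kwargs["td"])
        FitConfig(**fit_kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid fit settings: {exc}") from exc
    if cfg["weights"] not in ("internal", "pooled") and not isinstance(
            cfg["weights"], (str, Path)):
        raise PipelineConfigError("weights must be internal, pooled, or a CSV path")
    if cfg["average"] not in ("by-age", "per-patient"):
        raise PipelineConfigError("average must be by-age or per-patient")
    if not isinstance(cfg["seed"], int):
        raise PipelineConfigError("seed must be an integer")
    return cfg


def _stage(state: dict, state_path: Path, name: str) -> None:
    state["completed"].append(name)
    state_path.write_text(json.dumps(state, indent=1))


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run every stage and write the artifact set to ``out_dir``.

    Artifacts: ``registry.csv``/``lifetable.csv`` (when simulated),
    ``model_<cancer>_<sex>.json`` per stratum, ``summary.csv`` (full
    precision), ``table_means.csv`` / ``table_totals.csv`` (presentation),
    ``run.json`` (config echo, versions, seed) and ``state.json`` (stage
    marker).  Any stage error aborts with the stage name in the message;
    the state marker shows how far the run got.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=cfg["log_level"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state_path = out / "state.json"
    state = {"completed": [], "config": {k: str(v) for k, v in cfg.items()}}

    stage = "simulate"
    try:
        if cfg["registry"] is None:
            scenario = _SCENARIOS[cfg["scenario"]](cfg["seed"])
            registry = simulate_registry(scenario)
            table = make_life_table(scenario)
            registry.to_csv(out / "registry.csv", index=False)
            table.write_csv(out / "lifetable.csv")
        else:
            registry = read_registry(cfg["registry"])
            table = read_life_table(cfg["lifetable"])
        log.info("stage %s: %d registry rows", stage, len(registry))
        _stage(state, state_path, stage)

        stage = "prepare"
        w0, w1 = float(cfg["window"][0]), float(cfg["window"][1])
        period = make_period_dataset(first_tumour_filter(registry), w0, w1)
        log.info("stage %s: %d rows in window, %d excluded",
                 stage, len(period), period.n_excluded)
        _stage(state, state_path, stage)

        stage = "fit"
        fit_kwargs = dict(cfg["fit"])
        if "td" in fit_kwargs:
            fit_kwargs["td"] = tuple(fit_kwargs["td"])
        fit_config = FitConfig(**fit_kwargs)
        models = {}
        strata = period.frame[["cancer", "sex"]].drop_duplicates()
        for cancer, sex in sorted(strata.itertuples(index=False)):
            sub = period.subset(cancer=cancer, sex=sex)
            res = FlexParamRelSurv(sub, table, fit_config).fit()
            models[(cancer, sex)] = res
            res.to_json(out / f"model_{cancer}_{sex}.json")
            log.info("stage %s: (%s, %s) llf=%.2f converged=%s",
                     stage, cancer, sex, res.llf, res.converged)
        _stage(state, state_path, stage)

        stage = "standardize"
        weights = cfg["weights"]
        if weights not in ("internal", "pooled"):
            weights = read_weights_csv(weights, cfg["reference_year"])
        summary = summary_table(
            models, table, registry,
            weights=weights,
            year=cfg["reference_year"],
            dx_year=cfg["dx_year"],
            tau=cfg["tau"],
            average=cfg["average"],
            pll_mode=cfg["pll_mode"],
            order=cfg["quad_order"],
        )
        summary.to_csv(out / "summary.csv", index=False)
        _stage(state, state_path, stage)

        stage = "render"
        render_tables(summary, out)
        if cfg["plots"]:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            from .plotting import plot_totals

            for (cancer, sex), group in summary.groupby(["cancer", "sex"]):
                axes = plot_totals(group.sort_values("deprivation"))
                fig = np.ravel(axes)[0].figure
                fig.tight_layout()
                fig.savefig(out / f"totals_{cancer}_{sex}.png", dpi=120)
                plt.close(fig)
        _stage(state, state_path, stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "run.json").write_text(json.dumps({
        "lifelost_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg["seed"],
        "config": {k: str(v) for k, v in cfg.items()},
    }, indent=1))
    return out


def render_tables(summary: pd.DataFrame, out_dir: str | Path) -> None:
    """Presentation CSVs: means per group, and counts/means/totals per group.

    Means are rounded to 2 dp *here only*; the totals column is recomputed
    from the unrounded means.  Strata a sex does not contribute to are left
    as blank cells, not zeros.
    """
    out = Path(out_dir)

    means = summary.copy()
    means["mean_pll_pct"] = 100.0 * means["mean_pll"]
    wide = means.pivot_table(index=["cancer", "sex"], columns="deprivation",
                             values=["mean_lel", "mean_pll_pct"])
    wide.columns = [f"{m}_dep{d}" for m, d in wide.columns]
    wide.round(2).to_csv(out / "table_means.csv")

    rows = []
    for cancer in sorted(summary["cancer"].unique()):
        for dep in (1, 2, 3, 4, 5):
            row = {"cancer": cancer, "deprivation": dep}
            for sex in ("M", "F"):
                sub = summary[(summary["cancer"] == cancer)
                              & (summary["sex"] == sex)
                              & (summary["deprivation"] == dep)]
                label = "males" if sex == "M" else "females"
                if len(sub) == 0:
                    row[f"n_2013_{label}"] = ""
                    row[f"mean_lel_{label}"] = ""
                    row[f"total_years_{label}"] = ""
                else:
                    r = sub.iloc[0]
                    row[f"n_2013_{label}"] = int(r["n_ref_year"])
                    row[f"mean_lel_{label}"] = round(float(r["mean_lel"]), 2)
                    row[f"total_years_{label}"] = int(round(r["total_years_lost"]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "table_totals.csv", index=False)
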