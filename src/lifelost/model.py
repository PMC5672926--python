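"""Flexible parametric relative-survival (excess hazard) model.

The model places a restricted cubic spline of log time on the log cumulative
*excess* hazard scale:

    eta(t | x) = ln Lambda_E(t | x)
               = s(ln t; gamma) + x' beta + sum_l s_l(ln t; delta_l) x_l

where ``x`` holds deprivation dummies, a restricted cubic spline of age at
diagnosis and (optionally) their interaction, and the ``s_l`` terms give
deprivation and age *time-dependent* effects (non-proportional excess
hazards).  The excess hazard follows as

    lambda_E(t | x) = Lambda_E(t | x) * (d eta / d ln t) / t

and relative survival as ``R(t | x) = exp(-Lambda_E(t | x))``.  Because the
spline tails are linear in ``ln t``, the fitted log cumulative excess hazard
extrapolates linearly beyond the last knot (a Weibull-like tail); combined
with the expected survival from a life table this is what makes life-time
extrapolation of all-cause survival stable.

Estimation is maximum likelihood on a left-truncated (period-analysis)
dataset.  With entry time t0, exit time t, event indicator d and expected
hazard h* evaluated at the subject's attained age and calendar year at exit,
each subject contributes

    d * ln( h* + lambda_E(t) ) - Lambda_E(t) + Lambda_E(t0),

the expected cumulative hazard terms being parameter free and dropped.
Flexible splines can make ``lambda_E`` transiently negative; when the total
hazard ``h* + lambda_E`` falls below a small floor the log is replaced by a
smooth softplus surrogate during optimisation and any violations remaining
at the optimum are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .lifetables import LifeTable, Profile
from .period import PeriodData
from .splines import SplineSpec, knots_from_quantiles, rcs_basis, rcs_deriv

__all__ = [
    "FitConfig",
    "DesignInfo",
    "FlexParamRelSurv",
    "RelSurvResults",
    "ConvergenceError",
    "build_design",
    "log_likelihood",
    "fit_relsurv",
]

_DEP_DUMMIES = (2, 3, 4, 5)


class ConvergenceError(RuntimeError):
    """The optimizer did not reach the requested gradient tolerance."""


@dataclass
class FitConfig:
    """Model complexity and optimizer settings.

    ``df_baseline`` spline degrees of freedom for the baseline log-time
    effect (df d uses d+1 knots); ``df_age`` for the non-linear age effect;
    ``df_td`` for each time-dependent effect.  ``td`` selects which covariate
    blocks get time-dependent effects (subset of {"dep", "age"}).
    """

    df_baseline: int = 5
    df_age: int = 3
    df_td: int = 3
    td: tuple[str, ...] = ("dep", "age")
    dep_effects: bool = True
    interaction: bool = True
    standardize: bool = True
    guard_eps: float = 1e-10
    gtol: float = 1e-6
    ctol: float = 1e-4
    maxiter: int = 500

    def __post_init__(self) -> None:
        if self.df_baseline < 1 or self.df_td < 1:
            raise ValueError("df_baseline and df_td must be >= 1")
        if self.df_age < 0:
            raise ValueError("df_age must be >= 0 (0 drops the age effect)")
        if self.gtol <= 0 or self.ctol <= 0:
            raise ValueError("tolerances must be > 0")
        unknown = set(self.td) - {"dep", "age"}
        if unknown:
            raise ValueError(f"unknown time-dependent blocks: {sorted(unknown)}")


@dataclass
class DesignInfo:
    """Frozen covariate layout: everything needed to rebuild a design row.

    Column order (documented contract): intercept; baseline spline of ln t;
    deprivation dummies (levels 2..5 vs least deprived); age spline columns;
    age-spline x deprivation interaction columns; time-dependent spline
    columns for each deprivation dummy; time-dependent spline columns for
    each age-spline column.  ``center``/``scale`` record the optional column
    standardisation applied at fit time so predictions are invariant to it.
    """

    baseline: SplineSpec
    age_spec: SplineSpec | None = None
    dep_effects: bool = True
    interaction: bool = True
    td_dep: SplineSpec | None = None
    td_age: SplineSpec | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.interaction and not (self.dep_effects and self.age_spec):
            raise ValueError("interaction requires deprivation effects and an age spline")
        if self.td_dep is not None and not self.dep_effects:
            raise ValueError("time-dependent deprivation effect requires dep_effects")
        if self.td_age is not None and self.age_spec is None:
            raise ValueError("time-dependent age effect requires an age spline")

    @property
    def column_names(self) -> list[str]:
        names = ["const"]
        names += [f"lnt_b{j}" for j in range(1, self.baseline.df + 1)]
        if self.dep_effects:
            names += [f"dep{d}" for d in _DEP_DUMMIES]
        if self.age_spec is not None:
            names += [f"age_b{j}" for j in range(1, self.age_spec.df + 1)]
        if self.interaction:
            names += [f"dep{d}:age_b{j}"
                      for d in _DEP_DUMMIES
                      for j in range(1, self.age_spec.df + 1)]
        if self.td_dep is not None:
            names += [f"dep{d}:lnt_td{j}"
                      for d in _DEP_DUMMIES
                      for j in range(1, self.td_dep.df + 1)]
        if self.td_age is not None:
            names += [f"age_b{j}:lnt_td{m}"
                      for j in range(1, self.age_spec.df + 1)
                      for m in range(1, self.td_age.df + 1)]
        return names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def td_column_mask(self) -> np.ndarray:
        """Boolean mask of the time-dependent-effect columns."""
        mask = np.zeros(self.n_columns, dtype=bool)
        n_td = 0
        if self.td_dep is not None:
            n_td += len(_DEP_DUMMIES) * self.td_dep.df
        if self.td_age is not None:
            n_td += self.age_spec.df * self.td_age.df
        if n_td:
            mask[-n_td:] = True
        return mask


def build_design(info: DesignInfo, t, dep, age) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix ``X`` and its derivative w.r.t. ``ln t`` at (t, dep, age).

    ``t`` must be strictly positive; ``dep`` and ``age`` broadcast against it.
    Returns ``(X, dX)`` of shape (n, p) in the documented column order, with
    the fit-time standardisation (if any) applied.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    dep = np.broadcast_to(np.asarray(dep, dtype=int), t.shape)
    age = np.broadcast_to(np.asarray(age, dtype=float), t.shape)
    lnt = np.log(t)
    n = t.shape[0]

    parts: list[np.ndarray] = [np.ones((n, 1))]
    dparts: list[np.ndarray] = [np.zeros((n, 1))]

    B = rcs_basis(lnt, info.baseline)
    dB = rcs_deriv(lnt, info.baseline)
    parts.append(B)
    dparts.append(dB)

    zdep = np.empty((n, 0))
    if info.dep_effects:
        zdep = (dep[:, None] == np.asarray(_DEP_DUMMIES)).astype(float)
        parts.append(zdep)
        dparts.append(np.zeros_like(zdep))

    zage = np.empty((n, 0))
    if info.age_spec is not None:
        zage = rcs_basis(age, info.age_spec)
        parts.append(zage)
        dparts.append(np.zeros_like(zage))

    if info.interaction:
        inter = (zdep[:, :, None] * zage[:, None, :]).reshape(n, -1)
        parts.append(inter)
        dparts.append(np.zeros_like(inter))

    if info.td_dep is not None:
        Btd = rcs_basis(lnt, info.td_dep)
        dBtd = rcs_deriv(lnt, info.td_dep)
        parts.append((zdep[:, :, None] * Btd[:, None, :]).reshape(n, -1))
        dparts.append((zdep[:, :, None] * dBtd[:, None, :]).reshape(n, -1))

    if info.td_age is not None:
        Btd = rcs_basis(lnt, info.td_age)
        dBtd = rcs_deriv(lnt, info.td_age)
        parts.append((zage[:, :, None] * Btd[:, None, :]).reshape(n, -1))
        dparts.append((zage[:, :, None] * dBtd[:, None, :]).reshape(n, -1))

    X = np.hstack(parts)
    dX = np.hstack(dparts)
    if info.center is not None:
        X = (X - info.center) / info.scale
        dX = dX / info.scale
    return X, dX


def _smooth_log(u: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """C-infinity surrogate for ln(u) that stays finite as u -> 0-.

    Replaces u by eps*softplus(u/eps) (≈ u for u >> eps, ≈ eps*e^{u/eps} for
    u << 0) before taking the log.  Returns (value, d value / d u).
    """
    u = np.asarray(u, dtype=float)
    val = np.empty_like(u)
    dval = np.empty_like(u)
    big = u > 40.0 * eps
    val[big] = np.log(u[big])
    dval[big] = 1.0 / u[big]
    s = u[~big] / eps
    low = s < -30.0  # softplus(s) ~ e^s: log underflows, handle analytically
    sp = np.logaddexp(0.0, np.maximum(s, -30.0))
    v = np.log(eps) + np.where(low, s, np.log(sp))
    dv = np.where(low, 1.0 / eps, 1.0 / (1.0 + np.exp(-np.maximum(s, -30.0))) / (eps * sp))
    val[~big] = v
    dval[~big] = dv
    return val, dval


class FlexParamRelSurv:
    """Model object: a period dataset + life table + covariate layout.

    Parameters
    ----------
    data
        A :class:`~lifelost.period.PeriodData` (or a frame with columns
        ``sex, dep, age_dx, date_dx, t0, t, d``).
    life_table
        Background mortality rates used for the expected hazard at event
        times.
    config
        A :class:`FitConfig`; keyword arguments override its fields.

    Knots are placed from the data unless given explicitly: baseline (and
    time-dependent) knots at quantiles of log *event* times, age knots at
    the 2nd/98th percentiles of age at diagnosis with equally spaced interior
    quantiles.
    """

    def __init__(
        self,
        data: PeriodData | pd.DataFrame,
        life_table: LifeTable,
        config: FitConfig | None = None,
        *,
        baseline_knots=None,
        age_knots=None,
        td_knots=None,
        **overrides,
    ) -> None:
        if config is None:
            config = FitConfig()
        if overrides:
            config = replace(config, **overrides)
        self.config = config
        self.life_table = life_table

        frame = data.frame if isinstance(data, PeriodData) else data
        needed = {"sex", "dep", "age_dx", "date_dx", "t0", "t", "d"}
        missing = needed - set(frame.columns)
        if missing:
            raise ValueError(f"period dataset missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValueError("empty period dataset")
        self.frame = frame.reset_index(drop=True)

        t = self.frame["t"].to_numpy(dtype=float)
        t0 = self.frame["t0"].to_numpy(dtype=float)
        d = self.frame["d"].to_numpy(dtype=int)
        # zero-exposure rows (t0 == t) are tolerated: they contribute nothing
        # to the cumulative-hazard terms
        if np.any(t <= 0) or np.any(t0 < 0) or np.any(t < t0):
            raise ValueError("period dataset must satisfy 0 <= t0 <= t and t > 0")
        self.t, self.t0, self.d = t, t0, d
        self.nobs = len(t)
        self.n_events = int(d.sum())

        event_lnt = np.log(t[d == 1])
        needs_events = (baseline_knots is None
                        or (config.td and td_knots is None))
        if event_lnt.size == 0 and needs_events:
            raise ValueError("no events in dataset; cannot place spline knots")

        baseline = (SplineSpec(tuple(baseline_knots)) if baseline_knots is not None
                    else knots_from_quantiles(event_lnt, config.df_baseline))
        age_spec = None
        cfg_age = config.df_age
        ages = self.frame["age_dx"].to_numpy(dtype=float)
        if cfg_age and (age_knots is not None or np.unique(ages).size > 1):
            age_spec = (SplineSpec(tuple(age_knots)) if age_knots is not None
                        else knots_from_quantiles(ages, cfg_age,
                                                  boundary_quantiles=(0.02, 0.98)))
        td_spec = None
        if config.td:
            td_spec = (SplineSpec(tuple(td_knots)) if td_knots is not None
                       else knots_from_quantiles(event_lnt, config.df_td))

        dep_effects = config.dep_effects and self.frame["dep"].nunique() > 1
        self.info = DesignInfo(
            baseline=baseline,
            age_spec=age_spec,
            dep_effects=dep_effects,
            interaction=config.interaction and dep_effects and age_spec is not None,
            td_dep=td_spec if ("dep" in config.td and dep_effects) else None,
            td_age=td_spec if ("age" in config.td and age_spec is not None) else None,
        )
        self._build_arrays()

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        life_table: LifeTable,
        *,
        window: tuple[float, float] = (2007.0, 2014.0),
        config: FitConfig | None = None,
        **overrides,
    ) -> "FlexParamRelSurv":
        """Convenience constructor straight from registry records."""
        from .period import first_tumour_filter, make_period_dataset

        period = make_period_dataset(first_tumour_filter(records), *window)
        return cls(period, life_table, config=config, **overrides)

    # ------------------------------------------------------------------
    def _build_arrays(self) -> None:
        dep = self.frame["dep"].to_numpy(dtype=int)
        age = self.frame["age_dx"].to_numpy(dtype=float)

        X, dX = build_design(replace(self.info, center=None, scale=None),
                             self.t, dep, age)
        if self.config.standardize:
            center = X.mean(axis=0)
            scale = X.std(axis=0)
            center[0] = 0.0
            scale[0] = 1.0
            scale[scale < 1e-12] = 1.0
            self.info = replace(self.info, center=center, scale=scale)
            X = (X - center) / scale
            dX = dX / scale

        self._X_exit = X
        ev = self.d == 1
        self._ev_idx = np.flatnonzero(ev)
        self._dX_ev = dX[ev]
        self._t_ev = self.t[ev]

        en = self.t0 > 0
        self._en_idx = np.flatnonzero(en)
        if en.any():
            X_en, _ = build_design(self.info, self.t0[en], dep[en], age[en])
            self._X_entry = X_en
        else:
            self._X_entry = np.empty((0, self.info.n_columns))

        # expected hazard at each event subject's attained age/year at exit
        hstar = np.empty(self.nobs)
        for sex in self.frame["sex"].unique():
            m = (self.frame["sex"] == sex).to_numpy()
            hstar[m] = self.life_table.rate_at(
                sex, dep[m],
                np.floor(age[m] + self.t[m]),
                np.floor(self.frame["date_dx"].to_numpy(dtype=float)[m] + self.t[m]),
            )
        self._hstar = hstar
        self._hstar_ev = hstar[ev]

    # ------------------------------------------------------------------
    # likelihood
    # ------------------------------------------------------------------
    def _eta_pieces(self, params: np.ndarray):
        params = np.asarray(params, dtype=float)
        if params.shape != (self.info.n_columns,):
            raise ValueError(
                f"expected {self.info.n_columns} parameters, got {params.shape}")
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        eta = self._X_exit @ params
        Lam = np.exp(np.minimum(eta, 200.0))
        s_ev = self._dX_ev @ params
        lam_ev = Lam[self._ev_idx] * s_ev / self._t_ev
        Lam0 = (np.exp(np.minimum(self._X_entry @ params, 200.0))
                if len(self._X_entry) else np.zeros(0))
        return Lam, lam_ev, Lam0

    def loglike(self, params) -> float:
        """Log likelihood of the period dataset at ``params``."""
        Lam, lam_ev, Lam0 = self._eta_pieces(np.asarray(params, dtype=float))
        u = self._hstar_ev + lam_ev
        val, _ = _smooth_log(u, self.config.guard_eps)
        return float(val.sum() - Lam.sum() + Lam0.sum())

    def score(self, params) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        params = np.asarray(params, dtype=float)
        Lam, lam_ev, Lam0 = self._eta_pieces(params)
        u = self._hstar_ev + lam_ev
        _, w = _smooth_log(u, self.config.guard_eps)
        Lam_ev = Lam[self._ev_idx]
        # d u / d theta = lam_ev * X_ev + (Lam_ev / t_ev) * dX_ev
        g = -(Lam[:, None] * self._X_exit).sum(axis=0)
        if len(Lam0):
            g += (Lam0[:, None] * self._X_entry).sum(axis=0)
        X_ev = self._X_exit[self._ev_idx]
        g += ((w * lam_ev)[:, None] * X_ev).sum(axis=0)
        g += ((w * Lam_ev / self._t_ev)[:, None] * self._dX_ev).sum(axis=0)
        return g

    def guard_violations(self, params) -> int:
        """Number of event times where the total hazard is below the floor."""
        _, lam_ev, _ = self._eta_pieces(np.asarray(params, dtype=float))
        return int(np.sum(self._hstar_ev + lam_ev <= self.config.guard_eps))

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def _start_values(self) -> np.ndarray:
        """Deterministic Weibull-equivalent start for the proportional stage.

        Sets eta = ln(lambda0) + ln t (an exponential excess hazard at the
        crude excess rate) and every other coefficient to zero.
        """
        exposure = float(np.sum(self.t - self.t0))
        expected = float(np.sum(self._hstar * (self.t - self.t0)))
        d_excess = max(self.n_events - expected, max(1.0, 0.05 * self.n_events))
        lam0 = d_excess / exposure
        raw = np.zeros(self.info.n_columns)
        raw[0] = np.log(lam0)
        raw[1] = 1.0  # coefficient on the linear ln t column
        return self._to_internal(raw)

    def _to_internal(self, raw: np.ndarray) -> np.ndarray:
        """Map coefficients on raw columns to the standardized scale."""
        if self.info.center is None:
            return raw.copy()
        theta = raw * self.info.scale
        theta[0] = raw[0] + float(np.dot(raw[1:], self.info.center[1:]))
        return theta

    def _optimize(self, start, mask, gtol, maxiter):
        """Maximise the likelihood over the columns selected by ``mask``."""
        base = start.copy()
        idx = np.flatnonzero(mask)

        def neg(sub):
            th = base.copy()
            th[idx] = sub
            return -self.loglike(th)

        def neg_grad(sub):
            th = base.copy()
            th[idx] = sub
            return -self.score(th)[idx]

        res = optimize.minimize(neg, start[idx], jac=neg_grad, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        out = base.copy()
        out[idx] = res.x
        return out, res

    def fit(self, *, start=None, force: bool = False) -> "RelSurvResults":
        """Maximum-likelihood fit.

        A proportional-effects model (time-dependent columns pinned at zero)
        is fitted first from the documented deterministic start; its solution
        warm-starts the full model.  Raises :class:`ConvergenceError` unless
        the gradient inf-norm meets ``config.ctol`` (or ``force=True``).
        """
        p = self.info.n_columns
        if self.n_events <= p:
            raise ValueError(
                f"{self.n_events} events cannot identify {p} parameters")
        cfg = self.config
        theta = np.asarray(start, dtype=float) if start is not None else self._start_values()

        td_mask = self.info.td_column_mask()
        niter = 0
        if td_mask.any() and start is None:
            theta, res1 = self._optimize(theta, ~td_mask, cfg.gtol, cfg.maxiter)
            niter += res1.nit
        theta, res = self._optimize(theta, np.ones(p, dtype=bool), cfg.gtol, cfg.maxiter)
        niter += res.nit

        grad = self.score(theta)
        gnorm = float(np.max(np.abs(grad)))
        converged = bool(res.success or gnorm < cfg.ctol)
        if not converged:
            # one retry with a bounded-memory method from the same start
            res2 = optimize.minimize(
                lambda th: -self.loglike(th), theta,
                jac=lambda th: -self.score(th),
                method="L-BFGS-B",
                options={"maxiter": 4 * cfg.maxiter, "ftol": 1e-12, "gtol": cfg.gtol},
            )
            theta = res2.x
            grad = self.score(theta)
            gnorm = float(np.max(np.abs(grad)))
            niter += res2.nit
            converged = bool(res2.success or gnorm < cfg.ctol)
        if not converged and not force:
            raise ConvergenceError(
                f"optimizer stopped with max|grad| = {gnorm:.3e} "
                f"(ctol {cfg.ctol}) after {niter} iterations; "
                "pass force=True to inspect the non-converged model")

        return RelSurvResults(
            model=self,
            info=self.info,
            params=theta,
            llf=self.loglike(theta),
            grad_norm=gnorm,
            niter=int(niter),
            converged=converged,
            n_guard_violations=self.guard_violations(theta),
        )


@dataclass
class RelSurvResults:
    """Fitted model: coefficients, diagnostics and prediction surface.

    Can be reconstructed from JSON (:meth:`from_json`) without the original
    data, in which case only predictions are available.
    """

    info: DesignInfo
    params: np.ndarray
    llf: float
    grad_norm: float
    niter: int
    converged: bool
    n_guard_violations: int = 0
    model: FlexParamRelSurv | None = None
    _cov: np.ndarray | None = field(default=None, repr=False)

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------
    def design_row(self, profile: Profile, t) -> np.ndarray:
        """Covariate row(s) for a profile at time(s) ``t``."""
        X, _ = build_design(self.info, t, profile.deprivation, profile.age_at_diagnosis)
        return X

    def _check_age(self, profile: Profile) -> None:
        spec = self.info.age_spec
        if spec is not None and not (
            spec.knots[0] <= profile.age_at_diagnosis <= spec.knots[-1]
        ):
            # static message so the default "once per location" filter applies
            warnings.warn(
                "age at diagnosis lies outside the age-spline boundary knots; "
                "prediction extrapolates linearly in age",
                stacklevel=3,
            )

    def predict_log_cumulative_excess_hazard(self, profile: Profile, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr <= 0):
            raise ValueError("t must be > 0")
        self._check_age(profile)
        X, _ = build_design(self.info, t_arr, profile.deprivation,
                            profile.age_at_diagnosis)
        eta = X @ self.params
        return float(eta[0]) if np.ndim(t) == 0 else eta

    def predict_relative_survival(self, profile: Profile, t):
        """R(t|x) = exp(-Lambda_E(t|x)); extrapolates Weibull-like beyond follow-up."""
        eta = self.predict_log_cumulative_excess_hazard(profile, t)
        return np.exp(-np.exp(eta))

    def predict_excess_hazard(self, profile: Profile, t):
        """lambda_E(t|x) = Lambda_E * (d eta / d ln t) / t."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr <= 0):
            raise ValueError("t must be > 0")
        self._check_age(profile)
        X, dX = build_design(self.info, t_arr, profile.deprivation,
                             profile.age_at_diagnosis)
        lam = np.exp(X @ self.params) * (dX @ self.params) / t_arr
        return float(lam[0]) if np.ndim(t) == 0 else lam

    def tail_slope(self, profile: Profile) -> float:
        """d eta / d ln t beyond the last knot: the extrapolation exponent.

        Positive slope means the extrapolated relative survival keeps
        decreasing; the fit report surfaces this per covariate pattern.
        """
        specs = [self.info.baseline]
        for s in (self.info.td_dep, self.info.td_age):
            if s is not None:
                specs.append(s)
        lnt_big = max(s.knots[-1] for s in specs) + 1.0
        _, dX = build_design(self.info, np.exp(lnt_big), profile.deprivation,
                             profile.age_at_diagnosis)
        return float(dX[0] @ self.params)

    # ------------------------------------------------------------------
    # uncertainty
    # ------------------------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Observed-information covariance (central differences of the score)."""
        if self._cov is None:
            if self.model is None:
                raise RuntimeError("covariance needs the original data "
                                   "(results were loaded from JSON)")
            p = len(self.params)
            H = np.empty((p, p))
            for j in range(p):
                h = 1e-5 * (1.0 + abs(self.params[j]))
                up = self.params.copy()
                dn = self.params.copy()
                up[j] += h
                dn[j] -= h
                H[:, j] = (self.model.score(up) - self.model.score(dn)) / (2 * h)
            H = 0.5 * (H + H.T)
            self._cov = np.linalg.inv(-H)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    # ------------------------------------------------------------------
    def life_expectancy(self, profile: Profile, tau: float | None = None, **kw):
        """Loss in expectation of life for one profile (delegates to expectancy)."""
        from .expectancy import loss_in_expectation

        if self.model is None:
            raise RuntimeError("life expectancy needs a life table; use "
                               "lifelost.expectancy.loss_in_expectation directly")
        return loss_in_expectation(self, self.model.life_table, profile, tau=tau, **kw)

    def summary(self) -> str:
        """Human-readable coefficient table with fit diagnostics."""
        names = self.info.column_names
        try:
            bse = self.bse
        except RuntimeError:
            bse = np.full(len(self.params), np.nan)
        lines = [
            "Flexible parametric relative-survival model",
            "=" * 58,
            f"{'n obs':<22}{self.model.nobs if self.model else 'n/a'}",
            f"{'n events':<22}{self.model.n_events if self.model else 'n/a'}",
            f"{'log-likelihood':<22}{self.llf:.4f}",
            f"{'max |score|':<22}{self.grad_norm:.3e}",
            f"{'iterations':<22}{self.niter}",
            f"{'converged':<22}{self.converged}",
            f"{'hazard-floor hits':<22}{self.n_guard_violations}",
            f"{'baseline knots (ln t)':<22}"
            + ", ".join(f"{k:.3f}" for k in self.info.baseline.knots),
            "-" * 58,
            f"{'term':<18}{'coef':>12}{'std err':>12}",
            "-" * 58,
        ]
        for name, b, se in zip(names, self.params, bse):
            lines.append(f"{name:<18}{b:>12.5f}{se:>12.5f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        info = self.info
        return {
            "format": "lifelost-relsurv",
            "version": 1,
            "baseline_knots": list(info.baseline.knots),
            "age_knots": list(info.age_spec.knots) if info.age_spec else None,
            "td_dep_knots": list(info.td_dep.knots) if info.td_dep else None,
            "td_age_knots": list(info.td_age.knots) if info.td_age else None,
            "dep_effects": info.dep_effects,
            "interaction": info.interaction,
            "center": info.center.tolist() if info.center is not None else None,
            "scale": info.scale.tolist() if info.scale is not None else None,
            "column_names": info.column_names,
            "params": self.params.tolist(),
            "llf": self.llf,
            "grad_norm": self.grad_norm,
            "niter": self.niter,
            "converged": self.converged,
            "n_guard_violations": self.n_guard_violations,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "RelSurvResults":
        if doc.get("format") != "lifelost-relsurv":
            raise ValueError("not a lifelost model document")
        info = DesignInfo(
            baseline=SplineSpec(tuple(doc["baseline_knots"])),
            age_spec=SplineSpec(tuple(doc["age_knots"])) if doc["age_knots"] else None,
            dep_effects=doc["dep_effects"],
            interaction=doc["interaction"],
            td_dep=SplineSpec(tuple(doc["td_dep_knots"])) if doc["td_dep_knots"] else None,
            td_age=SplineSpec(tuple(doc["td_age_knots"])) if doc["td_age_knots"] else None,
            center=np.asarray(doc["center"]) if doc["center"] is not None else None,
            scale=np.asarray(doc["scale"]) if doc["scale"] is not None else None,
        )
        return cls(
            info=info,
            params=np.asarray(doc["params"], dtype=float),
            llf=doc["llf"],
            grad_norm=doc["grad_norm"],
            niter=doc["niter"],
            converged=doc["converged"],
            n_guard_violations=doc.get("n_guard_violations", 0),
        )

    @classmethod
    def from_json(cls, path) -> "RelSurvResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def log_likelihood(params, dataset, table: LifeTable, **model_kwargs) -> float:
    """Evaluate the period-analysis likelihood at explicit parameters."""
    return FlexParamRelSurv(dataset, table, **model_kwargs).loglike(params)


def fit_relsurv(dataset, table: LifeTable, config: FitConfig | None = None,
                **overrides) -> RelSurvResults:
    """One-call fit: build the model and maximise the likelihood."""
    return FlexParamRelSurv(dataset, table, config=config, **overrides).fit()
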