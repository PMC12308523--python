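"""Status x time models for the dyadic indices, with permutation inference.

Three responses are modelled as (possibly overdispersed, possibly
zero-inflated) k/n binomials on the logit scale:

* ``wa``        k = x,             n = m + f + x   (so k/n is the WA score)
* ``vai``       k = adj_m + adj_f, n = vx + vy     (so k/n is the VAI)
* ``preferred`` binary: breeding partner == preferred social partner

Fixed effects are pair status (reference level *faithful*), a polynomial in
experimental day (day is z-scored before expansion; degree 0 drops the day
terms for the aggregate models), their interaction, and optionally sex (the
preferred-partner model) and mean flock size (the VAI model). Degree-1 vs
degree-2 interaction structures are compared by AICc.

Dyadic index data violate ordinary GLM assumptions (pair-level dependence,
overdispersion), so permutation p-values (``p_perm``) are the primary
inferential surface:

* terms involving status are tested by permuting pair-status labels across
  pair ids (whole daily series move together, preserving within-pair
  dependence), stratified by season when a season column is present;
* pure temporal terms (day, day^2) cannot be tested by label permutation —
  under that null the permuted day coefficient concentrates at the
  population-average slope, not zero — so they are tested by shuffling the
  day values within each pair's series instead.

A datastream-style scheme (swapping individuals between same-day flocking
events and recomputing the indices) is available for sensitivity analysis via
:func:`datastream_permuted_tables`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

STATUS_ORDER = ("faithful", "divorcing", "new", "juvenile")

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_binomial",
    "compare_aicc",
    "detect_separation",
    "permutation_pvalues",
    "predict_curves",
    "fit_preferred_models",
    "aicc_from_aic",
    "datastream_permuted_tables",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one status x time model."""

    response: str  # "wa" | "vai" | "preferred"
    degree: int = 2  # 0 = aggregate (status only), 1 = linear, 2 = quadratic
    include_sex: bool = False
    include_flock_size: bool = False
    overdispersion: bool = False  # beta-binomial
    zero_inflation: bool = False
    reference_status: str = "faithful"

    def __post_init__(self) -> None:
        if self.response not in ("wa", "vai", "preferred"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.degree not in (0, 1, 2):
            raise ValueError("degree must be 0, 1 or 2")

    def describe(self) -> str:
        parts = [self.response, f"degree={self.degree}"]
        if self.include_sex:
            parts.append("sex")
        if self.include_flock_size:
            parts.append("flock_size")
        if self.overdispersion:
            parts.append("beta-binomial")
        if self.zero_inflation:
            parts.append("zero-inflated")
        return " ".join(parts)


@dataclass
class FitResult:
    """Coefficients and diagnostics for one fitted model."""

    spec: ModelSpec
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray
    loglike: float
    aic: float
    aicc: float
    n_obs: int
    converged: bool
    separation_flag: bool = False
    p_perm: dict = field(default_factory=dict)
    day_mean: float = 0.0
    day_sd: float = 1.0
    nuisance_means: dict = field(default_factory=dict)
    day_range: dict = field(default_factory=dict)  # status -> sorted day values
    extra_params: dict = field(default_factory=dict)  # dispersion / zero-inflation

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.terms,
        )
        if self.p_perm:
            frame["p_perm"] = [self.p_perm.get(t, np.nan) for t in self.terms]
        return frame


def aicc_from_aic(aic: float, n_params: int, n_obs: int) -> float:
    """Small-sample correction: AICc = AIC + 2k(k+1)/(n-k-1)."""
    if n_obs - n_params - 1 <= 0:
        return float("inf")
    return aic + 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1)


# ---------------------------------------------------------------------------
# Design construction


def _response(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """(k, n, filtered table) for the requested response; rows with n=0 drop."""
    if spec.response == "wa":
        k = table["x"].to_numpy(float)
        n = (table["x"] + table["m"] + table["f"]).to_numpy(float)
    elif spec.response == "vai":
        k = (table["adj_m"] + table["adj_f"]).to_numpy(float)
        n = (table["vx"] + table["vy"]).to_numpy(float)
    else:
        k = table["is_breeding_partner"].to_numpy(float)
        n = np.ones(len(table))
    keep = n > 0
    if spec.response == "vai" and spec.include_flock_size:
        keep &= table["mean_flock_size"].notna().to_numpy()
    return k[keep], n[keep], table.loc[keep].reset_index(drop=True)


def _status_dummies(status: np.ndarray, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = [s for s in STATUS_ORDER if s in set(status)]
    if reference not in levels:
        raise ValueError(f"reference status {reference!r} absent from data")
    non_ref = [s for s in levels if s != reference]
    cols = np.column_stack([(status == s).astype(float) for s in non_ref]) if non_ref else \
        np.empty((status.size, 0))
    return cols, [f"status[{s}]" for s in non_ref]


def _build_design(
    table: pd.DataFrame, spec: ModelSpec, day_mean: float, day_sd: float
) -> tuple[np.ndarray, list[str]]:
    n_rows = len(table)
    status = table["status"].to_numpy()
    if len(set(status)) < 2:
        raise ValueError("at least two pair-status levels are required")
    S, s_names = _status_dummies(status, spec.reference_status)
    cols = [np.ones(n_rows)]
    names = ["intercept"]
    cols.append(S)
    names.extend(s_names)
    if spec.degree >= 1:
        z = (table["experimental_day"].to_numpy(float) - day_mean) / day_sd
        for d in range(1, spec.degree + 1):
            suffix = "day" if d == 1 else f"day^{d}"
            cols.append((z ** d)[:, None])
            names.append(suffix)
            cols.append(S * (z ** d)[:, None])
            names.extend(f"{s}:{suffix}" for s in s_names)
    if spec.include_sex:
        cols.append((table["sex"].to_numpy() == "M").astype(float)[:, None])
        names.append("sex[M]")
    if spec.include_flock_size:
        fs = table["mean_flock_size"].to_numpy(float)
        cols.append(((fs - np.nanmean(fs)) / max(np.nanstd(fs), 1e-12))[:, None])
        names.append("mean_flock_size")
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, names


# ---------------------------------------------------------------------------
# Likelihoods


def _binom_loglik(k, n, eta):
    p = special.expit(eta)
    eps = 1e-12
    base = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    return base + k * np.log(p + eps) + (n - k) * np.log(1 - p + eps)


def _betabinom_loglik(k, n, eta, log_theta):
    p = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
    theta = np.exp(log_theta)
    a, b = p * theta, (1 - p) * theta
    base = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    return base + special.betaln(k + a, n - k + b) - special.betaln(a, b)


def _zi_mix(loglik_rows, k, logit_pi):
    pi = special.expit(logit_pi)
    out = np.where(
        k == 0,
        np.logaddexp(np.log(pi + 1e-300), np.log1p(-pi) + loglik_rows),
        np.log1p(-pi) + loglik_rows,
    )
    return out


def _negloglik(params, X, k, n, spec: ModelSpec):
    n_beta = X.shape[1]
    eta = X @ params[:n_beta]
    pos = n_beta
    if spec.overdispersion:
        rows = _betabinom_loglik(k, n, eta, params[pos])
        pos += 1
    else:
        rows = _binom_loglik(k, n, eta)
    if spec.zero_inflation:
        rows = _zi_mix(rows, k, params[pos])
        pos += 1
    return -float(rows.sum())


# ---------------------------------------------------------------------------
# Fast IRLS (plain binomial) — used for permutation refits


def _irls_binomial(X, k, n, max_iter=100, tol=1e-10):
    """Aggregated-binomial logistic IRLS. Returns (beta, cov, loglik, ok)."""
    p0 = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(p0 / (1 - p0))
    ok = False
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(n * p * (1 - p), 1e-10, None)
        z = eta + (k - n * p) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, None, -np.inf, False
        if not np.all(np.isfinite(beta_new)):
            return beta, None, -np.inf, False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol * (1.0 + np.max(np.abs(beta))):
            ok = True
            break
    eta = X @ beta
    p = special.expit(eta)
    w = np.clip(n * p * (1 - p), 1e-10, None)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = None
    ll = float(_binom_loglik(k, n, eta).sum())
    return beta, cov, ll, ok or np.max(np.abs(X @ beta)) < 50


# ---------------------------------------------------------------------------
# Fitting


def fit_binomial(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood fit of the specified model.

    Plain binomial models go through statsmodels GLM; beta-binomial and
    zero-inflated variants are fitted by direct likelihood optimisation
    started from the binomial solution, with standard errors from the
    numerical Hessian. Day is z-scored (mean/SD of the rows used) before
    polynomial expansion; faithful is the reference status level.
    """
    k, n, table = _response(table, spec)
    if len(table) == 0:
        raise ValueError("no usable rows for this response")
    day_mean = float(table["experimental_day"].mean())
    day_sd = float(table["experimental_day"].std(ddof=0)) or 1.0
    X, names = _build_design(table, spec, day_mean, day_sd)

    nuisance_means = {}
    if spec.include_flock_size:
        nuisance_means["mean_flock_size"] = float(np.nanmean(table["mean_flock_size"]))
    day_range = {
        s: sorted(table.loc[table["status"] == s, "experimental_day"].unique().tolist())
        for s in table["status"].unique()
    }

    if not spec.overdispersion and not spec.zero_inflation:
        glm = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial())
        res = glm.fit(maxiter=200)
        ll = float(_binom_loglik(k, n, X @ res.params).sum())
        n_params = X.shape[1]
        aic = 2 * n_params - 2 * ll
        converged = bool(res.converged) and np.all(np.isfinite(res.bse))
        fit = FitResult(
            spec=spec, terms=names, params=np.asarray(res.params),
            bse=np.asarray(res.bse), zvalues=np.asarray(res.tvalues),
            pvalues=np.asarray(res.pvalues),
            cov=np.asarray(res.cov_params()), loglike=ll, aic=aic,
            aicc=aicc_from_aic(aic, n_params, len(table)), n_obs=len(table),
            converged=converged, day_mean=day_mean, day_sd=day_sd,
            nuisance_means=nuisance_means, day_range=day_range,
        )
        if not converged:
            logger.warning("binomial fit did not converge: %s", spec.describe())
        return fit

    # Beta-binomial and/or zero-inflated: direct optimisation.
    beta0, _, _, _ = _irls_binomial(X, k, n)
    extra0 = []
    if spec.overdispersion:
        extra0.append(3.0)  # log theta; large theta ~ binomial
    if spec.zero_inflation:
        extra0.append(-2.0)  # logit pi; small structural-zero mass
    x0 = np.concatenate([beta0, extra0])
    res = optimize.minimize(
        _negloglik, x0, args=(X, k, n, spec), method="L-BFGS-B",
        options={"maxiter": 500},
    )
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, _negloglik, args=(X, k, n, spec))
    try:
        cov_all = np.linalg.inv(hess)
        bse_all = np.sqrt(np.clip(np.diag(cov_all), 0, None))
        have_se = np.all(np.isfinite(bse_all[: X.shape[1]])) and np.all(
            bse_all[: X.shape[1]] > 0
        )
    except np.linalg.LinAlgError:
        cov_all = np.full((res.x.size, res.x.size), np.nan)
        bse_all = np.full(res.x.size, np.nan)
        have_se = False
    n_beta = X.shape[1]
    n_params = res.x.size
    ll = -float(res.fun)
    aic = 2 * n_params - 2 * ll
    params = res.x[:n_beta]
    bse = bse_all[:n_beta]
    z = params / np.where(bse > 0, bse, np.nan)
    extra = {}
    pos = n_beta
    if spec.overdispersion:
        theta = float(np.exp(res.x[pos]))
        extra["theta"] = theta
        extra["rho"] = 1.0 / (1.0 + theta)
        pos += 1
    if spec.zero_inflation:
        extra["zero_inflation_prob"] = float(special.expit(res.x[pos]))
    converged = bool(res.success) and have_se
    if not converged:
        logger.warning(
            "%s fit flagged non-converged (success=%s, finite SEs=%s)",
            spec.describe(), res.success, have_se,
        )
    return FitResult(
        spec=spec, terms=names, params=params, bse=bse, zvalues=z,
        pvalues=2 * stats.norm.sf(np.abs(z)),
        cov=cov_all[:n_beta, :n_beta], loglike=ll, aic=aic,
        aicc=aicc_from_aic(aic, n_params, len(table)), n_obs=len(table),
        converged=converged, day_mean=day_mean, day_sd=day_sd,
        nuisance_means=nuisance_means, day_range=day_range, extra_params=extra,
    )


def compare_aicc(fits: Sequence[FitResult]) -> FitResult:
    """The converged candidate with minimal AICc (ties logged, first kept)."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged candidate fits to compare")
    best = min(usable, key=lambda f: f.aicc)
    ties = [f for f in usable if f is not best and abs(f.aicc - best.aicc) < 1e-9]
    if ties:
        logger.info("AICc tie between %d candidate(s); keeping %s",
                    len(ties) + 1, best.spec.describe())
    return best


# ---------------------------------------------------------------------------
# Separation


@dataclass(frozen=True)
class SeparationFlag:
    separated: bool
    reason: str


def detect_separation(
    table: pd.DataFrame, group_col: str = "status",
    response_col: str = "is_breeding_partner",
) -> dict[str, SeparationFlag]:
    """Flag predictor levels whose binary responses are all 0 or all 1.

    Such a level has an infinite maximum-likelihood logit coefficient; the
    aggregate model for the response should be skipped and the over-time
    model reported instead. Levels with no observations are flagged
    separately as degenerate.
    """
    flags: dict[str, SeparationFlag] = {}
    # observed=False keeps empty categorical levels visible (degenerate flag)
    for level, sub in table.groupby(group_col, sort=True, observed=False):
        values = sub[response_col].to_numpy()
        if values.size == 0:
            flags[str(level)] = SeparationFlag(True, "no observations")
        elif np.all(values == 0):
            flags[str(level)] = SeparationFlag(True, "all responses 0")
        elif np.all(values == 1):
            flags[str(level)] = SeparationFlag(True, "all responses 1")
        else:
            flags[str(level)] = SeparationFlag(False, "mixed responses")
    return flags


# ---------------------------------------------------------------------------
# Permutation inference


def permutation_pvalues(
    table: pd.DataFrame,
    spec: ModelSpec,
    B: int = 999,
    seed: int = 0,
    scheme: str = "status-label",
    terms: Sequence[str] | None = None,
) -> dict[str, float]:
    """Permutation p-values per model term.

    ``p_perm(term) = (1 + #{|coef_perm| >= |coef_obs|}) / (B + 1)``.

    Schemes:

    * ``"status-label"`` — permute pair-status labels across pair ids within
      season strata, keeping each pair's daily series intact. Valid for terms
      involving status; reported only for those.
    * ``"day-within-pair"`` — shuffle each pair's experimental-day values
      within its own series, breaking temporal trends while preserving the
      response distribution per pair. Valid for pure day terms; reported only
      for those.

    Refits use the plain-binomial mean model (point estimates only); more than
    20% failed refits aborts with a diagnostic error.
    """
    if scheme not in ("status-label", "day-within-pair"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    k, n, table = _response(table, spec)
    day_mean = float(table["experimental_day"].mean())
    day_sd = float(table["experimental_day"].std(ddof=0)) or 1.0
    X_obs, names = _build_design(table, spec, day_mean, day_sd)
    beta_obs, _, _, ok = _irls_binomial(X_obs, k, n)
    if not ok:
        raise RuntimeError("observed fit for permutation testing did not converge")

    if terms is None:
        if scheme == "status-label":
            terms = [t for t in names if "status[" in t]
        else:
            terms = [t for t in names if t.startswith("day")]
    idx = [names.index(t) for t in terms]
    obs = np.abs(beta_obs[idx])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    failures = 0

    pair_ids = table["pair_id"].to_numpy()
    season = table["season"].to_numpy() if "season" in table.columns else np.zeros(len(table))
    unit_frame = pd.DataFrame(
        {"pair_id": pair_ids, "season": season, "status": table["status"]}
    ).drop_duplicates("pair_id")
    unit_status = unit_frame["status"].to_numpy().copy()
    unit_season = unit_frame["season"].to_numpy()
    unit_pos = {p: i for i, p in enumerate(unit_frame["pair_id"])}
    row_unit = np.array([unit_pos[p] for p in pair_ids])
    strata = [np.flatnonzero(unit_season == s) for s in np.unique(unit_season)]

    day = table["experimental_day"].to_numpy(float)
    pair_rows = [np.flatnonzero(pair_ids == p) for p in unit_frame["pair_id"]]

    work = table.copy()
    for _ in range(B):
        if scheme == "status-label":
            perm_status = unit_status.copy()
            for stratum in strata:
                perm_status[stratum] = perm_status[rng.permutation(stratum)]
            work["status"] = perm_status[row_unit]
        else:
            perm_day = day.copy()
            for rows in pair_rows:
                perm_day[rows] = perm_day[rng.permutation(rows)]
            work["experimental_day"] = perm_day
        try:
            Xp, _ = _build_design(work, spec, day_mean, day_sd)
            beta_p, _, _, ok = _irls_binomial(Xp, k, n)
        except (ValueError, np.linalg.LinAlgError):
            ok = False
        if not ok:
            failures += 1
            if failures > 0.2 * B:
                raise RuntimeError(
                    f"permutation refits failing ({failures} of {B}); "
                    f"model: {spec.describe()}, scheme: {scheme}"
                )
            continue
        exceed += np.abs(beta_p[idx]) >= obs - 1e-12
    effective = B - failures
    pvals = (1.0 + exceed) / (effective + 1.0)
    return dict(zip(terms, pvals.tolist()))


# ---------------------------------------------------------------------------
# Predicted curves


def predict_curves(fit: FitResult, conf_level: float = 0.95) -> pd.DataFrame:
    """Per-status predicted index vs experimental day with delta-method CIs.

    Predictions use the inverse-logit of the linear predictor on each
    status's observed day grid, with nuisance covariates (sex, flock size)
    held at their sample means (standardised flock size enters at 0; sex at
    its sample mean requires no term because predictions average the dummy at
    0.5 only if sex was included — here sex[M] is set to 0.5).
    """
    zcrit = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    statuses = [fit.spec.reference_status] + [
        t[len("status["):-1] for t in fit.terms if t.startswith("status[")
    ]
    for status in statuses:
        days = fit.day_range.get(status)
        if not days:
            continue
        for day in days:
            xrow = np.zeros(len(fit.terms))
            z = (day - fit.day_mean) / fit.day_sd
            for j, term in enumerate(fit.terms):
                if term == "intercept":
                    xrow[j] = 1.0
                elif term == f"status[{status}]":
                    xrow[j] = 1.0
                elif term == "day":
                    xrow[j] = z
                elif term == "day^2":
                    xrow[j] = z ** 2
                elif term == f"status[{status}]:day":
                    xrow[j] = z
                elif term == f"status[{status}]:day^2":
                    xrow[j] = z ** 2
                elif term == "sex[M]":
                    xrow[j] = 0.5
                elif term == "mean_flock_size":
                    xrow[j] = 0.0  # standardised covariate at its mean
            eta = float(xrow @ fit.params)
            se = float(np.sqrt(xrow @ fit.cov @ xrow))
            rows.append(
                {
                    "response": fit.spec.response,
                    "status": status,
                    "experimental_day": day,
                    "prediction": special.expit(eta),
                    "ci_lo": special.expit(eta - zcrit * se),
                    "ci_hi": special.expit(eta + zcrit * se),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preferred-partner orchestration (separation-aware)


def fit_preferred_models(
    table: pd.DataFrame,
    B: int = 999,
    seed: int = 0,
    degree: int = 2,
) -> dict:
    """Fit the preferred-partner models, honouring perfect separation.

    If any status level is perfectly separated in the aggregate (all-winter)
    binary response, the aggregate model is skipped — its maximum-likelihood
    coefficients would be infinite — and only the over-time model is fitted,
    from which overall status differences are inferred.
    """
    flags = detect_separation(table)
    separated = {lvl: f for lvl, f in flags.items() if f.separated}
    out: dict = {"separation_flags": flags, "aggregate": None}
    if not separated:
        agg_spec = ModelSpec(response="preferred", degree=0, include_sex=True)
        agg = fit_binomial(table, agg_spec)
        agg.p_perm = permutation_pvalues(table, agg_spec, B=B, seed=seed)
        out["aggregate"] = agg
    else:
        logger.info(
            "aggregate preferred-partner model skipped; separated level(s): %s",
            ", ".join(sorted(separated)),
        )
    time_spec = ModelSpec(response="preferred", degree=degree, include_sex=True)
    time_fit = fit_binomial(table, time_spec)
    time_fit.separation_flag = bool(separated)
    time_fit.p_perm = permutation_pvalues(table, time_spec, B=B, seed=seed)
    out["over_time"] = time_fit
    return out


# ---------------------------------------------------------------------------
# Datastream permutation (sensitivity analysis)


def datastream_permuted_tables(
    events, pairs: pd.DataFrame, calendar, rng, n_swaps_factor: int = 10
):
    """One datastream permutation: swap individuals between same-day events.

    Repeatedly picks two events on the same date and exchanges one member
    (with that member's visits, shifted to the destination event's centre)
    between them, then recomputes the daily dyad table. Preserves each day's
    event count and sizes while breaking dyadic co-occurrence. Intended for
    sensitivity analysis of the label-based p_perm, not as the default.
    """
    from .dyadic_indices import daily_dyad_table
    from .flock_detection import FlockEvent

    by_date: dict = {}
    events = list(events)
    for i, e in enumerate(events):
        by_date.setdefault(e.date, []).append(i)
    n_swaps = n_swaps_factor * len(events)
    for _ in range(n_swaps):
        date = list(by_date)[rng.integers(len(by_date))]
        idxs = by_date[date]
        if len(idxs) < 2:
            continue
        i, j = rng.choice(idxs, size=2, replace=False)
        ei, ej = events[i], events[j]
        if not ei.members or not ej.members:
            continue
        bird_i = sorted(ei.members)[rng.integers(len(ei.members))]
        bird_j = sorted(ej.members)[rng.integers(len(ej.members))]
        if bird_i == bird_j or bird_i in ej.members or bird_j in ei.members:
            continue
        events[i] = _swap_member(ei, bird_i, ej, bird_j)
        events[j] = _swap_member(ej, bird_j, ei, bird_i)
    return daily_dyad_table(events, pairs, calendar)


def _swap_member(event, out_bird, other_event, in_bird):
    """Replace ``out_bird``'s visits with ``in_bird``'s, recentred."""
    from .flock_detection import FlockEvent

    centre = 0.5 * (event.start_time + event.end_time)
    other_centre = 0.5 * (other_event.start_time + other_event.end_time)
    kept = [(tag, t) for tag, t in event.visits if tag != out_bird]
    moved = [
        (in_bird, t - other_centre + centre)
        for tag, t in other_event.visits
        if tag == in_bird
    ]
    visits = tuple(sorted(kept + moved, key=lambda v: v[1]))
    times = [t for _, t in visits]
    return FlockEvent(
        event_id=event.event_id,
        feeder_id=event.feeder_id,
        date=event.date,
        start_time=min(times) if times else event.start_time,
        end_time=max(times) if times else event.end_time,
        members=frozenset(tag for tag, _ in visits),
        visits=visits,
    )
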