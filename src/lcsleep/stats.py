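"""Moderated regression, FDR, mediation and sensitivity analysis.

The inference chain this module implements, for a cross-sectional cohort
table with one row per participant:

1. interaction models ``outcome ~ predictor * group + covariates`` with a
   binary group moderator (age group), Wald F tests per term and the
   partial R² effect size ``F·df1 / (F·df1 + df2)``;
2. per-group simple slopes from the fitted interaction model;
3. Benjamini–Hochberg step-up FDR over a family of p-values;
4. Pearson correlation;
5. counterfactual linear mediation (controlled direct effect and pure
   indirect effect, reported as percentages of the total effect) with
   nonparametric case-resampling bootstrap;
6. an analytic sensitivity analysis: the minimum detectable partial
   correlation of one tested predictor in multiple regression, obtained
   by inverting the noncentral-t power function.

With one observation per participant a participant random intercept is
not identifiable (it is confounded with the residual), so the models are
fixed-effects linear models (default Gaussian; a log-link Gamma family is
available for right-skewed energy outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TermTest",
    "ModelResult",
    "MediationResult",
    "SensitivityResult",
    "fit_interaction_model",
    "simple_slopes",
    "bh_fdr",
    "pearson_correlation",
    "mediation_analysis",
    "sensitivity_min_effect",
    "run_primary_models",
    "PRIMARY_OUTCOMES",
]


# ---------------------------------------------------------------------------
# Interaction models


@dataclass(frozen=True)
class TermTest:
    f: float
    df1: int
    df2: float
    p: float
    partial_r2: float


@dataclass
class ModelResult:
    """Fitted interaction model: coefficients, Wald tests, bookkeeping."""

    outcome: str
    predictor: str
    moderator: str
    moderator_levels: tuple[str, str]  # (reference, indicator == 1)
    family: str
    n: int
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    term_tests: dict[str, TermTest]

    @property
    def interaction_p(self) -> float:
        return self.term_tests["interaction"].p

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "moderator": self.moderator,
            "moderator_levels": list(self.moderator_levels),
            "family": self.family,
            "n": self.n,
            "coefficients": {
                k: {"estimate": float(self.params[k]), "se": float(self.bse[k])}
                for k in self.params.index
            },
            "term_tests": {
                k: {"F": t.f, "df1": t.df1, "df2": t.df2, "p": t.p, "partial_r2": t.partial_r2}
                for k, t in self.term_tests.items()
            },
        }


def _encode_covariates(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = table[cov]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (s.astype(str) == lev).astype(float)
        else:
            cols[cov] = s.astype(float)
    return pd.DataFrame(cols, index=table.index)


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # name the involved columns via the null space of X'X
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    null_vec = np.abs(vt[-1])
    involved = [n for n, w in zip(names, null_vec) if w > 1e-6 * null_vec.max()]
    raise ValueError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear columns: {involved}"
    )


def fit_interaction_model(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    moderator: str,
    covariates: Sequence[str] = (),
    family: str = "gaussian",
) -> ModelResult:
    """Fit ``outcome ~ predictor * moderator + covariates``.

    The moderator must be binary; its alphabetically first level is the
    reference.  Every tested term has one degree of freedom, so the Wald
    F of each term is the squared coefficient t statistic, the Type-III
    test for this design.  Partial R² is ``F / (F + df2)``.

    ``family`` is ``"gaussian"`` (identity-link OLS) or ``"gamma"``
    (log-link Gamma GLM for right-skewed positive outcomes).
    """
    import statsmodels.api as sm

    for col in (outcome, predictor, moderator, *covariates):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from the cohort table")
    data = table[[outcome, predictor, moderator, *covariates]].dropna()
    if len(data) < 10:
        raise ValueError(f"only {len(data)} complete rows; need at least 10")

    levels = sorted(pd.unique(data[moderator].astype(str)))
    if len(levels) != 2:
        raise ValueError(
            f"moderator {moderator!r} must be binary, found levels {levels}"
        )
    ref, other = levels
    ind = (data[moderator].astype(str) == other).astype(float).to_numpy()
    x = data[predictor].astype(float).to_numpy()
    cov_df = _encode_covariates(data, covariates)

    names = ["const", predictor, f"{moderator}[{other}]", "interaction", *cov_df.columns]
    X = np.column_stack([np.ones(len(data)), x, ind, x * ind, cov_df.to_numpy()])
    _check_collinearity(X, names)

    y = data[outcome].astype(float).to_numpy()
    if family == "gaussian":
        fit = sm.OLS(y, X).fit()
        df_resid = float(fit.df_resid)
    elif family == "gamma":
        if np.any(y <= 0):
            raise ValueError("gamma family requires a strictly positive outcome")
        fit = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        df_resid = float(fit.df_resid)
    else:
        raise ValueError(f"unknown family {family!r}; use 'gaussian' or 'gamma'")

    params = pd.Series(np.asarray(fit.params), index=names)
    bse = pd.Series(np.asarray(fit.bse), index=names)
    covp = pd.DataFrame(np.asarray(fit.cov_params()), index=names, columns=names)

    term_map = {
        "predictor": predictor,
        "moderator": f"{moderator}[{other}]",
        "interaction": "interaction",
        **{c: c for c in cov_df.columns},
    }
    tests: dict[str, TermTest] = {}
    for term, col in term_map.items():
        t = params[col] / bse[col]
        f = float(t * t)
        p = float(stats.f.sf(f, 1, df_resid))
        tests[term] = TermTest(
            f=f, df1=1, df2=df_resid, p=p, partial_r2=float(f / (f + df_resid))
        )

    return ModelResult(
        outcome=outcome,
        predictor=predictor,
        moderator=moderator,
        moderator_levels=(ref, other),
        family=family,
        n=len(data),
        params=params,
        bse=bse,
        cov_params=covp,
        df_resid=df_resid,
        term_tests=tests,
    )


def simple_slopes(model: ModelResult, group: str) -> tuple[float, float, float]:
    """Per-group slope of the predictor, with its t statistic and p value.

    The slope in the reference group is the predictor coefficient; in the
    other group it is predictor + interaction.  The t statistic comes from
    the corresponding linear contrast of the coefficient covariance.
    """
    ref, other = model.moderator_levels
    if group not in (ref, other):
        raise ValueError(
            f"unknown group {group!r}; moderator levels are {model.moderator_levels}"
        )
    c = pd.Series(0.0, index=model.params.index)
    c[model.predictor] = 1.0
    if group == other:
        c["interaction"] = 1.0
    slope = float(c @ model.params)
    se = float(np.sqrt(c @ model.cov_params @ c))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), model.df_resid))
    return slope, t, p


# ---------------------------------------------------------------------------
# BH-FDR and correlation


def bh_fdr(
    pvalues: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, float, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(rejected, critical_p, adjusted_p)``: boolean rejection
    flags in input order, the largest p(k) with p(k) <= k·q/m (0.0 if no
    hypothesis is rejected), and monotone BH-adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(ranked <= thresholds)[0]
    rejected = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1]
        critical_p = float(ranked[k])
        rejected[order[: k + 1]] = True
    else:
        critical_p = 0.0
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj_sorted, 0.0, 1.0)
    return rejected, critical_p, adjusted


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Sample Pearson r with its two-sided t-test p-value and n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


# ---------------------------------------------------------------------------
# Mediation


@dataclass
class MediationResult:
    """Counterfactual decomposition of an exposure effect.

    ``cde`` is the controlled direct effect with the mediator fixed at
    its covariate-adjusted mean; ``pie`` the pure (natural) indirect
    effect; both also reported as percentages of the total effect with
    percentile-bootstrap SE/CI and bootstrap p-values (on the effect
    scale).  ``unstable`` flags a total effect indistinguishable from
    zero, where percentages are not interpretable.
    """

    cde: float
    pie: float
    total_effect: float
    cde_percent: float
    pie_percent: float
    cde_percent_se: float
    pie_percent_se: float
    cde_percent_ci: tuple[float, float]
    pie_percent_ci: tuple[float, float]
    cde_p: float
    pie_p: float
    n: int
    n_boot: int
    seed: int
    unstable: bool

    def to_dict(self) -> dict:
        return {
            "cde": self.cde,
            "pie": self.pie,
            "total_effect": self.total_effect,
            "cde_percent": self.cde_percent,
            "pie_percent": self.pie_percent,
            "cde_percent_se": self.cde_percent_se,
            "pie_percent_se": self.pie_percent_se,
            "cde_percent_ci": list(self.cde_percent_ci),
            "pie_percent_ci": list(self.pie_percent_ci),
            "cde_p": self.cde_p,
            "pie_p": self.pie_p,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "unstable": self.unstable,
        }


def _mediation_effects(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, covars: np.ndarray,
    interaction: bool = True,
) -> tuple[float, float, float]:
    """CDE, PIE and total effect from the two linear working models.

    Mediator model: M ~ X + C.  Outcome model: Y ~ X + M + X·M + C (the
    X·M term dropped when ``interaction=False``).  Counterfactual
    contrasts use a one-unit exposure change from the sample mean x0 and
    the covariate means; the CDE fixes the mediator at its
    covariate-adjusted mean (= fitted mediator at x0).  With no
    interaction these reduce to CDE = θ_X and PIE = a·b, the
    product-of-coefficients decomposition.
    """
    n = x.size
    ones = np.ones(n)
    Xm = np.column_stack([ones, x, covars])
    beta, *_ = np.linalg.lstsq(Xm, m, rcond=None)
    if interaction:
        Xy = np.column_stack([ones, x, m, x * m, covars])
        theta, *_ = np.linalg.lstsq(Xy, y, rcond=None)
        th_x, th_m, th_xm = theta[1], theta[2], theta[3]
    else:
        Xy = np.column_stack([ones, x, m, covars])
        theta, *_ = np.linalg.lstsq(Xy, y, rcond=None)
        th_x, th_m, th_xm = theta[1], theta[2], 0.0

    x0 = x.mean()
    cbar = covars.mean(axis=0) if covars.size else np.empty(0)
    em_x0 = beta[0] + beta[1] * x0 + (cbar @ beta[2:] if covars.size else 0.0)
    m_star = em_x0  # covariate-adjusted mediator mean (reference level)

    a = beta[1]
    cde = th_x + th_xm * m_star
    nde = th_x + th_xm * em_x0
    pie = (th_m + th_xm * x0) * a
    tie = (th_m + th_xm * (x0 + 1.0)) * a
    total = nde + tie
    return float(cde), float(pie), float(total)


def mediation_analysis(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
    transform: str | None = None,
    interaction: bool = True,
) -> MediationResult:
    """Linear counterfactual mediation with case-resampling bootstrap.

    The outcome model includes an exposure-by-mediator interaction; the
    controlled direct effect (CDE, mediator fixed at its adjusted mean)
    and pure indirect effect (PIE) are reported as percentages of the
    total effect, with percentile bootstrap CIs, bootstrap SEs, and
    two-sided bootstrap p-values for the effects themselves.

    ``transform="sqrt"`` square-roots the mediator first (for energy-like
    mediators generated on the squared scale); ``interaction=False``
    drops the exposure-by-mediator term, reducing PIE to the
    product-of-coefficients a·b.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    cols = [outcome, exposure, mediator, *covariates]
    for col in cols:
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from the cohort table")
    data = table[cols].dropna()
    n = len(data)
    if n < 10:
        raise ValueError(f"only {n} complete cases; need at least 10")

    m = data[mediator].astype(float).to_numpy()
    if transform == "sqrt":
        if np.any(m < 0):
            raise ValueError("sqrt transform requires a nonnegative mediator")
        m = np.sqrt(m)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(m) == 0:
        raise ValueError("degenerate mediator: zero variance")

    x = data[exposure].astype(float).to_numpy()
    y = data[outcome].astype(float).to_numpy()
    covars = (
        _encode_covariates(data, covariates).to_numpy()
        if covariates
        else np.empty((n, 0))
    )

    cde, pie, total = _mediation_effects(x, m, y, covars, interaction)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = _mediation_effects(x[idx], m[idx], y[idx], covars[idx], interaction)

    def boot_p(samples: np.ndarray) -> float:
        frac = (samples <= 0).mean()
        return float(np.clip(2.0 * min(frac, 1.0 - frac), 1.0 / n_boot, 1.0))

    # percentages of a total effect indistinguishable from zero are not
    # interpretable: flag when the TE bootstrap CI straddles zero
    te_lo, te_hi = np.percentile(boots[:, 2], [2.5, 97.5])
    unstable = bool(not np.isfinite(total) or (te_lo <= 0.0 <= te_hi))

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * boots[:, :2] / boots[:, 2][:, None]
    finite = np.isfinite(pct).all(axis=1)
    pct = pct[finite]
    cde_pct = 100.0 * cde / total if total != 0 else np.nan
    pie_pct = 100.0 * pie / total if total != 0 else np.nan

    ci = np.percentile(pct, [2.5, 97.5], axis=0) if pct.size else np.full((2, 2), np.nan)
    se = pct.std(axis=0, ddof=1) if pct.size else np.full(2, np.nan)

    return MediationResult(
        cde=cde,
        pie=pie,
        total_effect=total,
        cde_percent=float(cde_pct),
        pie_percent=float(pie_pct),
        cde_percent_se=float(se[0]),
        pie_percent_se=float(se[1]),
        cde_percent_ci=(float(ci[0, 0]), float(ci[1, 0])),
        pie_percent_ci=(float(ci[0, 1]), float(ci[1, 1])),
        cde_p=boot_p(boots[:, 0]),
        pie_p=boot_p(boots[:, 1]),
        n=n,
        n_boot=n_boot,
        seed=seed,
        unstable=bool(unstable),
    )


# ---------------------------------------------------------------------------
# Sensitivity analysis


@dataclass(frozen=True)
class SensitivityResult:
    n: int
    alpha: float
    power: float
    sides: int
    n_covariates: int
    min_detectable_r: float
    min_detectable_r2: float


def power_one_predictor(
    r: float, n: int, alpha: float, sides: int, n_covariates: int
) -> float:
    """Power of the t test of one predictor in multiple regression.

    Uses the noncentral t distribution with df = n - n_covariates - 2 and
    noncentrality sqrt(f²·n), f² = r²/(1-r²), where r is the partial
    correlation of the tested predictor.
    """
    df = n - n_covariates - 2
    if df <= 0:
        raise ValueError(f"nonpositive residual df ({df}); sample too small")
    if not 0 <= r < 1:
        raise ValueError("r must lie in [0, 1)")
    f2 = r * r / (1.0 - r * r)
    delta = np.sqrt(f2 * n)
    if sides == 1:
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(1.0 - stats.nct.cdf(crit, df, delta))
    if sides == 2:
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(
            1.0 - stats.nct.cdf(crit, df, delta) + stats.nct.cdf(-crit, df, delta)
        )
    raise ValueError("sides must be 1 or 2")


def sensitivity_min_effect(
    n: int,
    alpha: float = 0.05,
    power: float = 0.8,
    sides: int = 1,
    n_covariates: int = 4,
) -> SensitivityResult:
    """Smallest detectable |partial r| of one tested predictor.

    Numerically inverts :func:`power_one_predictor` over r.  At the
    design this package emulates (n = 52, one-sided α = 0.05, power 0.8,
    one tested predictor plus four covariates) the minimum detectable
    effect is r ≈ 0.33, R² ≈ 0.11.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    base = power_one_predictor(0.0, n, alpha, sides, n_covariates)
    if power <= base + 1e-12:
        r = 0.0
    else:
        r = float(
            optimize.brentq(
                lambda rr: power_one_predictor(rr, n, alpha, sides, n_covariates)
                - power,
                1e-12,
                1.0 - 1e-9,
                xtol=1e-12,
            )
        )
    return SensitivityResult(
        n=n,
        alpha=alpha,
        power=power,
        sides=sides,
        n_covariates=n_covariates,
        min_detectable_r=r,
        min_detectable_r2=r * r,
    )


# ---------------------------------------------------------------------------
# Primary model battery

#: outcome column -> extra covariates beyond (sex, bmi); the cumulative
#: energy outcomes add total sleep time because cumulated power grows
#: with time spent in the stage.
PRIMARY_OUTCOMES: dict[str, tuple[str, ...]] = {
    "psqi": (),
    "sol": (),
    "sleep_efficiency": (),
    "rem_percentage": (),
    "swe": ("tst",),
    "rem_theta_energy": ("tst",),
}


def run_primary_models(
    table: pd.DataFrame,
    predictor: str = "lc_activity",
    moderator: str = "age_group",
    base_covariates: Sequence[str] = ("sex", "bmi"),
    fdr_q: float = 0.05,
    family: str = "gaussian",
    fdr_on: str = "interaction",
) -> dict:
    """Fit the six primary interaction models and apply BH-FDR.

    One model per outcome in :data:`PRIMARY_OUTCOMES` (TST joins the
    covariates for the two energy outcomes).  The FDR family is the six
    ``fdr_on`` term p-values (interaction by default, configurable to the
    predictor main effect).  The report contains, per model, the term
    tests, the per-group simple slopes, and the FDR verdicts.
    """
    missing = [c for c in PRIMARY_OUTCOMES if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks primary outcome column(s): {missing}")

    models: dict[str, ModelResult] = {}
    report: dict = {"models": {}, "fdr": {}}
    pvals = []
    for outcome, extra in PRIMARY_OUTCOMES.items():
        res = fit_interaction_model(
            table,
            outcome=outcome,
            predictor=predictor,
            moderator=moderator,
            covariates=(*base_covariates, *extra),
            family=family,
        )
        models[outcome] = res
        pvals.append(res.term_tests[fdr_on].p)
        entry = res.to_dict()
        entry["simple_slopes"] = {}
        for group in res.moderator_levels:
            slope, t, p = simple_slopes(res, group)
            entry["simple_slopes"][group] = {"slope": slope, "t": t, "p": p}
        report["models"][outcome] = entry

    rejected, critical_p, adjusted = bh_fdr(pvals, q=fdr_q)
    report["fdr"] = {
        "term": fdr_on,
        "q": fdr_q,
        "critical_p": critical_p,
        "outcomes": {
            outcome: {
                "p": float(p),
                "adjusted_p": float(adj),
                "rejected": bool(rej),
            }
            for outcome, p, adj, rej in zip(PRIMARY_OUTCOMES, pvals, adjusted, rejected)
        },
    }
    report["_model_objects"] = models
    return report
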