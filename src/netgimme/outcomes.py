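"""Regression linkage of density metrics to clinical outcomes.

Six primary models are fit per run: {within-network, between-network}
density families crossed with three outcomes — slips (count of regular
cigarettes during the cessation attempt; negative-binomial with log
link), mean craving during treatment and cue-induced craving (both
log-transformed then ordinary least squares).  Every model adjusts for
age, sex, nicotine-dependence score (FTND) and treatment arm, and
model-level p-values are Bonferroni-corrected across the six models
(0.05 / 6 = 0.0083).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .density import METRICS

OUTCOMES = ("slips", "craving_treatment", "cue_craving")
DEFAULT_COVARIATES = ("age", "sex", "ftnd", "treatment")
WITHIN_METRICS = tuple(m for m in METRICS if m.split("_")[0].split("-")[0] == m.split("_")[0].split("-")[1])
BETWEEN_METRICS = tuple(m for m in METRICS if m not in WITHIN_METRICS)


@dataclass(frozen=True)
class RegressionSpec:
    outcome: str
    family: str  # "negative_binomial" or "gaussian_log_outcome"
    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.family not in ("negative_binomial", "gaussian_log_outcome"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class RegressionResult:
    spec: RegressionSpec
    coefficients: pd.DataFrame  # index: term; columns: b, beta, se, z, p
    model_stat: float  # LR chi2 (count) or F (linear)
    model_p: float
    df_model: tuple
    r_squared: float | None
    dispersion: float | None  # NB theta (var = mu + mu^2/theta)
    n_used: int
    converged: bool
    dropped: list[str] = field(default_factory=list)
    log_shift: float | None = None


def primary_specs(eligible_metrics: list[str]) -> list[RegressionSpec]:
    """The six primary models: {within, between} x three outcomes."""
    specs = []
    for outcome in OUTCOMES:
        family = "negative_binomial" if outcome == "slips" else "gaussian_log_outcome"
        for group in (WITHIN_METRICS, BETWEEN_METRICS):
            preds = tuple(m for m in group if m in eligible_metrics)
            specs.append(RegressionSpec(outcome=outcome, family=family, predictors=preds))
    return specs


def _design(spec: RegressionSpec, densities: pd.DataFrame, outcomes: pd.DataFrame):
    df = densities.join(outcomes, how="inner")
    cols = [spec.outcome, *spec.predictors, *spec.covariates]
    df = df[cols].dropna()
    y = df[spec.outcome]
    dropped = [
        c for c in (*spec.predictors, *spec.covariates) if float(df[c].std(ddof=0)) < 1e-12
    ]
    for c in dropped:
        warnings.warn(f"predictor {c!r} has no variation; dropped")
    keep = [c for c in (*spec.predictors, *spec.covariates) if c not in dropped]
    X = sm.add_constant(df[keep].astype(float), has_constant="add")
    return y, X, dropped


def fit_count_outcome_model(
    spec: RegressionSpec, densities: pd.DataFrame, outcomes: pd.DataFrame
) -> RegressionResult:
    """ML negative-binomial (NB2) regression of slips on density metrics.

    Reports per-predictor Wald statistics and the likelihood-ratio chi2
    against the covariate-only null, with the dispersion estimated
    jointly by ML.  Rows with missing data are dropped listwise.
    """
    if spec.family != "negative_binomial":
        raise ValueError("spec is not a count model")
    y, X, dropped = _design(spec, densities, outcomes)
    yv = y.to_numpy()
    if np.any(yv < 0) or not np.allclose(yv, np.round(yv)):
        raise ValueError("count outcome must be nonnegative integers")

    null_cols = ["const", *[c for c in spec.covariates if c in X.columns]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.NegativeBinomial(yv, X, loglike_method="nb2").fit(
                disp=0, maxiter=200, method="bfgs"
            )
            null = sm.NegativeBinomial(yv, X[null_cols], loglike_method="nb2").fit(
                disp=0, maxiter=200, method="bfgs"
            )
        converged = bool(full.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, ValueError):
        full = None
        converged = False
    if not converged:
        warnings.warn("negative-binomial fit did not converge; result flagged")
    if full is None:
        nan = float("nan")
        coef = pd.DataFrame(
            np.full((len(X.columns), 5), nan),
            index=list(X.columns), columns=["b", "beta", "se", "z", "p"],
        )
        return RegressionResult(
            spec=spec, coefficients=coef, model_stat=nan, model_p=nan,
            df_model=(len(X.columns) - len(null_cols),), r_squared=None,
            dispersion=None, n_used=int(len(yv)), converged=False, dropped=dropped,
        )

    terms = list(X.columns)
    params = np.asarray(full.params)[: len(terms)]
    bse = np.asarray(full.bse)[: len(terms)]
    zs = params / bse
    coef = pd.DataFrame(
        {
            "b": params,
            "beta": np.nan,
            "se": bse,
            "z": zs,
            "p": 2 * stats.norm.sf(np.abs(zs)),
        },
        index=terms,
    )
    k_extra = len(terms) - len(null_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # llf is evaluated lazily
        lr = max(2.0 * (full.llf - null.llf), 0.0)
    lr_p = float(stats.chi2.sf(lr, k_extra)) if k_extra > 0 else float("nan")
    alpha_hat = float(np.asarray(full.params)[-1])  # NB2 ancillary: var = mu + alpha mu^2
    theta = 1.0 / alpha_hat if alpha_hat > 0 else float("inf")
    return RegressionResult(
        spec=spec, coefficients=coef, model_stat=float(lr), model_p=lr_p,
        df_model=(k_extra,), r_squared=None, dispersion=theta,
        n_used=int(len(yv)), converged=converged, dropped=dropped,
    )


def log_transform(y: pd.Series) -> tuple[pd.Series, float]:
    """log(y), shifted as log(y - min(y) + 1) when any value is <= 0."""
    if (y <= 0).any():
        shift = 1.0 - float(y.min())
        return np.log(y + shift), shift
    return np.log(y), 0.0


def fit_continuous_outcome_model(
    spec: RegressionSpec, densities: pd.DataFrame, outcomes: pd.DataFrame
) -> RegressionResult:
    """OLS of the log-transformed outcome on density metrics.

    Standardized betas come from refitting with every variable z-scored;
    numerically beta = b * SD(predictor) / SD(transformed outcome).
    """
    if spec.family != "gaussian_log_outcome":
        raise ValueError("spec is not a continuous model")
    y, X, dropped = _design(spec, densities, outcomes)
    ly, shift = log_transform(y)
    if float(np.std(ly, ddof=0)) < 1e-12:
        raise ValueError("outcome is constant after transform")

    res = sm.OLS(ly, X).fit()
    sd_y = float(np.std(ly, ddof=1))
    betas = {}
    for term in X.columns:
        if term == "const":
            betas[term] = np.nan
        else:
            betas[term] = float(res.params[term] * np.std(X[term], ddof=1) / sd_y)
    coef = pd.DataFrame(
        {
            "b": res.params,
            "beta": pd.Series(betas),
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    return RegressionResult(
        spec=spec, coefficients=coef,
        model_stat=float(res.fvalue), model_p=float(res.f_pvalue),
        df_model=(int(res.df_model), int(res.df_resid)),
        r_squared=float(res.rsquared), dispersion=None,
        n_used=int(res.nobs), converged=True, dropped=dropped, log_shift=shift,
    )


def fit_outcome_model(
    spec: RegressionSpec, densities: pd.DataFrame, outcomes: pd.DataFrame
) -> RegressionResult:
    if spec.family == "negative_binomial":
        return fit_count_outcome_model(spec, densities, outcomes)
    return fit_continuous_outcome_model(spec, densities, outcomes)


def apply_bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Familywise correction across models: significant iff p < alpha/m."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return [p < threshold for p in p_values], threshold
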