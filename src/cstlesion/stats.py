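"""Association-layer statistics.

Group comparisons (Welch t, Cohen's d, chi-square), partial Pearson
correlations, P < 0.2 predictor screening, multivariable linear models with
standardized betas and variance inflation factors, logistic models with
odds ratios, Wald confidence intervals and AUC, CMCT abnormality z-scoring,
the log transform of lesion volume fractions, and Bonferroni thresholds.
Model fitting is delegated to statsmodels; this layer fixes the exact
conventions (standardization, strict thresholds, complete-case handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "LogisticResult",
    "SeparationError",
    "welch_t_test",
    "cohens_d",
    "chi_square_test",
    "partial_correlation_pearson",
    "screen_predictors",
    "fit_multivariable_linear",
    "fit_logistic",
    "cmct_status",
    "log_transform_fraction",
    "bonferroni_threshold",
    "normal_tail_probability",
]


class SeparationError(RuntimeError):
    """Raised when a logistic model is (quasi-)perfectly separated."""


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def welch_t_test(a, b) -> tuple[float, float, float]:
    """Two-sided two-sample t-test with the Welch (Satterthwaite) df.

    Returns ``(t, df, p)``.  Samples with fewer than 2 observations or both
    with zero variance are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("both groups have zero variance")
    pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    return float((mean_a - mean_b) / pooled)


def chi_square_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (df = 1), returning ``(chi2, p)``.

    The Yates continuity correction is off by default; pass ``yates=True``
    to enable it.  Zero marginals are an error.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a marginal of the table is zero")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation_pearson(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing linear covariate effects.

    Both variables are residualized on ``[1, covariates]`` by OLS; the p-value
    uses a t distribution with ``n - n_covariates - 2`` degrees of freedom.
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (np.size(covariates) == 0):
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    k = cov.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates are collinear")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("a residualized variable has zero variance")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def screen_predictors(
    outcome,
    candidates: pd.DataFrame,
    alpha: float = 0.2,
) -> list[str]:
    """Retain candidate predictors with univariate correlation p < alpha.

    The threshold is strict: ``p == alpha`` exactly is dropped.
    """
    retained = []
    y = np.asarray(outcome, dtype=float)
    for col in candidates.columns:
        _, p = partial_correlation_pearson(candidates[col].to_numpy(dtype=float), y)
        if p < alpha:
            retained.append(col)
    return retained


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Standardized multivariable linear fit.

    ``beta`` are standardized coefficients (all variables scaled to unit
    variance before fitting), so their magnitudes are comparable across
    predictors; ``vif`` are variance inflation factors on the standardized
    design.
    """

    beta: pd.Series
    pvalues: pd.Series
    adj_r2: float
    model_p: float
    vif: pd.Series
    n_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stand_beta": self.beta, "p": self.pvalues, "vif": self.vif}
        )

    def ranked_predictors(self) -> list[str]:
        """Predictors ordered by decreasing |standardized beta|."""
        return list(self.beta.abs().sort_values(ascending=False).index)


def fit_multivariable_linear(outcome, predictors: pd.DataFrame) -> RegressionResult:
    """Multivariable OLS with standardized betas, adjusted R² and VIF.

    All variables (outcome and predictors) are standardized to zero mean and
    unit variance before fitting; rows with any missing value are dropped
    (complete-case analysis).  Perfectly collinear predictors raise an error
    naming the offending pair.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    y = np.asarray(outcome, dtype=float)
    X = predictors.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete cases, have {n}")
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [c for c, s in zip(predictors.columns, sds) if s == 0]
        raise ValueError(f"zero-variance predictors: {bad}")
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(k, 1)
    worst = np.argmax(np.abs(corr[iu])) if k > 1 else None
    if worst is not None and np.abs(corr[iu][worst]) > 1 - 1e-10:
        i, j = iu[0][worst], iu[1][worst]
        raise ValueError(
            f"perfectly collinear predictors: {predictors.columns[i]!r} and "
            f"{predictors.columns[j]!r}"
        )
    Xs = (X - X.mean(axis=0)) / sds
    ys = (y - y.mean()) / y.std(ddof=1)
    design = sm.add_constant(Xs)
    fit = sm.OLS(ys, design).fit()
    names = list(predictors.columns)
    vif = pd.Series(
        [variance_inflation_factor(design, i + 1) for i in range(k)]
        if k > 1 else [1.0],
        index=names,
    )
    return RegressionResult(
        beta=pd.Series(fit.params[1:], index=names),
        pvalues=pd.Series(fit.pvalues[1:], index=names),
        adj_r2=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        vif=vif,
        n_used=n,
    )


@dataclass
class LogisticResult:
    """Maximum-likelihood logistic fit with OR, Wald 95% CI, p and AUC."""

    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    zvalues: pd.Series
    auc: float
    n_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "OR": self.odds_ratios,
                "ci95_low": self.ci_low,
                "ci95_high": self.ci_high,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def top_predictor(self) -> str:
        """Predictor with the largest |Wald z|."""
        return str(self.zvalues.abs().idxmax())


def fit_logistic(status, predictors: pd.DataFrame) -> LogisticResult:
    """Logistic regression of a binary status on predictors.

    Reports exponentiated coefficients (odds ratios) with Wald 95%
    confidence intervals and the AUC of the fitted probabilities.  Raises
    :class:`SeparationError` on (quasi-)perfect separation and ``ValueError``
    for a single-class outcome or zero-variance predictor.
    """
    import statsmodels.api as sm
    from sklearn.metrics import roc_auc_score

    y = np.asarray(status, dtype=float)
    X = predictors.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if (X.std(axis=0, ddof=1) == 0).any():
        bad = [c for c, s in zip(predictors.columns, X.std(axis=0, ddof=1)) if s == 0]
        raise ValueError(f"zero-variance predictors: {bad}")
    design = sm.add_constant(X)
    try:
        with np.errstate(all="ignore"):
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                # Newton's Hessian goes singular near separation; quasi-Newton
                # still converges when the MLE exists
                fit = sm.Logit(y, design).fit(method="bfgs", disp=0, maxiter=500)
    except Exception as exc:  # PerfectSeparationError and kin
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    converged = fit.mle_retvals.get("converged", True)
    if (
        not converged
        or not np.all(np.isfinite(bse))
        or np.any(bse > 1e3)
        or np.any(np.abs(params[1:]) > 30)
    ):
        raise SeparationError("fit did not converge: data are (quasi-)separable")
    probs = fit.predict(design)
    if np.all(probs[y == 1].min() > probs[y == 0].max()):
        raise SeparationError("fitted probabilities perfectly separate the classes")
    names = list(predictors.columns)
    z = 1.959963984540054  # two-sided 95% normal quantile
    coef = params[1:]
    se = bse[1:]
    return LogisticResult(
        odds_ratios=pd.Series(np.exp(coef), index=names),
        ci_low=pd.Series(np.exp(coef - z * se), index=names),
        ci_high=pd.Series(np.exp(coef + z * se), index=names),
        pvalues=pd.Series(np.asarray(fit.pvalues)[1:], index=names),
        zvalues=pd.Series(coef / se, index=names),
        auc=float(roc_auc_score(y, probs)),
        n_used=int(y.size),
    )


# ---------------------------------------------------------------------------
# thresholds and transforms
# ---------------------------------------------------------------------------

def cmct_status(
    cmct: float,
    hc_mean: float,
    hc_sd: float,
    threshold: float = 1.96,
) -> tuple[float, str]:
    """CMCT z-score against the HC reference and normal/abnormal status.

    ``z = (cmct - hc_mean) / hc_sd``; abnormal iff ``z > threshold``
    strictly.  Only prolongation counts as abnormal, since a shortened
    conduction time is not pathological.
    """
    if hc_sd <= 0:
        raise ValueError("hc_sd must be > 0")
    z = (cmct - hc_mean) / hc_sd
    return float(z), "abnormal" if z > threshold else "normal"


def log_transform_fraction(values, epsilon: float = 0.01) -> np.ndarray:
    """Natural log of (lesion volume fraction + epsilon).

    The offset keeps zero fractions finite (``ln(0.01) = -4.605``) while
    reducing the right skew of the raw percentages.  Negative inputs are an
    error.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("lesion volume fractions must be >= 0")
    return np.log(values + epsilon)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def normal_tail_probability(threshold: float, two_sided: bool = True) -> float:
    """Standard-normal tail mass beyond ``threshold`` (both tails by default).

    Connects the 1.96 criterion used for lesion severity and CMCT
    abnormality to its nominal P < 0.05 calibration.
    """
    tail = sps.norm.sf(abs(threshold))
    return float(2 * tail if two_sided else tail)
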