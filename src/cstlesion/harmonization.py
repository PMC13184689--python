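"""Parametric empirical-Bayes (ComBat) site harmonization.

Removes per-site location and scale effects from a features-by-subjects
matrix while preserving biological covariates (age, sex, group).  Features
are first standardized on the covariate model; per-batch location (gamma)
and scale (delta^2) estimates are then shrunk toward pooled priors — a
normal prior on locations and an inverse-gamma prior on scales, with
method-of-moments hyperparameters — by iterating the conditional posterior
modes to convergence.  Each variable family (MTR ROIs, qT1 ROIs, CMCT,
anatomical measures) should be harmonized in its own call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "CombatModel",
    "fit_combat",
    "apply_combat",
    "harmonize",
]


@dataclass
class FeatureMatrix:
    """Features x subjects matrix with batch labels and covariates.

    ``data`` is (n_features, n_subjects); ``batch`` one site label per
    subject; ``covariates`` an optional (n_subjects, p) design of biological
    covariates to preserve (without an intercept column).
    """

    data: np.ndarray
    batch: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.batch = np.asarray(self.batch)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (features x subjects)")
        if self.batch.shape[0] != self.data.shape[1]:
            raise ValueError("one batch label per subject is required")
        if pd.isna(self.batch).any():
            raise ValueError("missing batch labels are not allowed")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.data.shape[0])]
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != self.data.shape[1]:
                raise ValueError("covariates must have one row per subject")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: list[str],
        batch_col: str = "site",
        covariate_cols: list[str] | None = None,
    ) -> "FeatureMatrix":
        """Build from a subjects-in-rows table (numeric covariates only)."""
        cov = None
        cov_names: list[str] = []
        if covariate_cols:
            cov = df[covariate_cols].to_numpy(dtype=float)
            cov_names = list(covariate_cols)
        return cls(
            data=df[feature_cols].to_numpy(dtype=float).T,
            batch=df[batch_col].to_numpy(),
            feature_names=list(feature_cols),
            covariates=cov,
            covariate_names=cov_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.data.T, columns=self.feature_names)
        out["site"] = self.batch
        return out


@dataclass
class CombatModel:
    """Fitted ComBat parameters.

    Stores the standardization model (grand mean, covariate coefficients,
    pooled variance per feature), the empirical-Bayes batch location
    (``gamma_star``) and scale (``delta2_star``) estimates, and the prior
    hyperparameters.  ``identity`` marks the single-batch degenerate model;
    ``constant_features`` flags features passed through unchanged.
    """

    batches: list
    n_per_batch: np.ndarray
    grand_mean: np.ndarray  # (G,)
    beta_cov: np.ndarray | None  # (p, G)
    var_pooled: np.ndarray  # (G,)
    gamma_star: np.ndarray  # (B, G)
    delta2_star: np.ndarray  # (B, G)
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    feature_names: list[str]
    identity: bool = False
    constant_features: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "batches": [str(b) for b in self.batches],
            "feature_names": self.feature_names,
            "identity": self.identity,
        }
        for name in ("n_per_batch", "grand_mean", "var_pooled", "gamma_star",
                     "delta2_star", "gamma_bar", "tau2", "a_prior", "b_prior"):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        if self.beta_cov is not None:
            payload["beta_cov"] = self.beta_cov.tolist()
        if self.constant_features is not None:
            payload["constant_features"] = self.constant_features.tolist()
        Path(path).write_text(json.dumps(payload, indent=2))


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return float((2 * s2 + m**2) / s2)


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return float((m * s2 + m**3) / s2)


def _it_sol(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the EB conditional posterior modes for one batch."""
    n = np.isfinite(z_batch).sum(axis=1)
    gamma_old, delta2_old = gamma_hat.copy(), delta2_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta2_old * gamma_bar) / (
            n * tau2 + delta2_old
        )
        sum2 = np.nansum((z_batch - gamma_new[:, None]) ** 2, axis=1)
        delta2_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.max(np.abs(gamma_new - gamma_old) / np.abs(gamma_old)),
            np.max(np.abs(delta2_new - delta2_old) / np.abs(delta2_old)),
        )
        gamma_old, delta2_old = gamma_new, delta2_new
        if change < conv:
            break
    return gamma_old, delta2_old


def _design(batch: np.ndarray, batches: list, covariates: np.ndarray | None) -> np.ndarray:
    onehot = np.column_stack([(batch == b).astype(float) for b in batches])
    if covariates is not None and covariates.size:
        return np.column_stack([onehot, covariates])
    return onehot


def fit_combat(fm: FeatureMatrix, conv: float = 1e-4) -> CombatModel:
    """Fit parametric ComBat on a :class:`FeatureMatrix`.

    With a single batch the returned model is the identity adjustment.
    Batches with fewer than 3 subjects trigger a warning but are shrunk
    like any other.  A rank-deficient batch+covariate design is an error;
    features constant across all subjects are flagged and passed through.
    """
    import warnings

    Y = fm.data
    batches = list(pd.unique(fm.batch))
    n_per_batch = np.array([(fm.batch == b).sum() for b in batches])
    G, N = Y.shape
    constant = np.nanstd(Y, axis=1) == 0

    if len(batches) == 1:
        return CombatModel(
            batches=batches, n_per_batch=n_per_batch,
            grand_mean=np.nanmean(Y, axis=1),
            beta_cov=None, var_pooled=np.ones(G),
            gamma_star=np.zeros((1, G)), delta2_star=np.ones((1, G)),
            gamma_bar=np.zeros(1), tau2=np.ones(1),
            a_prior=np.ones(1), b_prior=np.ones(1),
            feature_names=fm.feature_names, identity=True,
            constant_features=constant,
        )
    small = [b for b, n in zip(batches, n_per_batch) if n < 3]
    if small:
        warnings.warn(
            f"batches with fewer than 3 subjects: {small}; EB shrinkage proceeds",
            stacklevel=2,
        )
    if (n_per_batch < 2).any():
        raise ValueError("every batch needs at least 2 subjects")

    X = _design(fm.batch, batches, fm.covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch + covariate design is rank deficient")

    work = Y[~constant]
    B_hat = np.linalg.solve(X.T @ X, X.T @ work.T)  # (b+p, G')
    nb = len(batches)
    grand_mean_w = (n_per_batch / N) @ B_hat[:nb]
    resid = work.T - X @ B_hat
    var_pooled_w = (resid**2).mean(axis=0)
    if (var_pooled_w <= 0).any():
        raise ValueError("pooled variance vanished for a non-constant feature")

    beta_cov_w = B_hat[nb:] if X.shape[1] > nb else None
    stand_mean = np.tile(grand_mean_w[:, None], (1, N))
    if beta_cov_w is not None:
        stand_mean = stand_mean + (fm.covariates @ beta_cov_w).T
    Z = (work - stand_mean) / np.sqrt(var_pooled_w)[:, None]

    gamma_star_w = np.zeros((nb, work.shape[0]))
    delta2_star_w = np.zeros((nb, work.shape[0]))
    gamma_bar = np.zeros(nb)
    tau2 = np.zeros(nb)
    a_prior = np.zeros(nb)
    b_prior = np.zeros(nb)
    for i, b in enumerate(batches):
        zb = Z[:, fm.batch == b]
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1)
        gamma_bar[i] = gamma_hat.mean()
        tau2[i] = gamma_hat.var(ddof=1)
        a_prior[i] = _aprior(delta2_hat)
        b_prior[i] = _bprior(delta2_hat)
        gamma_star_w[i], delta2_star_w[i] = _it_sol(
            zb, gamma_hat, delta2_hat, gamma_bar[i], tau2[i],
            a_prior[i], b_prior[i], conv=conv,
        )

    # re-expand to the full feature set (constant features get identity)
    def expand(arr_w: np.ndarray, fill: float, per_batch: bool = False) -> np.ndarray:
        if per_batch:
            out = np.full((nb, G), fill)
            out[:, ~constant] = arr_w
        else:
            out = np.full(G, fill)
            out[~constant] = arr_w
        return out

    grand_mean = expand(grand_mean_w, 0.0)
    grand_mean[constant] = np.nanmean(Y[constant], axis=1) if constant.any() else grand_mean[constant]
    beta_cov = None
    if beta_cov_w is not None:
        beta_cov = np.zeros((beta_cov_w.shape[0], G))
        beta_cov[:, ~constant] = beta_cov_w
    return CombatModel(
        batches=batches, n_per_batch=n_per_batch,
        grand_mean=grand_mean,
        beta_cov=beta_cov,
        var_pooled=expand(var_pooled_w, 1.0),
        gamma_star=expand(gamma_star_w, 0.0, per_batch=True),
        delta2_star=expand(delta2_star_w, 1.0, per_batch=True),
        gamma_bar=gamma_bar, tau2=tau2, a_prior=a_prior, b_prior=b_prior,
        feature_names=fm.feature_names,
        constant_features=constant,
    )


def apply_combat(model: CombatModel, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted ComBat adjustment.

    Requires the same features and only batch labels seen during fitting.
    Constant (flagged) features are returned unchanged.
    """
    if fm.feature_names != model.feature_names:
        raise ValueError("feature set differs from the fitted model")
    unseen = set(pd.unique(fm.batch)) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch labels: {sorted(unseen)}")
    if model.identity:
        return FeatureMatrix(
            data=fm.data.copy(), batch=fm.batch.copy(),
            feature_names=list(fm.feature_names),
            covariates=fm.covariates, covariate_names=list(fm.covariate_names),
        )
    Y = fm.data
    N = Y.shape[1]
    stand_mean = np.tile(model.grand_mean[:, None], (1, N))
    if model.beta_cov is not None:
        if fm.covariates is None:
            raise ValueError("model was fitted with covariates; none supplied")
        stand_mean = stand_mean + (fm.covariates @ model.beta_cov).T
    sigma = np.sqrt(model.var_pooled)[:, None]
    Z = (Y - stand_mean) / sigma
    adj = Z.copy()
    for i, b in enumerate(model.batches):
        idx = fm.batch == b
        if not idx.any():
            continue
        adj[:, idx] = (Z[:, idx] - model.gamma_star[i][:, None]) / np.sqrt(
            model.delta2_star[i]
        )[:, None]
    out = adj * sigma + stand_mean
    if model.constant_features is not None and model.constant_features.any():
        out[model.constant_features] = Y[model.constant_features]
    return FeatureMatrix(
        data=out, batch=fm.batch.copy(), feature_names=list(fm.feature_names),
        covariates=fm.covariates, covariate_names=list(fm.covariate_names),
    )


def harmonize(
    df: pd.DataFrame,
    feature_cols: list[str],
    batch_col: str = "site",
    covariate_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, CombatModel]:
    """Fit-and-apply ComBat on a subjects-in-rows table; returns a copy of
    ``df`` with the feature columns replaced by harmonized values."""
    fm = FeatureMatrix.from_dataframe(df, feature_cols, batch_col, covariate_cols)
    model = fit_combat(fm)
    adj = apply_combat(model, fm)
    out = df.copy()
    out[feature_cols] = adj.data.T
    return out, model
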