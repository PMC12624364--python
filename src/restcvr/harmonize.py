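"""Multi-site harmonization of regional features by empirical-Bayes ComBat.

Scanner and acquisition differences show up as per-site shifts (location)
and stretches (scale) of regional summary features. ComBat models feature
``g`` of subject ``i`` at site ``b`` as

    y_big = alpha_g + x_i' beta_g + gamma_bg + delta_bg * eps_big

fits the covariate model jointly with site indicators, standardizes by the
covariate-predicted mean and the pooled residual SD, and shrinks the
per-site location (gamma) and scale (delta) estimates toward site-level
priors — normal for gamma, inverse-gamma for delta^2, with method-of-moments
hyperparameters — by iterating the conditional posterior means to
convergence. The adjusted value restores the covariate-predicted mean:

    y_adj = sigma_g / delta*_bg * (z_big - gamma*_bg) + alpha_g + x_i' beta_g

Biological covariates (diagnosis, sex as +/-1 codes, mean-centered age) are
protected: their associated variation is carried through untouched. rCVR
features and FC features must be harmonized in separate models; the API
operates on one feature family per model.

Sample variances use the ddof=0 convention throughout, which makes a
single-site fit an exact identity transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_transform", "harmonize_features",
           "build_biological_covariates"]

DIAGNOSIS_CODES = {"ASD": -1.0, "NA": 1.0}
SEX_CODES = {"M": -1.0, "F": 1.0}


@dataclass
class CombatModel:
    """Fitted ComBat parameters for one feature family."""

    feature_names: list[str]
    site_levels: list[str]
    covariate_names: list[str]
    coef: np.ndarray              # (n_sites + n_covariates, n_features)
    grand_mean: np.ndarray        # (n_features,)
    pooled_sd: np.ndarray         # (n_features,)
    gamma_star: np.ndarray        # (n_sites, n_features)
    delta_star: np.ndarray        # (n_sites, n_features)
    gamma_bar: np.ndarray         # (n_sites,)
    tau_sq: np.ndarray            # (n_sites,)
    a_prior: np.ndarray           # (n_sites,)
    b_prior: np.ndarray           # (n_sites,)
    n_iter: list[int] = field(default_factory=list)
    converged: bool = True

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "CombatModel":
        d = json.loads(text)
        for k in ("coef", "grand_mean", "pooled_sd", "gamma_star", "delta_star",
                  "gamma_bar", "tau_sq", "a_prior", "b_prior"):
            d[k] = np.asarray(d[k], dtype=np.float64)
        return cls(**d)


def build_biological_covariates(pheno: pd.DataFrame, include_interaction: bool = False
                                ) -> pd.DataFrame:
    """Diagnosis, sex (+/-1 codes) and mean-centered age, as ComBat covariates.

    The interaction is off by default (only the three listed covariates are
    protected); ``include_interaction=True`` adds the diagnosis-by-sex
    product term.
    """
    dx = pheno["diagnosis"].map(DIAGNOSIS_CODES)
    sex = pheno["sex"].map(SEX_CODES)
    if dx.isna().any() or sex.isna().any():
        raise ValueError("diagnosis must be ASD/NA and sex must be F/M")
    cov = pd.DataFrame({
        "diagnosis": dx.to_numpy(dtype=float),
        "sex": sex.to_numpy(dtype=float),
        "age_centered": pheno["age_years"].to_numpy(dtype=float)
        - pheno["age_years"].mean(),
    }, index=pheno.index)
    if include_interaction:
        cov["diagnosis_x_sex"] = cov["diagnosis"] * cov["sex"]
    return cov


def _aprior(delta_hat_sq: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters for the scale prior."""
    m = float(delta_hat_sq.mean())
    s2 = float(delta_hat_sq.var())
    if s2 <= 1e-12:  # all scale estimates identical: point-mass prior
        return np.inf, np.inf
    a = (2.0 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def _postmean(g_hat, g_bar, n, d_star_sq, t2):
    return (n * t2 * g_hat + d_star_sq * g_bar) / (n * t2 + d_star_sq)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _eb_site(z_site: np.ndarray, g_hat, d_hat_sq, g_bar, t2, a, b,
             tol: float = 1e-4, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means for one site to convergence."""
    n = z_site.shape[0]
    if t2 <= 1e-12 and not np.isfinite(a):
        # degenerate priors (e.g. a single site with identical estimates):
        # no information to shrink with, keep the per-feature estimates.
        return g_hat.copy(), d_hat_sq.copy(), 0
    g_new, d_new = g_hat.copy(), d_hat_sq.copy()
    for it in range(1, max_iter + 1):
        g_old, d_old = g_new, d_new
        g_new = _postmean(g_hat, g_bar, n, d_new, t2) if t2 > 1e-12 else np.full_like(
            g_hat, g_bar
        )
        sum_sq = ((z_site - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a, b) if np.isfinite(a) else d_hat_sq
        change = max(
            np.abs(g_new - g_old).max(initial=0.0),
            np.abs(d_new - d_old).max(initial=0.0),
        )
        if change < tol:
            return g_new, d_new, it
    return g_new, d_new, max_iter


def combat_fit(
    features: pd.DataFrame,
    site: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> CombatModel:
    """Fit ComBat location/scale parameters with EB shrinkage.

    ``features`` is subjects x features (one family: regional rCVR *or*
    seed-FC values, never mixed); ``site`` the batch label per subject;
    ``covariates`` the biological design to protect. Every site needs at
    least 2 subjects and the covariate design must be full rank.
    """
    Y = features.to_numpy(dtype=np.float64)
    if np.isnan(Y).any():
        raise ValueError("features contain missing values; impute or drop first")
    site = pd.Series(np.asarray(site), index=features.index, name="site")
    levels = sorted(site.unique())
    counts = site.value_counts()
    singletons = [s for s in levels if counts[s] < 2]
    if singletons:
        raise ValueError(f"sites with a single subject cannot be harmonized: {singletons}")
    onehot = np.column_stack([(site == s).to_numpy(dtype=float) for s in levels])
    if covariates is not None:
        C = covariates.to_numpy(dtype=np.float64)
        cov_names = list(covariates.columns)
        X = np.column_stack([onehot, C])
    else:
        cov_names = []
        X = onehot
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates or empty site)")

    n, _ = Y.shape
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_sites = len(levels)
    weights = np.array([counts[s] for s in levels], dtype=float) / n
    grand_mean = weights @ coef[:n_sites]
    resid = Y - X @ coef
    pooled_sd = np.sqrt((resid**2).mean(axis=0))
    if (pooled_sd == 0).any():
        raise ValueError("zero pooled variance for some feature")

    stand_mean = grand_mean[None, :] + (C @ coef[n_sites:] if cov_names else 0.0)
    Z = (Y - stand_mean) / pooled_sd[None, :]

    gamma_star = np.empty((n_sites, Y.shape[1]))
    delta_star = np.empty_like(gamma_star)
    gamma_bar = np.empty(n_sites)
    tau_sq = np.empty(n_sites)
    a_prior = np.empty(n_sites)
    b_prior = np.empty(n_sites)
    n_iter = []
    for k, s in enumerate(levels):
        rows = (site == s).to_numpy()
        z_site = Z[rows]
        g_hat = z_site.mean(axis=0)
        d_hat_sq = z_site.var(axis=0)  # ddof=0: single-site fit is an identity
        gamma_bar[k] = g_hat.mean()
        tau_sq[k] = g_hat.var()
        a_prior[k], b_prior[k] = _aprior(d_hat_sq)
        g_star, d_star_sq, its = _eb_site(
            z_site, g_hat, d_hat_sq, gamma_bar[k], tau_sq[k], a_prior[k], b_prior[k]
        )
        gamma_star[k] = g_star
        delta_star[k] = np.sqrt(np.maximum(d_star_sq, 1e-300))
        n_iter.append(its)

    return CombatModel(
        feature_names=list(features.columns), site_levels=[str(s) for s in levels],
        covariate_names=cov_names, coef=coef, grand_mean=grand_mean,
        pooled_sd=pooled_sd, gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, tau_sq=tau_sq, a_prior=a_prior, b_prior=b_prior,
        n_iter=n_iter, converged=all(i < 100 for i in n_iter),
    )


def combat_transform(
    model: CombatModel,
    features: pd.DataFrame,
    site: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a fitted ComBat model: remove site location/scale, restore the
    covariate-predicted mean."""
    if list(features.columns) != model.feature_names:
        raise ValueError("feature labels differ from the fitted model")
    Y = features.to_numpy(dtype=np.float64)
    site = pd.Series(np.asarray(site).astype(str), index=features.index)
    unseen = sorted(set(site.unique()) - set(model.site_levels))
    if unseen:
        raise ValueError(f"site labels not seen at fit time: {unseen}")
    n_sites = len(model.site_levels)
    if model.covariate_names:
        if covariates is None or list(covariates.columns) != model.covariate_names:
            raise ValueError("transform needs the same covariate columns as the fit")
        stand_mean = model.grand_mean[None, :] + covariates.to_numpy(
            dtype=np.float64
        ) @ model.coef[n_sites:]
    else:
        stand_mean = np.broadcast_to(model.grand_mean[None, :], Y.shape)
    Z = (Y - stand_mean) / model.pooled_sd[None, :]
    out = np.empty_like(Y)
    for k, s in enumerate(model.site_levels):
        rows = (site == s).to_numpy()
        if not rows.any():
            continue
        out[rows] = (
            model.pooled_sd[None, :] / model.delta_star[k][None, :]
            * (Z[rows] - model.gamma_star[k][None, :])
            + stand_mean[rows]
        )
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def harmonize_features(
    features: pd.DataFrame, pheno: pd.DataFrame, include_interaction: bool = False
) -> tuple[pd.DataFrame, CombatModel]:
    """Fit-and-transform convenience for one feature family.

    Covariates are diagnosis, sex and mean-centered age from the phenotype
    table (the diagnosis-by-sex interaction optionally added).
    """
    cov = build_biological_covariates(pheno, include_interaction=include_interaction)
    cov.index = features.index
    site = pd.Series(pheno["site"].to_numpy().astype(str), index=features.index)
    model = combat_fit(features, site, cov)
    return combat_transform(model, features, site, cov), model
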