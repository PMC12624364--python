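"""Region-wise general linear models for diagnosis, sex and their interaction.

Two-level factors are effect coded: diagnosis ASD = -1 / NA = +1 and sex
M = -1 / F = +1, so the interaction column is the product of the codes, main
effects average over the other factor's levels, and with balanced noiseless
cells the fitted coefficients equal the closed-form cell-mean contrasts
(e.g. interaction = (mu_MA + mu_FN - mu_FA - mu_MN) / 4). Age is centered at
the mean of whichever sample enters the model; mean FD enters in raw mm.

The region scan across the atlas reports uncorrected p-values (an
exploratory characterization); Benjamini-Hochberg FDR is applied only to the
declared FC target families. Post-hoc models within sex (or diagnosis)
strata disentangle sex-specific diagnostic differences, and rCVR-FC
association models regress a seed region's connectivity on its rCVR within
each subgroup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DIAGNOSIS_CODES",
    "SEX_CODES",
    "GlmFit",
    "build_design",
    "fit_glm",
    "region_effects",
    "subgroup_effects",
    "cvr_fc_association",
    "bh_fdr",
    "relation_string",
]

logger = logging.getLogger(__name__)

DIAGNOSIS_CODES = {"ASD": -1.0, "NA": 1.0}
SEX_CODES = {"M": -1.0, "F": 1.0}

KNOWN_TERMS = (
    "intercept", "diagnosis", "sex", "diagnosis_x_sex", "age_centered",
    "mean_fd", "rcvr_seed",
)

DEFAULT_TERMS = ("intercept", "diagnosis", "sex", "diagnosis_x_sex",
                 "age_centered", "mean_fd")


def _code(series: pd.Series, codes: dict[str, float], what: str) -> np.ndarray:
    vals = series.astype(str)
    unknown = sorted(set(vals) - set(codes))
    if unknown:
        raise ValueError(f"unknown {what} level(s): {unknown}")
    return vals.map(codes).to_numpy(dtype=float)


def build_design(
    pheno: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    rcvr_seed: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix for the requested terms, plus the coding record.

    Age is centered at the sample mean of the rows passed in. A term that
    turns out constant in this sample (e.g. sex in an all-male stratum) is a
    rank error, raised here with the offending column named.
    """
    unknown = sorted(set(terms) - set(KNOWN_TERMS))
    if unknown:
        raise ValueError(f"unknown design terms: {unknown}")
    cols: dict[str, np.ndarray] = {}
    coding: dict = {}
    n = len(pheno)
    for term in terms:
        if term == "intercept":
            cols[term] = np.ones(n)
        elif term == "diagnosis":
            cols[term] = _code(pheno["diagnosis"], DIAGNOSIS_CODES, "diagnosis")
            coding["diagnosis"] = dict(DIAGNOSIS_CODES)
        elif term == "sex":
            cols[term] = _code(pheno["sex"], SEX_CODES, "sex")
            coding["sex"] = dict(SEX_CODES)
        elif term == "diagnosis_x_sex":
            dx = _code(pheno["diagnosis"], DIAGNOSIS_CODES, "diagnosis")
            sx = _code(pheno["sex"], SEX_CODES, "sex")
            cols[term] = dx * sx
            coding["diagnosis_x_sex"] = "product of diagnosis and sex codes"
        elif term == "age_centered":
            age = pheno["age_years"].to_numpy(dtype=float)
            cols[term] = age - age.mean()
            coding["age_centered"] = f"age - sample mean ({age.mean():.4f})"
        elif term == "mean_fd":
            cols[term] = pheno["mean_fd"].to_numpy(dtype=float)
        elif term == "rcvr_seed":
            if rcvr_seed is None:
                raise ValueError("rcvr_seed term requested but no values supplied")
            cols[term] = np.asarray(rcvr_seed, dtype=float)
    X = pd.DataFrame(cols, index=pheno.index)
    for name in X.columns:
        if name != "intercept" and X[name].std() == 0:
            raise ValueError(f"design column {name!r} is constant in this sample")
    return X, coding


@dataclass
class GlmFit:
    """OLS fit summary: per-term beta, SE, t, two-sided p; df; coding record."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    n: int
    coding: dict


def fit_glm(y: np.ndarray, X: pd.DataFrame, coding: dict | None = None) -> GlmFit:
    """Ordinary least squares with classical (sigma^2 (X'X)^-1) standard errors.

    t statistics and two-sided p-values use the t distribution with n - k
    residual degrees of freedom.
    """
    y = np.asarray(y, dtype=np.float64)
    A = X.to_numpy(dtype=np.float64)
    n, k = A.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than design columns ({k})")
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    idx = list(X.columns)
    return GlmFit(
        params=pd.Series(beta, index=idx), bse=pd.Series(se, index=idx),
        tvalues=pd.Series(t, index=idx), pvalues=pd.Series(p, index=idx),
        df_resid=df, n=n, coding=coding or {},
    )


def region_effects(
    features: pd.DataFrame,
    pheno: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    report_terms: tuple[str, ...] = ("diagnosis", "sex", "diagnosis_x_sex"),
    max_missing_fraction: float = 0.10,
) -> pd.DataFrame:
    """One GLM per region; signed betas and uncorrected p per reported term.

    Regions missing for more than ``max_missing_fraction`` of subjects are
    skipped with a log entry. Rows with a missing value for a region are
    dropped from that region's model (age re-centered within the fitted
    sample).
    """
    if len(features) != len(pheno):
        raise ValueError("features and phenotypes disagree on subject count")
    rows = []
    for region in features.columns:
        y = features[region].to_numpy(dtype=np.float64)
        ok = np.isfinite(y)
        if (~ok).mean() > max_missing_fraction:
            logger.warning("region %s missing for %.0f%% of subjects; skipped",
                           region, 100 * (~ok).mean())
            continue
        sub = pheno.loc[ok].reset_index(drop=True)
        X, coding = build_design(sub, terms)
        fit = fit_glm(y[ok], X, coding)
        for term in report_terms:
            rows.append({
                "region": region, "term": term,
                "beta": fit.params[term], "se": fit.bse[term],
                "t": fit.tvalues[term], "p": fit.pvalues[term], "n": fit.n,
            })
    return pd.DataFrame(rows)


def subgroup_effects(
    features: pd.DataFrame,
    pheno: pd.DataFrame,
    split: str,
    term: str,
    regions: list[str] | None = None,
    min_n_warn: int = 8,
) -> pd.DataFrame:
    """Post-hoc models within strata of ``split`` ('sex' or 'diagnosis').

    Within each stratum the model is outcome ~ term + age_centered + mean_fd.
    Small strata (n below ``min_n_warn``) run with a warning; an empty
    stratum is an error.
    """
    if split not in ("sex", "diagnosis"):
        raise ValueError("split must be 'sex' or 'diagnosis'")
    regions = list(features.columns) if regions is None else regions
    rows = []
    for level in sorted(pheno[split].unique()):
        stratum = pheno[split] == level
        if not stratum.any():
            raise ValueError(f"empty stratum {split}={level}")
        n_strat = int(stratum.sum())
        if n_strat < min_n_warn:
            warnings.warn(f"stratum {split}={level} has only {n_strat} subjects",
                          stacklevel=2)
        sub_pheno = pheno.loc[stratum].reset_index(drop=True)
        for region in regions:
            y = features.loc[stratum.to_numpy(), region].to_numpy(dtype=np.float64)
            ok = np.isfinite(y)
            X, coding = build_design(
                sub_pheno.loc[ok].reset_index(drop=True),
                ("intercept", term, "age_centered", "mean_fd"),
            )
            fit = fit_glm(y[ok], X, coding)
            rows.append({
                "region": region, "stratum": f"{split}={level}", "term": term,
                "beta": fit.params[term], "se": fit.bse[term],
                "t": fit.tvalues[term], "p": fit.pvalues[term], "n": fit.n,
            })
    return pd.DataFrame(rows)


_SUBGROUPS = {
    "females": ("sex", "F", "diagnosis"),
    "males": ("sex", "M", "diagnosis"),
    "autistic": ("diagnosis", "ASD", "sex"),
    "non-autistic": ("diagnosis", "NA", "sex"),
}


def cvr_fc_association(
    seed_rcvr: pd.Series,
    fc_profiles: pd.DataFrame,
    pheno: pd.DataFrame,
    subgroup: str,
) -> pd.DataFrame:
    """Per-target GLM of seed->target FC on seed rCVR within one subgroup.

    The model is FC ~ rcvr_seed + (diagnosis within sex subgroups, or sex
    within diagnosis subgroups) + age_centered + mean_fd. BH FDR is applied
    across the target family within the subgroup.
    """
    if subgroup not in _SUBGROUPS:
        raise ValueError(f"subgroup must be one of {sorted(_SUBGROUPS)}")
    col, level, covar = _SUBGROUPS[subgroup]
    sel = (pheno[col] == level).to_numpy()
    if not sel.any():
        raise ValueError(f"subgroup {subgroup} is empty")
    sub_pheno = pheno.loc[sel].reset_index(drop=True)
    rc = seed_rcvr.to_numpy(dtype=np.float64)[sel]
    if rc.std() == 0:
        raise ValueError("seed rCVR has zero variance in this subgroup")
    rows = []
    for target in fc_profiles.columns:
        y = fc_profiles[target].to_numpy(dtype=np.float64)[sel]
        ok = np.isfinite(y)
        X, coding = build_design(
            sub_pheno.loc[ok].reset_index(drop=True),
            ("intercept", "rcvr_seed", covar, "age_centered", "mean_fd"),
            rcvr_seed=rc[ok],
        )
        fit = fit_glm(y[ok], X, coding)
        rows.append({
            "target": target, "subgroup": subgroup,
            "beta": fit.params["rcvr_seed"], "se": fit.bse["rcvr_seed"],
            "t": fit.tvalues["rcvr_seed"], "p": fit.pvalues["rcvr_seed"],
            "n": fit.n,
        })
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    return table


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    adjusted_(i) = min over j >= rank(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p must be a 1D array")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def relation_string(
    features: pd.DataFrame, pheno: pd.DataFrame, region: str, alpha: float = 0.05
) -> str:
    """Human-readable subgroup relations derived from post-hoc fits.

    For each sex stratum, reports ASD vs NA as '>', '<' or '~' (no
    significant difference), and likewise F vs M within diagnosis strata.
    Under the coding (ASD=-1, F=+1) a negative diagnosis beta means ASD>NA
    and a negative sex beta means F<M.
    """
    parts = []
    by_sex = subgroup_effects(features, pheno, "sex", "diagnosis", regions=[region])
    for _, row in by_sex.iterrows():
        level = row["stratum"].split("=")[1]
        name = {"F": "Females", "M": "Males"}[level]
        if row["p"] < alpha:
            rel = "ASD<NA" if row["beta"] > 0 else "ASD>NA"
        else:
            rel = "ASD~NA"
        parts.append(f"{name}: {rel}")
    by_dx = subgroup_effects(features, pheno, "diagnosis", "sex", regions=[region])
    for _, row in by_dx.iterrows():
        level = row["stratum"].split("=")[1]
        if row["p"] < alpha:
            rel = "F>M" if row["beta"] > 0 else "F<M"
        else:
            rel = "F~M"
        parts.append(f"{level}: {rel}")
    return "; ".join(parts)
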