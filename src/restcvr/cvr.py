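"""Relative cerebrovascular reactivity (rCVR) mapping from resting-state BOLD.

The vasodilatory stimulus is not measured: its surrogate is the whole-brain
mean BOLD signal band-limited to 0.02-0.04 Hz, the frequency of respiratory
volume changes during natural breathing. Each voxel's (preprocessed) series
is regressed on that surrogate; the slope beta is the voxel's response per
unit surrogate change. Because the surrogate has arbitrary units, beta maps
are normalized to the mean beta over white matter (or over the whole brain,
the supplementary variant), giving the dimensionless relative CVR:

    rCVR_v = beta_v / mean(beta over reference voxels)

White matter is a suitable within-subject reference because it is far less
vascularized than gray matter, so a healthy gray-matter voxel is expected at
rCVR well above 1.

Voxels whose inverse temporal SNR (temporal SD / temporal mean) exceeds the
98th percentile of in-brain voxels are excluded before normalization and
regional averaging — these are dominated by large vessels, CSF pulsation or
artifact rather than parenchymal reactivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._filters import butter_bandpass
from .core import AtlasLabels, BoldRun, Co2Surrogate, CvrMap, SegmentationMasks

__all__ = [
    "global_signal",
    "bandpass",
    "make_surrogate",
    "cvr_beta_map",
    "itsnr_exclusion",
    "normalize_cvr",
    "regional_average",
    "motion_qc",
    "MotionQcReport",
]

DEFAULT_CVR_BAND_HZ = (0.02, 0.04)
DEFAULT_ITSNR_PERCENTILE = 98.0


def global_signal(bold: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Per-frame mean BOLD signal over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_shape:
        raise ValueError("mask grid does not match the BOLD grid")
    if not mask.any():
        raise ValueError("global-signal mask is empty")
    return bold.data[mask].mean(axis=0)


def bandpass(ts: np.ndarray, lo_hz: float, hi_hz: float, tr_s: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass after linear detrend."""
    return butter_bandpass(ts, lo_hz, hi_hz, tr_s)


def make_surrogate(
    bold: BoldRun,
    masks: SegmentationMasks,
    band_hz: tuple[float, float] = DEFAULT_CVR_BAND_HZ,
) -> Co2Surrogate:
    """CO2 surrogate: band-limited whole-brain (GM+WM+CSF) mean signal."""
    gs = global_signal(bold, masks.brain)
    filtered = bandpass(gs, band_hz[0], band_hz[1], bold.tr_s)
    if filtered.std() == 0:
        raise ValueError("surrogate has zero variance (no in-band global signal)")
    return Co2Surrogate(values=filtered, band_hz=band_hz, source="gm+wm+csf")


def cvr_beta_map(bold: BoldRun, surrogate: Co2Surrogate | np.ndarray) -> np.ndarray:
    """Voxel-wise OLS slope of the BOLD series on (intercept, surrogate)."""
    x = surrogate.values if isinstance(surrogate, Co2Surrogate) else np.asarray(surrogate)
    if x.size != bold.n_frames:
        raise ValueError("surrogate length must equal the frame count")
    xc = x - x.mean()
    den = float(xc @ xc)
    if den == 0:
        raise ValueError("surrogate has zero variance")
    Y = bold.data.reshape(-1, bold.n_frames)
    beta = (Y - Y.mean(axis=1, keepdims=True)) @ xc / den
    return beta.reshape(bold.grid_shape)


def itsnr_exclusion(
    bold_with_mean: BoldRun,
    mask: np.ndarray,
    percentile: float = DEFAULT_ITSNR_PERCENTILE,
) -> np.ndarray:
    """Exclude voxels with inverse tSNR strictly above the given percentile.

    Inverse tSNR = temporal SD / temporal mean, computed on data whose voxel
    means were retained through preprocessing. The percentile is taken over
    in-mask voxels with the linear-interpolation convention; exclusion uses a
    strict ">", so an all-tied map excludes nothing. Voxels with
    non-positive temporal mean inside the mask are auto-excluded with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    mean = bold_with_mean.data.mean(axis=3)
    sd = bold_with_mean.data.std(axis=3)
    excluded = np.zeros(bold_with_mean.grid_shape, dtype=bool)
    bad_mean = mask & (mean <= 0)
    if bad_mean.any():
        warnings.warn(
            f"{int(bad_mean.sum())} in-mask voxels with non-positive temporal mean "
            "auto-excluded", stacklevel=2,
        )
        excluded |= bad_mean
    valid = mask & ~bad_mean
    itsnr = np.zeros_like(mean)
    itsnr[valid] = sd[valid] / mean[valid]
    threshold = np.percentile(itsnr[valid], percentile)
    excluded |= valid & (itsnr > threshold)
    return excluded


def normalize_cvr(
    beta: np.ndarray,
    masks: SegmentationMasks,
    excluded: np.ndarray,
    mode: str = "white_matter",
) -> CvrMap:
    """Normalize a beta map to its reference mean, producing rCVR.

    ``mode='white_matter'`` uses the mean beta over non-excluded WM voxels;
    ``mode='global'`` uses the whole brain. A reference indistinguishable
    from zero signals that no vascular signal is present and is an error.
    """
    beta = np.asarray(beta, dtype=np.float64)
    excluded = np.asarray(excluded, dtype=bool)
    if mode == "white_matter":
        ref_mask = masks.wm & ~excluded
    elif mode == "global":
        ref_mask = masks.brain & ~excluded
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if int(ref_mask.sum()) < 10:
        raise ValueError(f"reference region for {mode} normalization has <10 voxels")
    reference = float(beta[ref_mask].mean())
    scale = float(beta[masks.brain & ~excluded].std())
    if abs(reference) <= 1e-6 * max(scale, 1e-300):
        raise ValueError(
            "degenerate reference: mean reference beta is ~0 relative to the beta "
            "spread (no vascular signal present)"
        )
    rcvr = beta / reference
    rcvr = np.where(excluded, np.nan, rcvr)
    return CvrMap(
        beta=beta, rcvr=rcvr, excluded=excluded,
        normalization_mode=mode, reference_beta=reference,
    )


def regional_average(
    volume: np.ndarray, atlas: AtlasLabels, excluded: np.ndarray | None = None
) -> pd.Series:
    """Mean of a voxel map within each atlas region, skipping excluded voxels.

    Regions left with no surviving voxels are NaN (missing), never zero.
    """
    volume = np.asarray(volume, dtype=np.float64)
    keep = ~np.asarray(excluded, dtype=bool) if excluded is not None else np.ones(
        volume.shape, dtype=bool
    )
    out = {}
    for rid in atlas.region_ids:
        sel = (atlas.labels == rid) & keep
        out[atlas.lookup[rid]] = float(volume[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="regional_mean")


@dataclass
class MotionQcReport:
    """Association between rCVR and subject motion (expected: none)."""

    global_r: float
    global_p: float
    per_region: pd.DataFrame
    n_subjects: int
    low_power: bool
    undefined: bool


def motion_qc(
    regional_rcvr: pd.DataFrame,
    gm_mean_rcvr: np.ndarray,
    mean_fd: np.ndarray,
) -> MotionQcReport:
    """Correlate gray-matter mean rCVR (and each region) with mean FD.

    Within-subject normalization should make rCVR robust to motion, so a
    sound pipeline shows no significant association. Fewer than 4 subjects
    is flagged as low power; zero-variance inputs yield an undefined flag.
    """
    gm = np.asarray(gm_mean_rcvr, dtype=np.float64)
    fd = np.asarray(mean_fd, dtype=np.float64)
    if gm.size != fd.size or gm.size != len(regional_rcvr):
        raise ValueError("subject counts disagree")
    n = gm.size
    low_power = n < 4
    if low_power:
        warnings.warn(f"motion QC on only {n} subjects: low power", stacklevel=2)
    undefined = gm.std() == 0 or fd.std() == 0
    if undefined:
        g_r, g_p = np.nan, np.nan
    else:
        g_r, g_p = sps.pearsonr(gm, fd)
    rows = []
    for region in regional_rcvr.columns:
        y = regional_rcvr[region].to_numpy(dtype=np.float64)
        ok = np.isfinite(y)
        if ok.sum() < 3 or y[ok].std() == 0 or fd[ok].std() == 0:
            rows.append({"region": region, "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(y[ok], fd[ok])
        rows.append({"region": region, "r": r, "p": p})
    return MotionQcReport(
        global_r=float(g_r), global_p=float(g_p),
        per_region=pd.DataFrame(rows), n_subjects=n,
        low_power=low_power, undefined=undefined,
    )
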