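"""BOLD preprocessing: motion regressors, FD censoring, nuisance regression, smoothing.

The cleaning model regresses each voxel series on an intercept, a linear
trend, 18 motion parameters (the 6 rigid-body parameters, their backward
differences, and their squares) and one one-hot "spike" column per frame
whose framewise displacement exceeds the censoring threshold. Censoring by
spike regression is algebraically equivalent, at the kept frames, to
deleting the censored frames and regressing on the remaining design.

Framewise displacement follows the sum-of-absolute-backward-differences
convention, with rotations converted to arc length on a 50 mm sphere. The
first frame has FD = 0 by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BoldRun

__all__ = [
    "CensorInfo",
    "InclusionDecision",
    "NuisanceDesign",
    "expand_motion",
    "compute_fd",
    "censor_design",
    "check_inclusion",
    "build_nuisance_design",
    "nuisance_regress",
    "smooth_gaussian",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.25

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _validate_motion(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be (frames, 6); got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 frames")
    if not np.isfinite(motion).all():
        raise ValueError("motion trace contains non-finite values")
    return motion


def expand_motion(motion: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters into the 18-column motion design.

    Columns are ordered [6 parameters, 6 backward-difference temporal
    derivatives (first row 0), 6 element-wise squares of the parameters].
    """
    motion = _validate_motion(motion)
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    return np.hstack([motion, deriv, motion**2])


def compute_fd(motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement in mm per frame; FD of the first frame is 0.

    ``FD_t = sum_i |d translation_i| + radius * sum_j |d rotation_j|`` with
    translations in mm and rotations in radians.
    """
    motion = _validate_motion(motion)
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


@dataclass
class CensorInfo:
    """Censoring summary: FD series, per-frame keep mask and what remains."""

    fd_series: np.ndarray
    keep_mask: np.ndarray
    tr_s: float
    threshold_mm: float

    @property
    def censored_fraction(self) -> float:
        return 1.0 - float(self.keep_mask.mean())

    @property
    def remaining_seconds(self) -> float:
        return float(self.keep_mask.sum()) * self.tr_s

    @property
    def n_censored(self) -> int:
        return int((~self.keep_mask).sum())


def censor_design(
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    tr_s: float = 2.5,
) -> tuple[np.ndarray, CensorInfo]:
    """One-hot spike column per frame with FD strictly above the threshold.

    Frames at exactly the threshold are kept (the censoring rule is a strict
    "greater than").
    """
    fd = np.asarray(fd, dtype=np.float64)
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    bad = fd > threshold_mm
    spikes = np.zeros((fd.size, int(bad.sum())))
    for j, t in enumerate(np.flatnonzero(bad)):
        spikes[t, j] = 1.0
    info = CensorInfo(fd_series=fd, keep_mask=~bad, tr_s=tr_s, threshold_mm=threshold_mm)
    return spikes, info


@dataclass
class InclusionDecision:
    include: bool
    censored_fraction: float
    remaining_seconds: float
    reasons: list[str] = field(default_factory=list)


def check_inclusion(
    censor: CensorInfo,
    tr_s: float | None = None,
    max_censored_fraction: float = 0.25,
    min_remaining_minutes: float = 4.0,
) -> InclusionDecision:
    """Participant inclusion rule: include iff the censored fraction is below
    ``max_censored_fraction`` and at least ``min_remaining_minutes`` of data
    survive censoring. On exclusion every violated rule is reported."""
    if not (0 < max_censored_fraction < 1):
        raise ValueError("max_censored_fraction must be in (0, 1)")
    tr = censor.tr_s if tr_s is None else tr_s
    frac = censor.censored_fraction
    remaining = float(censor.keep_mask.sum()) * tr
    reasons = []
    if frac >= max_censored_fraction:
        reasons.append(
            f"censored fraction {frac:.4g} >= {max_censored_fraction:.4g}"
        )
    if remaining < 60.0 * min_remaining_minutes:
        reasons.append(
            f"remaining data {remaining:.4g} s < {60.0 * min_remaining_minutes:.4g} s"
        )
    return InclusionDecision(
        include=not reasons,
        censored_fraction=frac,
        remaining_seconds=remaining,
        reasons=reasons,
    )


@dataclass
class NuisanceDesign:
    """Per-frame nuisance regressor matrix with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix / label mismatch")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


_MOTION_LABELS = (
    [f"mot_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"dmot_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"mot2_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
)


def build_nuisance_design(
    n_frames: int,
    motion: np.ndarray | None = None,
    spikes: np.ndarray | None = None,
    include_trend: bool = True,
    wm_series: np.ndarray | None = None,
    csf_series: np.ndarray | None = None,
    drop_collinear: bool = True,
) -> NuisanceDesign:
    """Assemble [intercept, trend, 18 motion columns, spikes, (WM, CSF)].

    Exactly-collinear columns (e.g. all-zero motion derivatives of a still
    subject) are dropped so the design is full column rank; the intercept is
    always kept.
    """
    cols: list[np.ndarray] = [np.ones(n_frames)]
    labels: list[str] = ["intercept"]
    if include_trend:
        cols.append(np.linspace(-1.0, 1.0, n_frames))
        labels.append("trend")
    if motion is not None:
        m18 = expand_motion(motion)
        if m18.shape[0] != n_frames:
            raise ValueError("motion trace length does not match frame count")
        cols.extend(m18.T)
        labels.extend(_MOTION_LABELS)
    if spikes is not None and spikes.size:
        if spikes.shape[0] != n_frames:
            raise ValueError("spike columns do not match frame count")
        for j in range(spikes.shape[1]):
            cols.append(spikes[:, j])
            labels.append(f"spike_{int(np.argmax(spikes[:, j])):04d}")
    if wm_series is not None:
        cols.append(np.asarray(wm_series, dtype=np.float64))
        labels.append("wm_mean")
    if csf_series is not None:
        cols.append(np.asarray(csf_series, dtype=np.float64))
        labels.append("csf_mean")
    X = np.column_stack(cols)
    if drop_collinear:
        X, labels = _prune_collinear(X, labels)
    return NuisanceDesign(matrix=X, labels=labels)


def _prune_collinear(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            keep.append(j)
            basis = cand
    return X[:, keep], [labels[j] for j in keep]


def nuisance_regress(bold: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Replace every voxel series by its least-squares residual against the
    design, then add back the voxel's own temporal mean.

    Retaining the mean keeps the temporal SNR of the cleaned data defined,
    which the inverse-tSNR voxel exclusion downstream relies on. Residuals
    are orthogonal to every design column.
    """
    X = design.matrix
    if X.shape[0] != bold.n_frames:
        raise ValueError("design rows must equal the BOLD frame count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = _collinear_columns(X, design.labels)
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {offenders}")
    Y = bold.data.reshape(-1, bold.n_frames).T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + bold.data.mean(axis=3).reshape(-1, 1)
    return BoldRun(out.reshape(bold.data.shape), bold.tr_s, bold.voxel_size_mm)


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    kept, pruned = _prune_collinear(X, labels)
    return sorted(set(labels) - set(pruned))


def smooth_gaussian(
    bold: BoldRun,
    fwhm_mm: float,
    mask: np.ndarray | None = None,
) -> BoldRun:
    """Spatial Gaussian smoothing with mask renormalization.

    sigma (mm) = fwhm / (2 sqrt(2 ln 2)). With a mask, smoothing is
    renormalized by the smoothed mask so that a spatially constant image is
    unchanged inside the mask; voxels outside the mask are zeroed.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return bold.copy()
    if fwhm_mm < min(bold.voxel_size_mm):
        warnings.warn(
            f"smoothing FWHM {fwhm_mm} mm is below the voxel size "
            f"{min(bold.voxel_size_mm)} mm", stacklevel=2,
        )
    sigma_vox = tuple(fwhm_mm * _FWHM_TO_SIGMA / v for v in bold.voxel_size_mm)
    if mask is None:
        sm = ndimage.gaussian_filter(bold.data, sigma=sigma_vox + (0.0,), mode="constant")
        norm = ndimage.gaussian_filter(
            np.ones(bold.grid_shape), sigma=sigma_vox, mode="constant"
        )
        out = sm / norm[..., None]
    else:
        m = np.asarray(mask, dtype=np.float64)
        sm = ndimage.gaussian_filter(
            bold.data * m[..., None], sigma=sigma_vox + (0.0,), mode="constant"
        )
        norm = ndimage.gaussian_filter(m, sigma=sigma_vox, mode="constant")
        out = np.zeros_like(bold.data)
        inside = m > 0
        out[inside] = sm[inside] / norm[inside, None]
    return BoldRun(out, bold.tr_s, bold.voxel_size_mm)
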