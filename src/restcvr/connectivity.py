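"""Seed-based functional connectivity in the 0.008-0.1 Hz band.

For FC the cleaning model additionally regresses out the mean white-matter
and CSF series (computed over one-voxel-eroded masks to limit gray-matter
partial-volume leakage), then band-passes to 0.008-0.1 Hz. Connectivity is
the Fisher z-transformed Pearson correlation between the seed region's mean
series and every other region's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._filters import butter_bandpass
from .core import AtlasLabels, BoldRun, SegmentationMasks
from .preprocess import NuisanceDesign, nuisance_regress

__all__ = [
    "FcProfile",
    "eroded_tissue_series",
    "fc_preprocess",
    "region_timeseries",
    "seed_connectivity",
]

DEFAULT_FC_BAND_HZ = (0.008, 0.1)
_R_CLIP = 1.0 - 1e-12


def eroded_tissue_series(bold: BoldRun, masks: SegmentationMasks) -> tuple[np.ndarray, np.ndarray]:
    """Mean WM and CSF series over one-voxel-eroded masks.

    Erosion falls back to the full mask when it would empty it (small
    phantoms).
    """
    out = []
    for m in (masks.wm, masks.csf):
        er = ndimage.binary_erosion(m)
        if not er.any():
            er = m
        out.append(bold.data[er].mean(axis=0))
    return out[0], out[1]


def fc_preprocess(
    bold: BoldRun,
    design: NuisanceDesign,
    band_hz: tuple[float, float] = DEFAULT_FC_BAND_HZ,
) -> BoldRun:
    """Nuisance regression (design must carry WM/CSF series) then band-pass.

    Residuals are orthogonal to the WM/CSF columns before filtering; the
    output is demeaned per voxel.
    """
    if "wm_mean" not in design.labels or "csf_mean" not in design.labels:
        raise ValueError("FC nuisance design must include wm_mean and csf_mean series")
    cleaned = nuisance_regress(bold, design)
    flat = cleaned.data.reshape(-1, cleaned.n_frames)
    filtered = butter_bandpass(flat, band_hz[0], band_hz[1], bold.tr_s)
    return BoldRun(filtered.reshape(bold.data.shape), bold.tr_s, bold.voxel_size_mm)


def region_timeseries(bold: BoldRun, atlas: AtlasLabels) -> pd.DataFrame:
    """frames x regions matrix: column r = per-frame mean over label-r voxels.

    Empty regions yield an all-NaN column (missing), preserving alignment
    with the atlas lookup.
    """
    if atlas.labels.shape != bold.grid_shape:
        raise ValueError("atlas grid does not match the BOLD grid")
    cols = {}
    for rid in atlas.region_ids:
        sel = atlas.labels == rid
        name = atlas.lookup[rid]
        cols[name] = bold.data[sel].mean(axis=0) if sel.any() else np.full(
            bold.n_frames, np.nan
        )
    return pd.DataFrame(cols)


@dataclass
class FcProfile:
    """Seed-to-region Fisher-z connectivity values (self-connection absent)."""

    seed: str
    z: pd.Series
    r: pd.Series
    band_hz: tuple[float, float]
    flags: dict[str, str] = field(default_factory=dict)


def seed_connectivity(
    region_ts: pd.DataFrame,
    seed: str,
    band_hz: tuple[float, float] = DEFAULT_FC_BAND_HZ,
) -> FcProfile:
    """Fisher z = atanh(r) of the seed column against every other column.

    |r| is clipped to 1 - 1e-12 before atanh; a clipped (degenerate) target
    is flagged. Constant target columns give NaN and a flag.
    """
    if seed not in region_ts.columns:
        raise ValueError(f"seed region {seed!r} not in the time-series table")
    if len(region_ts) < 5:
        raise ValueError("need at least 5 frames for connectivity")
    s = region_ts[seed].to_numpy(dtype=np.float64)
    if np.nanstd(s) == 0 or not np.isfinite(s).all():
        raise ValueError("seed column is constant or missing")
    sc = s - s.mean()
    s_norm = float(np.sqrt(sc @ sc))
    z_vals, r_vals, flags = {}, {}, {}
    for col in region_ts.columns:
        if col == seed:
            continue
        y = region_ts[col].to_numpy(dtype=np.float64)
        if not np.isfinite(y).all() or y.std() == 0:
            z_vals[col] = np.nan
            r_vals[col] = np.nan
            flags[col] = "constant-or-missing"
            continue
        yc = y - y.mean()
        r = float(sc @ yc / (s_norm * np.sqrt(yc @ yc)))
        if abs(r) >= _R_CLIP:
            flags[col] = "degenerate-correlation-clipped"
            r = np.sign(r) * _R_CLIP
        r_vals[col] = r
        z_vals[col] = float(np.arctanh(r))
    return FcProfile(
        seed=seed, z=pd.Series(z_vals, name="z"), r=pd.Series(r_vals, name="r"),
        band_hz=band_hz, flags=flags,
    )
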