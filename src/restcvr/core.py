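"""Core in-memory containers shared across the pipeline.

All volumes live on one common grid: a 4D BOLD run ``(x, y, z, t)``, 3D
boolean tissue masks, and a 3D integer atlas label volume. Registration to a
common space is assumed to have happened upstream; these containers only
carry the grid geometry (voxel size) and acquisition timing (TR) that the
signal processing needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldRun",
    "SegmentationMasks",
    "AtlasLabels",
    "Co2Surrogate",
    "CvrMap",
]


@dataclass
class BoldRun:
    """A 4D voxel time-series with repetition time and voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal intensities (arbitrary scanner units).
    tr_s : float
        Repetition time in seconds; must lie in (0, 10].
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t); got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 frames")
        if not (0 < self.tr_s <= 10):
            raise ValueError(f"TR must be in (0, 10] s; got {self.tr_s}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive lengths")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.tr_s

    def copy(self) -> "BoldRun":
        return BoldRun(self.data.copy(), self.tr_s, self.voxel_size_mm)


@dataclass
class SegmentationMasks:
    """Gray matter / white matter / CSF masks on the BOLD grid.

    The three masks must be pairwise disjoint and non-empty. The union is
    used as the whole-brain mask for the global-signal extraction.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("tissue masks must share one grid")
        for name, m in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if not m.any():
                raise ValueError(f"{name} mask is empty")
        if (self.gm & self.wm).any() or (self.gm & self.csf).any() or (self.wm & self.csf).any():
            raise ValueError("tissue masks must be pairwise disjoint")

    @property
    def brain(self) -> np.ndarray:
        """Whole-brain mask: union of GM, WM and CSF."""
        return self.gm | self.wm | self.csf


@dataclass
class AtlasLabels:
    """Integer atlas label volume plus a label -> region-name lookup.

    Labels are confined to gray matter (label 0 = background). Every nonzero
    label present in the volume must appear in the lookup table.
    """

    labels: np.ndarray
    lookup: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas label volume must be integer-typed")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(int(k) for k in self.lookup)
        if missing:
            raise ValueError(f"atlas labels absent from lookup: {sorted(missing)}")
        self.lookup = {int(k): str(v) for k, v in self.lookup.items()}

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.lookup)

    @property
    def region_names(self) -> list[str]:
        return [self.lookup[i] for i in self.region_ids]

    @property
    def n_regions(self) -> int:
        return len(self.lookup)

    def validate_within(self, gm_mask: np.ndarray) -> None:
        if (self.labels[~np.asarray(gm_mask, dtype=bool)] != 0).any():
            raise ValueError("atlas labels must be confined to the gray-matter mask")


@dataclass
class Co2Surrogate:
    """Band-limited whole-brain mean signal standing in for arterial CO2.

    ``values`` is demeaned (|mean| < 1e-9); the band it was filtered to is
    recorded with the series, together with a descriptor of the mask used.
    """

    values: np.ndarray
    band_hz: tuple[float, float]
    source: str = "whole-brain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("surrogate must be a 1D time series")
        self.values = self.values - self.values.mean()
        self.band_hz = (float(self.band_hz[0]), float(self.band_hz[1]))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CvrMap:
    """Voxel-wise CVR regression slope and its normalized (rCVR) form.

    ``rcvr = beta / reference`` at non-excluded voxels; excluded voxels carry
    NaN. ``reference`` is the mean beta over non-excluded reference voxels
    (white matter, or whole brain under global normalization).
    """

    beta: np.ndarray
    rcvr: np.ndarray
    excluded: np.ndarray
    normalization_mode: str
    reference_beta: float
    extras: dict = field(default_factory=dict)
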