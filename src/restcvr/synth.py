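"""Synthetic multi-site BOLD cohorts with a full ground-truth manifest.

The generator emulates the signal structure the rCVR/FC analysis assumes:

* a band-limited (0.02-0.04 Hz) global vasodilatory signal standing in for
  arterial CO2 fluctuation during natural breathing;
* voxel-wise vasodilatory gains with gray > white matter contrast (the
  default GM:WM gain ratio is 3.5, reflecting white matter's 70-75% lower
  vascular density) and a large CSF gain so that high-fluctuation CSF voxels
  are the ones the inverse-tSNR exclusion removes;
* per-region neuronal signals band-limited to 0.008-0.1 Hz with a
  configurable inter-regional correlation;
* head motion traces with drift and spikes, plus per-frame image artifacts
  proportional to framewise displacement at spike frames;
* additive/multiplicative site effects on regional summary features (applied
  at the feature level, mirroring what the harmonization step operates on);
* injected diagnosis / sex / diagnosis-by-sex effects on regional gains
  under the same +/-1 coding the group GLMs use.

The voxel signal model is multiplicative on the baseline intensity
(percent-signal convention), so estimated regression slopes are
dimensionless gains and white-matter normalization has transparent
semantics:

    y_v(t) = B * (1 + g_v * s(t) + a_n * n_r(t)) + artifact_v(t) + eps_v(t)

with ``B`` the baseline intensity, ``g_v`` the voxel's vasodilatory gain,
``s`` the unit-variance CO2 surrogate, ``n_r`` the unit-variance neuronal
signal of the voxel's region (gray matter only), and ``eps`` i.i.d. Gaussian
noise with SD ``noise_sd`` (default tSNR = baseline/noise_sd = 50).

Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._filters import fft_bandlimit
from .core import AtlasLabels, BoldRun, SegmentationMasks
from .preprocess import compute_fd

__all__ = [
    "AcquisitionConfig",
    "MotionSpec",
    "SubjectTruth",
    "SyntheticSubject",
    "CohortConfig",
    "CohortTruth",
    "make_co2_surrogate",
    "make_motion_trace",
    "make_neuronal_signals",
    "make_correlated_pair",
    "default_geometry",
    "make_subject",
    "plan_cohort",
    "iter_subjects",
    "make_cohort",
    "make_feature_cohort",
    "apply_site_effects",
]

# +/-1 effect coding shared with the group-stats module (kept here literally
# so the generator has no import cycle with stats).
DIAGNOSIS_CODES = {"ASD": -1.0, "NA": 1.0}
SEX_CODES = {"M": -1.0, "F": 1.0}

CO2_BAND_HZ = (0.02, 0.04)
NEURONAL_BAND_HZ = (0.008, 0.1)


@dataclass
class AcquisitionConfig:
    """Scan geometry and noise level for synthetic runs.

    Defaults describe a desk-scale phantom: 20^3 grid of 4 mm voxels,
    150 frames at TR 2.5 s (inside the study's 2-3 s TR window), baseline
    1000 with noise SD 20 (tSNR 50).
    """

    n_frames: int = 150
    tr_s: float = 2.5
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 4.0
    noise_sd: float = 20.0
    baseline_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.tr_s <= 10):
            raise ValueError("tr_s must be in (0, 10]")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 4 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")


@dataclass
class MotionSpec:
    """Spike times/amplitude and drift of a subject's motion trace."""

    spike_frames: tuple[int, ...] = ()
    spike_amp_mm: float = 0.5
    drift_mm_per_frame: float = 0.0

    def __post_init__(self) -> None:
        self.spike_frames = tuple(int(f) for f in self.spike_frames)


@dataclass
class SubjectTruth:
    """Ground truth for one subject: gains, network structure, motion.

    ``regional_cvr_gain`` holds the absolute dimensionless gain per atlas
    region; ``gain_ratio`` exposes the gain relative to white matter, which
    is what the rCVR map estimates. The gray-matter mean gain must strictly
    exceed the white-matter gain.
    """

    regional_cvr_gain: np.ndarray
    wm_cvr_gain: float
    network_corr: np.ndarray
    motion_spec: MotionSpec = field(default_factory=MotionSpec)
    csf_cvr_gain: float = 0.05

    def __post_init__(self) -> None:
        self.regional_cvr_gain = np.asarray(self.regional_cvr_gain, dtype=np.float64)
        if (self.regional_cvr_gain < 0).any() or self.wm_cvr_gain < 0:
            raise ValueError("CVR gains must be non-negative")
        c = np.asarray(self.network_corr, dtype=np.float64)
        if c.shape != (self.regional_cvr_gain.size,) * 2:
            raise ValueError("network_corr must be (n_regions, n_regions)")
        if not np.allclose(c, c.T, atol=1e-12) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("network_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("network_corr must be positive semi-definite")
        self.network_corr = c
        if self.wm_cvr_gain > 0 and self.regional_cvr_gain.mean() <= self.wm_cvr_gain:
            raise ValueError("gray-matter mean gain must exceed the white-matter gain")

    @property
    def gain_ratio(self) -> np.ndarray:
        return self.regional_cvr_gain / self.wm_cvr_gain


@dataclass
class SyntheticSubject:
    """One generated subject: images, masks, atlas, motion, phenotype row."""

    bold: BoldRun
    masks: SegmentationMasks
    atlas: AtlasLabels
    motion: np.ndarray
    phenotype: dict
    truth: SubjectTruth


def make_co2_surrogate(
    n_frames: int,
    tr_s: float,
    band_hz: tuple[float, float] = CO2_BAND_HZ,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited Gaussian surrogate for arterial CO2 fluctuation.

    White noise is brick-wall band-passed (ideal zero-phase filter) and
    standardized to zero mean, unit SD, so essentially all spectral power
    lies inside the requested band. Deterministic for a fixed seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    x = fft_bandlimit(rng.standard_normal(n_frames), band_hz[0], band_hz[1], tr_s)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate surrogate (no in-band variance)")
    return (x - x.mean()) / sd


def make_motion_trace(
    n_frames: int,
    spike_frames: tuple[int, ...] = (),
    spike_amp_mm: float = 0.5,
    drift_mm_per_frame: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """6-column motion trace (3 translations mm, 3 rotations rad).

    Drift is a linear trend on the x-translation; each spike is a sustained
    step on the y-translation, so FD exceeds the spike amplitude exactly at
    the spike frame. Spikes at frame 0 are invalid (FD undefined there).
    Alternating step signs keep the trace bounded. The seed argument is part
    of the generator API for forward compatibility; the default trace is
    deterministic and noise-free.
    """
    del seed  # the base trace is deterministic
    trace = np.zeros((n_frames, 6))
    trace[:, 0] = drift_mm_per_frame * np.arange(n_frames)
    sign = 1.0
    for f in sorted(set(int(f) for f in spike_frames)):
        if not (1 <= f <= n_frames - 1):
            raise ValueError(f"spike frame {f} outside [1, {n_frames - 1}]")
        trace[f:, 1] += sign * spike_amp_mm
        sign = -sign
    return trace


def make_neuronal_signals(
    n_series: int,
    n_frames: int,
    tr_s: float,
    corr: np.ndarray | None = None,
    band_hz: tuple[float, float] = NEURONAL_BAND_HZ,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited neuronal signals (rows), unit variance, zero mean.

    With a target correlation matrix, band-limited white rows are
    orthonormalized and mixed through the Cholesky factor, so the *sample*
    correlation matrix equals the target exactly. This requires the band to
    carry at least ``n_series`` degrees of freedom (2 x number of in-band
    DFT bins); otherwise a ValueError explains the limit. With ``corr=None``
    independent band-limited rows are returned.
    """
    rng = np.random.default_rng(seed)
    x = fft_bandlimit(rng.standard_normal((n_series, n_frames)), *band_hz, tr_s)
    if corr is None or np.allclose(corr, np.eye(n_series)):
        sd = x.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("degenerate neuronal series")
        return x / sd
    freqs = np.fft.rfftfreq(n_frames, d=tr_s)
    dof = 2 * int(((freqs >= band_hz[0]) & (freqs <= band_hz[1])).sum())
    if dof < n_series:
        raise ValueError(
            f"band {band_hz} at n={n_frames}, TR={tr_s}s carries only ~{dof} degrees "
            f"of freedom; cannot impose an exact {n_series}-region correlation "
            "(reduce regions, lengthen the run, or widen the band)"
        )
    q, _ = np.linalg.qr(x.T)  # (T, R), orthonormal zero-mean columns in band span
    L = np.linalg.cholesky(np.asarray(corr, dtype=np.float64) + 1e-12 * np.eye(n_series))
    return (L @ q.T) * np.sqrt(n_frames)


def make_correlated_pair(
    rho: float, n_frames: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A pair of series with *population* correlation rho (sample r varies)."""
    rng = np.random.default_rng(seed)
    u, v = rng.standard_normal((2, n_frames))
    return u, rho * u + np.sqrt(1.0 - rho**2) * v


def default_geometry(
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    n_regions: int = 91,
) -> tuple[SegmentationMasks, AtlasLabels]:
    """Concentric-sphere phantom: WM core, GM shell, CSF rim.

    The GM shell is parcellated into ``n_regions`` compact angular sectors
    (polar bands split into azimuthal arcs of near-equal voxel count), so
    every region is non-empty and labels are confined to gray matter.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    center = (np.asarray(grid_shape) - 1) / 2.0
    ii = np.indices(grid_shape).astype(np.float64)
    d = ii - center.reshape(3, 1, 1, 1)
    r = np.sqrt((d**2).sum(axis=0))
    r_brain = 0.95 * (min(grid_shape) - 1) / 2.0
    wm = r < 0.50 * r_brain
    gm = (r >= 0.50 * r_brain) & (r < 0.82 * r_brain)
    csf = (r >= 0.82 * r_brain) & (r <= r_brain)
    n_gm = int(gm.sum())
    if n_gm < n_regions:
        raise ValueError(f"grid too small: {n_gm} GM voxels for {n_regions} regions")

    gx, gy, gz = np.nonzero(gm)
    dx, dy, dz = gx - center[0], gy - center[1], gz - center[2]
    rr = np.sqrt(dx**2 + dy**2 + dz**2)
    cos_theta = np.where(rr > 0, dz / np.maximum(rr, 1e-12), 0.0)
    phi = np.arctan2(dy, dx)
    n_bands = max(1, int(round(np.sqrt(n_regions / 2.0))))
    band = np.clip(((cos_theta + 1.0) / 2.0 * n_bands).astype(int), 0, n_bands - 1)
    order = np.lexsort((phi, band))
    labels = np.zeros(grid_shape, dtype=np.int32)
    chunks = np.array_split(order, n_regions)
    for rid, chunk in enumerate(chunks, start=1):
        labels[gx[chunk], gy[chunk], gz[chunk]] = rid
    lookup = {rid: f"region_{rid:03d}" for rid in range(1, n_regions + 1)}
    masks = SegmentationMasks(gm=gm, wm=wm, csf=csf)
    atlas = AtlasLabels(labels=labels, lookup=lookup)
    atlas.validate_within(gm)
    return masks, atlas


def make_subject(
    truth: SubjectTruth,
    acq: AcquisitionConfig,
    surrogate: np.ndarray,
    seed: int = 0,
    masks: SegmentationMasks | None = None,
    atlas: AtlasLabels | None = None,
    phenotype: dict | None = None,
    neuronal_amp: float = 0.005,
    motion_artifact_per_mm: float = 0.2,
) -> SyntheticSubject:
    """Render one subject's 4D BOLD run from its ground truth.

    ``neuronal_amp`` scales the unit-variance regional neuronal signals
    (fraction of baseline); ``motion_artifact_per_mm`` is the SD of the
    image artifact added at motion-spike frames, as a fraction of baseline
    per mm of framewise displacement. Deterministic for a fixed seed.
    """
    surrogate = np.asarray(surrogate, dtype=np.float64)
    if surrogate.size != acq.n_frames:
        raise ValueError("surrogate length must equal n_frames")
    n_regions = truth.regional_cvr_gain.size
    if masks is None or atlas is None:
        masks, atlas = default_geometry(acq.grid_shape, n_regions)
    if masks.gm.shape != acq.grid_shape:
        raise ValueError(
            f"mask grid {masks.gm.shape} does not match acquisition grid {acq.grid_shape}"
        )
    if atlas.n_regions != n_regions:
        raise ValueError("atlas region count does not match truth.regional_cvr_gain")

    # independent sub-streams so adding/removing one component (e.g. motion
    # artifacts) never changes the realization of the others
    neuro_seed, artifact_seed, noise_seed = np.random.default_rng(seed).integers(
        2**31, size=3
    )
    ms = truth.motion_spec
    motion = make_motion_trace(
        acq.n_frames, ms.spike_frames, ms.spike_amp_mm, ms.drift_mm_per_frame
    )
    fd = compute_fd(motion)

    gain = np.zeros(acq.grid_shape)
    gain[masks.wm] = truth.wm_cvr_gain
    gain[masks.csf] = truth.csf_cvr_gain
    region_of_gm = atlas.labels[masks.gm] - 1  # 0-based region index per GM voxel
    gm_gain = truth.regional_cvr_gain[region_of_gm]
    gain[masks.gm] = gm_gain

    B = acq.baseline_intensity
    brain = masks.brain
    data = np.zeros(acq.grid_shape + (acq.n_frames,))
    data[brain] = B * (1.0 + gain[brain, None] * surrogate[None, :])
    if neuronal_amp > 0:
        neuro = make_neuronal_signals(
            n_regions, acq.n_frames, acq.tr_s, corr=truth.network_corr,
            seed=int(neuro_seed),
        )
        data[masks.gm] += B * neuronal_amp * neuro[region_of_gm]
    if motion_artifact_per_mm > 0:
        art_rng = np.random.default_rng(int(artifact_seed))
        n_brain = int(brain.sum())
        for t in np.flatnonzero(fd > 0.05):
            data[brain, t] += (
                B * motion_artifact_per_mm * fd[t] * art_rng.standard_normal(n_brain)
            )
    if acq.noise_sd > 0:
        noise_rng = np.random.default_rng(int(noise_seed))
        data[brain] += noise_rng.normal(
            0.0, acq.noise_sd, size=(int(brain.sum()), acq.n_frames)
        )

    bold = BoldRun(data, acq.tr_s, (acq.voxel_size_mm,) * 3)
    pheno = dict(phenotype) if phenotype else {
        "subject_id": "sub-0001", "site": "site01", "diagnosis": "NA",
        "sex": "M", "age_years": 10.5,
    }
    return SyntheticSubject(
        bold=bold, masks=masks, atlas=atlas, motion=motion, phenotype=pheno, truth=truth
    )


# ---------------------------------------------------------------------------
# Cohort-level generation


#: Study cell sizes (diagnosis, sex) -> n, mirroring the source cohort:
#: 95 autistic (16 female) and 199 non-autistic (74 female) children.
PAPER_MIRROR_CELLS = {
    ("ASD", "M"): 79,
    ("ASD", "F"): 16,
    ("NA", "M"): 125,
    ("NA", "F"): 74,
}

#: Diagnosis-by-sex effect pattern reported for the two affected regions
#: (coefficients under +/-1 coding, rCVR units): females ASD>NA (effects
#: 0.19 and 0.14), males no significant difference.
PAPER_PATTERN_EFFECTS = {
    "diagnosis": {"region_008": -0.06, "region_020": -0.06},
    "diagnosis_x_sex": {"region_008": -0.13, "region_020": -0.08},
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic multi-site cohort.

    ``effects`` maps GLM terms (``diagnosis``, ``sex``, ``diagnosis_x_sex``)
    to per-region coefficients in rCVR (gain-ratio) units under +/-1 coding.
    ``subject_sd`` is the subject-level regional noise SD in rCVR units; the
    default 0.5 is calibrated so the printed effect sizes and p-values at
    the study's cell sizes are mutually consistent (see docs/methods.md).
    """

    cells: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("ASD", "M"): 6, ("ASD", "F"): 6,
                                 ("NA", "M"): 6, ("NA", "F"): 6}
    )
    n_sites: int = 3
    n_regions: int = 91
    acq: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    wm_gain: float = 0.004
    csf_gain: float = 0.05
    base_ratio_mean: float = 3.5
    base_ratio_sd: float = 0.5
    subject_sd: float = 0.5
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    site_additive_sd: float = 0.2
    site_multiplicative_logsd: float = 0.1
    neuronal_amp: float = 0.005
    exact_network_corr: bool = False
    motion_drift_sd: float = 0.01
    motion_spike_rate: float = 1.5
    motion_spike_amp_range: tuple[float, float] = (0.3, 1.0)
    motion_artifact_per_mm: float = 0.2
    age_range: tuple[float, float] = (9.0, 12.0)

    @classmethod
    def paper_mirror(cls, **overrides) -> "CohortConfig":
        """The study-composition cohort: 294 children over 8 sites."""
        kw = dict(cells=dict(PAPER_MIRROR_CELLS), n_sites=8)
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_subjects(self) -> int:
        return sum(self.cells.values())

    @property
    def region_names(self) -> list[str]:
        return [f"region_{i:03d}" for i in range(1, self.n_regions + 1)]


@dataclass
class CohortTruth:
    """Manifest of everything the generator injected.

    Every injected effect is recorded here so recovery tests can read the
    truth instead of re-deriving it. ``true_features`` is the subjects x
    regions matrix of true gain ratios (what a perfect rCVR pipeline would
    measure, before site effects).
    """

    subjects: list[SubjectTruth]
    phenotype: pd.DataFrame
    site_additive: pd.DataFrame
    site_multiplicative: pd.DataFrame
    group_effects: dict[str, np.ndarray]
    base_ratio: np.ndarray
    wm_gain: float
    rng_seed: int
    region_names: list[str]

    @property
    def true_features(self) -> pd.DataFrame:
        mat = np.vstack([s.gain_ratio for s in self.subjects])
        return pd.DataFrame(
            mat, index=self.phenotype["subject_id"].to_numpy(), columns=self.region_names
        )

    def to_json(self) -> str:
        # all subjects share one network correlation matrix by construction;
        # store it once rather than per subject
        payload = {
            "phenotype": self.phenotype.to_dict(orient="list"),
            "site_additive": {
                "index": list(self.site_additive.index),
                "values": self.site_additive.to_numpy().tolist(),
            },
            "site_multiplicative": {
                "index": list(self.site_multiplicative.index),
                "values": self.site_multiplicative.to_numpy().tolist(),
            },
            "group_effects": {k: v.tolist() for k, v in self.group_effects.items()},
            "base_ratio": self.base_ratio.tolist(),
            "wm_gain": self.wm_gain,
            "rng_seed": self.rng_seed,
            "region_names": self.region_names,
            "network_corr": self.subjects[0].network_corr.tolist(),
            "subjects": [
                {
                    "regional_cvr_gain": s.regional_cvr_gain.tolist(),
                    "wm_cvr_gain": s.wm_cvr_gain,
                    "csf_cvr_gain": s.csf_cvr_gain,
                    "motion_spec": asdict(s.motion_spec),
                }
                for s in self.subjects
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        corr = np.asarray(d["network_corr"])
        subjects = [
            SubjectTruth(
                regional_cvr_gain=np.asarray(s["regional_cvr_gain"]),
                wm_cvr_gain=s["wm_cvr_gain"],
                csf_cvr_gain=s["csf_cvr_gain"],
                network_corr=corr,
                motion_spec=MotionSpec(
                    spike_frames=tuple(s["motion_spec"]["spike_frames"]),
                    spike_amp_mm=s["motion_spec"]["spike_amp_mm"],
                    drift_mm_per_frame=s["motion_spec"]["drift_mm_per_frame"],
                ),
            )
            for s in d["subjects"]
        ]
        return cls(
            subjects=subjects,
            phenotype=pd.DataFrame(d["phenotype"]),
            site_additive=pd.DataFrame(
                d["site_additive"]["values"], index=d["site_additive"]["index"],
                columns=d["region_names"],
            ),
            site_multiplicative=pd.DataFrame(
                d["site_multiplicative"]["values"],
                index=d["site_multiplicative"]["index"], columns=d["region_names"],
            ),
            group_effects={k: np.asarray(v) for k, v in d["group_effects"].items()},
            base_ratio=np.asarray(d["base_ratio"]),
            wm_gain=d["wm_gain"],
            rng_seed=d["rng_seed"],
            region_names=list(d["region_names"]),
        )


def _effects_to_vectors(config: CohortConfig) -> dict[str, np.ndarray]:
    names = config.region_names
    out: dict[str, np.ndarray] = {}
    for term in ("diagnosis", "sex", "diagnosis_x_sex"):
        vec = np.zeros(config.n_regions)
        for region, coef in config.effects.get(term, {}).items():
            if isinstance(region, (int, np.integer)):
                idx = int(region) - 1
                if not (0 <= idx < config.n_regions):
                    raise ValueError(f"unknown region label {region}")
            else:
                if region not in names:
                    raise ValueError(f"unknown region label {region!r}")
                idx = names.index(region)
            vec[idx] = coef
        out[term] = vec
    unknown = set(config.effects) - {"diagnosis", "sex", "diagnosis_x_sex"}
    if unknown:
        raise ValueError(f"unknown effect terms: {sorted(unknown)}")
    return out


def plan_cohort(config: CohortConfig, seed: int) -> CohortTruth:
    """Draw the cohort-level ground truth (no images yet).

    Subjects are assigned to sites round-robin within each (diagnosis, sex)
    cell so the cells stay balanced across sites. Per-subject regional gain
    ratios are base + coded group effects + subject noise; motion specs are
    drawn per subject (drift plus Poisson-count spikes).
    """
    if min(config.cells.values(), default=0) < 1:
        raise ValueError("every requested (diagnosis, sex) cell needs n >= 1")
    if config.n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    effects = _effects_to_vectors(config)
    base = np.clip(
        rng.normal(config.base_ratio_mean, config.base_ratio_sd, config.n_regions),
        1.5, None,
    )
    sites = [f"site{i + 1:02d}" for i in range(config.n_sites)]
    site_add = pd.DataFrame(
        rng.normal(0.0, config.site_additive_sd, (config.n_sites, config.n_regions)),
        index=sites, columns=config.region_names,
    )
    site_mult = pd.DataFrame(
        np.exp(rng.normal(0.0, config.site_multiplicative_logsd,
                          (config.n_sites, config.n_regions))),
        index=sites, columns=config.region_names,
    )
    corr = np.eye(config.n_regions)

    rows, subjects = [], []
    counter = 0
    for (dx, sex), n in sorted(config.cells.items()):
        for i in range(n):
            counter += 1
            site = sites[i % config.n_sites]
            age = rng.uniform(*config.age_range)
            code = DIAGNOSIS_CODES[dx], SEX_CODES[sex]
            ratio = (
                base
                + code[0] * effects["diagnosis"]
                + code[1] * effects["sex"]
                + code[0] * code[1] * effects["diagnosis_x_sex"]
                + rng.normal(0.0, config.subject_sd, config.n_regions)
            )
            ratio = np.clip(ratio, 0.2, None)
            n_spikes = rng.poisson(config.motion_spike_rate)
            spike_frames = tuple(
                sorted(rng.choice(np.arange(1, config.acq.n_frames), size=n_spikes,
                                  replace=False))
            ) if n_spikes else ()
            ms = MotionSpec(
                spike_frames=spike_frames,
                spike_amp_mm=float(rng.uniform(*config.motion_spike_amp_range)),
                drift_mm_per_frame=float(abs(rng.normal(0.0, config.motion_drift_sd))),
            )
            truth = SubjectTruth(
                regional_cvr_gain=ratio * config.wm_gain,
                wm_cvr_gain=config.wm_gain,
                network_corr=corr,
                motion_spec=ms,
                csf_cvr_gain=config.csf_gain,
            )
            trace = make_motion_trace(
                config.acq.n_frames, ms.spike_frames, ms.spike_amp_mm,
                ms.drift_mm_per_frame,
            )
            rows.append({
                "subject_id": f"sub-{counter:04d}", "site": site, "diagnosis": dx,
                "sex": sex, "age_years": round(age, 2),
                "mean_fd": float(compute_fd(trace).mean()),
            })
            subjects.append(truth)
    pheno = pd.DataFrame(rows)
    return CohortTruth(
        subjects=subjects, phenotype=pheno, site_additive=site_add,
        site_multiplicative=site_mult, group_effects=effects, base_ratio=base,
        wm_gain=config.wm_gain, rng_seed=int(seed), region_names=config.region_names,
    )


def iter_subjects(truth: CohortTruth, config: CohortConfig, seed: int):
    """Yield SyntheticSubject one at a time (one 4D volume in memory).

    Geometry is built once and shared; per-subject render seeds derive from
    the cohort seed so the stream is reproducible.
    """
    masks, atlas = default_geometry(config.acq.grid_shape, config.n_regions)
    seed_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    render_seeds = seed_rng.integers(2**31, size=len(truth.subjects))
    for st, (_, row), s in zip(truth.subjects, truth.phenotype.iterrows(), render_seeds):
        surrogate = make_co2_surrogate(
            config.acq.n_frames, config.acq.tr_s, CO2_BAND_HZ, seed=int(s) ^ 0x5A5A
        )
        yield make_subject(
            st, config.acq, surrogate, seed=int(s), masks=masks, atlas=atlas,
            phenotype=row.to_dict(), neuronal_amp=config.neuronal_amp,
            motion_artifact_per_mm=config.motion_artifact_per_mm,
        )


def make_cohort(config: CohortConfig, seed: int) -> tuple[list[SyntheticSubject], CohortTruth]:
    """Materialize a full cohort in memory (small cohorts only)."""
    truth = plan_cohort(config, seed)
    return list(iter_subjects(truth, config, seed)), truth


def make_feature_cohort(
    config: CohortConfig, seed: int, measurement_sd: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Regional feature table straight from the truth (no image rendering).

    Returns (features, phenotype, truth) where features are true gain ratios
    with site effects applied, plus optional i.i.d. measurement noise. This
    is the fast path for cohort-level statistical studies where the imaging
    stages have already been validated.
    """
    truth = plan_cohort(config, seed)
    features = apply_site_effects(
        truth.true_features, truth.phenotype["site"].to_numpy(), truth
    )
    if measurement_sd > 0:
        rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31) ^ 0x3C3C)
        features = features + rng.normal(0.0, measurement_sd, features.shape)
    return features, truth.phenotype, truth


def apply_site_effects(
    features: pd.DataFrame, site: np.ndarray, truth: CohortTruth
) -> pd.DataFrame:
    """Apply the manifest's multiplicative then additive site effects."""
    out = features.copy()
    for s in np.unique(site):
        rows = site == s
        out.loc[rows, :] = (
            out.loc[rows, :] * truth.site_multiplicative.loc[s].to_numpy()
            + truth.site_additive.loc[s].to_numpy()
        )
    return out
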