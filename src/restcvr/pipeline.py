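"""End-to-end orchestration: simulate -> preprocess -> rCVR -> FC -> harmonize -> stats.

Subjects are processed streaming (one 4D volume in memory at a time) so a
full study-sized cohort runs on a laptop. Every output directory receives an
echo of the configuration and a run manifest keyed by the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .connectivity import (
    eroded_tissue_series,
    fc_preprocess,
    region_timeseries,
    seed_connectivity,
)
from .core import AtlasLabels, BoldRun, SegmentationMasks
from .cvr import (
    cvr_beta_map,
    itsnr_exclusion,
    make_surrogate,
    motion_qc,
    normalize_cvr,
    regional_average,
)
from .harmonize import harmonize_features
from .preprocess import (
    build_nuisance_design,
    censor_design,
    check_inclusion,
    compute_fd,
    nuisance_regress,
    smooth_gaussian,
)
from .stats import region_effects, subgroup_effects
from .synth import CohortConfig, iter_subjects, plan_cohort, apply_site_effects

__all__ = ["PipelineConfig", "SubjectResult", "RunManifest", "process_subject",
           "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults are the study's printed values."""

    band_cvr_hz: tuple[float, float] = (0.02, 0.04)
    band_fc_hz: tuple[float, float] = (0.008, 0.1)
    fd_threshold_mm: float = 0.25
    max_censored_fraction: float = 0.25
    min_remaining_minutes: float = 4.0
    smoothing_fwhm_mm: float = 8.0
    itsnr_percentile: float = 98.0
    normalization_mode: str = "white_matter"
    head_radius_mm: float = 50.0
    rng_seed: int = 0
    censor: bool = True
    compute_fc: bool = False
    fc_seeds: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band_cvr_hz", "band_fc_hz", "fc_seeds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SubjectResult:
    """Per-subject outputs of the imaging stages."""

    subject_id: str
    regional_rcvr: pd.Series
    gm_mean_rcvr: float
    wm_reference_beta: float
    mean_fd: float
    censored_fraction: float
    remaining_seconds: float
    include: bool
    exclude_reasons: list[str]
    fc_z: dict[str, pd.Series] = field(default_factory=dict)


def process_subject(
    bold: BoldRun,
    masks: SegmentationMasks,
    atlas: AtlasLabels,
    motion: np.ndarray,
    cfg: PipelineConfig,
    subject_id: str = "subject",
) -> SubjectResult:
    """Run the full single-subject imaging chain.

    Order of operations: FD + spike design, nuisance regression (trend + 18
    motion parameters + spikes), spatial smoothing, CO2-surrogate extraction
    from the fully preprocessed data, voxel-wise beta, inverse-tSNR
    exclusion, reference normalization, atlas averaging — then, optionally,
    the FC branch (WM/CSF nuisance series added, 0.008-0.1 Hz band,
    seed-to-region Fisher z).
    """
    fd = compute_fd(motion, cfg.head_radius_mm)
    spikes, censor = censor_design(fd, cfg.fd_threshold_mm, bold.tr_s)
    decision = check_inclusion(
        censor, bold.tr_s, cfg.max_censored_fraction, cfg.min_remaining_minutes
    )
    use_spikes = spikes if cfg.censor else None
    design = build_nuisance_design(bold.n_frames, motion=motion, spikes=use_spikes)
    cleaned = nuisance_regress(bold, design)
    smoothed = smooth_gaussian(cleaned, cfg.smoothing_fwhm_mm, masks.brain)
    surrogate = make_surrogate(smoothed, masks, cfg.band_cvr_hz)
    beta = cvr_beta_map(smoothed, surrogate)
    excluded = itsnr_exclusion(smoothed, masks.brain, cfg.itsnr_percentile)
    cvr_map = normalize_cvr(beta, masks, excluded, cfg.normalization_mode)
    regional = regional_average(cvr_map.rcvr, atlas, excluded)
    gm_keep = masks.gm & ~excluded
    gm_mean = float(cvr_map.rcvr[gm_keep].mean()) if gm_keep.any() else np.nan

    fc_z: dict[str, pd.Series] = {}
    if cfg.compute_fc and cfg.fc_seeds:
        wm_ts, csf_ts = eroded_tissue_series(bold, masks)
        fc_design = build_nuisance_design(
            bold.n_frames, motion=motion, spikes=use_spikes,
            wm_series=wm_ts, csf_series=csf_ts,
        )
        fc_run = fc_preprocess(bold, fc_design, cfg.band_fc_hz)
        fc_run = smooth_gaussian(fc_run, cfg.smoothing_fwhm_mm, masks.brain)
        region_ts = region_timeseries(fc_run, atlas)
        for seed in cfg.fc_seeds:
            fc_z[seed] = seed_connectivity(region_ts, seed, cfg.band_fc_hz).z

    return SubjectResult(
        subject_id=subject_id,
        regional_rcvr=regional,
        gm_mean_rcvr=gm_mean,
        wm_reference_beta=cvr_map.reference_beta,
        mean_fd=float(fd.mean()),
        censored_fraction=censor.censored_fraction,
        remaining_seconds=censor.remaining_seconds,
        include=decision.include,
        exclude_reasons=decision.reasons,
        fc_z=fc_z,
    )


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    config_hash: str
    version: str
    stages: list[str]
    n_subjects: int
    n_included: int
    inclusion: dict[str, dict]
    outputs: dict[str, str]

    def write(self, path: str | Path) -> None:
        rio.write_json(dataclasses.asdict(self), path)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    cohort_config: CohortConfig | None = None,
    input_dir: str | Path | None = None,
    seed: int | None = None,
    write_subject_files: bool = False,
) -> RunManifest:
    """Execute every stage and write TSV/JSON outputs under ``out_dir``.

    Either simulate a cohort (``cohort_config``) or read one from
    ``input_dir`` (per-subject ``<id>_bold.nii.gz`` and ``<id>_motion.txt``,
    shared masks/atlas, ``phenotypes.tsv``). Subjects failing the inclusion
    rule are dropped before harmonization, with reasons recorded in the
    manifest.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.rng_seed if seed is None else seed
    stages: list[str] = []
    outputs: dict[str, str] = {}

    # ---- stage: acquire subjects -------------------------------------------
    truth = None
    if cohort_config is not None:
        truth = plan_cohort(cohort_config, seed)
        pheno = truth.phenotype.copy()
        subjects = iter_subjects(truth, cohort_config, seed)
        (out / "truth.json").write_text(truth.to_json())
        outputs["truth"] = str(out / "truth.json")
        stages.append("simulate")
    elif input_dir is not None:
        input_dir = Path(input_dir)
        pheno = rio.read_phenotypes(input_dir / "phenotypes.tsv")
        masks = rio.read_masks(input_dir)
        atlas = rio.read_atlas(input_dir / "atlas.nii.gz", input_dir / "atlas_lookup.tsv")

        def _reader():
            for sid in pheno["subject_id"]:
                yield sid, rio.read_bold(input_dir / f"{sid}_bold.nii.gz"), rio.read_motion(
                    input_dir / f"{sid}_motion.txt"
                )

        subjects = None
    else:
        raise ValueError("either cohort_config or input_dir is required")

    # ---- stage: per-subject imaging ----------------------------------------
    results: list[SubjectResult] = []
    if cohort_config is not None:
        for subj in subjects:
            sid = subj.phenotype["subject_id"]
            if write_subject_files:
                rio.write_bold(subj.bold, out / f"{sid}_bold.nii.gz")
                rio.write_motion(subj.motion, out / f"{sid}_motion.txt")
            results.append(
                process_subject(subj.bold, subj.masks, subj.atlas, subj.motion, cfg, sid)
            )
            masks, atlas = subj.masks, subj.atlas
    else:
        for sid, bold, motion in _reader():
            results.append(process_subject(bold, masks, atlas, motion, cfg, sid))
    stages.append("preprocess+rcvr" + ("+fc" if cfg.compute_fc else ""))

    features = pd.DataFrame(
        {r.subject_id: r.regional_rcvr for r in results}
    ).T
    features.index.name = "subject_id"
    if truth is not None:
        features = apply_site_effects(features, pheno["site"].to_numpy(), truth)
    qc = pd.DataFrame([
        {
            "subject_id": r.subject_id, "mean_fd": r.mean_fd,
            "censored_fraction": r.censored_fraction,
            "remaining_minutes": r.remaining_seconds / 60.0,
            "include": r.include, "reasons": "; ".join(r.exclude_reasons),
        }
        for r in results
    ]).set_index("subject_id")
    rio.write_table(qc, out / "qc.tsv")
    outputs["qc"] = str(out / "qc.tsv")
    pheno = pheno.set_index("subject_id", drop=False)
    pheno["mean_fd"] = qc["mean_fd"]

    # ---- stage: motion QC ---------------------------------------------------
    gm_means = np.array([r.gm_mean_rcvr for r in results])
    if len(results) >= 4:
        report = motion_qc(features, gm_means, qc["mean_fd"].to_numpy())
        rio.write_json(
            {"global_r": report.global_r, "global_p": report.global_p},
            out / "motion_qc.json",
        )
        outputs["motion_qc"] = str(out / "motion_qc.json")
        stages.append("motion_qc")

    # ---- stage: inclusion ---------------------------------------------------
    included = [r.subject_id for r in results if r.include]
    inclusion = {
        r.subject_id: {"include": r.include, "reasons": r.exclude_reasons}
        for r in results
    }
    features_inc = features.loc[included]
    pheno_inc = pheno.loc[included].reset_index(drop=True)
    rio.write_table(features_inc, out / "rcvr_regional_raw.tsv")
    stages.append("inclusion")

    # ---- stage: harmonization (one model per feature family) ---------------
    n_sites = pheno_inc["site"].nunique()
    if n_sites > 1 and len(pheno_inc) > n_sites * 2:
        harmonized, model = harmonize_features(features_inc, pheno_inc)
        (out / "combat_rcvr.json").write_text(model.to_json())
        outputs["combat_rcvr"] = str(out / "combat_rcvr.json")
        stages.append("harmonize")
    else:
        harmonized = features_inc
        logger.info("single site or tiny cohort: harmonization skipped")
    rio.write_table(harmonized, out / "rcvr_regional.tsv")
    outputs["rcvr_regional"] = str(out / "rcvr_regional.tsv")

    # ---- stage: group statistics -------------------------------------------
    stats_table = region_effects(harmonized, pheno_inc)
    rio.write_table(stats_table, out / "stats_regions.tsv", index=False)
    outputs["stats_regions"] = str(out / "stats_regions.tsv")
    sig_int = stats_table.query("term == 'diagnosis_x_sex' and p < 0.05")["region"]
    if len(sig_int):
        posthoc = subgroup_effects(
            harmonized, pheno_inc, split="sex", term="diagnosis",
            regions=list(sig_int),
        )
        rio.write_table(posthoc, out / "stats_posthoc_sex.tsv", index=False)
        outputs["stats_posthoc_sex"] = str(out / "stats_posthoc_sex.tsv")
    stages.append("stats")

    # ---- stage: FC harmonization + association ------------------------------
    if cfg.compute_fc and cfg.fc_seeds:
        from .stats import cvr_fc_association

        for seed_region in cfg.fc_seeds:
            fc_table = pd.DataFrame(
                {r.subject_id: r.fc_z[seed_region] for r in results}
            ).T.loc[included]
            if n_sites > 1 and len(pheno_inc) > n_sites * 2:
                fc_table, fc_model = harmonize_features(fc_table, pheno_inc)
            assoc = []
            for subgroup in ("females", "males", "autistic", "non-autistic"):
                try:
                    assoc.append(cvr_fc_association(
                        harmonized[seed_region], fc_table, pheno_inc, subgroup
                    ))
                except ValueError as err:
                    logger.warning("FC association %s/%s skipped: %s",
                                   seed_region, subgroup, err)
            if assoc:
                table3 = pd.concat(assoc, ignore_index=True)
                table3.insert(0, "seed", seed_region)
                path = out / f"stats_cvr_fc_{seed_region}.tsv"
                rio.write_table(table3, path, index=False)
                outputs[f"cvr_fc_{seed_region}"] = str(path)
        stages.append("cvr_fc")

    rio.write_json(cfg.to_dict(), out / "config.json")
    manifest = RunManifest(
        config=cfg.to_dict(), config_hash=cfg.config_hash, version=__version__,
        stages=stages, n_subjects=len(results), n_included=len(included),
        inclusion=inclusion, outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
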