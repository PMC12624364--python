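"""File I/O: NIfTI volumes, motion text tables, phenotype TSV, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AtlasLabels, BoldRun, SegmentationMasks

__all__ = [
    "read_bold", "write_bold", "write_volume", "read_volume",
    "read_masks", "write_masks", "read_atlas", "write_atlas",
    "read_motion", "write_motion",
    "read_phenotypes", "write_phenotypes",
    "read_table", "write_table", "write_json", "read_json",
]

PHENO_CATEGORIES = {"diagnosis": {"ASD", "NA"}, "sex": {"F", "M"}}
REQUIRED_PHENO_COLUMNS = ("subject_id", "site", "diagnosis", "sex", "age_years")


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def read_bold(path: str | Path, tr_override_s: float | None = None) -> BoldRun:
    """Load a 4D NIfTI; TR comes from the time-axis spacing unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = tr_override_s if tr_override_s is not None else (
        float(zooms[3]) if len(zooms) > 3 else 0.0
    )
    if not tr or tr <= 0:
        raise ValueError(f"{path}: TR missing from header and no override given")
    return BoldRun(data, tr_s=tr, voxel_size_mm=tuple(float(z) for z in zooms[:3]))


def write_bold(bold: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float64), _affine(bold.voxel_size_mm))
    img.header.set_zooms(bold.voxel_size_mm + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_volume(volume: np.ndarray, path: str | Path,
                 voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)) -> None:
    """Write a 3D map (float) or label/mask volume (integer) as NIfTI."""
    arr = np.asarray(volume)
    dtype = np.int32 if arr.dtype.kind in "bui" else np.float64
    nib.save(nib.Nifti1Image(arr.astype(dtype), _affine(voxel_size_mm)), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data


def write_masks(masks: SegmentationMasks, out_dir: str | Path, prefix: str = "",
                voxel_size_mm=(4.0, 4.0, 4.0)) -> None:
    out = Path(out_dir)
    for name in ("gm", "wm", "csf"):
        write_volume(getattr(masks, name).astype(np.int32),
                     out / f"{prefix}mask_{name}.nii.gz", voxel_size_mm)


def read_masks(out_dir: str | Path, prefix: str = "") -> SegmentationMasks:
    out = Path(out_dir)
    vols = {name: read_volume(out / f"{prefix}mask_{name}.nii.gz") > 0
            for name in ("gm", "wm", "csf")}
    return SegmentationMasks(**vols)


def write_atlas(atlas: AtlasLabels, path: str | Path, lookup_path: str | Path,
                voxel_size_mm=(4.0, 4.0, 4.0)) -> None:
    write_volume(atlas.labels, path, voxel_size_mm)
    pd.DataFrame(
        {"label": atlas.region_ids, "region": atlas.region_names}
    ).to_csv(lookup_path, sep="\t", index=False)


def read_atlas(path: str | Path, lookup_path: str | Path) -> AtlasLabels:
    labels = read_volume(path).astype(np.int32)
    tab = pd.read_csv(lookup_path, sep="\t")
    return AtlasLabels(labels=labels,
                       lookup=dict(zip(tab["label"].astype(int), tab["region"])))


def read_motion(path: str | Path) -> np.ndarray:
    """6-column whitespace-delimited motion parameters (mm, mm, mm, rad x3)."""
    motion = np.loadtxt(str(path))
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns")
    return motion


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(motion), fmt="%.8f")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with subject_id, site, diagnosis {ASD,NA}, sex {F,M}, age.

    Unknown category levels and duplicate subject ids are errors naming the
    offending rows; an optional (possibly empty) IQ column is tolerated.
    """
    # keep_default_na: the non-autistic group label "NA" must survive parsing
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False, na_values=[""])
    if "age" in df.columns and "age_years" not in df.columns:
        df = df.rename(columns={"age": "age_years"})
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    for col, allowed in PHENO_CATEGORIES.items():
        bad = ~df[col].astype(str).isin(allowed)
        if bad.any():
            offenders = df.loc[bad, ["subject_id", col]].to_dict(orient="records")
            raise ValueError(f"{path}: invalid {col} values: {offenders}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject ids: {sorted(dup.unique())}")
    if (df["age_years"] <= 0).any():
        raise ValueError(f"{path}: ages must be positive")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(str(path), sep="\t", index=False)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(str(path), sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
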