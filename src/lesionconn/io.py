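"""File formats: ROI time-series TSV, motion parameter text files (with
dialect handling), partition and manifest TSVs, square matrix dumps, YAML
configs, and the optional NIfTI extraction path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, NetworkPartition, SubjectRecord
from .preprocess import extract_roi_series

__all__ = [
    "MotionDialect",
    "write_timeseries", "read_timeseries",
    "write_motion", "read_motion",
    "write_partition", "read_partition",
    "write_matrix", "read_matrix",
    "write_dataset", "read_dataset",
    "write_config", "read_config",
    "extract_nifti_series",
]


@dataclass(frozen=True)
class MotionDialect:
    """Column convention of a 6-parameter motion file.

    ``order``: "trans-first" (3 translations then 3 rotations, the default)
    or "rot-first".  ``rotation_unit``: "rad" or "deg".
    """

    order: str = "trans-first"
    rotation_unit: str = "rad"

    def to_canonical(self, raw: np.ndarray) -> np.ndarray:
        """Return (T, 6) as translations (mm) then rotations (radians)."""
        P = np.asarray(raw, dtype=float)
        if P.ndim != 2 or P.shape[1] != 6:
            raise ValueError("motion file must have 6 columns")
        if self.order == "rot-first":
            P = P[:, [3, 4, 5, 0, 1, 2]]
        elif self.order != "trans-first":
            raise ValueError(f"unknown order {self.order!r}")
        if self.rotation_unit == "deg":
            P = P.copy()
            P[:, 3:] = np.deg2rad(P[:, 3:])
        elif self.rotation_unit != "rad":
            raise ValueError(f"unknown rotation unit {self.rotation_unit!r}")
        return P


def write_timeseries(path, roi_series: np.ndarray,
                     roi_ids: list[str] | None = None) -> None:
    """Rows = ROIs, columns = volumes, first column = ROI id."""
    n, T = roi_series.shape
    ids = roi_ids or [f"roi{i:03d}" for i in range(n)]
    df = pd.DataFrame(roi_series, index=pd.Index(ids, name="roi_id"),
                      columns=[f"t{t:04d}" for t in range(T)])
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_motion(path, params: np.ndarray) -> None:
    np.savetxt(path, params, fmt="%.10g")


def read_motion(path, dialect: MotionDialect = MotionDialect()) -> np.ndarray:
    try:
        raw = np.loadtxt(path)
    except ValueError as exc:
        raise ValueError(f"malformed motion file {path}: {exc}") from exc
    return dialect.to_canonical(np.atleast_2d(raw))


def write_partition(path, partition: NetworkPartition,
                    roi_ids: list[str] | None = None) -> None:
    n = partition.n_rois
    ids = roi_ids or [f"roi{i:03d}" for i in range(n)]
    df = pd.DataFrame({
        "roi_id": ids,
        "network_label": [partition.names[k] for k in partition.labels],
        "is_lesion": [int(i in partition.lesion) for i in range(n)],
    })
    df.to_csv(path, sep="\t", index=False)


def read_partition(path) -> tuple[NetworkPartition, list[str]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "network_label", "is_lesion"):
        if col not in df.columns:
            raise ValueError(f"partition file missing column {col!r}")
    names = tuple(dict.fromkeys(df["network_label"]))
    idx = {n: k for k, n in enumerate(names)}
    labels = np.array([idx[n] for n in df["network_label"]])
    lesion = frozenset(np.flatnonzero(df["is_lesion"].to_numpy() != 0).tolist())
    return (NetworkPartition(labels=labels, names=names, lesion=lesion),
            list(df["roi_id"]))


def write_matrix(path, matrix: np.ndarray, ids: list[str]) -> None:
    pd.DataFrame(matrix, index=pd.Index(ids, name="roi_id"),
                 columns=ids).to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_dataset(out_dir, spec: CohortSpec, subjects: list[SubjectRecord],
                  partition: NetworkPartition) -> Path:
    """One TSV + motion file per subject, a partition TSV, a manifest TSV
    and the generator configuration echoed to YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        ts = out / f"{sub.id}_timeseries.tsv"
        mo = out / f"{sub.id}_motion.txt"
        art = out / f"{sub.id}_artifacts.tsv"
        write_timeseries(ts, sub.roi_series)
        write_motion(mo, sub.motion_params)
        write_timeseries(art, sub.artifact_series,
                         roi_ids=["wm", "csf", "whole_brain"])
        rows.append({"id": sub.id, "group": sub.group, "sex": sub.sex,
                     "timeseries": ts.name, "motion": mo.name,
                     "artifacts": art.name})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_partition(out / "partition.tsv", partition)
    write_config(out / "cohort_spec.yaml", spec)
    return out


def read_dataset(data_dir) -> tuple[list[SubjectRecord], NetworkPartition]:
    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.tsv", sep="\t")
    partition, _ = read_partition(data / "partition.tsv")
    subjects = []
    for _, row in manifest.iterrows():
        roi, _ = read_timeseries(data / row["timeseries"])
        art, _ = read_timeseries(data / row["artifacts"])
        params = read_motion(data / row["motion"])
        subjects.append(SubjectRecord(
            roi_series=roi, motion_params=params, artifact_series=art,
            group=row["group"], sex=row["sex"], id=row["id"]))
    return subjects, partition


def write_config(path, spec_or_dict) -> None:
    if isinstance(spec_or_dict, CohortSpec):
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(spec_or_dict).items()}
    else:
        data = dict(spec_or_dict)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def extract_nifti_series(image_path, label_path, min_overlap: float = 0.5):
    """Per-label ROI series from a 4D NIfTI and an integer label image.

    The image mask is the set of voxels with non-zero temporal variance.
    Labels with fewer than ``min_overlap`` of their voxels inside the mask
    are excluded (returned separately), mirroring coverage-based ROI
    exclusion.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=float)
    lab = np.asanyarray(nib.load(str(label_path)).dataobj)
    lab = np.rint(lab).astype(int)
    if img.ndim != 4:
        raise ValueError("expected a 4D image")
    if lab.shape != img.shape[:3]:
        raise ValueError("label image does not match the 4D image grid")
    mask = img.std(axis=3) > 0
    series: dict[int, np.ndarray] = {}
    excluded: list[int] = []
    for label in np.unique(lab):
        if label == 0:
            continue
        vox = lab == label
        inside = vox & mask
        if inside.sum() < min_overlap * vox.sum():
            excluded.append(int(label))
            continue
        block = img[inside]                 # (voxels, T)
        series[int(label)] = extract_roi_series(block).values
    return series, excluded
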