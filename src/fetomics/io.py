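"""Readers/writers: NIfTI volumes and masks, the cohort fixture, feature tables
and metric reports.

Volumes are stored as NIfTI-1 with a diagonal affine built from the voxel
spacing (the phantom has no anatomical orientation); values round-trip at
float32 precision, spacing exactly.  The packaged cohort CSV transcribes the
34-patient study table (diagnosis, conventional PET parameters, survival
with censoring flags) and is the input to the table-reproduction statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicPETSeries, FrameSchedule, VOIMask, make_frame_schedule

__all__ = [
    "CohortRecord",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "load_table1_fixture",
    "fixture_frame",
    "write_metrics_report",
    "write_feature_table",
    "read_feature_table",
]


@dataclass(frozen=True)
class CohortRecord:
    """One patient of the clinical cohort table."""

    patient_id: int
    diagnosis: str  # "EP" or "PSP"
    tbr_mean: float
    tbr_max: float
    ttp: float  # minutes
    slope: float  # SUV/h
    pfs_months: float | None
    os_months: float | None
    pfs_censored: bool
    os_censored: bool
    mgmt: str  # "meth" | "unmeth" | "missing"
    idh: str  # "wt" | "mut"


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_series(series: DynamicPETSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.values.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms((*series.voxel_size, 1.0))
    nib.save(img, str(path))


def read_series(
    path: str | Path, schedule: FrameSchedule | None = None
) -> DynamicPETSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D NIfTI (x, y, z, frame), got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    schedule = schedule or make_frame_schedule()
    return DynamicPETSeries(
        values=data, voxel_size=tuple(float(z) for z in zooms), schedule=schedule
    )


def write_mask(voi: VOIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(voi.mask.astype(np.uint8), _affine(voi.voxel_size))
    img.header.set_zooms(voi.voxel_size)
    nib.save(img, str(path))


def read_mask(path: str | Path, provenance: str = "background") -> VOIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI mask, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return VOIMask(
        mask=data > 0,
        voxel_size=tuple(float(z) for z in zooms),
        provenance=provenance,
    )


def fixture_frame() -> pd.DataFrame:
    """The packaged 34-patient cohort table as a DataFrame."""
    with resources.files("fetomics.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df.rename(columns={"ttp_min": "ttp", "slope_suv_h": "slope"})
    return df


def load_table1_fixture() -> list[CohortRecord]:
    """The packaged cohort as typed records (missing values -> None)."""
    df = fixture_frame()
    records = []
    for _, r in df.iterrows():
        records.append(
            CohortRecord(
                patient_id=int(r["patient_id"]),
                diagnosis=str(r["diagnosis"]),
                tbr_mean=float(r["tbr_mean"]),
                tbr_max=float(r["tbr_max"]),
                ttp=float(r["ttp"]),
                slope=float(r["slope"]),
                pfs_months=None if pd.isna(r["pfs_months"]) else float(r["pfs_months"]),
                os_months=None if pd.isna(r["os_months"]) else float(r["os_months"]),
                pfs_censored=bool(r["pfs_censored"]),
                os_censored=bool(r["os_censored"]),
                mgmt="missing" if pd.isna(r["mgmt"]) else str(r["mgmt"]),
                idh=str(r["idh"]),
            )
        )
    return records


def write_metrics_report(metrics, path: str | Path) -> None:
    """JSON serialization of a ClassificationMetrics (or a dict of them)."""
    from .stats import ClassificationMetrics  # local import to avoid a cycle

    def encode(obj):
        if isinstance(obj, ClassificationMetrics):
            return obj.as_dict()
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(json.dumps(encode(metrics), indent=2, allow_nan=True))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV serialization of a feature table (keys + 944 feature columns).

    An empty table still writes the full canonical header so downstream
    schema checks do not depend on content.
    """
    from .radiomics.engine import feature_names

    if table.empty and not any(c.startswith("original_") for c in table.columns):
        table = pd.DataFrame(
            columns=["patient_id", "segmentation_threshold"] + feature_names()
        )
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
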