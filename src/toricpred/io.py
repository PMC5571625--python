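"""Cohort CSV schema, ingest/emit, and run manifests.

A cohort is one row per eye.  Units are fixed by the column dictionary
below: diopters (D) for powers and cylinders, degrees for axes, millimetres
for radii/axial length/ACD, micrometres for pachymetry.  Manifest
refractions are in minus- (or plus-) cylinder spectacle notation; on ingest
the cylinder is converted to a steep-meridian astigmatism (steep meridian =
cylinder axis + 90° for minus cylinder).

Cohort CSVs are written at full float precision so that write→read is
lossless; rounded formatting is applied only to derived results tables.
Leading ``#`` comment lines stamp the seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .double_angle import Astigmatism
from .optics import SurfaceGeometry

#: Column dictionary of the eye-record CSV (name → description, units).
COLUMN_DICTIONARY: dict[str, str] = {
    "eye_id": "unique eye identifier",
    "subgroup_axis_deg": "preoperative anterior steep meridian used for WTR/ATR grouping (deg)",
    "ant_r_steep_mm": "preop anterior corneal radius, steep meridian (mm)",
    "ant_r_flat_mm": "preop anterior corneal radius, flat meridian (mm)",
    "ant_axis_deg": "preop anterior steep-meridian axis (deg)",
    "post_r_steep_mm": "preop posterior corneal radius, steep meridian (mm)",
    "post_r_flat_mm": "preop posterior corneal radius, flat meridian (mm)",
    "post_axis_deg": "preop posterior steep-meridian axis (deg)",
    "ant_r_steep_1m_mm": "1-month anterior radius, steep meridian (mm)",
    "ant_r_flat_1m_mm": "1-month anterior radius, flat meridian (mm)",
    "ant_axis_1m_deg": "1-month anterior steep axis (deg)",
    "post_r_steep_1m_mm": "1-month posterior radius, steep meridian (mm)",
    "post_r_flat_1m_mm": "1-month posterior radius, flat meridian (mm)",
    "post_axis_1m_deg": "1-month posterior steep axis (deg)",
    "ant_r_steep_3m_mm": "3-month anterior radius, steep meridian (mm)",
    "ant_r_flat_3m_mm": "3-month anterior radius, flat meridian (mm)",
    "ant_axis_3m_deg": "3-month anterior steep axis (deg)",
    "post_r_steep_3m_mm": "3-month posterior radius, steep meridian (mm)",
    "post_r_flat_3m_mm": "3-month posterior radius, flat meridian (mm)",
    "post_axis_3m_deg": "3-month posterior steep axis (deg)",
    "axial_length_mm": "axial length (mm)",
    "acd_mm": "anterior chamber depth (mm)",
    "cct_um": "central corneal thickness (µm); may be empty",
    "iol_sphere_d": "implanted IOL spherical-equivalent power (D)",
    "iol_toric_cyl_d": "implanted IOL toric cylinder at the IOL plane (D)",
    "intended_axis_deg": "intended toric IOL alignment axis (deg)",
    "observed_axis_1m_deg": "observed IOL axis at 1 month (deg)",
    "observed_axis_3m_deg": "observed IOL axis at 3 months (deg)",
    "manifest_pre_sphere_d": "preop manifest sphere, spectacle plane (D)",
    "manifest_pre_cyl_d": "preop manifest cylinder, spectacle plane (D, signed)",
    "manifest_pre_axis_deg": "preop manifest cylinder axis (deg)",
    "manifest_1m_sphere_d": "1-month manifest sphere (D)",
    "manifest_1m_cyl_d": "1-month manifest cylinder (D, signed)",
    "manifest_1m_axis_deg": "1-month manifest cylinder axis (deg)",
    "manifest_3m_sphere_d": "3-month manifest sphere (D)",
    "manifest_3m_cyl_d": "3-month manifest cylinder (D, signed)",
    "manifest_3m_axis_deg": "3-month manifest cylinder axis (deg)",
    "iolmaster_mag_d": "IOLMaster corneal astigmatism magnitude (D)",
    "iolmaster_axis_deg": "IOLMaster steep-meridian axis (deg)",
    "simk_mag_d": "Pentacam SimK astigmatism magnitude (D)",
    "simk_axis_deg": "Pentacam SimK steep axis (deg)",
    "wavefront_mag_d": "Pentacam corneal-wavefront astigmatism magnitude (D)",
    "wavefront_axis_deg": "Pentacam corneal-wavefront steep axis (deg)",
    "barrett_iolmaster_mag_d": "Barrett toric calculator astigmatism on IOLMaster Ks (D, optional)",
    "barrett_iolmaster_axis_deg": "its steep axis (deg, optional)",
    "barrett_simk_mag_d": "Barrett toric calculator astigmatism on SimK (D, optional)",
    "barrett_simk_axis_deg": "its steep axis (deg, optional)",
}

REQUIRED_COLUMNS = [c for c in COLUMN_DICTIONARY if not c.startswith("barrett_")]


@dataclass
class RunManifest:
    """Provenance record written next to every output set."""

    seed: Optional[int]
    config_sha256: str
    package_version: str = __version__
    inputs: dict[str, str] | None = None
    timestamp: str = ""

    def write(self, path: Path) -> None:
        payload = {
            "package": "toricpred",
            "package_version": self.package_version,
            "seed": self.seed,
            "config_sha256": self.config_sha256,
            "inputs": self.inputs or {},
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_cohort_csv(df: pd.DataFrame, path: str | Path, *, seed=None, config_sha256="") -> None:
    path = Path(path)
    header = f"# toricpred cohort v{__version__}; seed={seed}; config_sha256={config_sha256}\n"
    path.write_text(header + df.to_csv(index=False))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema check; raises with row/column coordinates on violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    problems: list[str] = []
    for col in df.columns:
        if col == "eye_id" or col not in COLUMN_DICTIONARY:
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        allowed_na = col == "cct_um" or col.startswith("barrett_")
        bad = series.isna() & df[col].notna() if allowed_na else series.isna()
        for idx in df.index[bad][:5]:
            problems.append(f"row {idx}, column {col!r}: non-numeric or missing value")
        if col.endswith("_mm") or col.endswith("_um"):
            for idx in df.index[series <= 0][:5]:
                problems.append(f"row {idx}, column {col!r}: must be positive")
    if problems:
        raise ValueError("cohort validation failed:\n" + "\n".join(problems))


def _surface(row: pd.Series, prefix: str, suffix: str = "") -> SurfaceGeometry:
    s = f"_{suffix}" if suffix else ""
    return SurfaceGeometry(
        r_steep_mm=float(row[f"{prefix}_r_steep{s}_mm"]),
        r_flat_mm=float(row[f"{prefix}_r_flat{s}_mm"]),
        steep_axis_deg=float(row[f"{prefix}_axis{s}_deg"]),
    )


def _optional_astig(row: pd.Series, mag_col: str, axis_col: str) -> Optional[Astigmatism]:
    if mag_col not in row.index or pd.isna(row[mag_col]):
        return None
    return Astigmatism(float(row[mag_col]), float(row[axis_col]))


def row_to_record(row: pd.Series):
    """Build an :class:`~toricpred.modalities.EyeRecord` from one CSV row."""
    from .modalities import EyeRecord  # local import: avoid cycle

    return EyeRecord(
        eye_id=str(row["eye_id"]),
        subgroup_axis_deg=float(row["subgroup_axis_deg"]),
        anterior=_surface(row, "ant"),
        posterior=_surface(row, "post"),
        anterior_post_1m=_surface(row, "ant", "1m"),
        posterior_post_1m=_surface(row, "post", "1m"),
        anterior_post_3m=_surface(row, "ant", "3m"),
        posterior_post_3m=_surface(row, "post", "3m"),
        axial_length_mm=float(row["axial_length_mm"]),
        acd_mm=float(row["acd_mm"]),
        cct_um=None if pd.isna(row["cct_um"]) else float(row["cct_um"]),
        iol_sphere_d=float(row["iol_sphere_d"]),
        iol_toric_cyl_d=float(row["iol_toric_cyl_d"]),
        intended_axis_deg=float(row["intended_axis_deg"]),
        observed_axis_1m_deg=float(row["observed_axis_1m_deg"]),
        observed_axis_3m_deg=float(row["observed_axis_3m_deg"]),
        manifest_pre=(
            float(row["manifest_pre_sphere_d"]),
            float(row["manifest_pre_cyl_d"]),
            float(row["manifest_pre_axis_deg"]),
        ),
        manifest_1m=(
            float(row["manifest_1m_sphere_d"]),
            float(row["manifest_1m_cyl_d"]),
            float(row["manifest_1m_axis_deg"]),
        ),
        manifest_3m=(
            float(row["manifest_3m_sphere_d"]),
            float(row["manifest_3m_cyl_d"]),
            float(row["manifest_3m_axis_deg"]),
        ),
        device_iolmaster=Astigmatism(float(row["iolmaster_mag_d"]), float(row["iolmaster_axis_deg"])),
        device_simk=Astigmatism(float(row["simk_mag_d"]), float(row["simk_axis_deg"])),
        device_wavefront=Astigmatism(float(row["wavefront_mag_d"]), float(row["wavefront_axis_deg"])),
        barrett_iolmaster=_optional_astig(row, "barrett_iolmaster_mag_d", "barrett_iolmaster_axis_deg"),
        barrett_simk=_optional_astig(row, "barrett_simk_mag_d", "barrett_simk_axis_deg"),
    )


def cohort_records(df: pd.DataFrame):
    """Iterate EyeRecords of a validated cohort DataFrame."""
    for _, row in df.iterrows():
        yield row_to_record(row)
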