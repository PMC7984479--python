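"""File formats: NIfTI-1 volumes, sinogram files, and schema-checked CSV tables.

Volumes are stored as NIfTI-1 with the concentration (kBq/mL) in a float32
data array and the voxel geometry in the affine; arrays are written with
NIfTI's (x, y, z) axis order, transposed from the package's (slice, row,
col) convention. Sinograms are NIfTI arrays with axes (slice, angle,
radial bin) plus a JSON sidecar holding the acquisition parameters. All
tables are RFC-4180 CSV (UTF-8, "." decimal) with a leading
``# betapet-table-version=1`` comment line and fixed, validated headers.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionModel, ProjectionData
from .geometry import ActivityVolume, GridGeometry

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]

TABLE_VERSION_LINE = "# betapet-table-version=1"

TABLE_SCHEMAS: dict[str, list[str]] = {
    "metrics": [
        "mode",
        "replicate",
        "beta",
        "object_id",
        "diameter_mm",
        "group",
        "rc_pct",
        "cr_pct",
        "bv_pct",
        "suv_mean",
        "suv_max",
        "suv_peak",
        "snr",
        "cnr",
        "pvc_applied",
        "rc_predicted",
        "extrapolated",
    ],
    "rc_models": ["beta", "slope", "intercept", "r2", "dmin", "dmax", "contrast"],
    "scores": [
        "group",
        "beta",
        "reader",
        "general_quality",
        "sharpness",
        "conspicuity",
        "overall",
    ],
    "trace": ["iteration", "loglik", "penalty", "objective"],
    "catalog": [
        "lesion_id",
        "diameter_mm",
        "cz_mm",
        "cy_mm",
        "cx_mm",
        "activity_kbq_ml",
        "group",
    ],
}


class FormatError(ValueError):
    """A file does not conform to the documented format."""


def write_volume(volume: ActivityVolume, path) -> None:
    """Write an activity volume as NIfTI-1 (float32 data, mm geometry)."""
    grid = volume.grid
    affine = np.diag(
        [grid.voxel_size[2], grid.voxel_size[1], grid.voxel_size[0], 1.0]
    )
    affine[:3, 3] = [grid.origin[2], grid.origin[1], grid.origin[0]]
    data = volume.values.astype(np.float32).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def read_volume(path) -> ActivityVolume:
    """Read a NIfTI-1 activity volume written by :func:`write_volume`."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D volume, got {data.ndim}-D (field: dim)")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"invalid voxel spacing {zooms} (field: pixdim)")
    origin_xyz = img.affine[:3, 3]
    grid = GridGeometry(
        shape=data.shape[::-1],
        voxel_size=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
    )
    return ActivityVolume(grid, np.maximum(data.transpose(2, 1, 0).astype(float), 0.0))


def write_projections(proj: ProjectionData, path) -> None:
    """Write a sinogram stack as NIfTI (axes slice, angle, radial) + JSON sidecar."""
    path = pathlib.Path(path)
    img = nib.Nifti1Image(proj.values.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        "kind": proj.kind,
        "axes": ["slice", "angle", "radial"],
        "acquisition": {
            "n_angles": proj.acq.n_angles,
            "n_radial_bins": proj.acq.n_radial_bins,
            "radial_bin_size": proj.acq.radial_bin_size,
            "psf_fwhm": proj.acq.psf_fwhm,
            "count_scale": proj.acq.count_scale,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_projections(path) -> ProjectionData:
    path = pathlib.Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not path.exists() or not sidecar_path.exists():
        raise FileNotFoundError(f"{path} (and sidecar {sidecar_path.name})")
    sidecar = json.loads(sidecar_path.read_text())
    acq = AcquisitionModel(**sidecar["acquisition"])
    values = np.asanyarray(nib.load(str(path)).dataobj)
    return ProjectionData(acq, values, kind=sidecar["kind"])


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a schema-checked CSV with the format-version header line."""
    cols = TABLE_SCHEMAS.get(schema)
    if cols is None:
        raise KeyError(f"unknown table schema {schema!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns for schema {schema!r}: {missing}")
    with open(path, "w", newline="") as f:
        f.write(TABLE_VERSION_LINE + "\n")
        df[cols].to_csv(f, index=False, float_format="%.10g")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schema-checked CSV; validates the header and score invariants."""
    cols = TABLE_SCHEMAS.get(schema)
    if cols is None:
        raise KeyError(f"unknown table schema {schema!r}")
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != cols:
        raise FormatError(
            f"header mismatch for schema {schema!r}: expected {cols}, "
            f"got {list(df.columns)}"
        )
    if schema == "scores" and len(df):
        comp_sum = df[["general_quality", "sharpness", "conspicuity"]].sum(axis=1)
        if not np.allclose(df["overall"], comp_sum):
            bad = df.index[~np.isclose(df["overall"], comp_sum)].tolist()
            raise FormatError(
                f"overall column inconsistent with component sum at rows {bad}"
            )
    return df
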