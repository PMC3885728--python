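"""File formats: NIfTI volumes, CSV measurement/study tables, YAML configs.

Optical volumes are stored as 4-D NIfTI (channels: mu_a, mu_s', mask) and
source volumes as 3-D NIfTI, with the voxel size in the header zooms;
measurement sets and study tables are plain CSV with fixed headers; system
matrices can be cached in Matrix Market format.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .phantom import OpticalVolume, SourceVolume, validate_study, STUDY_COLUMNS
from .forward import (
    AcquisitionGeometry,
    MeasurementSet,
    SystemMatrix,
    MEASUREMENT_COLUMNS,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_measurements",
    "write_measurements",
    "read_study",
    "write_study",
    "read_geometry",
    "write_geometry",
    "save_system_matrix",
    "load_system_matrix",
]


def _voxel_size_from_header(img) -> float:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel size in header: {zooms}")
    if not np.allclose(zooms, zooms[0], rtol=1e-5):
        raise ValueError(f"anisotropic voxel sizes unsupported: {zooms}")
    return float(zooms[0])


def write_volume(vol: OpticalVolume | SourceVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI; OpticalVolume as 4-D (mu_a, mu_s', mask)."""
    path = Path(path)
    if isinstance(vol, OpticalVolume):
        data = np.stack([vol.mu_a, vol.mu_s_prime, vol.mask.astype(np.float32)], axis=-1)
    else:
        data = vol.yield_
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms((vol.voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> OpticalVolume | SourceVolume:
    """Read a NIfTI volume written by :func:`write_volume`.

    4-D with three channels loads as an OpticalVolume; 3-D as a SourceVolume.
    Headers without a positive isotropic voxel size are rejected.
    """
    img = nib.load(str(path))
    voxel_size = _voxel_size_from_header(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        if data.shape[-1] != 3:
            raise ValueError(
                f"expected 3 channels (mu_a, mu_s', mask), got {data.shape[-1]}"
            )
        return OpticalVolume(
            voxel_size=voxel_size,
            mu_a=data[..., 0],
            mu_s_prime=data[..., 1],
            mask=data[..., 2] > 0.5,
        )
    if data.ndim == 3:
        return SourceVolume(voxel_size=voxel_size, yield_=data)
    raise ValueError(f"unsupported volume dimensionality {data.ndim}")


def write_measurements(ms: MeasurementSet, path: str | Path) -> Path:
    path = Path(path)
    ms.table.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> MeasurementSet:
    """Load a measurement CSV; rows are canonicalized and keys must be unique."""
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return MeasurementSet(table=df)


def write_study(study: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    study[STUDY_COLUMNS].to_csv(path, index=False)
    return path


def read_study(path: str | Path, expected_days: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Load a study CSV with strict header validation.

    When ``expected_days`` is given, days absent from the table are flagged
    in ``df.attrs['missing_days']`` (never interpolated).
    """
    df = pd.read_csv(path)
    validate_study(df)
    df = df[STUDY_COLUMNS].sort_values(["group", "animal_id", "day"]).reset_index(drop=True)
    if expected_days is not None:
        present = set(df["day"].unique())
        df.attrs["missing_days"] = sorted(int(d) for d in set(expected_days) - present)
    return df


def write_geometry(geom: AcquisitionGeometry, path: str | Path) -> Path:
    payload = {
        "projection_angles": [float(a) for a in geom.projection_angles],
        "excitation_positions": {
            str(a): [[float(v) for v in p] for p in geom.excitation_positions[a]]
            for a in geom.projection_angles
        },
        "detector_positions": {
            str(a): [[float(v) for v in p] for p in geom.detector_positions[a]]
            for a in geom.projection_angles
        },
        "excitation_wavelength_nm": float(geom.excitation_wavelength_nm),
        "emission_wavelength_nm": float(geom.emission_wavelength_nm),
        "source_power_mw": float(geom.source_power_mw),
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_geometry(path: str | Path) -> AcquisitionGeometry:
    payload = yaml.safe_load(Path(path).read_text())
    angles = tuple(float(a) for a in payload["projection_angles"])
    exc = {
        a: [np.asarray(p, dtype=float) for p in payload["excitation_positions"][str(a)]]
        for a in angles
    }
    det = {
        a: [np.asarray(p, dtype=float) for p in payload["detector_positions"][str(a)]]
        for a in angles
    }
    return AcquisitionGeometry(
        projection_angles=angles,
        excitation_positions=exc,
        detector_positions=det,
        excitation_wavelength_nm=float(payload.get("excitation_wavelength_nm", 488.0)),
        emission_wavelength_nm=float(payload.get("emission_wavelength_nm", 525.0)),
        source_power_mw=float(payload.get("source_power_mw", 20.0)),
    )


def save_system_matrix(sm: SystemMatrix, path: str | Path) -> Path:
    """Cache a system matrix in Matrix Market format (plus a sidecar YAML)."""
    path = Path(path)
    scipy_io.mmwrite(str(path), sparse.csr_matrix(sm.matrix))
    meta = {
        "voxel_indices": [int(i) for i in sm.voxel_indices],
        "grid_shape": [int(s) for s in sm.grid_shape],
        "voxel_size": float(sm.voxel_size),
        "normalized": bool(sm.normalized),
        "row_index": sm.row_index.to_dict(orient="list"),
    }
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def load_system_matrix(path: str | Path) -> SystemMatrix:
    path = Path(path)
    matrix = np.asarray(scipy_io.mmread(str(path)).todense())
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    return SystemMatrix(
        matrix=matrix,
        voxel_indices=np.asarray(meta["voxel_indices"], dtype=np.int64),
        grid_shape=tuple(meta["grid_shape"]),
        voxel_size=float(meta["voxel_size"]),
        row_index=pd.DataFrame(meta["row_index"]),
        normalized=bool(meta["normalized"]),
    )
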