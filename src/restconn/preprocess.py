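"""Volumetric run I/O and minimal preprocessing.

The pipeline accepts already-aligned 4D runs; the only preprocessing it
performs is masking, FWHM-parameterised Gaussian smoothing, and
per-voxel linear detrending plus z-scoring.  Slice-timing correction,
realignment and template normalisation are deliberately out of scope:
they belong to the scanner-side toolchain, and synthetic data does not
need them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import detrend

__all__ = [
    "BoldRun",
    "FormatError",
    "FWHM_PER_SIGMA",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "smooth_run",
    "standardize_timecourses",
    "default_mask",
    "read_run",
    "write_run",
    "read_subject_table",
]

#: FWHM = 2 * sqrt(2 * ln 2) * sigma for a Gaussian.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class FormatError(ValueError):
    """Input file does not have the expected layout."""


@dataclass
class BoldRun:
    """One subject's 4D run plus the covariates the group model uses.

    ``data`` is indexed ``(x, y, z, t)``; ``mask`` is a 3D boolean array
    selecting analysis voxels; ``sex`` is a 0/1 code.
    """

    subject_id: str
    group: str
    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    mask: np.ndarray
    age: float
    sex: int
    severity: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise FormatError(f"run {self.subject_id}: data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError(f"run {self.subject_id}: need at least 2 timepoints")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(f"run {self.subject_id}: mask shape {self.mask.shape} "
                             f"does not match volume shape {self.data.shape[:3]}")
        if not self.mask.any():
            raise ValueError(f"run {self.subject_id}: mask selects no voxels")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError(f"run {self.subject_id}: non-finite values inside mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def masked_timecourses(self) -> np.ndarray:
        """In-mask voxel time series, shape (n_mask_voxels, t)."""
        return self.data[self.mask]


def fwhm_to_sigma(fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    voxel = np.asarray(voxel_size_mm, dtype=float)
    return fwhm_mm / (FWHM_PER_SIGMA * voxel)


def gaussian_smooth(volume, fwhm_mm, voxel_size_mm):
    """Separable Gaussian smoothing of a 3D volume.

    Uses reflective boundary handling so total intensity is conserved on
    the small grids this package targets; ``fwhm_mm = 0`` is an exact
    identity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("gaussian_smooth expects a 3D volume")
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    if fwhm_mm == 0:
        return volume.copy()
    return gaussian_filter(volume, sigma=sigma, mode="reflect")


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Smooth every volume of a run with :func:`gaussian_smooth`."""
    if fwhm_mm == 0:
        return run
    out = np.empty_like(run.data)
    for t in range(run.n_volumes):
        out[..., t] = gaussian_smooth(run.data[..., t], fwhm_mm, run.voxel_size_mm)
    return _replace_data(run, out, run.mask)


def default_mask(data: np.ndarray) -> np.ndarray:
    """Analysis mask: voxels with finite, non-constant time series."""
    var = np.var(data, axis=3)
    return np.isfinite(var) & (var > 0)


def standardize_timecourses(run: BoldRun) -> BoldRun:
    """Linearly detrend and z-score each in-mask voxel time series.

    Voxels whose series has zero variance are dropped from the mask with
    a warning rather than producing NaNs.  The operation is idempotent
    up to floating-point error.
    """
    mask = run.mask.copy()
    series = run.data[mask]
    sd = series.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"run {run.subject_id}: dropping {int(dead.sum())} "
                      "zero-variance voxel(s) from mask")
        idx = np.flatnonzero(mask.ravel())[dead]
        flat = mask.ravel()
        flat[idx] = False
        mask = flat.reshape(mask.shape)
        series = run.data[mask]
    series = detrend(series, axis=1, type="linear")
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    series = (series - mu) / sd
    out = np.zeros_like(run.data)
    out[mask] = series
    return _replace_data(run, out, mask)


def _replace_data(run: BoldRun, data, mask) -> BoldRun:
    return BoldRun(subject_id=run.subject_id, group=run.group, data=data,
                   voxel_size_mm=run.voxel_size_mm, tr_seconds=run.tr_seconds,
                   mask=mask, age=run.age, sex=run.sex, severity=run.severity)


def read_run(path, subject_row) -> BoldRun:
    """Load a 4D NIfTI-1 run and attach a subject-table row.

    ``subject_row`` is any mapping with keys ``subject_id``, ``group``,
    ``age``, ``sex`` and optionally ``severity``.  The analysis mask
    defaults to nonzero-variance voxels; pass ``mask`` in the row (a
    path to a 0/1 NIfTI) to override.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable header / not a NIfTI
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else float(
        subject_row.get("tr_seconds", 0.0) or 0.0)
    mask_path = subject_row.get("mask") if hasattr(subject_row, "get") else None
    if mask_path:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    else:
        mask = default_mask(data)
    severity = subject_row.get("severity") if hasattr(subject_row, "get") else None
    if severity is not None and (severity == "" or (isinstance(severity, float) and np.isnan(severity))):
        severity = None
    return BoldRun(subject_id=str(subject_row["subject_id"]),
                   group=str(subject_row["group"]), data=data,
                   voxel_size_mm=voxel_size, tr_seconds=tr, mask=mask,
                   age=float(subject_row["age"]), sex=int(subject_row["sex"]),
                   severity=None if severity is None else float(severity))


def write_run(run: BoldRun, path) -> None:
    """Write a run as NIfTI-1 with voxel sizes and TR in the header."""
    affine = np.diag(list(run.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.tr_seconds,))
    nib.save(img, str(path))


def read_subject_table(path) -> pd.DataFrame:
    """Read the cohort table (TSV with subject_id, group, age, sex[, severity])."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"subject table {path} lacks required column(s): "
                          + ", ".join(sorted(missing)))
    return df
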