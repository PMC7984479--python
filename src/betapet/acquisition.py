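"""Finite-resolution parallel-beam acquisition model with Poisson counting.

The scanner stand-in is a slice-by-slice parallel-beam projector: the
activity volume is blurred with an isotropic Gaussian point-spread function
(the source of the partial-volume effect) and then line-integrated at
``n_angles`` view angles into ``n_radial_bins`` radial bins per slice.

The projector is realized as an explicit sparse matrix P (pixel-driven with
linear interpolation onto radial bins), so forward projection is exactly
linear and the adjoint used by the reconstruction is exactly P^T. Expected
counts are ``count_scale`` times the line integral in kBq*mm/mL; measured
data are independent Poisson draws per bin. Attenuation and scatter are not
simulated: the model emulates fully corrected data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .geometry import ActivityVolume, GridGeometry

__all__ = [
    "AcquisitionModel",
    "ProjectionData",
    "system_matrix",
    "forward_project",
    "back_project",
    "sample_counts",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionModel:
    """Parallel-beam acquisition geometry and statistics.

    Parameters
    ----------
    n_angles : int
        Number of view angles, evenly spaced over 180 degrees.
    n_radial_bins : int
        Radial bins per view.
    radial_bin_size : float
        Radial bin pitch in mm.
    psf_fwhm : float
        Full width at half maximum, mm, of the image-space Gaussian blur
        applied before projection (0 disables the resolution model).
    count_scale : float
        Detector sensitivity: expected counts per kBq*mm/mL of line
        integral. Controls the Poisson noise level.
    """

    n_angles: int = 60
    n_radial_bins: int = 96
    radial_bin_size: float = 2.73
    psf_fwhm: float = 4.5
    count_scale: float = 0.03

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_radial_bins < 1:
            raise ValueError("n_radial_bins must be >= 1")
        if self.radial_bin_size <= 0:
            raise ValueError("radial_bin_size must be > 0")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    def without_psf(self) -> "AcquisitionModel":
        return replace(self, psf_fwhm=0.0)

    def projection_shape(self, grid: GridGeometry) -> tuple[int, int, int]:
        return (grid.shape[0], self.n_angles, self.n_radial_bins)


@dataclass
class ProjectionData:
    """Sinogram stack indexed (slice, angle, radial bin).

    ``kind`` is ``"expected"`` for noise-free expected counts (nonnegative
    reals) or ``"sampled"`` for Poisson-sampled counts (nonnegative
    integers).
    """

    acq: AcquisitionModel
    values: np.ndarray
    kind: str = "expected"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.shape[1:] != (
            self.acq.n_angles,
            self.acq.n_radial_bins,
        ):
            raise ValueError(
                f"projection shape {values.shape} inconsistent with acquisition "
                f"({self.acq.n_angles} angles x {self.acq.n_radial_bins} bins)"
            )
        if self.kind not in ("expected", "sampled"):
            raise ValueError(f"kind must be 'expected' or 'sampled', got {self.kind!r}")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("projection values must be finite and nonnegative")
        if self.kind == "sampled" and not np.all(values == np.round(values)):
            raise ValueError("sampled projection values must be integers")
        self.values = values

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


@lru_cache(maxsize=8)
def _system_matrix_cached(
    inplane_shape: tuple[int, int],
    inplane_voxel: tuple[float, float],
    inplane_origin: tuple[float, float],
    n_angles: int,
    n_radial_bins: int,
    radial_bin_size: float,
    count_scale: float,
) -> sp.csr_matrix:
    ny, nx = inplane_shape
    dy, dx = inplane_voxel
    y = (inplane_origin[0] + np.arange(ny) * dy)[:, None]
    x = (inplane_origin[1] + np.arange(nx) * dx)[None, :]
    pix = np.arange(ny * nx)
    # each pixel deposits (area / bin width) * count_scale, split linearly
    # between the two radial bins straddling its center coordinate
    weight = dy * dx / radial_bin_size * count_scale
    s_center = (n_radial_bins - 1) / 2.0
    rows, cols, vals = [], [], []
    angles = np.arange(n_angles) * np.pi / n_angles
    for a, theta in enumerate(angles):
        s = (x * np.cos(theta) + y * np.sin(theta)).ravel() / radial_bin_size + s_center
        b0 = np.floor(s).astype(int)
        frac = s - b0
        for b, w in ((b0, 1.0 - frac), (b0 + 1, frac)):
            ok = (b >= 0) & (b < n_radial_bins) & (w > 0)
            rows.append(a * n_radial_bins + b[ok])
            cols.append(pix[ok])
            vals.append(w[ok] * weight)
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_angles * n_radial_bins, ny * nx),
    )
    return mat.tocsr()


def system_matrix(grid: GridGeometry, acq: AcquisitionModel) -> sp.csr_matrix:
    """Per-slice system matrix P of shape (n_angles*n_radial_bins, ny*nx)."""
    return _system_matrix_cached(
        grid.shape[1:],
        grid.voxel_size[1:],
        grid.origin[1:],
        acq.n_angles,
        acq.n_radial_bins,
        acq.radial_bin_size,
        acq.count_scale,
    )


def apply_psf(volume: ActivityVolume, fwhm_mm: float) -> ActivityVolume:
    """Isotropic Gaussian resolution blur in image space (mm FWHM)."""
    if fwhm_mm == 0:
        return volume
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / v for v in volume.grid.voxel_size]
    return ActivityVolume(volume.grid, gaussian_filter(volume.values, sigma_vox))


def forward_project(volume: ActivityVolume, acq: AcquisitionModel) -> ProjectionData:
    """Expected sinogram: PSF blur then parallel-beam line integrals.

    Linear in the input volume.
    """
    blurred = apply_psf(volume, acq.psf_fwhm)
    P = system_matrix(volume.grid, acq)
    nz = volume.grid.shape[0]
    flat = blurred.values.reshape(nz, -1).T  # (ny*nx, nz)
    proj = (P @ flat).T.reshape(acq.projection_shape(volume.grid))
    return ProjectionData(acq, np.maximum(proj, 0.0), kind="expected")


def back_project(
    proj_values: np.ndarray, grid: GridGeometry, acq: AcquisitionModel
) -> np.ndarray:
    """Adjoint P^T of the (PSF-free) projector, slice by slice."""
    if proj_values.shape != acq.projection_shape(grid):
        raise ValueError(
            f"projection shape {proj_values.shape} does not match "
            f"{acq.projection_shape(grid)} for this grid/acquisition"
        )
    P = system_matrix(grid, acq)
    nz = grid.shape[0]
    flat = proj_values.reshape(nz, -1).T
    img = (P.T @ flat).T.reshape(grid.shape)
    if acq.psf_fwhm > 0:  # Gaussian blur is self-adjoint
        sigma_vox = [acq.psf_fwhm * _FWHM_TO_SIGMA / v for v in grid.voxel_size]
        img = gaussian_filter(img, sigma_vox)
    return img


def sample_counts(expected: ProjectionData, seed: int) -> ProjectionData:
    """Independent Poisson draw per bin; identical seed gives identical data."""
    if expected.kind != "expected":
        raise ValueError("sample_counts expects expected-count projections")
    vals = expected.values
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("expected counts must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    return ProjectionData(expected.acq, rng.poisson(vals).astype(float), kind="sampled")
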