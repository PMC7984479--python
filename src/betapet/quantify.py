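"""Image-derived metrics: VOI segmentation, NEMA ROIs, RC/CR/BV, SUVs, SNR, CNR.

The NEMA image-quality metrics are

    RC = A_M / A_K * 100%            (recovery coefficient)
    CR = (A_M/A_B - 1) / (C - 1) * 100%   (contrast recovery)
    BV = SD_B / C_B * 100%           (background variability)

with A_M the measured mean concentration in a sphere VOI, A_K the known
sphere concentration, A_B/C_B the mean and SD_B the standard deviation over
the 60 background ROI means (12 in-plane positions x 5 slices), and C the
known sphere-to-background contrast. SUV_bw = r / (a'/w) with r the
concentration (kBq/mL), a' the decay-corrected injected dose (kBq) and w
the body weight (g). SUVpeak is the highest mean over a 1 mL spherical
kernel moved across the tumor VOI.

VOIs are drawn with a fixed 42% of max threshold on a single reference-beta
image and propagated unchanged to all other beta reconstructions, matching
how image-quality studies decouple delineation from the reconstruction
under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import ActivityVolume, GridGeometry
from .phantom import PhantomSpec, sphere_mask

__all__ = [
    "SegmentationError",
    "ROIPlacementError",
    "VOIMask",
    "BackgroundROISet",
    "SUVContext",
    "SUVRecord",
    "segment_voi",
    "propagate_voi",
    "recovery_coefficient",
    "contrast_recovery",
    "background_variability",
    "place_background_rois",
    "suv",
    "suv_mean",
    "suv_max",
    "suv_peak",
    "spherical_kernel",
    "snr",
    "reference_noise_sd",
    "cnr",
    "cnr_background_annulus",
]

ONE_ML_DIAMETER_MM = 2.0 * (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)  # ~12.407


class SegmentationError(RuntimeError):
    """Threshold segmentation produced no usable voxel set."""


class ROIPlacementError(RuntimeError):
    """Background ROI constraints could not be satisfied."""


@dataclass
class VOIMask:
    """Boolean VOI with provenance of how and on which image it was drawn."""

    mask: np.ndarray
    grid: GridGeometry
    threshold_fraction: float
    reference_beta: float | None = None
    object_id: str | int | None = None
    propagated_to_beta: float | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not mask.any():
            raise SegmentationError("VOI mask is empty")
        self.mask = mask

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BackgroundROISet:
    """Sixty background ROIs: 12 in-plane centers replicated on 5 slices."""

    centers_mm: list[tuple[float, float]]  # (y, x) of the 12 in-plane positions
    slice_indices: list[int]
    diameter_mm: float
    masks: list[np.ndarray] = field(repr=False)

    @property
    def n_rois(self) -> int:
        return len(self.masks)

    def roi_means(self, image: ActivityVolume) -> np.ndarray:
        return np.array([image.values[m].mean() for m in self.masks])


@dataclass(frozen=True)
class SUVContext:
    """Injected dose a' (kBq, decay-corrected) and body weight w (g)."""

    injected_dose_kbq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.injected_dose_kbq <= 0 or self.body_weight_g <= 0:
            raise ValueError("injected dose and body weight must be > 0")

    @property
    def dose_per_weight(self) -> float:
        """kBq/g; with the 1 g ~ 1 mL convention, kBq/mL."""
        return self.injected_dose_kbq / self.body_weight_g


@dataclass
class SUVRecord:
    """SUV triple for one lesion at one beta, with PVC bookkeeping."""

    lesion_id: int | str
    beta: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    pvc_applied: bool = False
    rc_used: float | None = None


def segment_voi(
    image: ActivityVolume,
    seed_point,
    fraction: float = 0.42,
    reference_beta: float | None = None,
    object_id=None,
    search_radius_mm: float | None = None,
) -> VOIMask:
    """Fixed-threshold VOI: connected region above ``fraction`` x local max.

    The local maximum is found by greedy hill-climbing (26-neighborhood)
    from ``seed_point``; the mask is the connected component of
    ``image >= fraction * max`` containing that maximum.

    ``search_radius_mm`` optionally restricts the component to a box of
    that half-width around the local maximum. This mirrors delineation on
    a workstation where the object's CT extent bounds the VOI tool: in a
    warm background, a fixed fraction of a partial-volume-suppressed
    maximum can fall below the background level, and an unbounded
    connected component would flood the entire phantom.
    """
    if not (0 < fraction < 1):
        raise ValueError("threshold fraction must lie in (0, 1)")
    seed = tuple(int(round(s)) for s in seed_point)
    if not image.grid.contains_index(seed):
        raise ValueError(f"seed point {seed} outside grid {image.grid.shape}")
    vals = image.values
    # greedy ascent to the nearest local maximum
    current = seed
    shape = vals.shape
    while True:
        z, y, x = current
        nb = vals[
            max(0, z - 1) : z + 2, max(0, y - 1) : y + 2, max(0, x - 1) : x + 2
        ]
        local = np.unravel_index(int(np.argmax(nb)), nb.shape)
        best = (max(0, z - 1) + local[0], max(0, y - 1) + local[1], max(0, x - 1) + local[2])
        if vals[best] <= vals[current]:
            break
        current = best
    peak_val = vals[current]
    if peak_val <= 0:
        raise SegmentationError(f"no positive local maximum near seed {seed}")
    if search_radius_mm is not None:
        box = tuple(
            slice(
                max(0, c - int(np.ceil(search_radius_mm / v))),
                min(n, c + int(np.ceil(search_radius_mm / v)) + 1),
            )
            for c, v, n in zip(current, image.grid.voxel_size, shape)
        )
    else:
        box = tuple(slice(0, n) for n in shape)
    sub = vals[box]
    above = sub >= fraction * peak_val
    labels, _ = ndimage.label(above)
    local_idx = tuple(c - b.start for c, b in zip(current, box))
    lab = labels[local_idx]
    if lab == 0:
        raise SegmentationError("threshold excluded the seed's local maximum")
    mask = np.zeros(shape, dtype=bool)
    mask[box] = labels == lab
    return VOIMask(
        mask=mask,
        grid=image.grid,
        threshold_fraction=fraction,
        reference_beta=reference_beta,
        object_id=object_id,
    )


def propagate_voi(voi: VOIMask, target: ActivityVolume, target_beta: float | None = None) -> VOIMask:
    """Reuse a reference-image VOI on another reconstruction of the same grid."""
    if target.grid != voi.grid:
        raise ValueError(
            f"grid mismatch: VOI on {voi.grid.shape}, target {target.grid.shape}"
        )
    return replace(voi, mask=voi.mask.copy(), propagated_to_beta=target_beta)


def recovery_coefficient(measured_mean: float, known: float) -> float:
    """RC = A_M / A_K x 100%."""
    if known <= 0:
        raise ValueError("known activity concentration A_K must be > 0")
    if measured_mean < 0:
        raise ValueError("measured mean must be >= 0")
    return 100.0 * measured_mean / known


def contrast_recovery(measured_mean: float, background_mean: float, contrast: float) -> float:
    """CR = (A_M/A_B - 1)/(C - 1) x 100%."""
    if background_mean <= 0:
        raise ValueError("background mean A_B must be > 0")
    if contrast <= 1:
        raise ValueError("contrast C must be > 1")
    return 100.0 * (measured_mean / background_mean - 1.0) / (contrast - 1.0)


def background_variability(sd_b: float, c_b: float) -> float:
    """BV = SD_B / C_B x 100% over the background ROI means."""
    if c_b <= 0:
        raise ValueError("background mean C_B must be > 0")
    return 100.0 * sd_b / c_b


def _disc_mask_2d(grid: GridGeometry, cy: float, cx: float, radius: float) -> np.ndarray:
    y = grid.axis_coords(1)[:, None]
    x = grid.axis_coords(2)[None, :]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def place_background_rois(
    image: ActivityVolume,
    phantom: PhantomSpec,
    sphere_diameter: float,
    n_positions: int = 12,
    slice_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2),
    sphere_margin: float = 4.0,
    body_margin: float = 2.0,
    roi_gap: float = 1.0,
) -> BackgroundROISet:
    """Place 12 x 5 = 60 circular background ROIs of the given diameter.

    Centers are searched greedily on a polar candidate lattice around the
    phantom axis, at the largest sphere diameter (37 mm); all smaller
    diameters reuse the same centers concentrically, so ROI sets for
    different spheres are mutually consistent. Constraints: ROIs stay
    inside the body by ``body_margin``, clear every sphere (in-plane) by
    ``sphere_margin`` and do not overlap each other.
    """
    grid = image.grid
    d_place = max(s.diameter for s in phantom.spheres) if phantom.spheres else sphere_diameter
    r_place = d_place / 2.0
    body = phantom.body
    sphere_xy = [(s.center[1], s.center[2], s.radius) for s in phantom.spheres]

    def feasible(cy: float, cx: float, accepted) -> bool:
        if not body.contains_point(cy, cx, margin=r_place + body_margin):
            return False
        for sy, sx, sr in sphere_xy:
            if np.hypot(cy - sy, cx - sx) < sr + r_place + sphere_margin:
                return False
        for ay, ax in accepted:
            if np.hypot(cy - ay, cx - ax) < d_place + roi_gap:
                return False
        return True

    # candidate lattice: rings outward-in plus the phantom center
    candidates: list[tuple[float, float]] = []
    max_r = max(body.semi_x, body.semi_y)
    for radius in np.arange(max_r, -1.0, -4.0):
        if radius <= 0:
            candidates.append((body.center_y, body.center_x))
            continue
        n_ang = max(8, int(2 * np.pi * radius / 8.0))
        for t in np.linspace(0, 2 * np.pi, n_ang, endpoint=False):
            candidates.append(
                (body.center_y + radius * np.sin(t), body.center_x + radius * np.cos(t))
            )
    accepted: list[tuple[float, float]] = []
    for cy, cx in candidates:
        if len(accepted) >= n_positions:
            break
        if feasible(cy, cx, accepted):
            accepted.append((cy, cx))
    if len(accepted) < n_positions:
        raise ROIPlacementError(
            f"only {len(accepted)} of {n_positions} background ROIs of diameter "
            f"{d_place} mm could be placed"
        )

    # central slice = slice of the sphere centers (max-intensity plane)
    cz = phantom.spheres[0].center[0] if phantom.spheres else 0.0
    central = int(round(grid.world_to_voxel((cz, 0, 0))[0]))
    slices = [central + o for o in slice_offsets]
    if min(slices) < 0 or max(slices) >= grid.shape[0]:
        raise ROIPlacementError("background ROI slices fall outside the grid")

    radius = sphere_diameter / 2.0
    masks = []
    for k in slices:
        for cy, cx in accepted:
            disc = _disc_mask_2d(grid, cy, cx, radius)
            m = np.zeros(grid.shape, dtype=bool)
            m[k] = disc
            if not m.any():
                raise ROIPlacementError("ROI contains no voxel centers (grid too coarse)")
            masks.append(m)
    return BackgroundROISet(
        centers_mm=accepted, slice_indices=slices, diameter_mm=sphere_diameter, masks=masks
    )


def suv(r: float, ctx: SUVContext) -> float:
    """SUV_bw = r / (a'/w)."""
    if r < 0:
        raise ValueError("activity concentration must be >= 0")
    return r / ctx.dose_per_weight


def suv_mean(image: ActivityVolume, voi: VOIMask, ctx: SUVContext) -> float:
    return suv(float(image.values[voi.mask].mean()), ctx)


def suv_max(image: ActivityVolume, voi: VOIMask, ctx: SUVContext) -> float:
    return suv(float(image.values[voi.mask].max()), ctx)


def spherical_kernel(grid: GridGeometry, diameter_mm: float = ONE_ML_DIAMETER_MM) -> np.ndarray:
    """Normalized spherical mean kernel (voxel centers inside the sphere)."""
    half = [int(np.floor(diameter_mm / 2.0 / v)) for v in grid.voxel_size]
    if all(h < 1 for h in half):
        raise ValueError(
            f"grid too coarse for a {diameter_mm:.1f} mm kernel "
            f"(< 2 voxels across); use a finer grid"
        )
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, grid.voxel_size)]
    z, y, x = np.meshgrid(*axes, indexing="ij")
    ball = (z**2 + y**2 + x**2) <= (diameter_mm / 2.0) ** 2
    return ball / ball.sum()


def suv_peak(image: ActivityVolume, voi: VOIMask, ctx: SUVContext) -> float:
    """Highest 1 mL spherical-kernel mean over sphere centers inside the VOI.

    Ties are broken by the smallest center index in scan order (the
    convolution is deterministic and argmax takes the first maximum).
    """
    kernel = spherical_kernel(image.grid)
    means = ndimage.convolve(image.values, kernel, mode="constant", cval=0.0)
    in_voi = means[voi.mask]
    # first maximum in scan order among VOI voxels
    return suv(float(in_voi.max()), ctx)


def snr(lesion_suv_max: float, reference_sd: float) -> float:
    """Lesion SUVmax divided by the reference-region SUV standard deviation."""
    if reference_sd <= 0:
        raise ValueError("reference SD must be > 0 (degenerate noise reference)")
    return lesion_suv_max / reference_sd


def reference_noise_sd(
    image: ActivityVolume,
    ref_mask: np.ndarray,
    ctx: SUVContext,
    voi_diameter_mm: float = 10.0,
    n_vois: int = 3,
) -> float:
    """Noise measure: mean SD of SUVs over 1.0-cm spherical VOIs in the
    reference (liver-like) region.

    VOIs are placed deterministically along the region's central axis.
    """
    grid = image.grid
    idx = np.argwhere(ref_mask)
    if idx.size == 0:
        raise ValueError("reference mask is empty")
    center = idx.mean(axis=0)
    kernel = spherical_kernel(grid, voi_diameter_mm)
    hz = (np.array(kernel.shape) - 1) // 2
    # spread VOI centers along z through the region center
    zs = np.unique(idx[:, 0])
    z_picks = np.quantile(zs, np.linspace(0.25, 0.75, n_vois)).round().astype(int)
    sds = []
    for zc in z_picks:
        c = (int(zc), int(round(center[1])), int(round(center[2])))
        sl = tuple(slice(ci - h, ci + h + 1) for ci, h in zip(c, hz))
        box = image.values[sl]
        if box.shape != kernel.shape:
            continue
        vals = box[kernel > 0]
        sds.append(np.std([suv(v, ctx) for v in vals], ddof=1))
    if not sds:
        raise ValueError("no 1-cm VOI fits inside the reference region")
    sd = float(np.mean(sds))
    if sd <= 0:
        raise ValueError("reference SD is zero (degenerate noise reference)")
    return sd


def cnr(mean_lesion: float, mean_background: float, sd_background: float) -> float:
    """CNR = (mean_lesion - mean_background) / SD_background."""
    if sd_background <= 0:
        raise ValueError("background SD must be > 0")
    return (mean_lesion - mean_background) / sd_background


def cnr_background_annulus(
    voi: VOIMask,
    lung_mask: np.ndarray,
    inner_factor: float = 1.5,
    outer_factor: float = 2.5,
) -> np.ndarray:
    """Neighboring-tissue shell for CNR: annulus between ``inner_factor`` and
    ``outer_factor`` times the VOI-equivalent radius, clipped to the lung
    compartment."""
    grid = voi.grid
    idx = np.argwhere(voi.mask)
    center_vox = idx.mean(axis=0)
    vol_ml = voi.n_voxels * grid.voxel_volume_ml
    r_eq = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    z, y, x = grid.meshgrid()
    c = grid.voxel_to_world(center_vox)
    dist = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
    shell = (dist >= inner_factor * r_eq) & (dist <= outer_factor * r_eq)
    shell &= np.asarray(lung_mask, dtype=bool) & ~voi.mask
    if not shell.any():
        raise ValueError("empty CNR background annulus")
    return shell
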