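"""Digital phantoms: a NEMA-IQ-like six-sphere phantom and clinical lesion fields.

The NEMA-style phantom mirrors the standard image-quality phantom: six hot
spheres (10, 13, 17, 22, 28, 37 mm diameter) on a ring inside an elliptical
body compartment, filled at a 4:1 sphere-to-background activity ratio with
13.2 kBq/mL in the spheres. The clinical phantom emulates small pulmonary
nodules (5-30 mm) in a low-uptake thorax-like background with a separate
uniform liver-like compartment used as the noise reference region.

Voxelization uses corner-subsampled fractional fill: each voxel samples a
``subsample``^3 lattice of points and takes the inside-sphere fraction, which
reduces staircase bias on the smallest spheres. ``subsample=1`` reduces to a
voxel-center membership test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ActivityVolume, GridGeometry

__all__ = [
    "GeometryError",
    "PlacementError",
    "BodyEllipse",
    "SphereSpec",
    "PhantomSpec",
    "NEMA_SPHERE_DIAMETERS_MM",
    "nema_phantom_spec",
    "default_grid",
    "build_phantom",
    "sphere_mask",
    "build_clinical_phantom",
    "SUBCENTIMETER_GROUP",
    "MEDIUM_GROUP",
]

#: Sphere diameters of the NEMA image-quality phantom, mm.
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

SUBCENTIMETER_GROUP = "<10 mm"
MEDIUM_GROUP = "10-30 mm"


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (overlap, out of body, out of grid)."""


class PlacementError(RuntimeError):
    """Random placement could not satisfy the clearance constraints."""


@dataclass(frozen=True)
class BodyEllipse:
    """Elliptical-cylinder body compartment, axis along z, centered in-plane.

    semi_x/semi_y are the in-plane semi-axes in mm; the cylinder spans the
    full z extent of the grid.
    """

    semi_x: float = 125.0
    semi_y: float = 98.0
    center_x: float = 0.0
    center_y: float = 0.0

    def contains_point(self, y: float, x: float, margin: float = 0.0) -> bool:
        a = self.semi_x - margin
        b = self.semi_y - margin
        if a <= 0 or b <= 0:
            return False
        return ((x - self.center_x) / a) ** 2 + ((y - self.center_y) / b) ** 2 <= 1.0

    def mask(self, grid: GridGeometry, margin: float = 0.0) -> np.ndarray:
        """Boolean in-plane membership broadcast over slices (voxel centers)."""
        y = grid.axis_coords(1)[:, None]
        x = grid.axis_coords(2)[None, :]
        a = self.semi_x - margin
        b = self.semi_y - margin
        inplane = ((x - self.center_x) / a) ** 2 + ((y - self.center_y) / b) ** 2 <= 1.0
        return np.broadcast_to(inplane, grid.shape).copy()


@dataclass(frozen=True)
class SphereSpec:
    """A hot sphere: center (z, y, x) in world mm, diameter mm, activity kBq/mL."""

    center: tuple[float, float, float]
    diameter: float
    activity: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"sphere diameter must be > 0, got {self.diameter}")
        if self.activity < 0:
            raise GeometryError(f"sphere activity must be >= 0, got {self.activity}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Spheres plus a uniform background inside an elliptical body."""

    spheres: tuple[SphereSpec, ...]
    background_activity: float
    body: BodyEllipse = field(default_factory=BodyEllipse)

    def __post_init__(self) -> None:
        if self.background_activity < 0:
            raise GeometryError("background_activity must be >= 0")
        object.__setattr__(self, "spheres", tuple(self.spheres))
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        for s in self.spheres:
            _, cy, cx = s.center
            # conservative inclusion test: shrink the ellipse by the radius
            if not self.body.contains_point(cy, cx, margin=s.radius):
                raise GeometryError(
                    f"sphere at {s.center} with diameter {s.diameter} mm extends "
                    "outside the body compartment"
                )
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                d = float(np.linalg.norm(np.subtract(a.center, b.center)))
                if d < a.radius + b.radius:
                    raise GeometryError(
                        f"spheres at {a.center} and {b.center} overlap "
                        f"(center distance {d:.1f} mm)"
                    )

    @property
    def contrast(self) -> float:
        """Sphere-to-background activity ratio C (requires uniform sphere activity)."""
        if not self.spheres:
            raise GeometryError("phantom has no spheres")
        if self.background_activity <= 0:
            raise GeometryError("contrast undefined for zero background")
        acts = {s.activity for s in self.spheres}
        if len(acts) != 1:
            raise GeometryError("contrast undefined: spheres have differing activities")
        return acts.pop() / self.background_activity


def default_grid(shape: tuple[int, int, int] = (32, 96, 96)) -> GridGeometry:
    """Desk-scale reconstruction grid: 2.73 mm in-plane pitch, 2.8 mm slices."""
    return GridGeometry(shape=shape, voxel_size=(2.8, 2.73, 2.73))


def nema_phantom_spec(
    background_activity: float = 3.3,
    contrast: float = 4.0,
    ring_radius: float = 52.0,
    center_z: float = 0.0,
    body: BodyEllipse | None = None,
) -> PhantomSpec:
    """Six-sphere image-quality phantom at the study's fill (4:1, 13.2 kBq/mL).

    Spheres sit on a ring of ``ring_radius`` mm in the central slice, 60 deg
    apart, ordered by increasing diameter.
    """
    body = body or BodyEllipse()
    activity = background_activity * contrast
    angles = np.deg2rad(np.arange(6) * 60.0)
    spheres = tuple(
        SphereSpec(
            center=(center_z, ring_radius * np.sin(t), ring_radius * np.cos(t)),
            diameter=d,
            activity=activity,
        )
        for d, t in zip(NEMA_SPHERE_DIAMETERS_MM, angles)
    )
    return PhantomSpec(spheres=spheres, background_activity=background_activity, body=body)


def _fractional_fill(
    grid: GridGeometry, center, radius: float, subsample: int
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Per-voxel inside-sphere fraction over the sphere's bounding box."""
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    lo = grid.world_to_voxel(np.subtract(center, radius))
    hi = grid.world_to_voxel(np.add(center, radius))
    idx = tuple(
        slice(max(0, int(np.floor(l))), min(n, int(np.ceil(h)) + 1))
        for l, h, n in zip(lo, hi, grid.shape)
    )
    offsets = [
        ((np.arange(subsample) + 0.5) / subsample - 0.5) * v for v in grid.voxel_size
    ]
    frac = np.zeros(tuple(s.stop - s.start for s in idx))
    coords = [
        grid.axis_coords(a)[idx[a]] - center[a] for a in range(3)
    ]
    r2 = radius * radius
    for oz in offsets[0]:
        dz2 = (coords[0] + oz) ** 2
        for oy in offsets[1]:
            dy2 = (coords[1] + oy) ** 2
            for ox in offsets[2]:
                dx2 = (coords[2] + ox) ** 2
                frac += (
                    dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
                ) <= r2
    frac /= subsample**3
    return idx, frac


def sphere_mask(grid: GridGeometry, center, diameter: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the sphere."""
    z, y, x = grid.meshgrid()
    r2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    return r2 <= (diameter / 2.0) ** 2


def build_phantom(
    spec: PhantomSpec, grid: GridGeometry, subsample: int = 3
) -> ActivityVolume:
    """Rasterize a phantom spec onto a grid.

    Voxels inside a sphere take the sphere's activity, voxels in the body
    background take ``background_activity`` and voxels outside the body are
    zero; sphere boundaries are anti-aliased by corner subsampling.
    """
    body = spec.body.mask(grid)
    values = np.where(body, spec.background_activity, 0.0)
    for s in spec.spheres:
        idx, frac = _fractional_fill(grid, s.center, s.radius, subsample)
        box = values[idx]
        values[idx] = box + (s.activity - spec.background_activity) * frac
    return ActivityVolume(grid, values)


def _place_lesions(
    diameters: np.ndarray,
    body: BodyEllipse,
    grid: GridGeometry,
    rng: np.random.Generator,
    liver_center: tuple[float, float],
    liver_radius: float,
    clearance: float,
    max_tries: int,
) -> list[tuple[float, float, float]]:
    """Rejection-sample lesion centers honoring all clearance constraints."""
    z_lo = grid.axis_coords(0)[0]
    z_hi = grid.axis_coords(0)[-1]
    placed: list[tuple[float, float, float]] = []  # parallel to sorted order
    order = np.argsort(diameters)[::-1]  # big lesions first: easier packing
    centers: dict[int, tuple[float, float, float]] = {}
    for k in order:
        r = diameters[k] / 2.0
        ok = False
        for _ in range(max_tries):
            cx = rng.uniform(-body.semi_x + r, body.semi_x - r)
            cy = rng.uniform(-body.semi_y + r, body.semi_y - r)
            cz = rng.uniform(z_lo + r + clearance, z_hi - r - clearance)
            if not body.contains_point(cy, cx, margin=r + clearance):
                continue
            d_liver = np.hypot(cy - liver_center[0], cx - liver_center[1])
            if d_liver < liver_radius + r + clearance:
                continue
            good = True
            for j, c in centers.items():
                rj = diameters[j] / 2.0
                if np.linalg.norm(np.subtract((cz, cy, cx), c)) < r + rj + clearance:
                    good = False
                    break
            if good:
                centers[k] = (cz, cy, cx)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place lesion of diameter {diameters[k]:.1f} mm after "
                f"{max_tries} tries ({len(centers)} of {len(diameters)} placed)"
            )
    del placed
    return [centers[k] for k in range(len(diameters))]


def build_clinical_phantom(
    lesion_diameters,
    lesion_to_background: float = 4.0,
    grid: GridGeometry | None = None,
    seed: int = 0,
    background_activity: float = 1.0,
    liver_activity: float = 1.5,
    liver_center: tuple[float, float] = (30.0, -55.0),
    liver_radius: float = 25.0,
    clearance: float = 8.0,
    subsample: int = 3,
    max_tries: int = 5000,
) -> tuple[ActivityVolume, pd.DataFrame, np.ndarray]:
    """Lesion phantom emulating small pulmonary nodules at a fixed contrast.

    Spherical lesions are embedded in a uniform low-uptake body ("lung-like"
    background) at ``lesion_to_background`` contrast, with a separate uniform
    liver-like cylinder serving as the noise reference region. Returns the
    truth volume, a lesion catalog (id, center, diameter, activity, size
    group) and the boolean reference-region mask.
    """
    grid = grid or default_grid()
    diameters = np.asarray(list(lesion_diameters), dtype=float)
    if diameters.size and not np.all((diameters > 3.0) & (diameters < 40.0)):
        raise GeometryError("lesion diameters must lie in (3, 40) mm")
    if lesion_to_background <= 0:
        raise GeometryError("lesion_to_background must be > 0")
    body = BodyEllipse()
    rng = np.random.default_rng(seed)
    centers = _place_lesions(
        diameters, body, grid, rng, liver_center, liver_radius, clearance, max_tries
    )

    values = np.where(body.mask(grid), background_activity, 0.0)
    # liver compartment: uniform cylinder spanning the central 60% of slices
    y = grid.axis_coords(1)[:, None]
    x = grid.axis_coords(2)[None, :]
    liver_inplane = (y - liver_center[0]) ** 2 + (x - liver_center[1]) ** 2 <= liver_radius**2
    nz = grid.shape[0]
    z_keep = np.zeros(nz, dtype=bool)
    z_keep[int(0.2 * nz) : int(0.8 * nz) + 1] = True
    liver_mask = liver_inplane[None, :, :] & z_keep[:, None, None]
    values[liver_mask] = liver_activity

    lesion_activity = background_activity * lesion_to_background
    rows = []
    for i, (d, c) in enumerate(zip(diameters, centers)):
        idx, frac = _fractional_fill(grid, c, d / 2.0, subsample)
        values[idx] += (lesion_activity - background_activity) * frac
        rows.append(
            {
                "lesion_id": i,
                "diameter_mm": float(d),
                "cz_mm": c[0],
                "cy_mm": c[1],
                "cx_mm": c[2],
                "activity_kbq_ml": lesion_activity,
                "group": SUBCENTIMETER_GROUP if d < 10.0 else MEDIUM_GROUP,
            }
        )
    catalog = pd.DataFrame(
        rows,
        columns=[
            "lesion_id",
            "diameter_mm",
            "cz_mm",
            "cy_mm",
            "cx_mm",
            "activity_kbq_ml",
            "group",
        ],
    )
    # reference mask eroded in-plane so 1-cm noise VOIs stay interior
    ref_inplane = (y - liver_center[0]) ** 2 + (x - liver_center[1]) ** 2 <= (
        liver_radius - 6.0
    ) ** 2
    ref_mask = ref_inplane[None, :, :] & z_keep[:, None, None]
    return ActivityVolume(grid, values), catalog, ref_mask
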