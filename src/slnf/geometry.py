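"""Detector, collimator and reconstruction-grid geometry.

Coordinate convention (fixed for reproducibility of pixel/voxel indices):
right-handed frame with the origin at the center of the collimator plate,
z pointing into the scene (towards the sources), the detector plane at
z = -plane_offset behind the plate.  Detector row 0 / column 0 is the
top-left pixel; rows increase downwards (-y), columns increase with +x.
Voxel linearization is x-fastest, then y, then z.

The reconstruction grid is centered on the plate in x and y; its first
z-plane sits one spacing in front of the plate (z = spacing), so the
grid never touches the degenerate z = 0 plane.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DetectorSpec",
    "PinholeSpec",
    "CollimatorSpec",
    "VolumeGrid",
    "GeometryModel",
    "voxel_center",
    "nearest_voxel",
    "trace_ray",
    "default_pinhole_pattern",
    "load_geometry",
    "geometry_hash",
]


class GeometryError(ValueError):
    """Invalid or degenerate geometry configuration."""


@dataclass(frozen=True)
class DetectorSpec:
    """Binned detector plane.

    The physical device reads out ``raw_shape`` pixels which are summed in
    ``bin_factor`` x ``bin_factor`` neighborhoods; all imaging here happens at
    the binned resolution ``n_rows`` x ``n_cols`` with pitch ``pixel_pitch``
    (mm per binned pixel).  ``plane_offset`` is the plate-to-detector distance
    in mm (detector sits behind the plate at z = -plane_offset).
    """

    n_rows: int = 257
    n_cols: int = 515
    pixel_pitch: float = 0.15
    raw_shape: tuple[int, int] = (514, 1030)
    bin_factor: int = 2
    plane_offset: float = 30.0
    quantum_efficiency: float = 0.10

    def __post_init__(self) -> None:
        raw_r, raw_c = self.raw_shape
        if raw_r != self.n_rows * self.bin_factor or raw_c != self.n_cols * self.bin_factor:
            raise GeometryError(
                f"raw_shape {self.raw_shape} is not bin_factor={self.bin_factor} "
                f"times the binned shape ({self.n_rows}, {self.n_cols})"
            )
        if self.pixel_pitch <= 0:
            raise GeometryError("pixel_pitch must be positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise GeometryError("quantum_efficiency must be in (0, 1]")
        if self.plane_offset <= 0:
            raise GeometryError("plane_offset must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        """Physical width (x extent) in mm."""
        return self.n_cols * self.pixel_pitch

    @property
    def height(self) -> float:
        """Physical height (y extent) in mm."""
        return self.n_rows * self.pixel_pitch


@dataclass(frozen=True)
class PinholeSpec:
    """A single pinhole aperture in the collimator plate.

    ``center`` is its (x, y) position on the plate (z = 0).  For the binary
    system matrix rays pass through the center (ideal point aperture); the
    1 mm physical diameter only matters as optional blur in the simulator.
    """

    center: tuple[float, float]
    diameter: float = 1.0
    channel_length: float = 1.0
    fov_half_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("pinhole diameter must be positive")
        if not 0 < self.fov_half_angle < 90:
            raise GeometryError("fov_half_angle must be in (0, 90) degrees")


@dataclass(frozen=True)
class CollimatorSpec:
    pinholes: tuple[PinholeSpec, ...]
    plate_extent: tuple[float, float] = (80.0, 40.0)
    penetration_fraction: float = 0.075

    def __post_init__(self) -> None:
        if len(self.pinholes) < 1:
            raise GeometryError("collimator needs at least one pinhole")
        if not 0 <= self.penetration_fraction < 1:
            raise GeometryError("penetration_fraction must be in [0, 1)")
        w, h = self.plate_extent
        for ph in self.pinholes:
            x, y = ph.center
            if abs(x) > w / 2 or abs(y) > h / 2:
                raise GeometryError(f"pinhole at {ph.center} outside plate extent {self.plate_extent}")


@dataclass(frozen=True)
class VolumeGrid:
    """Reconstruction grid of point-source candidate positions.

    ``n_x * n_y * n_z`` sampling points with isotropic ``spacing`` (mm).
    x and y are centered on the plate; z starts at one spacing in front of
    the plate: voxel (i, j, k) sits at
    ``x = (i - (n_x-1)/2) * spacing``, ``y = (j - (n_y-1)/2) * spacing``,
    ``z = (k + 1) * spacing``.  Linear index = i + n_x * (j + n_y * k).
    """

    n_x: int = 60
    n_y: int = 100
    n_z: int = 200
    spacing: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise GeometryError("grid counts must all be >= 1")
        if self.spacing <= 0:
            raise GeometryError("grid spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y * self.n_z

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the grid planes along each axis (mm)."""
        xs = (np.arange(self.n_x) - (self.n_x - 1) / 2) * self.spacing
        ys = (np.arange(self.n_y) - (self.n_y - 1) / 2) * self.spacing
        zs = (np.arange(self.n_z) + 1) * self.spacing
        return xs, ys, zs

    def all_centers(self) -> np.ndarray:
        """(M, 3) array of voxel centers in linear-index order (x fastest)."""
        xs, ys, zs = self.axes()
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass(frozen=True)
class GeometryModel:
    """Complete imaging geometry: detector + collimator + grid."""

    detector: DetectorSpec
    collimator: CollimatorSpec
    grid: VolumeGrid


def voxel_center(grid: VolumeGrid, index: int) -> tuple[float, float, float]:
    """World coordinate (x, y, z) in mm of the voxel with the given linear index."""
    if not 0 <= index < grid.n_voxels:
        raise IndexError(f"voxel index {index} out of range [0, {grid.n_voxels})")
    i = index % grid.n_x
    j = (index // grid.n_x) % grid.n_y
    k = index // (grid.n_x * grid.n_y)
    s = grid.spacing
    return (
        (i - (grid.n_x - 1) / 2) * s,
        (j - (grid.n_y - 1) / 2) * s,
        (k + 1) * s,
    )


def nearest_voxel(grid: VolumeGrid, x: float, y: float, z: float) -> tuple[int, float]:
    """Linear index of the grid point nearest to (x, y, z), plus snap distance (mm).

    Coordinates are clipped into the grid, so an off-grid source snaps to the
    closest boundary voxel (the snap distance records the quantization).
    """
    s = grid.spacing
    i = int(np.clip(round(x / s + (grid.n_x - 1) / 2), 0, grid.n_x - 1))
    j = int(np.clip(round(y / s + (grid.n_y - 1) / 2), 0, grid.n_y - 1))
    k = int(np.clip(round(z / s - 1), 0, grid.n_z - 1))
    idx = i + grid.n_x * (j + grid.n_y * k)
    cx, cy, cz = voxel_center(grid, idx)
    dist = float(np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2))
    return idx, dist


def trace_ray(
    source: tuple[float, float, float],
    pinhole: PinholeSpec,
    detector: DetectorSpec,
) -> int | None:
    """Project a point source through one pinhole onto the detector.

    Intersects the straight line source -> pinhole-center with the detector
    plane at z = -plane_offset.  Returns the linear index of the binned pixel
    containing the intersection, or None if the ray's angle to the plate
    normal exceeds the pinhole field of view or the intersection misses the
    detector.  A source on the plate plane (z = 0) is degenerate.
    """
    sx, sy, sz = source
    if sz == 0:
        raise GeometryError("source on the collimator plate plane (z = 0) is degenerate")
    if sz < 0:
        raise GeometryError("source must be in front of the plate (z > 0)")
    px, py = pinhole.center
    # angle between the ray direction and the plate normal
    lateral = np.hypot(px - sx, py - sy)
    if np.degrees(np.arctan2(lateral, sz)) > pinhole.fov_half_angle:
        return None
    # pinhole camera: the image point is the pinhole plus the inverted,
    # magnified source offset (similar triangles with ratio offset/z)
    m = detector.plane_offset / sz
    dx = px + (px - sx) * m
    dy = py + (py - sy) * m
    col = int(np.floor((dx + detector.width / 2) / detector.pixel_pitch))
    row = int(np.floor((detector.height / 2 - dy) / detector.pixel_pitch))
    if not (0 <= row < detector.n_rows and 0 <= col < detector.n_cols):
        return None
    return row * detector.n_cols + col


def default_pinhole_pattern(
    n: int = 9,
    plate_extent: tuple[float, float] = (80.0, 40.0),
    fov_half_angle: float = 45.0,
    seed: int = 20230915,
) -> tuple[PinholeSpec, ...]:
    """A jittered square grid of pinholes spanning the plate.

    The true multi-pinhole arrangement of the physical collimator is device
    specific and treated as a configuration input; this default produces a
    deterministic, non-degenerate pattern (jitter breaks symmetry so distinct
    voxels cast distinct fingerprints).  The pattern spans the central 60 %
    of the plate: concentrated enough that positions in the working volume
    keep most of their fingerprint spots on the detector, yet wide enough
    that edge pinholes drop out of view for off-axis sources (so fingerprint
    size genuinely varies with position, as on the physical device).
    """
    side = int(np.ceil(np.sqrt(n)))
    rng = np.random.default_rng(seed)
    w, h = plate_extent
    xs = np.linspace(-w / 2 * 0.6, w / 2 * 0.6, side)
    ys = np.linspace(-h / 2 * 0.6, h / 2 * 0.6, side)
    jitter_x = min(0.1 * w / side, 2.0)
    jitter_y = min(0.1 * h / side, 2.0)
    holes = []
    for y in ys:
        for x in xs:
            if len(holes) >= n:
                break
            cx = float(x + rng.uniform(-jitter_x, jitter_x))
            cy = float(y + rng.uniform(-jitter_y, jitter_y))
            holes.append(PinholeSpec(center=(cx, cy), fov_half_angle=fov_half_angle))
    return tuple(holes)


# ---------------------------------------------------------------------------
# configuration I/O


def _model_to_dict(model: GeometryModel) -> dict:
    d = model.detector
    return {
        "detector": {
            "rows": d.n_rows,
            "cols": d.n_cols,
            "pitch_mm": d.pixel_pitch,
            "raw_shape": list(d.raw_shape),
            "bin_factor": d.bin_factor,
            "offset_mm": d.plane_offset,
            "quantum_efficiency": d.quantum_efficiency,
        },
        "collimator": {
            "plate_extent_mm": list(model.collimator.plate_extent),
            "penetration": model.collimator.penetration_fraction,
            "pinholes": [
                {
                    "x": ph.center[0],
                    "y": ph.center[1],
                    "diameter_mm": ph.diameter,
                    "fov_deg": 2 * ph.fov_half_angle,
                }
                for ph in model.collimator.pinholes
            ],
        },
        "grid": {
            "nx": model.grid.n_x,
            "ny": model.grid.n_y,
            "nz": model.grid.n_z,
            "spacing_mm": model.grid.spacing,
        },
    }


def save_geometry(model: GeometryModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_model_to_dict(model), sort_keys=True))


def load_geometry(path: str | Path) -> GeometryModel:
    """Read a geometry model from a YAML (or JSON — valid YAML) config file."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        det = raw["detector"]
        col = raw["collimator"]
        grd = raw["grid"]
        detector = DetectorSpec(
            n_rows=int(det["rows"]),
            n_cols=int(det["cols"]),
            pixel_pitch=float(det["pitch_mm"]),
            raw_shape=tuple(det.get("raw_shape", (det["rows"] * 2, det["cols"] * 2))),
            bin_factor=int(det.get("bin_factor", 2)),
            plane_offset=float(det.get("offset_mm", 30.0)),
            quantum_efficiency=float(det.get("quantum_efficiency", 0.10)),
        )
        pinholes = tuple(
            PinholeSpec(
                center=(float(p["x"]), float(p["y"])),
                diameter=float(p.get("diameter_mm", 1.0)),
                fov_half_angle=float(p.get("fov_deg", 90.0)) / 2,
            )
            for p in col["pinholes"]
        )
        collimator = CollimatorSpec(
            pinholes=pinholes,
            plate_extent=tuple(col.get("plate_extent_mm", (80.0, 40.0))),
            penetration_fraction=float(col.get("penetration", 0.075)),
        )
        grid = VolumeGrid(
            n_x=int(grd["nx"]), n_y=int(grd["ny"]), n_z=int(grd["nz"]),
            spacing=float(grd["spacing_mm"]),
        )
    except KeyError as exc:
        raise GeometryError(f"geometry config missing required key: {exc}") from exc
    return GeometryModel(detector=detector, collimator=collimator, grid=grid)


def geometry_hash(model: GeometryModel) -> str:
    """Stable hash of the full geometry; keys the system-matrix cache."""
    blob = json.dumps(_model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def describe(model: GeometryModel) -> str:
    """Human-readable summary of the resolved geometry."""
    d, c, g = model.detector, model.collimator, model.grid
    lines = [
        f"detector : {d.n_rows} x {d.n_cols} binned pixels "
        f"({d.height:.2f} x {d.width:.2f} mm, pitch {d.pixel_pitch} mm), "
        f"plane at z = {-d.plane_offset} mm",
        f"collimator: {len(c.pinholes)} pinholes on a "
        f"{c.plate_extent[0]} x {c.plate_extent[1]} mm plate, "
        f"penetration {c.penetration_fraction:.1%}",
        f"grid     : {g.n_x} x {g.n_y} x {g.n_z} = {g.n_voxels:,} voxels, "
        f"spacing {g.spacing} mm (z in [{g.spacing}, {g.n_z * g.spacing}] mm)",
        f"hash     : {geometry_hash(model)}",
    ]
    for i, ph in enumerate(c.pinholes):
        lines.append(
            f"  pinhole {i}: ({ph.center[0]:+.2f}, {ph.center[1]:+.2f}) mm, "
            f"d={ph.diameter} mm, FoV {2 * ph.fov_half_angle:.0f} deg"
        )
    return "\n".join(lines)
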