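"""Self-contained synthetic fixture bundles for tests and demonstrations.

Three geometry profiles share the physical detector size (38.4 x 76.8 mm)
so the same collimator pattern serves all of them:

* ``tiny``       — 64 x 128 detector, 12 x 20 x 20 grid (4,800 voxels):
                   small enough that the naive reference oracles scan it in
                   well under a second.
* ``default``    — 128 x 256 detector, 15 x 25 x 45 grid (16,875 voxels)
                   at 4 mm spacing: the reduced benchmark geometry; the
                   9-position phantom (20 mm spacing, 120 mm standoff) falls
                   exactly on grid points.
* ``full_scale`` — the real acquisition dimensions: 257 x 515 binned pixels
                   at 0.15 mm pitch and a 60 x 100 x 200 grid at 2 mm
                   spacing (M = 1,200,000); for performance checks only.

``make_fixture`` writes a complete on-disk bundle (geometry YAML, system
matrix cache, phantom CSV, seeded TIFF stacks, and expected outputs computed
by the independent brute-force oracles in :mod:`slnf.reference`, never by
the main implementation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .geometry import (
    CollimatorSpec,
    DetectorSpec,
    GeometryModel,
    VolumeGrid,
    default_pinhole_pattern,
    geometry_hash,
    save_geometry,
)
from .io import write_tiff_stack
from .simulator import AcquisitionConfig, generate_grid_phantom, simulate_acquisition
from .system_matrix import build_system_matrix

__all__ = ["PROFILES", "profile_geometry", "make_fixture", "phantom_standoff"]

PROFILES = ("tiny", "default", "full_scale")

#: z standoff (mm) of the nearest phantom row from the collimator plate
PHANTOM_STANDOFF = {"tiny": 40.0, "default": 120.0, "full_scale": 120.0}


def phantom_standoff(profile: str) -> float:
    return PHANTOM_STANDOFF[profile]


def profile_geometry(profile: str) -> GeometryModel:
    """The geometry model for a named profile (deterministic)."""
    plate = (80.0, 40.0)
    pinholes = default_pinhole_pattern(n=9, plate_extent=plate)
    collimator = CollimatorSpec(pinholes=pinholes, plate_extent=plate)
    if profile == "tiny":
        detector = DetectorSpec(
            n_rows=64, n_cols=128, pixel_pitch=0.6, raw_shape=(128, 256), bin_factor=2
        )
        grid = VolumeGrid(n_x=12, n_y=20, n_z=20, spacing=4.0)
    elif profile == "default":
        detector = DetectorSpec(
            n_rows=128, n_cols=256, pixel_pitch=0.3, raw_shape=(256, 512), bin_factor=2
        )
        grid = VolumeGrid(n_x=15, n_y=25, n_z=45, spacing=4.0)
    elif profile == "full_scale":
        detector = DetectorSpec()  # 257 x 515, pitch 0.15, raw 514 x 1030
        grid = VolumeGrid()  # 60 x 100 x 200 at 2 mm
    else:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    return GeometryModel(detector=detector, collimator=collimator, grid=grid)


def make_fixture(profile: str, seed: int, out_dir: str | Path) -> dict:
    """Generate a fixture bundle under ``out_dir``; returns its manifest.

    Contents: ``geometry.yaml``, ``A.cache.npz``, ``phantom.csv``,
    ``stack/rep_*.tif`` (one seeded acquisition of phantom position 5),
    and ``expected.json`` with oracle-computed reference results
    (footprints of probe voxels from the per-ray loop, the greedy oracle's
    reconstruction of the simulated stack, and hand-computed quartiles).
    Bit-identical for a fixed (profile, seed).
    """
    model = profile_geometry(profile)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_geometry(model, out / "geometry.yaml")
    A = build_system_matrix(model)
    A.save(out / "A.cache.npz")

    phantom = generate_grid_phantom(
        spacing=20.0, origin_offset=(0.0, 0.0, phantom_standoff(profile))
    )
    pd.DataFrame(
        [
            {
                "id": i + 1,
                "x_mm": s.position[0],
                "y_mm": s.position[1],
                "z_mm": s.position[2],
                "activity_mbq": s.activity,
            }
            for i, s in enumerate(phantom)
        ]
    ).to_csv(out / "phantom.csv", index=False)

    det = model.detector
    cfg = AcquisitionConfig(n_repeats=3, seed=seed)
    stack, meta = simulate_acquisition([phantom[4]], A, model.grid, cfg)
    write_tiff_stack(stack.reshape(-1, det.n_rows, det.n_cols), out / "stack")

    expected = _oracle_expected(model, A, stack, seed)
    (out / "expected.json").write_text(json.dumps(expected, indent=2, sort_keys=True))
    manifest = {
        "profile": profile,
        "seed": seed,
        "geometry_hash": geometry_hash(model),
        "n_pixels": A.n_pixels,
        "n_voxels": A.n_voxels,
        "files": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _oracle_expected(model: GeometryModel, A, stack: np.ndarray, seed: int) -> dict:
    """Reference results computed only with :mod:`slnf.reference` primitives."""
    det, grid, col = model.detector, model.grid, model.collimator
    rng = np.random.default_rng(seed)
    pinholes_xy = [ph.center for ph in col.pinholes]
    fov = col.pinholes[0].fov_half_angle
    probes = sorted(rng.choice(grid.n_voxels, size=min(16, grid.n_voxels), replace=False).tolist())
    centers = reference.enumerate_voxel_centers(grid.n_x, grid.n_y, grid.n_z, grid.spacing)
    probe_columns = reference.brute_force_columns(
        [centers[j] for j in probes], pinholes_xy, det.plane_offset,
        det.pixel_pitch, det.n_rows, det.n_cols, fov,
    )
    # greedy oracle on the first simulated repeat needs all columns; only
    # affordable on the tiny profile, skipped otherwise
    recon = None
    if grid.n_voxels <= 5000:
        all_columns = reference.brute_force_columns(
            centers, pinholes_xy, det.plane_offset,
            det.pixel_pitch, det.n_rows, det.n_cols, fov,
        )
        voxels, scores = reference.greedy_oracle(all_columns, stack[0], n_sources=1)
        recon = {"voxels": voxels, "scores": scores}
    return {
        "probe_voxels": probes,
        "probe_footprints": probe_columns,
        "oracle_reconstruction": recon,
        "quartile_check": {
            "values": [1, 2, 3, 4, 5],
            "median": reference.quartiles_by_hand([1, 2, 3, 4, 5], 0.5),
            "q3": reference.quartiles_by_hand([1, 2, 3, 4, 5], 0.75),
        },
    }
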