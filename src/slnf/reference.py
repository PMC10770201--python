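"""Independent brute-force reference implementations for cross-validation.

Everything here is written from first principles with plain Python loops and
imports nothing from the rest of the package: these are the oracles the test
suite and fixtures compare the optimized implementation against.  Inputs are
plain numbers and arrays (no package types), so the two code paths share no
logic.  Do not use these at scale — they are deliberately naive.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "enumerate_voxel_centers",
    "project_point",
    "brute_force_columns",
    "exhaustive_correlation_scan",
    "greedy_oracle",
    "explicit_trace_score",
    "quartiles_by_hand",
]


def enumerate_voxel_centers(n_x, n_y, n_z, spacing):
    """Voxel centers by nested loops, x fastest; grid centered in x/y,
    z starting one spacing in front of the plate."""
    out = []
    for k in range(n_z):
        for j in range(n_y):
            for i in range(n_x):
                out.append(
                    (
                        (i - (n_x - 1) / 2.0) * spacing,
                        (j - (n_y - 1) / 2.0) * spacing,
                        (k + 1) * spacing,
                    )
                )
    return out


def project_point(
    source_xyz,
    pinhole_xy,
    plane_offset,
    pixel_pitch,
    n_rows,
    n_cols,
    fov_half_angle_deg,
):
    """Similar-triangles pinhole projection, coded independently.

    The detector plane lies ``plane_offset`` behind the pinhole plate; the ray
    from the source through the pinhole center crosses it at
    pinhole + (pinhole - source) * plane_offset / source_z (point inversion).
    Returns (row, col) of the containing pixel or None.
    """
    sx, sy, sz = source_xyz
    px, py = pinhole_xy
    if sz <= 0:
        raise ValueError("source must be strictly in front of the plate")
    lat = math.sqrt((px - sx) ** 2 + (py - sy) ** 2)
    if math.degrees(math.atan2(lat, sz)) > fov_half_angle_deg:
        return None
    t = plane_offset / sz
    hit_x = px + (px - sx) * t
    hit_y = py + (py - sy) * t
    half_w = n_cols * pixel_pitch / 2.0
    half_h = n_rows * pixel_pitch / 2.0
    col = math.floor((hit_x + half_w) / pixel_pitch)
    row = math.floor((half_h - hit_y) / pixel_pitch)
    if 0 <= row < n_rows and 0 <= col < n_cols:
        return row, col
    return None


def brute_force_columns(
    centers,
    pinholes_xy,
    plane_offset,
    pixel_pitch,
    n_rows,
    n_cols,
    fov_half_angle_deg,
):
    """Per-voxel footprints by an explicit per-ray loop.

    Returns a list (one entry per voxel) of sorted unique linear pixel indices.
    """
    columns = []
    for c in centers:
        hits = set()
        for ph in pinholes_xy:
            rc = project_point(
                c, ph, plane_offset, pixel_pitch, n_rows, n_cols, fov_half_angle_deg
            )
            if rc is not None:
                hits.add(rc[0] * n_cols + rc[1])
        columns.append(sorted(hits))
    return columns


def exhaustive_correlation_scan(columns, d_obs):
    """Score every voxel by summing observed counts over its footprint and
    return (best_voxel, best_score) with ties broken toward the lowest index."""
    best_voxel, best_score = 0, -math.inf
    for j, fp in enumerate(columns):
        score = 0.0
        for px in fp:
            score += float(d_obs[px])
        if score > best_score:
            best_voxel, best_score = j, score
    return best_voxel, best_score


def greedy_oracle(columns, d_obs, n_sources):
    """Naive greedy extraction: full exhaustive scan per round, then zero the
    winner's footprint pixels.  Returns lists of voxels and scores."""
    d = [float(v) for v in np.asarray(d_obs).ravel()]
    voxels, scores = [], []
    for _ in range(n_sources):
        j, s = exhaustive_correlation_scan(columns, d)
        voxels.append(j)
        scores.append(s)
        for px in columns[j]:
            d[px] = 0.0
    return voxels, scores


def explicit_trace_score(d):
    """Assessability by literally forming the rank-1 matrix d (d^T d)^-2 d^T
    and taking its trace.  O(len(d)^2) — test-scale vectors only."""
    d = np.asarray(d, dtype=float).ravel()
    s = float(d @ d)
    if s == 0:
        raise ValueError("zero vector has no score")
    mat = np.outer(d, d) / (s * s)
    return float(np.trace(mat))


def quartiles_by_hand(values, p):
    """Linear interpolation of order statistics at rank p*(n-1)+1."""
    xs = sorted(float(v) for v in values)
    if not xs:
        raise ValueError("empty list")
    h = p * (len(xs) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
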