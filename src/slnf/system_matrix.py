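"""Sparse binary system matrix A mapping voxelized activity to detector pixels.

A is N x M with A[i, j] = 1 iff a straight line exists from voxel j through
some pinhole center to detector pixel i (ideal point apertures, so each
column holds at most one pixel per pinhole — the voxel's "fingerprint").
Forward projection of an activity vector u is the matrix-vector product A u.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .geometry import GeometryModel, geometry_hash

__all__ = ["SystemMatrix", "build_system_matrix", "forward_project", "column_footprint"]

CACHE_FORMAT_VERSION = 1


class SystemMatrix:
    """Binary N x M operator with fast column extraction (CSC storage).

    Attributes
    ----------
    csc : scipy.sparse.csc_matrix
        Binary matrix, dtype float64 for fast matvecs.
    n_pixels, n_voxels : int
        N (detector pixels) and M (grid voxels).
    geometry_hash : str
        Hash of the geometry the matrix was built from (cache key).
    """

    def __init__(self, csc: sp.csc_matrix, geom_hash: str = "") -> None:
        if (csc.data != 1).any():
            raise ValueError("system matrix entries must all be binary")
        self.csc = csc
        self.geometry_hash = geom_hash

    @property
    def n_pixels(self) -> int:
        return self.csc.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.csc.shape[1]

    @property
    def nnz(self) -> int:
        return self.csc.nnz

    def column(self, voxel: int) -> np.ndarray:
        """Dense binary column (length N) — the voxel's projected fingerprint."""
        self._check_voxel(voxel)
        col = np.zeros(self.n_pixels)
        col[self.footprint(voxel)] = 1.0
        return col

    def footprint(self, voxel: int) -> np.ndarray:
        """Sorted pixel indices illuminated by the voxel (nonzeros of column)."""
        self._check_voxel(voxel)
        lo, hi = self.csc.indptr[voxel], self.csc.indptr[voxel + 1]
        return self.csc.indices[lo:hi].copy()

    def footprint_sizes(self) -> np.ndarray:
        """nnz of every column (length M)."""
        return np.diff(self.csc.indptr)

    def correlate_all(self, d_obs: np.ndarray) -> np.ndarray:
        """Correlation score of every voxel column with an observed image: A^T d."""
        return self.csc.T @ np.asarray(d_obs, dtype=float).ravel()

    def duplicate_footprints(self) -> list[np.ndarray]:
        """Groups of voxel indices whose footprints are identical and non-empty.

        Such voxels are mutually indistinguishable to the reconstruction; this
        diagnostic surfaces the degeneracy instead of hiding it.
        """
        groups: dict[bytes, list[int]] = {}
        indptr, indices = self.csc.indptr, self.csc.indices
        for j in range(self.n_voxels):
            fp = indices[indptr[j]:indptr[j + 1]]
            if fp.size == 0:
                continue
            groups.setdefault(np.sort(fp).tobytes(), []).append(j)
        return [np.array(g) for g in groups.values() if len(g) > 1]

    def ambiguous_footprints(self) -> np.ndarray:
        """Voxels whose footprint is contained in some other voxel's footprint.

        On its own noiseless projection such a voxel ties with every voxel
        whose footprint is a superset (the unnormalized correlation cannot
        separate them), so exact recovery is only guaranteed for voxels NOT
        in this set.  Includes duplicate footprints as a special case.
        O(M * pinholes * ray-length) — diagnostic scale, not for M ~ 1e6.
        """
        csr = self.csc.tocsr()
        out = []
        for j in range(self.n_voxels):
            fp = self.footprint(j)
            if fp.size == 0:
                continue
            cands: np.ndarray | None = None
            for p in fp:
                owners = csr.indices[csr.indptr[p]:csr.indptr[p + 1]]
                cands = owners if cands is None else np.intersect1d(cands, owners, assume_unique=True)
                if cands.size <= 1:
                    break
            if cands is not None and cands.size > 1:
                out.append(j)
        return np.array(out, dtype=np.int64)

    def _check_voxel(self, voxel: int) -> None:
        if not 0 <= voxel < self.n_voxels:
            raise IndexError(f"voxel index {voxel} out of range [0, {self.n_voxels})")

    # -- cache -------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the matrix to an .npz cache archive (versioned, documented).

        Layout: format_version, geometry_hash, shape (N, M), and the CSC
        indptr/indices arrays (data is implicitly all-ones).
        """
        np.savez_compressed(
            path,
            format_version=CACHE_FORMAT_VERSION,
            geometry_hash=self.geometry_hash,
            shape=np.array(self.csc.shape, dtype=np.int64),
            indptr=self.csc.indptr.astype(np.int64),
            indices=self.csc.indices.astype(np.int64),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SystemMatrix":
        with np.load(path, allow_pickle=False) as z:
            if int(z["format_version"]) != CACHE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported cache format version {int(z['format_version'])}"
                )
            shape = tuple(z["shape"])
            indptr = z["indptr"]
            indices = z["indices"]
            csc = sp.csc_matrix(
                (np.ones(len(indices)), indices, indptr), shape=shape
            )
            return cls(csc, geom_hash=str(z["geometry_hash"]))


def build_system_matrix(geometry: GeometryModel) -> SystemMatrix:
    """Trace every voxel through every pinhole and assemble A.

    Deterministic for a fixed geometry (two builds are identical).  A voxel
    reached through two pinholes landing on the same pixel keeps a single
    binary 1.  Vectorized per pinhole over all voxel centers.
    """
    det = geometry.detector
    grid = geometry.grid
    if grid.n_voxels == 0:
        raise ValueError("grid has zero voxels")
    centers = grid.all_centers()  # (M, 3)
    M = grid.n_voxels
    N = det.n_pixels
    rows_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    sx, sy, sz = centers[:, 0], centers[:, 1], centers[:, 2]
    for ph in geometry.collimator.pinholes:
        px, py = ph.center
        lateral = np.hypot(px - sx, py - sy)
        in_fov = np.degrees(np.arctan2(lateral, sz)) <= ph.fov_half_angle
        m = det.plane_offset / sz
        dx = px + (px - sx) * m
        dy = py + (py - sy) * m
        col = np.floor((dx + det.width / 2) / det.pixel_pitch).astype(np.int64)
        row = np.floor((det.height / 2 - dy) / det.pixel_pitch).astype(np.int64)
        ok = in_fov & (row >= 0) & (row < det.n_rows) & (col >= 0) & (col < det.n_cols)
        voxels = np.nonzero(ok)[0]
        rows_all.append(row[ok] * det.n_cols + col[ok])
        cols_all.append(voxels)
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_all) if cols_all else np.empty(0, dtype=np.int64)
    coo = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(N, M))
    csc = coo.tocsc()
    csc.sum_duplicates()
    csc.data[:] = 1.0  # two pinholes hitting one pixel stay binary
    csc.sort_indices()
    return SystemMatrix(csc, geom_hash=geometry_hash(geometry))


def forward_project(A: SystemMatrix, u: np.ndarray) -> np.ndarray:
    """Expected detector image A u (flattened, length N) for activity vector u."""
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != A.n_voxels:
        raise ValueError(f"activity vector length {u.shape[0]} != n_voxels {A.n_voxels}")
    if (u < 0).any():
        raise ValueError("activity vector must be non-negative")
    return A.csc @ u


def column_footprint(A: SystemMatrix, voxel: int) -> np.ndarray:
    """Pixel indices illuminated by one voxel; size <= number of pinholes."""
    return A.footprint(voxel)
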