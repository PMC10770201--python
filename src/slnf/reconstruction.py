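"""Greedy fingerprint localization of a known number of point sources.

Each candidate voxel's projected fingerprint (a binary system-matrix column)
is scored against the observed image by the plain inner product
C(d_proj, d_obs) = sum_i d_proj_i * d_obs_i — for a binary fingerprint this
is simply the observed counts collected on the footprint.  The algorithm
repeatedly picks the best-scoring voxel, zeroes the observed pixels inside
its footprint so the next-strongest source dominates, and repeats for the
requested number of sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VolumeGrid, voxel_center
from .system_matrix import SystemMatrix

__all__ = ["correlation", "slnf_reconstruct", "voxel_to_position", "Reconstruction"]


@dataclass(frozen=True)
class SourceEstimate:
    voxel: int
    position: tuple[float, float, float] | None
    score: float
    rank: int
    n_ties: int  # voxels sharing the maximal score this round


@dataclass
class Reconstruction:
    """Result of a greedy reconstruction: estimates in extraction order."""

    sources: list[SourceEstimate]
    residual: np.ndarray  # observed image after the final masking step
    degenerate: bool = False  # True if a round saw an all-zero image

    @property
    def voxels(self) -> list[int]:
        return [s.voxel for s in self.sources]

    @property
    def scores(self) -> list[float]:
        return [s.score for s in self.sources]


def correlation(d_proj: np.ndarray, d_obs: np.ndarray) -> float:
    """Inner-product match score between a projected and an observed image."""
    d_proj = np.asarray(d_proj, dtype=float).ravel()
    d_obs = np.asarray(d_obs, dtype=float).ravel()
    if d_proj.shape != d_obs.shape:
        raise ValueError(f"shape mismatch: {d_proj.shape} vs {d_obs.shape}")
    return float(d_proj @ d_obs)


def slnf_reconstruct(
    d_obs: np.ndarray,
    A: SystemMatrix,
    n_sources: int,
    grid: VolumeGrid | None = None,
    stop_fraction: float | None = None,
) -> Reconstruction:
    """Localize ``n_sources`` point sources in an observed detector image.

    Per round: score all M voxel columns against the current image (A^T d),
    take the argmax (ties broken towards the lowest voxel index, and counted),
    then zero the observed pixels in the winner's footprint.  The number of
    sources is assumed known; ``stop_fraction`` optionally stops early once a
    round's best score falls below that fraction of the first round's.

    An all-zero image makes every voxel tie at score 0; the result is then
    flagged ``degenerate`` rather than silently returning voxel 0.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    d = np.asarray(d_obs, dtype=float).ravel().copy()
    if d.shape[0] != A.n_pixels:
        raise ValueError(f"image length {d.shape[0]} != n_pixels {A.n_pixels}")
    estimates: list[SourceEstimate] = []
    degenerate = False
    first_score = None
    for rank in range(n_sources):
        scores = A.correlate_all(d)
        best = int(np.argmax(scores))  # first maximum = lowest voxel index
        best_score = float(scores[best])
        n_ties = int(np.count_nonzero(scores == best_score))
        if best_score <= 0:
            degenerate = True
        if first_score is None:
            first_score = best_score
        elif stop_fraction is not None and best_score < stop_fraction * first_score:
            break
        pos = voxel_center(grid, best) if grid is not None else None
        estimates.append(
            SourceEstimate(voxel=best, position=pos, score=best_score,
                           rank=rank, n_ties=n_ties)
        )
        d[A.footprint(best)] = 0.0  # mask the found source's fingerprint
    return Reconstruction(sources=estimates, residual=d, degenerate=degenerate)


def voxel_to_position(recon: Reconstruction, grid: VolumeGrid) -> list[tuple[float, float, float]]:
    """Map extracted voxels to world coordinates (mm) in extraction order."""
    return [voxel_center(grid, s.voxel) for s in recon.sources]
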