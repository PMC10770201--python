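"""A-optimal-design assessability score for candidate source positions.

For a point source at voxel i with detector fingerprint d (a binary column
of the system matrix), the assessability statistic is

    V(i) = trace( d (d^T d)^-2 d^T )

which for a vector argument reduces in closed form to 1 / (d^T d), i.e.
1 / nnz(d) for binary d.  Fewer illuminated pixels carry less information,
so a HIGHER score flags a position that is HARDER to localize.  The score
is computed via the closed form; the explicit rank-1 trace is kept only as
an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import VolumeGrid, nearest_voxel
from .simulator import SourceSpec
from .system_matrix import SystemMatrix

__all__ = ["assessability", "rank_positions", "AssessabilityTable"]


class InvisiblePositionError(ValueError):
    """The position's fingerprint is empty — no detector pixel sees it."""


def assessability(d: np.ndarray) -> float:
    """Closed-form score 1 / (d^T d) of a fingerprint vector.

    Raises for an all-zero fingerprint (the position is invisible to the
    detector and has no defined score).
    """
    d = np.asarray(d, dtype=float).ravel()
    s = float(d @ d)
    if s == 0:
        raise InvisiblePositionError("all-zero fingerprint: position is invisible")
    return 1.0 / s


@dataclass
class AssessabilityTable:
    """Per-position scores with a hardest-first ranking."""

    table: pd.DataFrame  # columns: index, x_mm, y_mm, z_mm, voxel, nnz, score, rank, visible

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_positions(
    positions: list[SourceSpec],
    A: SystemMatrix,
    grid: VolumeGrid,
) -> AssessabilityTable:
    """Score candidate positions and rank them descending (hardest first).

    Positions snap to their nearest grid voxel.  An invisible position
    (empty footprint) is listed with ``visible=False`` and NaN score instead
    of being dropped.  Ties share the smallest applicable rank.
    """
    rows = []
    for i, src in enumerate(positions, start=1):
        x, y, z = src.position
        voxel, _snap = nearest_voxel(grid, x, y, z)
        nnz = int(A.footprint(voxel).size)
        score = 1.0 / nnz if nnz > 0 else np.nan
        rows.append(
            {"index": i, "x_mm": x, "y_mm": y, "z_mm": z, "voxel": voxel,
             "nnz": nnz, "score": score, "visible": nnz > 0}
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["score"].rank(ascending=False, method="min").astype("Int64")
    return AssessabilityTable(table=df)
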