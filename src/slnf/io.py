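"""File formats: 16-bit TIFF count images, source CSVs, run manifests."""

from __future__ import annotations

import json
import platform
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulator import SourceSpec

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_tiff_stack",
    "read_tiff_stack",
    "read_sources_csv",
    "write_sources_csv",
    "write_manifest",
]

UINT16_MAX = 65535


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a count image as 16-bit grayscale TIFF (row 0 = top).

    Counts above 65535 are clipped with a warning — the physical detector
    is a 16-bit counter.
    """
    image = np.asarray(image)
    if image.max(initial=0) > UINT16_MAX:
        warnings.warn(
            f"{int((image > UINT16_MAX).sum())} pixel(s) exceed 65535 and were clipped",
            stacklevel=2,
        )
    tifffile.imwrite(Path(path), np.clip(image, 0, UINT16_MAX).astype(np.uint16))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def write_tiff_stack(stack: np.ndarray, out_dir: str | Path) -> list[Path]:
    """One TIFF per repeat: rep_000.tif, rep_001.tif, ..."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = out / f"rep_{i:03d}.tif"
        write_tiff(frame, p)
        paths.append(p)
    return paths


def read_tiff_stack(in_dir: str | Path) -> np.ndarray:
    paths = sorted(Path(in_dir).glob("rep_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no rep_*.tif images under {in_dir}")
    return np.stack([read_tiff(p) for p in paths])


def read_sources_csv(path: str | Path) -> list[SourceSpec]:
    """Columns: id, x_mm, y_mm, z_mm, activity_mbq."""
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "z_mm", "activity_mbq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sources CSV missing columns: {sorted(missing)}")
    return [
        SourceSpec(
            position=(float(r.x_mm), float(r.y_mm), float(r.z_mm)),
            activity=float(r.activity_mbq),
        )
        for r in df.itertuples()
    ]


def write_sources_csv(sources: list[SourceSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": i + 1,
                "x_mm": s.position[0],
                "y_mm": s.position[1],
                "z_mm": s.position[2],
                "activity_mbq": s.activity,
            }
            for i, s in enumerate(sources)
        ]
    ).to_csv(path, index=False)


def write_manifest(out_dir: str | Path, stage: str, **fields) -> Path:
    """Write the run manifest every output directory carries exactly one of."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        **fields,
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
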