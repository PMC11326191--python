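"""TIFF and JSON sidecar I/O for quadrant sets, phase images and label maps.

Quadrant sets are stored either as a 4-page TIFF (page order TL, TR, BL, BR)
or as four suffixed files ``<base>_TL.tif`` ... ``<base>_BR.tif``.  Derived
images (DF, E, QDF, phase) are 32-bit float TIFF; label maps are 16-bit.
Ground truth and calibration results travel as schema-versioned JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .qdf_core import AcquisitionMeta, CalibrationResult, QuadrantSet

SUFFIXES = ("TL", "TR", "BL", "BR")
SIDECAR_SCHEMA_VERSION = 1


def write_quadrant_set(base: str | Path, q: QuadrantSet, multipage: bool = False) -> list[Path]:
    """Write a quadrant set as uint16 TIFF(s); returns the written paths."""
    base = Path(base)
    stack = [np.asarray(img) for img in q.quadrants()]
    if multipage:
        path = base.with_suffix(".tif")
        tifffile.imwrite(path, np.stack(stack).astype(np.uint16))
        return [path]
    paths = []
    for name, img in zip(SUFFIXES, stack):
        path = base.parent / f"{base.name}_{name}.tif"
        tifffile.imwrite(path, img.astype(np.uint16))
        paths.append(path)
    return paths


def read_quadrant_set(base: str | Path, meta: AcquisitionMeta | None = None) -> QuadrantSet:
    """Read a quadrant set from a 4-page TIFF or four suffixed files.

    ``base`` may be a 4-page TIFF path or the common prefix of
    ``<base>_TL.tif`` etc.  Raises FileNotFoundError naming the first missing
    quadrant file.
    """
    base = Path(base)
    if base.is_file():
        stack = tifffile.imread(base)
        if stack.ndim != 3 or stack.shape[0] != 4:
            raise ValueError(f"{base}: expected a 4-page TIFF, got shape {stack.shape}")
        frames = [stack[i].astype(float) for i in range(4)]
    else:
        frames = []
        for name in SUFFIXES:
            path = base.parent / f"{base.name}_{name}.tif"
            if not path.exists():
                raise FileNotFoundError(f"missing quadrant frame: {path}")
            frames.append(tifffile.imread(path).astype(float))
    return QuadrantSet(*frames, meta=meta or AcquisitionMeta())


def write_float_tiff(path: str | Path, image: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_float_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_label_tiff(path: str | Path, labels: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))
    return path


def write_calibration(path: str | Path, result: CalibrationResult) -> Path:
    path = Path(path)
    payload = {"schema_version": SIDECAR_SCHEMA_VERSION, **dataclasses.asdict(result)}
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_calibration(path: str | Path) -> CalibrationResult:
    data = json.loads(Path(path).read_text())
    data.pop("schema_version", None)
    return CalibrationResult(**data)


def write_ground_truth(path: str | Path, records: list[dict]) -> Path:
    path = Path(path)
    payload = {"schema_version": SIDECAR_SCHEMA_VERSION, "cells": records}
    path.write_text(json.dumps(payload, indent=2))
    return path
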