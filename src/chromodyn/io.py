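"""Reading and writing scenes, label images and trace tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import ImageScene

__all__ = ["write_scene", "read_scene", "read_image", "write_label_image"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_scene(scene: ImageScene, tiff_path, sidecar_path=None) -> None:
    """Write a two-channel scene as a multi-page TIFF (page 0 = DAPI,
    page 1 = GFP) with an optional JSON ground-truth sidecar."""
    stack = np.stack([scene.dapi, scene.gfp]).astype(np.float32)
    tifffile.imwrite(str(tiff_path), stack)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps(_jsonable(scene.sidecar), indent=1))


def read_scene(tiff_path, sidecar_path=None) -> ImageScene:
    stack = tifffile.imread(str(tiff_path))
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected a multi-page TIFF with DAPI and GFP pages")
    sidecar = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        sidecar = json.loads(Path(sidecar_path).read_text())
    return ImageScene(dapi=np.asarray(stack[0], dtype=np.float64),
                      gfp=np.asarray(stack[1], dtype=np.float64),
                      sidecar=sidecar)


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def write_label_image(labels: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), labels.astype(np.int32))
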