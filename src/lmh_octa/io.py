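"""File formats: TIFF angiograms, PNG masks, JSON polygons, CSV/YAML tables.

Angiograms travel as 16-bit grayscale TIFF (frame stacks as multi-page
TIFF), binary masks as 8-bit PNG, polygons as JSON lists of ``[x_mm,
y_mm]`` vertices (closed implicitly), cohorts as CSV, and run
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .binarize import EnFaceAngiogram, normalize_image

__all__ = [
    "save_angiogram",
    "load_angiogram",
    "save_mask",
    "load_mask",
    "save_polygon",
    "load_polygon",
    "save_yaml",
    "load_yaml",
]

_U16 = 65535


def save_angiogram(path, angio: EnFaceAngiogram) -> None:
    """Write the en-face image (and frames, if any) as 16-bit TIFF pages."""
    pages = [angio.image] if angio.frames is None else [angio.image, *angio.frames]
    data = np.stack([np.clip(p, 0, 1) for p in pages]).astype(np.float64)
    tifffile.imwrite(path, np.rint(data * _U16).astype(np.uint16))


def load_angiogram(path, pixel_pitch_um: float, plexus: str = "SCP") -> EnFaceAngiogram:
    """Read a (multi-page) grayscale TIFF/PNG; page 0 is the en-face image,
    further pages are the frame stack.  Intensities are normalized."""
    path = Path(path)
    raw = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    if np.issubdtype(raw.dtype, np.integer):
        # integer images are fixed-point fractions of the dtype range
        arr = raw.astype(float) / np.iinfo(raw.dtype).max
    else:
        arr = np.asarray(raw, dtype=float)
        if arr.min() < 0 or arr.max() > 1:
            arr = normalize_image(arr)
    if arr.ndim == 2:
        return EnFaceAngiogram(
            image=arr, pixel_pitch_um=pixel_pitch_um, plexus=plexus
        )
    if arr.ndim != 3:
        raise ValueError("expected a 2-D image or a 3-D page stack")
    return EnFaceAngiogram(
        image=arr[0],
        frames=arr[1:] if arr.shape[0] > 1 else None,
        pixel_pitch_um=pixel_pitch_um,
        plexus=plexus,
    )


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def save_polygon(path, poly_mm: np.ndarray) -> None:
    verts = [[float(x), float(y)] for x, y in np.asarray(poly_mm, dtype=float)]
    Path(path).write_text(json.dumps(verts))


def load_polygon(path) -> np.ndarray:
    verts = json.loads(Path(path).read_text())
    arr = np.asarray(verts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: polygon JSON must be a list of [x_mm, y_mm] pairs")
    return arr


def save_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
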