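"""Reading and writing images, masks, manifests and metric tables.

Images round-trip through 8/16-bit grayscale TIFF or PNG; intensities are
normalized to [0, 1] on read (dividing by the full-scale value of the
recorded bit depth). Pixel pitch is never trusted from image headers — it
must come from the manifest or configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import EnFaceAngiogram, as_mask

PathLike = Union[str, Path]

#: Columns every cohort manifest must provide.
MANIFEST_REQUIRED = (
    "subject_id", "visit", "eye", "slab", "image_path", "pitch_x_um", "pitch_y_um",
)
#: Optional per-image overrides.
MANIFEST_OPTIONAL = ("fovea_row", "fovea_col", "disc_mask_path", "truth_path")


def write_image(path: PathLike, img: EnFaceAngiogram, bits: int = 16) -> None:
    """Write a [0,1] image as 8- or 16-bit grayscale TIFF/PNG."""
    if bits not in (8, 16):
        raise ValueError(f"unsupported bit depth {bits}")
    full = (1 << bits) - 1
    dtype = np.uint8 if bits == 8 else np.uint16
    data = np.round(np.clip(img.pixels, 0.0, 1.0) * full).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_image(
    path: PathLike,
    pitch_x_um: float,
    pitch_y_um: float,
    slab: Optional[str] = None,
    **meta_ids,
) -> EnFaceAngiogram:
    """Read a grayscale image and normalize intensities to [0, 1].

    ``pitch_*_um`` are required: image headers are not trusted for physical
    scale. The source bit depth is recorded in ``meta['bits']``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected grayscale, got shape {data.shape}")
    if data.dtype == np.uint8:
        bits = 8
    elif data.dtype == np.uint16:
        bits = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {data.dtype} (8/16-bit only)")
    img = EnFaceAngiogram(
        pixels=data.astype(np.float64) / ((1 << bits) - 1),
        pitch_x_um=pitch_x_um,
        pitch_y_um=pitch_y_um,
        slab=slab,
        **meta_ids,
    )
    img.meta["bits"] = bits
    img.meta["source"] = str(path)
    return img


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit {0, 255} PNG."""
    mask = as_mask(mask)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path: PathLike, like: Optional[np.ndarray] = None) -> np.ndarray:
    """Read a {0, 255} PNG mask as boolean; validate shape against ``like``."""
    data = np.asarray(iio.imread(Path(path)))
    if data.ndim == 3:
        data = data[:, :, 0]
    return as_mask(data > 0, like=like)


def write_truth(path: PathLike, truth_dict: dict) -> None:
    """Write scene ground-truth scalars as a JSON sidecar."""
    Path(path).write_text(json.dumps(truth_dict, indent=1, sort_keys=True))


def read_truth(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Raises ``ValueError`` naming any missing required column; referenced
    image paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required column(s): {', '.join(missing)}")
    root = path.parent
    for col in ("image_path", "disc_mask_path", "truth_path"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda p: str((root / p).resolve()) if isinstance(p, str) and p and not Path(p).is_absolute() else p
            )
    return df


def write_table(path: PathLike, df: pd.DataFrame) -> None:
    """Write a metrics/report table as CSV with a fixed column order.

    Floats are serialized with ``repr`` round-trip precision so reruns with
    identical inputs produce byte-identical files.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
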