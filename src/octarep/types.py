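"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays normalized to [0, 1], wrapped in
  :class:`EnFaceAngiogram` together with their physical pixel pitch;
* binary masks are plain 2-D boolean ``numpy`` arrays registered to the
  image grid (same shape, same 0-based row/col indexing);
* all physical scales carry units in their names (``*_um``, ``*_mm``) and
  are converted to pixels through the per-axis pitch, never assumed
  isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Default widefield scan geometry: a 15 x 9 mm field sampled at 800 x 534
#: pixels. The nominal sampling is isotropic but the exact quotients differ
#: slightly per axis, so the pitch is kept per-axis everywhere.
DEFAULT_WIDTH_PX = 800
DEFAULT_HEIGHT_PX = 534
DEFAULT_FIELD_MM = (15.0, 9.0)  # (x extent, y extent)
DEFAULT_PITCH_X_UM = DEFAULT_FIELD_MM[0] * 1000.0 / DEFAULT_WIDTH_PX   # 18.75
DEFAULT_PITCH_Y_UM = DEFAULT_FIELD_MM[1] * 1000.0 / DEFAULT_HEIGHT_PX  # ~16.854

SLABS = ("SCP", "DCP", "CC")


@dataclass
class EnFaceAngiogram:
    """A 2-D en-face angiogram with physical pitch and acquisition metadata.

    Parameters
    ----------
    pixels
        2-D float array, intensities in [0, 1].
    pitch_x_um, pitch_y_um
        Physical size of one pixel along image columns (x) and rows (y),
        in micrometres. Must be positive.
    slab
        One of ``"SCP"``, ``"DCP"``, ``"CC"`` (superficial plexus, deep
        plexus, choriocapillaris) or ``None`` when not applicable.
    subject_id, visit, eye
        Optional cohort identifiers carried through the pipeline.
    """

    pixels: np.ndarray
    pitch_x_um: float = DEFAULT_PITCH_X_UM
    pitch_y_um: float = DEFAULT_PITCH_Y_UM
    slab: Optional[str] = None
    subject_id: Optional[str] = None
    visit: Optional[int] = None
    eye: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not (self.pitch_x_um > 0 and self.pitch_y_um > 0):
            raise ValueError("pixel pitch must be positive")
        if self.slab is not None and self.slab not in SLABS:
            raise ValueError(f"unknown slab {self.slab!r}; expected one of {SLABS}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        """Physical area of one pixel in square micrometres."""
        return self.pitch_x_um * self.pitch_y_um

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceAngiogram":
        """Return a copy with new pixel data and identical metadata."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


def as_mask(arr: np.ndarray, like: Optional[np.ndarray] = None) -> np.ndarray:
    """Validate and coerce ``arr`` to a 2-D boolean mask.

    If ``like`` is given, the mask shape must match it exactly (masks are
    always registered to their source grid).
    """
    mask = np.asarray(arr)
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got ndim={mask.ndim}")
    if like is not None and mask.shape != np.asarray(like).shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {np.asarray(like).shape}")
    return mask
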