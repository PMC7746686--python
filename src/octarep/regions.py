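"""Macular / peripheral partition and exclusion masks on the widefield grid.

The macular region is an axis-aligned rectangle of physical size 6 x 6 mm
centred on the fovea; the periphery is its exact complement within the
field. A pixel belongs to the macula iff its centre (integer row/col
coordinate) lies in the half-open rectangle ``[centre - 3 mm, centre + 3 mm)``
on each axis — half-open so the partition is exact for every pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import as_mask

MACULA_SIZE_MM_DEFAULT = 6.0


@dataclass
class RegionPartition:
    """Disjoint, exhaustive macula/periphery masks plus optional disc mask."""

    macula: np.ndarray
    periphery: np.ndarray
    fovea_center_px: tuple[float, float]
    disc: Optional[np.ndarray] = None

    def region_mask(self, region: str) -> np.ndarray:
        if region == "macula":
            return self.macula
        if region == "periphery":
            return self.periphery
        if region == "whole":
            return self.macula | self.periphery
        raise ValueError(f"unknown region {region!r}")


def make_partition(
    shape: Sequence[int],
    pitch_um: Sequence[float],
    fovea_center_px: Optional[Sequence[float]] = None,
    macula_size_mm: float = MACULA_SIZE_MM_DEFAULT,
    disc: Optional[np.ndarray] = None,
) -> RegionPartition:
    """Build the macula/periphery partition.

    Parameters
    ----------
    shape
        Grid shape ``(n_rows, n_cols)``.
    pitch_um
        ``(pitch_y_um, pitch_x_um)`` — per-axis physical pixel size.
    fovea_center_px
        ``(row, col)`` of the fovea; defaults to the geometric image centre
        ``((n_rows-1)/2, (n_cols-1)/2)`` since widefield scans are
        fovea-centred.
    macula_size_mm
        Edge length of the macular square, default 6 mm.

    Raises
    ------
    ValueError
        If the macular rectangle does not fit inside the grid.
    """
    n_rows, n_cols = int(shape[0]), int(shape[1])
    pitch_y, pitch_x = float(pitch_um[0]), float(pitch_um[1])
    if pitch_y <= 0 or pitch_x <= 0:
        raise ValueError("pitch must be positive")
    if fovea_center_px is None:
        fovea_center_px = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    fr, fc = float(fovea_center_px[0]), float(fovea_center_px[1])
    if not (0 <= fr < n_rows and 0 <= fc < n_cols):
        raise ValueError(f"fovea centre {fovea_center_px} outside grid {shape}")

    half_rows = macula_size_mm * 1000.0 / 2.0 / pitch_y  # half-extent in px
    half_cols = macula_size_mm * 1000.0 / 2.0 / pitch_x
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    in_rows = (rows >= fr - half_rows) & (rows < fr + half_rows)
    in_cols = (cols >= fc - half_cols) & (cols < fc + half_cols)
    if fr - half_rows < -0.5 or fr + half_rows > n_rows - 0.5 or \
       fc - half_cols < -0.5 or fc + half_cols > n_cols - 0.5:
        raise ValueError(
            f"macular rectangle ({macula_size_mm} mm) exceeds grid bounds for "
            f"shape {shape} at pitch ({pitch_y}, {pitch_x}) um"
        )
    macula = np.outer(in_rows, in_cols)
    return RegionPartition(
        macula=macula,
        periphery=~macula,
        fovea_center_px=(fr, fc),
        disc=None if disc is None else as_mask(disc, like=macula),
    )


def disc_mask_from_circle(
    shape: Sequence[int], center_px: Sequence[float], radius_px: float
) -> np.ndarray:
    """Rasterize a circular optic-disc mask (pixel-centre inclusion).

    ``radius_px == 0`` yields an empty mask.
    """
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    n_rows, n_cols = int(shape[0]), int(shape[1])
    rr, cc = np.ogrid[:n_rows, :n_cols]
    return ((rr - float(center_px[0])) ** 2 + (cc - float(center_px[1])) ** 2
            ) <= radius_px ** 2 if radius_px > 0 else np.zeros((n_rows, n_cols), bool)


def load_or_draw_disc_mask(source, shape: Sequence[int]) -> np.ndarray:
    """Return a disc mask from a file path or a ``(center, radius_px)`` spec."""
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        from .io import read_mask

        return read_mask(source, like=np.empty(tuple(shape)))
    center, radius = source
    return disc_mask_from_circle(shape, center, radius)
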