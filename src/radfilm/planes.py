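"""Planar dose container used throughout the pipeline.

Coordinate convention: pixel centers, x to the right and y up (anterior-view
coronal plane), with the machine isocenter at (0, 0).  Row 0 of the pixel
array is the top of the plane (largest y).  ``origin_mm`` is the (x, y)
position of the center of pixel (0, 0).

Invalid pixels (e.g. produced by resampling outside the source extent) are
stored as NaN and excluded from downstream evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Provenance = Literal["film", "plan", "synthetic", "detector"]


@dataclass
class DosePlane:
    """A 2-D dose (or netOD) grid with physical geometry.

    Parameters
    ----------
    dose_gy
        (rows, cols) float array.  Unit is Gy unless ``unit`` says otherwise.
        NaN marks invalid (out-of-support) pixels.
    pixel_spacing_mm
        (sx, sy) pixel pitch in mm.
    origin_mm
        (x, y) of the center of pixel (0, 0); x right, y up, isocenter (0, 0).
    provenance
        Where the plane came from: ``film``, ``plan``, ``synthetic``
        or ``detector``.
    """

    dose_gy: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float]
    provenance: Provenance = "synthetic"
    label: str = ""
    unit: str = "Gy"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.ndim != 2 or self.dose_gy.size == 0:
            raise ValueError("dose grid must be a non-empty 2-D array")
        sx, sy = self.pixel_spacing_mm
        if sx <= 0 or sy <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = (float(sx), float(sy))
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.dose_gy.shape

    def x_coords(self) -> np.ndarray:
        """x (mm) of each column's pixel centers, increasing to the right."""
        sx, _ = self.pixel_spacing_mm
        return self.origin_mm[0] + sx * np.arange(self.shape[1])

    def y_coords(self) -> np.ndarray:
        """y (mm) of each row's pixel centers; row 0 is the top (largest y)."""
        _, sy = self.pixel_spacing_mm
        return self.origin_mm[1] - sy * np.arange(self.shape[0])

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) pixel indices of physical positions (mm)."""
        sx, sy = self.pixel_spacing_mm
        col = (np.asarray(x, dtype=float) - self.origin_mm[0]) / sx
        row = (self.origin_mm[1] - np.asarray(y, dtype=float)) / sy
        return row, col

    def max_dose(self) -> float:
        m = np.nanmax(self.dose_gy)
        return float(m)

    def copy(self) -> "DosePlane":
        return DosePlane(
            self.dose_gy.copy(),
            self.pixel_spacing_mm,
            self.origin_mm,
            provenance=self.provenance,
            label=self.label,
            unit=self.unit,
            meta=dict(self.meta),
        )


def centered_plane(
    values: np.ndarray,
    spacing_mm: float | tuple[float, float],
    provenance: Provenance = "synthetic",
    label: str = "",
    unit: str = "Gy",
) -> DosePlane:
    """Wrap an array in a DosePlane whose geometric center sits at isocenter."""
    values = np.asarray(values, dtype=float)
    if np.isscalar(spacing_mm) or isinstance(spacing_mm, (int, float)):
        spacing = (float(spacing_mm), float(spacing_mm))
    else:
        spacing = (float(spacing_mm[0]), float(spacing_mm[1]))
    rows, cols = values.shape
    ox = -spacing[0] * (cols - 1) / 2.0
    oy = spacing[1] * (rows - 1) / 2.0
    return DosePlane(values, spacing, (ox, oy), provenance=provenance, label=label, unit=unit)


def robust_max(values: np.ndarray, top_fraction: float = 0.005) -> float:
    """Noise-resistant maximum: mean of the top ``top_fraction`` of valid pixels.

    Single hot pixels on scanned film can dominate a plain max; averaging the
    top 0.5% of the distribution gives a stable normalization value.  With
    ``top_fraction`` small relative to 1/n this degrades gracefully to the
    exact maximum.
    """
    flat = np.asarray(values, dtype=float).ravel()
    flat = flat[np.isfinite(flat)]
    if flat.size == 0:
        raise ValueError("no finite values to take a maximum over")
    k = max(1, int(np.ceil(top_fraction * flat.size)))
    top = np.partition(flat, flat.size - k)[flat.size - k:]
    return float(np.mean(top))
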