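"""Geometry of parallel fibril arrays and their rasterization.

The substrate is a 1-D array of parallel gelatin stripes ("fibrils") on a
flat base, described by an axis angle, a center-to-center spacing and a
stripe width, imaged on a square-pixel grid.

Coordinate convention used throughout the package: ``x`` runs along image
columns, ``y`` along rows (y increases downward, the raster convention);
angles are measured in degrees from the +x axis toward +y and treated as
axial (period 180 degrees), wrapped into ``(-90, 90]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FibrilArraySpec", "DegenerateGeometryError", "generate_fibril_mask"]


class DegenerateGeometryError(ValueError):
    """Raised when a pattern is not representable on the pixel grid."""


@dataclass(frozen=True)
class FibrilArraySpec:
    """Geometry of the fibril pattern and the imaging grid.

    Parameters
    ----------
    axis_angle : float
        Fibril axis in degrees, wrapped into ``(-90, 90]``.
    spacing : float
        Center-to-center stripe pitch in micrometers.
    fibril_width : float
        Stripe width in micrometers; must be smaller than ``spacing``.
    field_width, field_height : float
        Imaged field size in micrometers.
    pixel_size : float
        Micrometers per pixel (square pixels).
    """

    axis_angle: float = 0.0
    spacing: float = 40.0
    fibril_width: float = 5.0
    field_width: float = 1000.0
    field_height: float = 1000.0
    pixel_size: float = 0.51

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.fibril_width <= 0:
            raise ValueError("fibril_width must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.fibril_width >= self.spacing:
            raise ValueError("fibril_width must be smaller than spacing")
        if not (-90.0 < self.axis_angle <= 90.0):
            raise ValueError("axis_angle must lie in (-90, 90]")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape ``(rows, cols)`` of the imaged field."""
        return (
            int(round(self.field_height / self.pixel_size)),
            int(round(self.field_width / self.pixel_size)),
        )

    @property
    def pitch_px(self) -> float:
        """Stripe pitch expressed in pixels."""
        return self.spacing / self.pixel_size

    def across_axis_coordinate(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Signed distance (um) of points from the line through the origin
        along the fibril axis, i.e. the coordinate perpendicular to the
        fibrils along which the pattern repeats."""
        a = np.deg2rad(self.axis_angle)
        return -np.asarray(x_um) * np.sin(a) + np.asarray(y_um) * np.cos(a)

    def nearest_fibril_center(self, d_um: np.ndarray) -> np.ndarray:
        """Across-axis coordinate of the fibril centerline nearest to ``d_um``.

        Centerlines sit at ``spacing/2 + k*spacing`` so that a stripe is
        fully contained in the field near each boundary.
        """
        d = np.asarray(d_um, dtype=float)
        return np.round((d - self.spacing / 2.0) / self.spacing) * self.spacing + self.spacing / 2.0


def generate_fibril_mask(spec: FibrilArraySpec) -> np.ndarray:
    """Rasterize the fibril pattern as a boolean stripe mask.

    A pixel is on-fibril when the center of that pixel lies within
    ``fibril_width/2`` of the nearest stripe centerline. Deterministic.

    Raises
    ------
    DegenerateGeometryError
        If spacing or stripe width falls below one pixel.
    """
    if spec.spacing < spec.pixel_size or spec.fibril_width < spec.pixel_size:
        raise DegenerateGeometryError(
            f"pattern (spacing={spec.spacing} um, width={spec.fibril_width} um) "
            f"not representable at {spec.pixel_size} um/px"
        )
    rows, cols = spec.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    x_um = (xx + 0.5) * spec.pixel_size
    y_um = (yy + 0.5) * spec.pixel_size
    d = spec.across_axis_coordinate(x_um, y_um)
    offset = np.abs(d - spec.nearest_fibril_center(d))
    return offset <= spec.fibril_width / 2.0
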