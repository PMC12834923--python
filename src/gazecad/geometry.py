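"""Pixel-box geometry shared across the pipeline.

Boxes are axis-aligned rectangles in 0-based image pixel coordinates with
half-open extents ``[x_min, x_max) x [y_min, y_max)``, matching raster
indexing.  Area-of-interest (AOI) membership, however, is inclusive of the
expanded boundary: a gaze sample sitting exactly on the margin edge counts
as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PixelBox"]


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned box, half-open in both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def expand(self, margin: float) -> "PixelBox":
        if margin < 0:
            raise ValueError("margin must be >= 0")
        return PixelBox(
            self.x_min - margin, self.y_min - margin,
            self.x_max + margin, self.y_max + margin,
        )

    def clip(self, width: float, height: float) -> "PixelBox":
        return PixelBox(
            max(self.x_min, 0.0), max(self.y_min, 0.0),
            min(self.x_max, width), min(self.y_max, height),
        )

    def contains(self, x, y, inclusive: bool = True):
        """Vectorised point-membership test.

        ``inclusive=True`` treats all four edges as part of the box (the AOI
        convention); ``inclusive=False`` applies the half-open raster
        convention.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if inclusive:
            return (
                (x >= self.x_min) & (x <= self.x_max)
                & (y >= self.y_min) & (y <= self.y_max)
            )
        return (
            (x >= self.x_min) & (x < self.x_max)
            & (y >= self.y_min) & (y < self.y_max)
        )

    def intersects(self, other: "PixelBox") -> bool:
        """Closed-set overlap test (touching edges count as intersecting)."""
        return not (
            self.x_max < other.x_min or other.x_max < self.x_min
            or self.y_max < other.y_min or other.y_max < self.y_min
        )
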