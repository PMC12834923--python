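"""The five eye-tracking metrics computed from raw gaze sample streams.

A read is a stream of (t, x, y, valid) samples recorded at a nominal rate
(60 Hz for the eye tracker modelled here).  Metrics operate on the raw
samples directly — no fixation-detection filter (I-DT/I-VT) is applied.
"First fixation" on the lesion is therefore the first *valid sample* whose
point falls inside the lesion area of interest (AOI): the lesion bounding
box expanded by a margin (default 50 px, roughly the foveal span of ~1.1
degrees at a typical workstation geometry).

The metrics:

* interpretation time — wall-clock duration of the read, start to case
  advance, independent of tracking validity;
* lesion dwell time — each valid in-AOI sample contributes one sampling
  interval (1/rate s); no interpolation across dropped samples;
* time to first fixation (TTFF) — timestamp of the earliest valid in-AOI
  sample, absent when the gaze never enters the AOI;
* gaze-path length — summed Euclidean distance between consecutive valid
  samples; the polyline bridges dropout gaps of any length;
* lung-field coverage — fraction of cell x cell grid tiles of the lung
  field crossed by the gaze polyline dilated by a buffer (defaults 50 px
  each).  The grid is anchored at the image origin; a tile belongs to the
  lung field iff its centre pixel lies inside the lung mask; a lung tile is
  covered iff its (closed) square is within the buffer distance of the
  polyline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import PixelBox

__all__ = [
    "GazeRecording",
    "LesionAOI",
    "MetricRecord",
    "interpretation_time",
    "dwell_time",
    "time_to_first_fixation",
    "path_length",
    "lung_coverage",
    "lung_tiles",
    "covered_lung_tiles",
    "visual_angle",
    "render_overlay",
]


class RecordingError(ValueError):
    """Malformed gaze recording or incompatible inputs."""


@dataclass
class GazeRecording:
    """One read of one case: ordered gaze samples plus the read duration.

    ``duration`` runs from read start to case advance and may exceed the
    last sample timestamp (the tracker can drop the tail of a read).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    duration: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise RecordingError("sample arrays have mismatched lengths")
        if self.sampling_rate <= 0:
            raise RecordingError("sampling_rate must be > 0")
        if n:
            if self.t[0] < 0:
                raise RecordingError("negative timestamp")
            if np.any(np.diff(self.t) <= 0):
                raise RecordingError("timestamps must be strictly increasing")
            if self.duration < self.t[-1] - 1e-9:
                raise RecordingError("duration shorter than the last sample timestamp")
        if self.duration < 0:
            raise RecordingError("negative duration")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_points(self) -> np.ndarray:
        """(n_valid, 2) array of valid sample coordinates, in time order."""
        return np.column_stack([self.x[self.valid], self.y[self.valid]])


@dataclass(frozen=True)
class LesionAOI:
    """Lesion bounding box expanded by a foveal margin, clipped to the image."""

    box: PixelBox
    margin: float = 50.0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    def region(self, image_width: float, image_height: float) -> PixelBox:
        return self.box.expand(self.margin).clip(image_width, image_height)

    def contains(self, x, y, image_width: float, image_height: float):
        return self.region(image_width, image_height).contains(x, y, inclusive=True)


@dataclass
class MetricRecord:
    """The five per-read metrics plus the tracking capture ratio."""

    interpretation_time: float
    dwell_time: float | None
    time_to_first_fixation: float | None
    path_length: float
    coverage: float
    capture_ratio: float

    def __post_init__(self) -> None:
        if self.dwell_time is not None and self.dwell_time > self.interpretation_time + 1e-9:
            raise ValueError("dwell time exceeds interpretation time")
        if (
            self.time_to_first_fixation is not None
            and self.time_to_first_fixation > self.interpretation_time + 1e-9
        ):
            raise ValueError("time to first fixation exceeds interpretation time")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage outside [0, 1]")
        if self.path_length < 0:
            raise ValueError("negative path length")


def interpretation_time(rec: GazeRecording) -> float:
    """Total read duration in seconds; unaffected by sample validity."""
    return float(rec.duration)


def _inside_aoi(rec: GazeRecording, aoi: LesionAOI) -> np.ndarray:
    return rec.valid & aoi.contains(rec.x, rec.y, rec.image_width, rec.image_height)


def dwell_time(rec: GazeRecording, aoi: LesionAOI) -> float:
    """Cumulative gaze time inside the lesion AOI, in seconds.

    Each valid in-AOI sample counts one sampling interval.
    """
    return float(_inside_aoi(rec, aoi).sum() / rec.sampling_rate)


def time_to_first_fixation(rec: GazeRecording, aoi: LesionAOI) -> float | None:
    """Timestamp of the first valid sample inside the AOI, or None."""
    hits = np.flatnonzero(_inside_aoi(rec, aoi))
    if hits.size == 0:
        return None
    return float(rec.t[hits[0]])


def path_length(rec: GazeRecording) -> float:
    """Summed Euclidean distance between consecutive valid samples (px)."""
    pts = rec.valid_points()
    if pts.shape[0] < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def lung_tiles(mask: np.ndarray, cell: int = 50) -> np.ndarray:
    """(n, 2) integer array of (col, row) grid-tile indices in the lung field.

    The grid is anchored at pixel (0, 0).  A tile belongs to the lung field
    iff its centre pixel (tile origin + cell//2 in each axis) lies inside
    the image and the mask is truthy there; partial edge tiles whose centre
    falls outside the image are not tiles.
    """
    if cell <= 0:
        raise ValueError("cell must be > 0")
    h, w = mask.shape
    half = cell // 2
    cxs = np.arange(half, w, cell)
    cys = np.arange(half, h, cell)
    inside = np.asarray(mask, dtype=bool)[np.ix_(cys, cxs)]
    rows, cols = np.nonzero(inside)
    return np.column_stack([cols, rows])


def covered_lung_tiles(
    points: np.ndarray, tiles: np.ndarray, cell: int, buffer: float
) -> np.ndarray:
    """Boolean mask over ``tiles``: which tile squares lie within ``buffer``
    of the polyline through ``points`` (closed-set distance, so touching
    counts).  Empty point set covers nothing."""
    n_pts = 0 if points is None else len(points)
    if n_pts == 0:
        return np.zeros(len(tiles), dtype=bool)
    if n_pts == 1:
        geom = shapely.Point(points[0])
    else:
        geom = shapely.LineString(points)
    x0 = tiles[:, 0] * float(cell)
    y0 = tiles[:, 1] * float(cell)
    boxes = shapely.box(x0, y0, x0 + cell, y0 + cell)
    # cheap bounding-box prefilter before exact distance tests
    bx0, by0, bx1, by1 = geom.bounds
    near = ~(
        (x0 + cell < bx0 - buffer) | (x0 > bx1 + buffer)
        | (y0 + cell < by0 - buffer) | (y0 > by1 + buffer)
    )
    out = np.zeros(len(tiles), dtype=bool)
    if near.any():
        out[near] = shapely.dwithin(boxes[near], geom, buffer)
    return out


def lung_coverage(
    rec: GazeRecording,
    mask: np.ndarray,
    cell: int = 50,
    buffer: float = 50.0,
) -> float:
    """Fraction of lung-field grid tiles crossed by the buffered gaze path."""
    h, w = mask.shape
    if (w, h) != (rec.image_width, rec.image_height):
        raise RecordingError(
            f"mask is {w}x{h} but recording images are "
            f"{rec.image_width}x{rec.image_height}"
        )
    tiles = lung_tiles(mask, cell=cell)
    if len(tiles) == 0:
        raise RecordingError("lung mask contains no grid tiles")
    pts = rec.valid_points()
    if pts.shape[0] < 1:
        return 0.0
    covered = covered_lung_tiles(pts, tiles, cell, buffer)
    return float(covered.sum() / len(tiles))


def visual_angle(extent_px: float, pixel_pitch_mm: float, viewing_distance_cm: float) -> float:
    """Visual angle (degrees) subtended by ``extent_px`` pixels.

    ``2 * atan(extent * pitch / (2 * distance))``; e.g. 50 px at 0.233 mm
    pitch viewed from 60 cm subtends about 1.1 degrees.
    """
    if extent_px < 0:
        raise ValueError("extent must be >= 0")
    if pixel_pitch_mm <= 0 or viewing_distance_cm <= 0:
        raise ValueError("pixel pitch and viewing distance must be > 0")
    extent_mm = extent_px * pixel_pitch_mm
    return math.degrees(2.0 * math.atan2(extent_mm, 2.0 * viewing_distance_cm * 10.0))


def render_overlay(
    rec: GazeRecording, mask: np.ndarray, buffer: float = 50.0
) -> np.ndarray:
    """Diagnostic RGB rendering of a read: lung tint, path, buffered band.

    The lung field is tinted cyan; the gaze polyline is shaded from black
    (start) to white (end); the band within ``buffer`` of the path is
    coloured orange grading to red with local path-overlap density.  Output
    is a (H, W, 3) uint8 array with the input dimensions; deterministic.
    """
    from scipy.ndimage import distance_transform_edt, uniform_filter
    from skimage.draw import line as draw_line

    h, w = mask.shape
    img = np.zeros((h, w, 3), dtype=float)
    lung = np.asarray(mask, dtype=bool)
    img[lung] = (0.0, 90.0, 90.0)

    pts = rec.valid_points()
    hits = np.zeros((h, w), dtype=np.int32)
    if len(pts) >= 1:
        pix = np.clip(np.round(pts).astype(int), [0, 0], [w - 1, h - 1])
        hits[pix[0, 1], pix[0, 0]] += 1
        for (x0, y0), (x1, y1) in zip(pix[:-1], pix[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            hits[rr, cc] += 1
        dist = distance_transform_edt(hits == 0)
        band = dist <= buffer
        density = uniform_filter(
            (hits > 0).astype(float), size=max(3, int(2 * buffer + 1))
        )
        dmax = density[band].max() if band.any() else 1.0
        rel = density / dmax if dmax > 0 else density
        # orange (255,160,0) -> red (255,0,0) with overlap density
        img[band, 0] = 255.0
        img[band, 1] = 160.0 * (1.0 - rel[band])
        img[band, 2] = 0.0
        # polyline shaded dark (start) to light (end)
        n_seg = max(len(pix) - 1, 1)
        for i, ((x0, y0), (x1, y1)) in enumerate(zip(pix[:-1], pix[1:])):
            rr, cc = draw_line(y0, x0, y1, x1)
            shade = 255.0 * i / n_seg
            img[rr, cc] = shade
        if len(pix) == 1:
            img[pix[0, 1], pix[0, 0]] = 0.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
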