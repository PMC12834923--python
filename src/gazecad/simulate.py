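"""Synthetic reader-study generator with known ground truth.

Generates complete datasets for the pipeline: elliptical lung masks, lesion
and prompt boxes, 60 Hz gaze recordings with sample dropout, and binary
decisions, for every reader x session x case of a crossover design.  The
generator *targets the measured metrics directly*: for each read it draws
latent values of the five metrics (log-normal around the reader's medians,
multiplied by a per-case factor shared across readers and sessions, plus an
additive condition effect when the CAD box is displayed) and then
constructs a sample stream whose recomputed metrics land on those targets:

* interpretation time — the sample count fixes the duration exactly;
* dwell / TTFF — a visit to the lesion box is scheduled so that the first
  *valid* in-lesion sample sits at the target latency and the valid
  in-lesion count matches the target dwell (dropout-aware, since the
  metrics are computed from valid samples only, as they are for real data);
* coverage — a region of lung grid tiles is grown to the target size and
  scanned in a serpentine route; the region size is iterated against the
  real coverage metric until the measured value matches;
* path length — a perpendicular zigzag of bisected amplitude is added to
  the route so the valid-sample polyline length matches the target.

No saccadic physiology is modelled; the construction exists so that every
downstream stage can be tested against a known truth.  Latent targets,
achieved values and feasibility flags are recorded with every read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .design import CaseSpec, DesignConfig, Group, STUDY_DESIGN, allocate_cases
from .geometry import PixelBox
from .metrics import GazeRecording, covered_lung_tiles, lung_tiles

__all__ = [
    "ReaderProfile",
    "ConditionEffects",
    "MetricDispersion",
    "GeneratorConfig",
    "LatentTargets",
    "SimulatedRead",
    "StudyBundle",
    "PlacementError",
    "make_lung_mask",
    "sample_lesion_box",
    "simulate_scanpath",
    "simulate_study",
    "simulate_metric_values",
    "paper_defaults",
]

WITH_BB = "with_bb"
WITHOUT_BB = "without_bb"


class PlacementError(RuntimeError):
    """Could not place a box or construct a mask with the given inputs."""


@dataclass(frozen=True)
class ReaderProfile:
    """Baseline (no-CAD) behaviour of one reader.

    Medians are on the measured-metric scale: seconds for times, pixels for
    path length, a fraction in (0, 1] for lung coverage.  ``dropout_rate``
    is the mean fraction of gaze samples lost per read; the realised rate
    varies read-to-read (Beta with concentration ``dropout_concentration``),
    which is what occasionally pushes a read under the validity threshold.
    ``prompt_adoption`` is the weight pulling the session-1 decision toward
    agreement with the displayed box.
    """

    reader_id: str
    median_interpretation_time_s: float
    median_dwell_s: float
    median_ttff_s: float
    median_path_px: float
    median_coverage: float
    dropout_rate: float = 0.0
    dropout_concentration: float = 2.5
    decision_sensitivity: float = 0.75
    decision_specificity: float = 0.85
    prompt_adoption: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "median_interpretation_time_s", "median_dwell_s", "median_ttff_s",
            "median_path_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.median_coverage <= 1.0):
            raise ValueError("median_coverage must be in (0, 1]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ConditionEffects:
    """Additive shifts applied when the CAD box is displayed.

    Units follow the reported scale of each metric: seconds, seconds,
    seconds (negative = faster first arrival), pixels, and percentage
    points of lung coverage.
    """

    delta_interpretation_time_s: float = 0.0
    delta_dwell_s: float = 0.0
    delta_ttff_s: float = 0.0
    delta_path_px: float = 0.0
    delta_coverage_pp: float = 0.0

    @property
    def delta_coverage_fraction(self) -> float:
        return self.delta_coverage_pp / 100.0


@dataclass(frozen=True)
class MetricDispersion:
    """Log-scale spread of each metric.

    Each sigma is applied twice, independently: once as a per-case factor
    (shared by all readers and sessions of a case — the case random
    intercept) and once per read, so the total log-sd of a metric is
    sigma * sqrt(2).
    """

    sigma_time: float = 0.33
    sigma_dwell: float = 0.45
    sigma_ttff: float = 0.50
    sigma_path: float = 0.33
    sigma_coverage: float = 0.07
    #: correlation between the path and coverage draws (case and read level):
    #: a read that roams farther also covers more of the lung, and strongly
    #: discordant draws would be geometrically impossible anyway
    rho_path_coverage: float = 0.75
    #: correlation between the duration and TTFF draws: a long search is
    #: long largely because the lesion took long to find, and TTFF can
    #: never exceed the read duration
    rho_time_ttff: float = 0.6


@dataclass
class GeneratorConfig:
    readers: list[ReaderProfile]
    effects: ConditionEffects
    design: DesignConfig = STUDY_DESIGN
    image_width: int = 2560
    image_height: int = 1440
    sampling_rate: float = 60.0
    dispersion: MetricDispersion = field(default_factory=MetricDispersion)
    lesion_size_range: tuple[int, int] = (40, 90)
    aoi_margin: float = 50.0
    coverage_cell: int = 50
    coverage_buffer: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.readers:
            raise ValueError("at least one reader profile is required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


_FIVE = ("time", "dwell", "ttff", "path", "coverage")


@dataclass
class LatentTargets:
    """Drawn metric targets, achieved values, and feasibility flags."""

    condition: str
    duration_s: float
    dwell_s: float | None
    ttff_s: float | None
    path_px: float
    coverage: float
    achieved_dwell_s: float | None
    achieved_ttff_s: float | None
    achieved_path_px: float
    achieved_coverage: float
    dropout: float
    flags: tuple[str, ...] = ()


@dataclass
class SimulatedRead:
    reader: str
    session: int
    case_id: str
    condition: str
    recording: GazeRecording
    latent: LatentTargets
    decision: str | None = None


def make_lung_mask(width: int, height: int, seed: int) -> np.ndarray:
    """Two disjoint elliptical "lungs", laid out like a portrait chest
    radiograph pillarboxed on a landscape display.

    A PA radiograph shown fit-to-height on a wide monitor occupies a
    roughly square central window, and the two lung fields fill about
    40-50 % of that window — some 15-20 % of the full frame.  The mask
    emulates that: two tall ellipses flanking a mediastinal gap, together
    covering ~15-19 % of the frame.  Deterministic per seed; boolean
    raster of shape (height, width).
    """
    if width < 64 or height < 64:
        raise ValueError("mask dimensions must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=bool)
    for cx_frac in (0.40, 0.60):
        cx = (cx_frac + rng.uniform(-0.006, 0.006)) * width
        cy = (0.50 + rng.uniform(-0.03, 0.03)) * height
        a = rng.uniform(0.082, 0.090) * width   # horizontal semi-axis
        b = rng.uniform(0.29, 0.33) * height    # vertical semi-axis
        rr, cc = _draw_ellipse(cy, cx, b, a, shape=mask.shape)
        mask[rr, cc] = True
    return mask


def sample_lesion_box(
    mask: np.ndarray,
    size_range: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> PixelBox:
    """A box of side lengths in ``size_range`` centred on a lung-mask pixel."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise PlacementError("cannot place a box on an empty mask")
    h_img, w_img = mask.shape
    lo, hi = size_range
    for _ in range(max_tries):
        k = rng.integers(xs.size)
        cx, cy = int(xs[k]), int(ys[k])
        bw = int(rng.integers(lo, hi + 1))
        bh = int(rng.integers(lo, hi + 1))
        x0 = cx - bw // 2
        y0 = cy - bh // 2
        if x0 < 0 or y0 < 0 or x0 + bw > w_img or y0 + bh > h_img:
            continue
        return PixelBox(float(x0), float(y0), float(x0 + bw), float(y0 + bh))
    raise PlacementError(f"no in-bounds placement after {max_tries} tries")


def _lognorm(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _grow_tile_order(
    tiles: np.ndarray, start_idx: int, tiebreak: np.ndarray
) -> list[int]:
    """Compact growth order over the tile grid (4-adjacency): tiles join in
    order of distance from the seed, which keeps the grown region near-disk
    shaped and the serpentine route over it short.  Growth restarts at the
    nearest unvisited tile when a connected component (one lung) is
    exhausted.  ``tiebreak`` perturbs the ordering deterministically."""
    import heapq

    index_of = {(int(c), int(r)): i for i, (c, r) in enumerate(tiles)}
    visited = np.zeros(len(tiles), dtype=bool)
    order: list[int] = []
    current = start_idx
    while True:
        seed_cr = tiles[current].astype(float)
        dist = np.hypot(*(tiles - seed_cr).T)
        heap = [(0.0, current)]
        visited[current] = True
        while heap:
            _, i = heapq.heappop(heap)
            order.append(i)
            c, r = int(tiles[i, 0]), int(tiles[i, 1])
            for dc, dr in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                j = index_of.get((c + dc, r + dr))
                if j is not None and not visited[j]:
                    visited[j] = True
                    heapq.heappush(heap, (float(dist[j]) + tiebreak[j], j))
        if visited.all():
            return order
        last = tiles[order[-1]]
        unv = np.flatnonzero(~visited)
        d = np.abs(tiles[unv] - last).sum(axis=1)
        current = int(unv[np.argmin(d)])
        # loop continues with the new seed


def _band_route(
    sel: np.ndarray, cell: int, split_x: float | None = None, band_rows: int = 3
) -> np.ndarray:
    """Boustrophedon route over a tile set: tiles are grouped into
    ``band_rows``-row horizontal bands and each band is crossed once along
    its full x-span, so every selected tile sits within one tile row (and
    within the buffer) of a run.  ``split_x`` routes each side of a split
    (the two lungs) separately, avoiding runs across the mediastinum.
    """
    if len(sel) == 0:
        return np.empty((0, 2), dtype=float)
    half = cell / 2.0
    if split_x is None:
        parts = [sel]
    else:
        left = sel[:, 0] * cell + half < split_x
        parts = [sel[left], sel[~left]]
    pts: list[tuple[float, float]] = []
    flip = False
    for part in parts:
        if len(part) == 0:
            continue
        bands: dict[int, list[np.ndarray]] = {}
        for tile in part:
            bands.setdefault(int(tile[1]) // band_rows, []).append(tile)
        for b in sorted(bands):
            tl = np.asarray(bands[b])
            x0 = tl[:, 0].min() * cell + half
            x1 = tl[:, 0].max() * cell + half
            y = 0.5 * (tl[:, 1].min() + tl[:, 1].max()) * cell + half
            a, z = (x0, x1) if not flip else (x1, x0)
            pts.append((a, y))
            if x1 > x0:
                pts.append((z, y))
            flip = not flip
    return np.asarray(pts, dtype=float)


def _positions_along(waypoints: np.ndarray, n: int, fallback: np.ndarray) -> np.ndarray:
    """Place ``n`` points evenly (by arc length) along the waypoint
    polyline; degenerate routes collapse onto a single point."""
    if n == 0:
        return np.empty((0, 2), dtype=float)
    if len(waypoints) == 0:
        return np.tile(fallback, (n, 1))
    if len(waypoints) == 1:
        return np.tile(waypoints[0], (n, 1))
    seg = np.diff(waypoints, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    if total == 0:
        return np.tile(waypoints[0], (n, 1))
    u = np.linspace(0.0, total, n)
    x = np.interp(u, arc, waypoints[:, 0])
    y = np.interp(u, arc, waypoints[:, 1])
    return np.column_stack([x, y])


def _push_out(points: np.ndarray, region: PixelBox, active: np.ndarray) -> np.ndarray:
    """Move active points that fall inside ``region`` just outside its
    nearest edge (the gaze must not graze the lesion AOI outside the
    scheduled visit)."""
    pts = points.copy()
    inside = active & region.contains(pts[:, 0], pts[:, 1], inclusive=True)
    if not inside.any():
        return pts
    x, y = pts[inside, 0], pts[inside, 1]
    d = np.column_stack([
        x - region.x_min,          # distance to the left edge
        region.x_max - x,          # right
        y - region.y_min,          # top
        region.y_max - y,          # bottom
    ])
    choice = np.argmin(d, axis=1)
    x = np.where(choice == 0, region.x_min - 1.0, np.where(choice == 1, region.x_max + 1.0, x))
    y = np.where(choice == 2, region.y_min - 1.0, np.where(choice == 3, region.y_max + 1.0, y))
    pts[inside, 0] = x
    pts[inside, 1] = y
    return pts


def _valid_path_length(pos: np.ndarray, valid: np.ndarray) -> float:
    pts = pos[valid]
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def simulate_scanpath(
    case: CaseSpec,
    condition: str,
    profile: ReaderProfile,
    effects: ConditionEffects,
    rng: np.random.Generator,
    *,
    mask: np.ndarray,
    dispersion: MetricDispersion | None = None,
    case_factors: dict[str, float] | None = None,
    sampling_rate: float = 60.0,
    aoi_margin: float = 50.0,
    cell: int = 50,
    buffer: float = 50.0,
    tiles: np.ndarray | None = None,
    max_coverage_iters: int = 10,
) -> tuple[GazeRecording, LatentTargets]:
    """Generate one read of one case; see the module docstring for the
    construction.  ``tiles`` may carry precomputed ``lung_tiles(mask, cell)``
    to avoid recomputation across the reads of a case."""
    if condition not in (WITH_BB, WITHOUT_BB):
        raise ValueError(f"unknown condition {condition!r}")
    disp = dispersion or MetricDispersion()
    f = case_factors or {m: 1.0 for m in _FIVE}
    with_bb = condition == WITH_BB
    eff = effects if with_bb else ConditionEffects()
    rate = float(sampling_rate)
    h_img, w_img = mask.shape
    flags: list[str] = []

    # ---- latent metric targets --------------------------------------------
    z_time = rng.standard_normal()
    duration = profile.median_interpretation_time_s * f["time"] * float(
        np.exp(disp.sigma_time * z_time)
    )
    duration = max(duration + eff.delta_interpretation_time_s, 1.5)
    n = max(int(round(duration * rate)), 16)
    duration = n / rate

    rho = disp.rho_path_coverage
    z_cov = rng.standard_normal()
    z_path = rho * z_cov + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal()
    path_target = profile.median_path_px * f["path"] * float(np.exp(disp.sigma_path * z_path))
    path_target = max(path_target + eff.delta_path_px, 100.0)
    cov_target = profile.median_coverage * f["coverage"] * float(
        np.exp(disp.sigma_coverage * z_cov)
    )
    cov_target = float(np.clip(cov_target + eff.delta_coverage_fraction, 0.02, 0.98))

    lesion = case.lesion_box if case.lesion_present else None
    dwell_target = ttff_target = None
    if lesion is not None:
        dwell_target = _lognorm(rng, profile.median_dwell_s * f["dwell"], disp.sigma_dwell)
        dwell_target = max(dwell_target + eff.delta_dwell_s, 1.0 / rate)
        r_tt = disp.rho_time_ttff
        z_ttff = r_tt * z_time + np.sqrt(max(1.0 - r_tt * r_tt, 0.0)) * rng.standard_normal()
        ttff_target = profile.median_ttff_s * f["ttff"] * float(
            np.exp(disp.sigma_ttff * z_ttff)
        )
        ttff_target = max(ttff_target + eff.delta_ttff_s, 0.05)
        if dwell_target > 0.8 * duration:
            dwell_target = 0.8 * duration
            flags.append("dwell_rescaled")
        if ttff_target > duration - dwell_target - 0.2:
            ttff_target = max(0.05, duration - dwell_target - 0.2)
            flags.append("ttff_rescaled")

    # ---- dropout ----------------------------------------------------------
    if profile.dropout_rate > 0:
        kappa = profile.dropout_concentration
        d_read = float(rng.beta(profile.dropout_rate * kappa, (1 - profile.dropout_rate) * kappa))
    else:
        d_read = 0.0
    valid = rng.random(n) >= d_read
    valid_idx = np.flatnonzero(valid)

    # ---- lesion-visit scheduling (on valid samples) -----------------------
    visit_window = np.zeros(n, dtype=bool)
    achieved_dwell = achieved_ttff = None
    if lesion is not None and valid_idx.size >= 6:
        c_w = max(1, int(round(dwell_target * rate)))
        cap = max(1, int(0.8 * valid_idx.size))
        if c_w > cap:
            c_w = cap
            flags.append("dwell_rescaled_dropout")
        start_pos = int(np.searchsorted(valid_idx / rate, ttff_target))
        start_pos = min(max(start_pos, 1), valid_idx.size - c_w)
        visit_valid = valid_idx[start_pos:start_pos + c_w]
        visit_window[visit_valid[0]:visit_valid[-1] + 1] = True
        achieved_dwell = c_w / rate
        achieved_ttff = visit_valid[0] / rate
    elif lesion is not None:
        flags.append("no_visit")

    aoi_region = None
    if lesion is not None:
        aoi_region = lesion.expand(aoi_margin).clip(w_img, h_img)
        if aoi_region.width * aoi_region.height >= 0.9 * w_img * h_img:
            flags.append("aoi_unavoidable")
            aoi_region = None

    # ---- route construction and coverage targeting ------------------------
    if tiles is None:
        tiles = lung_tiles(mask, cell=cell)
    n_tiles = len(tiles)
    if n_tiles == 0:
        raise PlacementError("mask has no lung tiles")
    # route tiles stay clear of the lesion AOI so free samples (with their
    # zigzag offsets, bounded by h_max below) can never create unscheduled
    # dwell; the scheduled visit itself covers the AOI tiles
    h_max = 45.0
    if aoi_region is not None:
        guard = aoi_region.expand(h_max)
        half = cell / 2.0
        cx = tiles[:, 0] * cell + half
        cy = tiles[:, 1] * cell + half
        keep = ~(
            (cx + half >= guard.x_min) & (cx - half <= guard.x_max)
            & (cy + half >= guard.y_min) & (cy - half <= guard.y_max)
        )
        cand = tiles[keep]
    else:
        cand = tiles
    if len(cand) == 0:
        cand = tiles
        flags.append("aoi_guard_dropped")

    tiebreak = rng.random(len(cand)) * 0.5
    if lesion is not None:
        # grow the scanned region outward from the lesion neighbourhood so
        # the route passes near the scheduled visit and the jump is short
        half = cell / 2.0
        d_lesion = np.hypot(
            cand[:, 0] * cell + half - lesion.center[0],
            cand[:, 1] * cell + half - lesion.center[1],
        )
        start_idx = int(np.argmin(d_lesion + tiebreak * cell))
    else:
        start_idx = int(rng.integers(len(cand)))
    grow_order = _grow_tile_order(cand, start_idx, tiebreak)

    ys_m, xs_m = np.nonzero(mask)
    centroid = np.array([xs_m.mean(), ys_m.mean()]) if xs_m.size else np.array(
        [w_img / 2.0, h_img / 2.0]
    )
    free_idx = np.flatnonzero(~visit_window)
    route_noise = rng.standard_normal((n, 2)) * 0.5
    zig_sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)

    lesion_center = np.array(lesion.center) if lesion is not None else None
    lesion_jitter = None
    if lesion is not None:
        sd = min(lesion.width, lesion.height) / 8.0
        lesion_jitter = rng.standard_normal((n, 2)) * sd

    n_free_before = int((~visit_window[: visit_window.argmax()]).sum()) if visit_window.any() else 0

    def build(k: int, h: float) -> np.ndarray:
        sel = cand[grow_order[:k]]
        wps = _band_route(sel, cell, split_x=w_img / 2.0)
        if visit_window.any() and len(wps) >= 2 and lesion_center is not None:
            # traverse the serpentine in whichever direction puts the route
            # nearest the lesion at the moment the visit starts, keeping the
            # jump (and its path-length cost) small
            frac = n_free_before / max(free_idx.size, 1)
            best = None
            for cand_wps in (wps, wps[::-1]):
                at = _positions_along(cand_wps, 201, centroid)[
                    int(round(frac * 200))
                ]
                d = float(np.hypot(*(at - lesion_center)))
                if best is None or d < best[0]:
                    best = (d, cand_wps)
            wps = best[1]
        pos = np.empty((n, 2), dtype=float)
        pos[free_idx] = _positions_along(wps, free_idx.size, centroid)
        pos[free_idx] += route_noise[free_idx]
        if h > 0 and free_idx.size:
            # zigzag perpendicular to the local direction of travel
            p = pos[free_idx]
            d = np.gradient(p, axis=0) if len(p) > 1 else np.zeros_like(p)
            norm = np.hypot(d[:, 0], d[:, 1])
            norm[norm == 0] = 1.0
            perp = np.column_stack([-d[:, 1], d[:, 0]]) / norm[:, None]
            pos[free_idx] = p + perp * (zig_sign[free_idx] * h)[:, None]
        if visit_window.any():
            jitter = np.clip(
                lesion_jitter[visit_window],
                [lesion.x_min + 0.5 - lesion_center[0], lesion.y_min + 0.5 - lesion_center[1]],
                [lesion.x_max - 0.5 - lesion_center[0], lesion.y_max - 0.5 - lesion_center[1]],
            )
            pos[visit_window] = lesion_center + jitter
        if aoi_region is not None:
            pos = _push_out(pos, aoi_region, active=~visit_window)
        pos[:, 0] = np.clip(pos[:, 0], 0.0, w_img - 1.0)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, h_img - 1.0)
        return pos

    def measure_cov(pos: np.ndarray) -> float:
        pts = pos[valid]
        if len(pts) == 0:
            return 0.0
        return float(covered_lung_tiles(pts, tiles, cell, buffer).sum() / n_tiles)

    def fit_coverage(k: int, h: float) -> tuple[int, np.ndarray, float]:
        """Secant-style adjustment of the region size until the measured
        coverage (at zigzag amplitude ``h``) hits the target."""
        pos = build(k, h)
        cov = measure_cov(pos)
        k_prev = cov_prev = None
        for _ in range(max_coverage_iters):
            err_tiles = (cov_target - cov) * n_tiles
            if abs(err_tiles) <= 1.5:
                break
            gain = 1.0
            if k_prev is not None and k != k_prev and cov != cov_prev:
                slope = (cov - cov_prev) * n_tiles / (k - k_prev)
                if 0.2 < slope < 5.0:
                    gain = 1.0 / slope
            k_prev, cov_prev = k, cov
            step = int(round(np.clip(gain * err_tiles, -0.3 * n_tiles, 0.3 * n_tiles)))
            if step == 0:
                step = 1 if err_tiles > 0 else -1
            k_new = int(np.clip(k + step, 1, len(cand)))
            if k_new == k:
                break
            k = k_new
            pos = build(k, h)
            cov = measure_cov(pos)
        return k, pos, cov

    def fit_path(k: int) -> tuple[float, np.ndarray]:
        """Bisect the zigzag amplitude so the valid-sample polyline length
        matches the path target at region size ``k``."""
        pos0 = build(k, 0.0)
        if _valid_path_length(pos0, valid) >= path_target:
            return 0.0, pos0
        pos_hi = build(k, h_max)
        if _valid_path_length(pos_hi, valid) <= path_target:
            return h_max, pos_hi
        lo, hi = 0.0, h_max
        for _ in range(18):
            mid = 0.5 * (lo + hi)
            if _valid_path_length(build(k, mid), valid) < path_target:
                lo = mid
            else:
                hi = mid
        return hi, build(k, hi)

    # the two targets interact: the zigzag that lengthens the path also
    # widens the covered band, so alternate the two fits until stable
    k = int(np.clip(round(cov_target * n_tiles * 0.9), 1, len(cand)))
    h_cur = 0.0
    for _ in range(3):
        k, pos, cov = fit_coverage(k, h_cur)
        h_new, pos = fit_path(k)
        if abs(h_new - h_cur) < 2.0:
            h_cur = h_new
            break
        h_cur = h_new
    achieved_path = _valid_path_length(pos, valid)
    achieved_cov = measure_cov(pos)
    if abs(cov_target - achieved_cov) * n_tiles > 3.0:
        flags.append("coverage_unmet")
    if achieved_path > 1.10 * path_target:
        flags.append("path_overshoot")
    elif achieved_path < 0.90 * path_target:
        flags.append("path_shortfall")

    rec = GazeRecording(
        t=np.arange(n) / rate,
        x=pos[:, 0],
        y=pos[:, 1],
        valid=valid,
        sampling_rate=rate,
        duration=duration,
        image_width=w_img,
        image_height=h_img,
    )
    latent = LatentTargets(
        condition=condition,
        duration_s=duration,
        dwell_s=dwell_target,
        ttff_s=ttff_target,
        path_px=path_target,
        coverage=cov_target,
        achieved_dwell_s=achieved_dwell,
        achieved_ttff_s=achieved_ttff,
        achieved_path_px=achieved_path,
        achieved_coverage=achieved_cov,
        dropout=d_read,
        flags=tuple(flags),
    )
    return rec, latent


def simulate_metric_values(
    readers: list[ReaderProfile],
    effects: ConditionEffects,
    n_cases: int,
    rng: np.random.Generator,
    dispersion: MetricDispersion | None = None,
) -> pd.DataFrame:
    """Draw per-read metric values from the generator's statistical layer.

    This is the distributional model the scanpath construction is built to
    reproduce — log-normal spread around each reader's medians with a
    shared per-case factor (the case random intercept), an additive
    condition shift in session 1, and the correlation structure of
    ``MetricDispersion`` — without any gaze geometry.  Useful for
    calibration studies (power, type-I error) where thousands of replicate
    studies are needed.  Floors are applied as in the scanpath generator
    (times > 0, coverage clipped to [0.02, 0.98]); geometric feasibility
    caps are not.

    Returns a long table: reader, case_id, session, condition, and the
    five metric columns named as in the metrics table.
    """
    disp = dispersion or MetricDispersion()
    sig = {
        "time": disp.sigma_time, "dwell": disp.sigma_dwell, "ttff": disp.sigma_ttff,
        "path": disp.sigma_path, "coverage": disp.sigma_coverage,
    }

    def correlated(z: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        r = disp.rho_time_ttff
        z["ttff"] = r * z["time"] + np.sqrt(1 - r * r) * z["ttff"]
        r = disp.rho_path_coverage
        z["path"] = r * z["coverage"] + np.sqrt(1 - r * r) * z["path"]
        return z

    zc = correlated({m: rng.standard_normal(n_cases) for m in _FIVE})
    rows = []
    for profile in readers:
        med = {
            "time": profile.median_interpretation_time_s,
            "dwell": profile.median_dwell_s,
            "ttff": profile.median_ttff_s,
            "path": profile.median_path_px,
            "coverage": profile.median_coverage,
        }
        for session in (1, 2):
            zr = correlated({m: rng.standard_normal(n_cases) for m in _FIVE})
            eff = effects if session == 1 else ConditionEffects()
            delta = {
                "time": eff.delta_interpretation_time_s,
                "dwell": eff.delta_dwell_s,
                "ttff": eff.delta_ttff_s,
                "path": eff.delta_path_px,
                "coverage": eff.delta_coverage_fraction,
            }
            vals = {
                m: med[m] * np.exp(sig[m] * (zc[m] + zr[m])) + delta[m] for m in _FIVE
            }
            vals["time"] = np.maximum(vals["time"], 1.5)
            vals["dwell"] = np.maximum(vals["dwell"], 1.0 / 60.0)
            vals["ttff"] = np.maximum(vals["ttff"], 0.05)
            vals["path"] = np.maximum(vals["path"], 100.0)
            vals["coverage"] = np.clip(vals["coverage"], 0.02, 0.98)
            for i in range(n_cases):
                rows.append(
                    {
                        "reader": profile.reader_id,
                        "case_id": f"case{i:03d}",
                        "session": session,
                        "condition": "session1" if session == 1 else "session2",
                        "interpretation_time_s": vals["time"][i],
                        "dwell_s": vals["dwell"][i],
                        "ttff_s": vals["ttff"][i],
                        "path_px": vals["path"][i],
                        "coverage": vals["coverage"][i],
                        "coverage_pct": 100.0 * vals["coverage"][i],
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """Everything one simulated study produces, kept in memory.

    Masks are not stored (one full-resolution raster per case would
    dominate memory); they are regenerated on demand from each case's
    ``mask_seed``, which is cheap and exact.
    """

    config: GeneratorConfig
    cases: list[CaseSpec]
    reads: list[SimulatedRead]
    case_factors: dict[str, dict[str, float]]

    def mask_for(self, case: CaseSpec) -> np.ndarray:
        return make_lung_mask(case.image_width, case.image_height, case.mask_seed)

    @property
    def reads_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reader": r.reader,
                    "session": r.session,
                    "case_id": r.case_id,
                    "decision": r.decision,
                }
                for r in self.reads
            ]
        )

    @property
    def latent_table(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            la = r.latent
            rows.append(
                {
                    "reader": r.reader,
                    "session": r.session,
                    "case_id": r.case_id,
                    "condition": la.condition,
                    "duration_s": la.duration_s,
                    "dwell_s": la.dwell_s,
                    "ttff_s": la.ttff_s,
                    "path_px": la.path_px,
                    "coverage": la.coverage,
                    "achieved_dwell_s": la.achieved_dwell_s,
                    "achieved_ttff_s": la.achieved_ttff_s,
                    "achieved_path_px": la.achieved_path_px,
                    "achieved_coverage": la.achieved_coverage,
                    "dropout": la.dropout,
                    "flags": ";".join(la.flags),
                }
            )
        return pd.DataFrame(rows)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _sample_fp_box(
    case: CaseSpec,
    mask: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PixelBox:
    """A spurious prompt box, size-matched to the lesion distribution and —
    for FN_FP cases — disjoint from the lesion AOI."""
    forbidden = None
    if case.lesion_box is not None:
        forbidden = case.lesion_box.expand(config.aoi_margin).clip(
            case.image_width, case.image_height
        )
    for _ in range(300):
        box = sample_lesion_box(mask, config.lesion_size_range, rng)
        if forbidden is None or not box.intersects(forbidden):
            return box
    raise PlacementError("could not place a prompt box clear of the lesion AOI")


def simulate_study(config: GeneratorConfig) -> StudyBundle:
    """Run the full crossover design: every reader reads every case twice.

    Session 1 shows the CAD display, so reads of cases with a displayed box
    use the with-box condition; session 2 (after washout) is always
    without.  Decisions are drawn from each reader's operating point, with
    the session-1 positive-call probability pulled toward the display by
    the reader's ``prompt_adoption``.  Fully deterministic per seed.
    """
    root = np.random.SeedSequence(config.seed)
    alloc_ss, case_root = root.spawn(2)
    case_ids = [f"case{i:03d}" for i in range(config.design.n_total)]
    cases = allocate_cases(config.design, case_ids, _child_seed(alloc_ss))
    case_seeds = case_root.spawn(len(cases))

    reads: list[SimulatedRead] = []
    factors_by_case: dict[str, dict[str, float]] = {}
    for case, case_ss in zip(cases, case_seeds):
        case.image_width = config.image_width
        case.image_height = config.image_height
        mask_ss, box_ss, fct_ss, reads_ss = case_ss.spawn(4)
        case.mask_seed = _child_seed(mask_ss)
        mask = make_lung_mask(config.image_width, config.image_height, case.mask_seed)
        rng_box = np.random.default_rng(_child_seed(box_ss))
        if case.lesion_present:
            case.lesion_box = sample_lesion_box(mask, config.lesion_size_range, rng_box)
        if case.group is Group.TP:
            case.displayed_box = case.lesion_box
        elif case.group.has_displayed_box:
            case.displayed_box = _sample_fp_box(case, mask, config, rng_box)
        case.validate(check_boxes=True, aoi_margin=config.aoi_margin)

        rng_f = np.random.default_rng(_child_seed(fct_ss))
        disp = config.dispersion
        # case factors mirror the read-level correlation structure
        z = {m: rng_f.standard_normal() for m in _FIVE}
        r = disp.rho_time_ttff
        z["ttff"] = r * z["time"] + np.sqrt(1.0 - r * r) * z["ttff"]
        r = disp.rho_path_coverage
        z["path"] = r * z["coverage"] + np.sqrt(1.0 - r * r) * z["path"]
        sigmas = {
            "time": disp.sigma_time,
            "dwell": disp.sigma_dwell,
            "ttff": disp.sigma_ttff,
            "path": disp.sigma_path,
            "coverage": disp.sigma_coverage,
        }
        f = {m: float(np.exp(sigmas[m] * z[m])) for m in _FIVE}
        factors_by_case[case.case_id] = f

        tiles = lung_tiles(mask, cell=config.coverage_cell)
        read_seeds = reads_ss.spawn(2 * len(config.readers))
        for (profile, session), read_ss in zip(
            itertools.product(config.readers, (1, 2)), read_seeds
        ):
            condition = (
                WITH_BB if session == 1 and case.displayed_box is not None else WITHOUT_BB
            )
            rng_read = np.random.default_rng(_child_seed(read_ss))
            rec, latent = simulate_scanpath(
                case,
                condition,
                profile,
                config.effects,
                rng_read,
                mask=mask,
                dispersion=config.dispersion,
                case_factors=f,
                sampling_rate=config.sampling_rate,
                aoi_margin=config.aoi_margin,
                cell=config.coverage_cell,
                buffer=config.coverage_buffer,
                tiles=tiles,
            )
            p_pos = (
                profile.decision_sensitivity
                if case.lesion_present
                else 1.0 - profile.decision_specificity
            )
            if session == 1:
                prompt = 1.0 if case.displayed_box is not None else 0.0
                p_pos = (1.0 - profile.prompt_adoption) * p_pos + profile.prompt_adoption * prompt
            decision = "positive" if rng_read.random() < p_pos else "negative"
            reads.append(
                SimulatedRead(
                    reader=profile.reader_id,
                    session=session,
                    case_id=case.case_id,
                    condition=condition,
                    recording=rec,
                    latent=latent,
                    decision=decision,
                )
            )
    return StudyBundle(config=config, cases=cases, reads=reads, case_factors=factors_by_case)


def paper_defaults(seed: int = 0, **overrides) -> GeneratorConfig:
    """The calibrated study configuration.

    Reader baselines are the session-2 (no CAD) medians of the three
    radiologists' gaze metrics, their unaided decision operating points,
    and display-adoption weights reflecting the observed concordance
    ordering; condition effects are the study-level contrasts (+4.9 s
    interpretation time, +1.3 s lesion dwell, -1.3 s time to first
    fixation, +2076 px path length, +10.5 points lung coverage).  The
    design is the 96/12/12/48/12 allocation (80 % display sensitivity and
    specificity) on 2560 x 1440 images sampled at 60 Hz.
    """
    readers = [
        ReaderProfile(
            "R1", 10.2, 1.2, 1.9, 5706.0, 0.680,
            dropout_rate=0.12, dropout_concentration=2.0,
            decision_sensitivity=0.675, decision_specificity=0.950,
            prompt_adoption=0.60,
        ),
        ReaderProfile(
            "R2", 4.4, 0.4, 2.7, 2308.0, 0.468,
            dropout_rate=0.10, dropout_concentration=2.0,
            decision_sensitivity=0.792, decision_specificity=0.633,
            prompt_adoption=0.90,
        ),
        ReaderProfile(
            "R3", 8.6, 1.3, 1.4, 4782.0, 0.624,
            dropout_rate=0.04, dropout_concentration=4.0,
            decision_sensitivity=0.600, decision_specificity=0.967,
            prompt_adoption=0.65,
        ),
    ]
    effects = ConditionEffects(
        delta_interpretation_time_s=4.9,
        delta_dwell_s=1.3,
        delta_ttff_s=-1.3,
        delta_path_px=2076.0,
        delta_coverage_pp=10.5,
    )
    cfg = GeneratorConfig(readers=readers, effects=effects, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
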