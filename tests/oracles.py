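"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — per-sample python loops and
first-principles geometry — and shares no code with the package's metric
implementations.
"""

import math

import numpy as np


def dwell_oracle(rec, region) -> float:
    """Per-sample membership loop: valid samples inside the (inclusive)
    region contribute one sampling interval each."""
    count = 0
    for t, x, y, v in zip(rec.t, rec.x, rec.y, rec.valid):
        if v and region.x_min <= x <= region.x_max and region.y_min <= y <= region.y_max:
            count += 1
    return count / rec.sampling_rate


def path_oracle(rec) -> float:
    """Pairwise-distance summation over valid samples."""
    pts = [(x, y) for x, y, v in zip(rec.x, rec.y, rec.valid) if v]
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total


def _point_seg_dist(px, py, ax, ay, bx, by) -> float:
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    vv = vx * vx + vy * vy
    t = 0.0 if vv == 0 else max(0.0, min(1.0, (wx * vx + wy * vy) / vv))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _segs_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
        )

    for d, (a, b, c) in (
        (d1, (p3, p4, p1)), (d2, (p3, p4, p2)),
        (d3, (p1, p2, p3)), (d4, (p1, p2, p4)),
    ):
        if d == 0 and on_seg(a, b, c):
            return True
    return False


def _seg_seg_dist(p1, p2, p3, p4) -> float:
    if _segs_intersect(p1, p2, p3, p4):
        return 0.0
    return min(
        _point_seg_dist(*p1, *p3, *p4),
        _point_seg_dist(*p2, *p3, *p4),
        _point_seg_dist(*p3, *p1, *p2),
        _point_seg_dist(*p4, *p1, *p2),
    )


def _box_seg_dist(x0, y0, x1, y1, a, b) -> float:
    """Distance from the closed box [x0,x1]x[y0,y1] to segment a-b."""
    if (x0 <= a[0] <= x1 and y0 <= a[1] <= y1) or (x0 <= b[0] <= x1 and y0 <= b[1] <= y1):
        return 0.0
    corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    edges = list(zip(corners, corners[1:] + corners[:1]))
    return min(_seg_seg_dist(a, b, e0, e1) for e0, e1 in edges)


def _box_point_dist(x0, y0, x1, y1, p) -> float:
    dx = max(x0 - p[0], 0.0, p[0] - x1)
    dy = max(y0 - p[1], 0.0, p[1] - y1)
    return math.hypot(dx, dy)


def covered_tiles_geometric(points, tiles, cell, buffer) -> list[bool]:
    """Exact first-principles check: a tile square is covered iff its
    closed box is within ``buffer`` of some segment of the polyline (or of
    the single point when only one sample exists)."""
    pts = [tuple(p) for p in np.atleast_2d(points)]
    out = []
    for col, row in tiles:
        x0, y0 = col * cell, row * cell
        x1, y1 = x0 + cell, y0 + cell
        if len(pts) == 1:
            d = _box_point_dist(x0, y0, x1, y1, pts[0])
        else:
            d = min(
                _box_seg_dist(x0, y0, x1, y1, a, b)
                for a, b in zip(pts[:-1], pts[1:])
            )
        out.append(d <= buffer)
    return out


def covered_tiles_pixel(points, tiles, cell, buffer, width, height):
    """Pixel-rasterisation oracle: mark every integer pixel within
    ``buffer`` of the polyline, then call a tile covered iff any marked
    pixel falls inside it.  Sampling the plane on the integer grid can
    miss sub-pixel grazing contacts, so alongside the verdicts it returns
    each tile's exact clearance margin ``|distance - buffer|`` so callers
    can ignore knife-edge tiles."""
    pts = [tuple(p) for p in np.atleast_2d(points)]
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    dist = np.full((height, width), np.inf)
    if len(pts) == 1:
        dist = np.hypot(xs - pts[0][0], ys - pts[0][1])
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            vx, vy = b[0] - a[0], b[1] - a[1]
            vv = vx * vx + vy * vy
            if vv == 0:
                d = np.hypot(xs - a[0], ys - a[1])
            else:
                t = np.clip(((xs - a[0]) * vx + (ys - a[1]) * vy) / vv, 0.0, 1.0)
                d = np.hypot(xs - (a[0] + t * vx), ys - (a[1] + t * vy))
            dist = np.minimum(dist, d)
    hit = dist <= buffer
    verdicts, margins = [], []
    for col, row in tiles:
        x0, y0 = col * cell, row * cell
        block = hit[y0:min(y0 + cell + 1, height), x0:min(x0 + cell + 1, width)]
        verdicts.append(bool(block.any()))
        dblock = dist[y0:min(y0 + cell + 1, height), x0:min(x0 + cell + 1, width)]
        margins.append(abs(float(dblock.min()) - buffer))
    return verdicts, margins
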