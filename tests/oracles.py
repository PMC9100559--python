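"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (shoelace,
L'Huilier spherical excess, ray casting, brute-force enumeration) and
shares no code path with treerisk itself.
"""

import numpy as np

R_KM = 6371.0088


def shoelace_area(xs, ys) -> float:
    """Planar polygon area by the shoelace formula (vertices in order)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    return 0.5 * abs(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))


def spherical_polygon_area_km2(lons, lats) -> float:
    """Geodesic polygon area on the sphere by fan triangulation, with each
    triangle's signed spherical excess computed as a solid angle (the
    Van Oosterom & Strackee formula), which is numerically robust for the
    thin triangles a fan produces.

    Vertices must be in ring order.
    """
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    v = np.column_stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])
    a = v[0]
    total = 0.0
    for i in range(1, len(v) - 1):
        b, c = v[i], v[i + 1]
        num = np.dot(a, np.cross(b, c))
        den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
        total += 2.0 * np.arctan2(num, den)
    return abs(total) * R_KM**2


def ray_casting_contains(polygon_xy, px, py) -> bool:
    """Even-odd point-in-polygon test. polygon_xy: list of (x, y) vertices."""
    inside = False
    n = len(polygon_xy)
    for i in range(n):
        x1, y1 = polygon_xy[i]
        x2, y2 = polygon_xy[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_force_aoo_km2(lons, lats, cell_km=2.0) -> float:
    """AOO by direct cell enumeration in an independently coded cylindrical
    equal-area projection with the same convention (standard parallel at
    the mean latitude, origin at the mean longitude)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lat_ts = lats.mean()
    lon0 = np.degrees(np.arctan2(np.mean(np.sin(np.radians(lons))), np.mean(np.cos(np.radians(lons)))))
    cells = set()
    for lon, lat in zip(lons, lats):
        dlon = (lon - lon0 + 180.0) % 360.0 - 180.0
        x = R_KM * np.radians(dlon) * np.cos(np.radians(lat_ts))
        y = R_KM * np.sin(np.radians(lat)) / np.cos(np.radians(lat_ts))
        # same convention as the package: a cell is centered on the origin
        cells.add((int(np.floor((x + cell_km / 2) / cell_km)), int(np.floor((y + cell_km / 2) / cell_km))))
    return len(cells) * cell_km**2


def grid_lookup(grid_header, values, lon, lat):
    """Nearest-cell raster lookup from scratch given a header dict with
    keys xll, yll, cellsize and the (nrows, ncols) value array."""
    nrows, ncols = values.shape
    col = int(np.floor((lon - grid_header["xll"]) / grid_header["cellsize"]))
    row = nrows - 1 - int(np.floor((lat - grid_header["yll"]) / grid_header["cellsize"]))
    if not (0 <= row < nrows and 0 <= col < ncols):
        return np.nan
    return values[row, col]


def brute_force_threshold(confidence, correct, target):
    """Exhaustive search over every candidate confidence threshold: the
    smallest one whose retained subset reaches the target accuracy."""
    confidence = np.asarray(confidence, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    best = None
    for t in sorted(set(confidence.tolist())):
        retained = confidence >= t
        if correct[retained].mean() >= target:
            best = (t, float(correct[retained].mean()), int((~retained).sum()))
            break
    return best  # None when unattainable
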