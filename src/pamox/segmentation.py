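"""Single-vessel segmentation: padded ROI -> Otsu threshold -> spurious
fragment removal -> centerline and diameter.

The threshold maximizes the between-class variance over a 256-bin histogram
of min-max-normalized values (ties broken to the lowest bin edge).  This is
re-implemented here rather than delegated to an imaging library because the
binning and tie-break semantics are part of the algorithm contract; a brute
force maximizer serves as the oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .types import AmplitudeMap, VesselMask

N_BINS = 256


def otsu_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold of a sample of values.

    Returns a threshold in the original units such that foreground is
    ``values > threshold``.  Constant input raises
    ``ValueError("degenerate histogram")``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("need at least two finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("degenerate histogram")
    norm = (v - lo) / (hi - lo)
    hist, _ = np.histogram(norm, bins=N_BINS, range=(0.0, 1.0))
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)                       # class-0 weight up to bin k
    mu = np.cumsum(p * np.arange(N_BINS))      # class-0 first moment
    mu_t = mu[-1]
    # between-class variance for a cut after bin k (k = 0 .. N_BINS-2)
    omega0 = omega[:-1]
    mu0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega0 - mu0) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))                # argmax returns lowest tie
    edge = (k + 1) / N_BINS                    # upper edge of bin k
    return lo + edge * (hi - lo)


def segment_vessel(amap: AmplitudeMap, roi: tuple[int, int, int, int],
                   min_fragment_px: int = 10) -> VesselMask:
    """Otsu-threshold an ROI and remove isolated or spurious fragments.

    Foreground pixels are those above the Otsu threshold within the ROI;
    8-connected components smaller than ``min_fragment_px`` are removed,
    except that the largest component is always retained.
    """
    r0, r1, c0, c1 = roi
    ny, nx = amap.values.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError("ROI must lie inside the map")
    sub = amap.values[r0:r1, c0:c1]
    thr = otsu_threshold(sub)                  # raises on constant ROI
    fg = sub > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels = cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes >= min_fragment_px
    keep[int(np.argmax(sizes))] = True         # largest always survives
    cleaned = keep[labels]
    full = np.zeros((ny, nx), dtype=bool)
    full[r0:r1, c0:c1] = cleaned
    return VesselMask(mask=full, roi=roi, source=amap)


def _skeleton_graph(coords: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pts = {tuple(p) for p in coords}
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pts}
    for r, c in pts:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pts:
                    adj[(r, c)].append(q)
    return adj


def _bfs_farthest(adj, start):
    """Return (farthest node, path from start to it) by BFS."""
    prev = {start: None}
    frontier = [start]
    last = start
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    nxt.append(v)
        if nxt:
            last = nxt[-1]
        frontier = nxt
    path = []
    node = last
    while node is not None:
        path.append(node)
        node = prev[node]
    path.reverse()
    return last, path


def centerline(mask: VesselMask) -> np.ndarray:
    """Morphological skeleton pruned to its longest path, ordered end-to-end.

    Returns an (N, 2) array of (row, col) indices.  Masks of fewer than
    three pixels are rejected.
    """
    if mask.n_pixels < 3:
        raise ValueError("mask too small for a centerline")
    skel = skeletonize(mask.mask)
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:
        # degenerate thin masks can skeletonize to nothing; fall back to pixels
        coords = mask.pixels
    if coords.shape[0] == 1:
        return coords
    adj = _skeleton_graph(coords)
    # double-BFS longest shortest path, restricted to the largest component
    start = tuple(coords[0])
    far, _ = _bfs_farthest(adj, start)
    _, path = _bfs_farthest(adj, far)
    return np.asarray(path, dtype=int)


def diameter(mask: VesselMask, path: np.ndarray,
             spacing_um: tuple[float, float]) -> float:
    """Mean perpendicular chord length of the mask along the centerline (um).

    At each interior path point (two points trimmed at each end) the local
    direction is taken from the neighbouring path points and the mask chord
    perpendicular to it is measured by sub-pixel ray marching in physical
    coordinates.
    """
    path = np.asarray(path)
    if path.shape[0] < 5:
        raise ValueError("centerline too short to measure a diameter")
    sx, sy = spacing_um
    ny, nx = mask.mask.shape
    step = 0.1 * min(sx, sy)
    max_um = max(nx * sx, ny * sy)

    def inside(x_um: float, y_um: float) -> bool:
        c = int(x_um / sx)
        r = int(y_um / sy)
        return 0 <= r < ny and 0 <= c < nx and mask.mask[r, c]

    chords = []
    for i in range(2, path.shape[0] - 2):
        r_prev, c_prev = path[i - 1]
        r_next, c_next = path[i + 1]
        # direction in physical units
        dx, dy = (c_next - c_prev) * sx, (r_next - r_prev) * sy
        norm = float(np.hypot(dx, dy))
        if norm == 0.0:
            continue
        px, py = -dy / norm, dx / norm          # perpendicular unit vector
        r, c = path[i]
        x0, y0 = (c + 0.5) * sx, (r + 0.5) * sy
        extent = 0.0
        for sgn in (+1.0, -1.0):
            s = 0.0
            while s < max_um and inside(x0 + sgn * (s + step) * px,
                                        y0 + sgn * (s + step) * py):
                s += step
            extent += s
        chords.append(extent + step)            # center sample itself
    if not chords:
        raise ValueError("no usable chords along centerline")
    return float(np.mean(chords))
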