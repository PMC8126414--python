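"""Synthetic inputs with exact ground truth for every pipeline stage.

Generators emulate the study conditions: honeycomb epithelial sheets for the
vertex model, elongated/collapsed lumen cross-section polygons, bead tracks
advected by an elliptical Poiseuille profile, and growing tubular binary-image
series with known centerline length and width.  Every generator is
deterministic under a fixed seed and returns machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TissueMesh
from .vertex_model import VertexModelParams, CellStates

__all__ = [
    "GroundTruth", "make_honeycomb", "make_lumen_polygon",
    "make_bead_tracks", "make_tube_image_series",
]


@dataclass
class GroundTruth:
    """Generator parameters and exact expected downstream quantities."""

    params: dict
    values: dict

    def to_dict(self) -> dict:
        return {"params": self.params, "values": self.values}


# ---------------------------------------------------------------------------
# honeycomb tissue
# ---------------------------------------------------------------------------

def make_honeycomb(n_cells: int = 100, aspect_ratio: float | None = 1.0,
                   seed: int = 0,
                   params: VertexModelParams | None = None
                   ) -> tuple[TissueMesh, CellStates]:
    """Regular hexagonal tessellation of ``n_cells`` unit-area cells.

    Cells are arranged in rows of pointy-top hexagons; the lattice is then
    scaled anisotropically (area preserving) so the bounding box matches the
    requested aspect ratio (height/width).  ``aspect_ratio=None`` keeps the
    regular (unstrained) lattice at whatever aspect the row/column counts
    give.  The top-most and bottom-most rows are flagged differentiated
    (never divide); cycle durations and division thresholds are sampled from
    the configured Gaussians.
    """
    if n_cells < 9:
        raise ValueError("need at least 9 cells (3x3)")
    if params is None:
        params = VertexModelParams(seed=seed)
    row_widths, cost = _best_row_layout(
        n_cells, 1.0 if aspect_ratio is None else aspect_ratio)
    area = params.target_area
    s = np.sqrt(area / (1.5 * np.sqrt(3.0)))  # hexagon side

    # pointy-top hexagon: vertices at angles 90 + 60k degrees
    dx = np.sqrt(3.0) * s
    dy = 1.5 * s
    ang = np.deg2rad(90 + 60 * np.arange(6))
    hexagon = s * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    verts: list[np.ndarray] = []
    vmap: dict[tuple[int, int], int] = {}
    cells = []
    boundary_row = []

    def vid(p):
        key = (round(p[0] / (s * 1e-6)), round(p[1] / (s * 1e-6)))
        if key not in vmap:
            vmap[key] = len(verts)
            verts.append(p)
        return vmap[key]

    rows = len(row_widths)
    for r, ncol in enumerate(row_widths):
        x_off = 0.5 * dx if r % 2 else 0.0
        # wider rows are shifted by whole lattice cells (the stagger pattern
        # only admits offsets of 0 or dx/2 modulo dx), roughly centring them
        x_off -= dx * ((ncol - min(row_widths) + 1) // 2)
        for c in range(ncol):
            center = np.array([c * dx + x_off, r * dy])
            loop = [vid(center + h) for h in hexagon]  # CCW (increasing angle)
            cells.append(np.array(loop, dtype=np.intp))
            boundary_row.append(1 if r == rows - 1 else (-1 if r == 0 else 0))

    vertices = np.array(verts)
    mesh = TissueMesh(vertices, cells)

    if aspect_ratio is not None and cost > np.log(1.1):
        # the regular lattice cannot reach the requested aspect: rescale
        # anisotropically (area preserving).  When the layout is already
        # within 10% of the target, the unstrained regular lattice is kept —
        # residual lattice strain would bias the first division orientations.
        w = np.ptp(vertices[:, 0])
        h = np.ptp(vertices[:, 1])
        k = np.sqrt(aspect_ratio * w / h)
        mesh.vertices[:, 1] *= k
        mesh.vertices[:, 0] /= k
        mesh.invalidate()

    rng = np.random.default_rng(seed)
    boundary_row = np.array(boundary_row, dtype=np.intp)
    states = CellStates.fresh(n_cells, params, rng,
                              proliferative=(boundary_row == 0),
                              boundary_row=boundary_row)
    return mesh, states


def _best_row_layout(n: int, aspect: float) -> tuple[list[int], float]:
    """Row widths of a hexagon lattice of exactly ``n`` cells near ``aspect``.

    Rows may differ by one cell (the remainder rows are one wider), so any
    count is reachable with regular, unstrained hexagons; the row number
    minimising the bounding-box aspect mismatch is chosen.
    """
    best = None
    for r in range(3, n // 3 + 1):
        base, extra = divmod(n, r)
        if base < 2:
            continue
        widest = base + (1 if extra else 0)
        h = 1.5 * (r - 1) + 2.0
        w = np.sqrt(3.0) * (widest + 0.5)
        cost = abs(np.log((h / w) / aspect))
        if best is None or cost < best[0]:
            best = (cost, r, base, extra)
    if best is None or best[0] > np.log(2.0):
        raise ValueError(
            f"cannot arrange {n} cells in a honeycomb of aspect {aspect}")
    cost, r, base, extra = best
    widths = [base] * r
    if extra:
        # widen interior rows, spread evenly, keeping the outer rows narrow
        positions = np.linspace(1, r - 2, extra).round().astype(int)
        for p in np.unique(positions):
            widths[int(p)] += 1
        # handle collisions from rounding
        missing = n - sum(widths)
        i = 1
        while missing > 0 and i < r - 1:
            if widths[i] == base:
                widths[i] += 1
                missing -= 1
            i += 1
    return widths, cost


# ---------------------------------------------------------------------------
# lumen cross-section polygons
# ---------------------------------------------------------------------------

def make_lumen_polygon(kind: str = "ellipse", a: float = 20.0, b: float = 1.0,
                       n_vertices: int = 512,
                       waist_fraction: float = 0.3) -> np.ndarray:
    """Simple CCW polygon emulating a lumen cross-section (coordinates in um).

    ``ellipse`` gives an elongated elliptical lumen (the open configuration);
    ``dumbbell`` emulates a partially collapsed lumen with a central waist
    whose half-width is ``sqrt(waist_fraction)*b`` and two side lobes.
    """
    if not (a >= b > 0):
        raise ValueError("require a >= b > 0")
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    if kind == "ellipse":
        poly = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    elif kind == "dumbbell":
        if not (0 < waist_fraction <= 1):
            raise ValueError("waist_fraction must be in (0, 1]")
        w = waist_fraction
        u = np.sin(t) ** 2
        # half-width profile h(u) = sqrt(u * (1 - (1-w) u)); for w < 1/2 the
        # maximum sits at u* = 1/(2(1-w)) < 1, giving two lobes with a waist
        # of relative half-width sqrt(w) at the centre (u = 1)
        if w < 0.5:
            u_star = 1.0 / (2.0 * (1.0 - w))
            peak = np.sqrt(u_star * (1.0 - (1.0 - w) * u_star))
        else:
            peak = np.sqrt(w)
        y = np.sign(np.sin(t)) * (b / peak) * np.sqrt(u * (1.0 - (1.0 - w) * u))
        poly = np.stack([a * np.cos(t), y], axis=1)
    else:
        raise ValueError(f"unknown lumen kind {kind!r}")
    from shapely.geometry import Polygon
    if not Polygon(poly).is_valid:
        raise ValueError("generated polygon is self-intersecting")
    return poly


# ---------------------------------------------------------------------------
# bead tracks
# ---------------------------------------------------------------------------

def make_bead_tracks(a: float = 50.0, b: float = 10.0, u_max: float = 0.73,
                     n_beads: int = 100, dt: float = 60.0,
                     duration: float = 600.0, noise_sd: float = 0.0,
                     seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Bead tracks advected by elliptical Poiseuille flow (image-plane 2D).

    Beads are placed uniformly in the elliptical cross-section (semi-axes
    ``a``, ``b`` um) and move axially with speed u_max*(1 - p^2/a^2 - q^2/b^2).
    The emitted table has columns (track_id, t_s, x_um, y_um) with y the axial
    coordinate and x the transverse position along the major axis, matching
    the 2D projection available when imaging beads in a lumen.  Defaults
    emulate the measured lower bound on the maximal flow speed of 0.73 um/s.
    """
    if u_max <= 0:
        raise ValueError("u_max must be positive")
    rng = np.random.default_rng(seed)
    # rejection-sample positions in the ellipse
    p = np.empty(n_beads)
    q = np.empty(n_beads)
    got = 0
    while got < n_beads:
        cand = rng.uniform(-1, 1, size=(2 * n_beads, 2))
        ok = cand[:, 0] ** 2 + cand[:, 1] ** 2 < 1.0
        take = min(n_beads - got, ok.sum())
        sel = cand[ok][:take]
        p[got:got + take] = a * sel[:, 0]
        q[got:got + take] = b * sel[:, 1]
        got += take
    speeds = u_max * (1.0 - (p / a) ** 2 - (q / b) ** 2)
    times = np.arange(0.0, duration + dt / 2, dt)
    rows = []
    for i in range(n_beads):
        y = speeds[i] * times
        x = np.full_like(times, p[i])
        if noise_sd > 0:
            x = x + rng.normal(0, noise_sd, len(times))
            y = y + rng.normal(0, noise_sd, len(times))
        for t_s, xx, yy in zip(times, x, y):
            rows.append((i, t_s, xx, yy))
    df = pd.DataFrame(rows, columns=["track_id", "t_s", "x_um", "y_um"])
    gt = GroundTruth(
        params=dict(a=a, b=b, u_max=u_max, n_beads=n_beads, dt=dt,
                    duration=duration, noise_sd=noise_sd, seed=seed),
        values=dict(u_max=u_max, u_mean=u_max / 2.0,
                    bead_speeds=speeds.tolist()),
    )
    return df, gt


# ---------------------------------------------------------------------------
# growing tube image series
# ---------------------------------------------------------------------------

def make_tube_image_series(length0: float = 60.0, width0: float = 14.0,
                           length_growth: float = 2.0, width_growth: float = 0.8,
                           n_frames: int = 5, branching: int | None = None,
                           pixel_size: float = 1.0, noise: float = 0.0,
                           seed: int = 0, canvas: tuple[int, int] | None = None,
                           curvature: float = 0.08,
                           ) -> tuple[np.ndarray, GroundTruth]:
    """Binary image series of a growing tube with exact ground truth.

    Lengths/widths are in um and interpolate geometrically from
    (length0, width0) to (length0*length_growth, width0*width_growth) over
    ``n_frames`` frames.  The tube is a gently curved polyline rendered with
    round caps: a pixel is foreground iff its centre is within width/2 of the
    centerline, so mask widths are unbiased to < 0.5 px.  With ``branching``
    set, a side branch appears at that frame index.  Returns a (T, H, W)
    uint8 stack and the per-frame true centerline lengths and widths.
    """
    if width0 * width_growth / pixel_size < 4:
        raise ValueError("final width below 4 px; increase width or resolution")
    rng = np.random.default_rng(seed)
    lengths = length0 * length_growth ** (np.arange(n_frames) / max(n_frames - 1, 1))
    widths = width0 * width_growth ** (np.arange(n_frames) / max(n_frames - 1, 1))

    lmax = lengths[-1]
    margin = widths.max() + 4 * pixel_size
    if canvas is None:
        # curved centerline stays within a band of height ~ curvature * lmax;
        # a side branch (if any) extends up to ~0.45 lmax above the midline
        head = 0.9 if branching is not None else 0.3
        hpx = int(np.ceil((2 * curvature * lmax + 2 * margin + lmax * head)
                          / pixel_size))
        wpx = int(np.ceil((lmax + 2 * margin) / pixel_size))
        canvas = (max(hpx, 64), max(wpx, 64))
    H, W = canvas

    def centerline(L, n=400):
        # arc-length parameterised gentle sine curve starting at the left
        x0 = margin
        y0 = H * pixel_size / 2.0
        tt = np.linspace(0, L, n)
        amp = curvature * lmax
        pts = np.stack([x0 + tt, y0 + amp * np.sin(np.pi * tt / lmax)], axis=1)
        # reparameterise to exact arc length L
        seg = np.diff(pts, axis=0)
        cum = np.concatenate([[0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        want = np.linspace(0, L, n) * (cum[-1] / cum[-1])
        # scale the parameter so that total arc length equals L
        scale = L / cum[-1]
        pts[:, 0] = x0 + (pts[:, 0] - x0) * scale
        pts[:, 1] = y0 + (pts[:, 1] - y0) * scale
        return pts

    yy, xx = np.mgrid[0:H, 0:W]
    px = (xx + 0.0) * pixel_size
    py = (yy + 0.0) * pixel_size

    frames = np.zeros((n_frames, H, W), dtype=np.uint8)
    true_branch_lengths = []
    for k in range(n_frames):
        pts = centerline(lengths[k])
        dist = _dist_to_polyline(px, py, pts)
        mask = dist <= widths[k] / 2.0
        blens = {"main": float(_polyline_length(pts))}
        if branching is not None and k >= branching:
            # side branch from the midpoint of the tube, growing like the main
            frac = (k - branching + 1) / max(n_frames - branching, 1)
            bl = 0.5 * lengths[k] * frac
            base = pts[len(pts) // 2]
            direction = np.array([0.6, -1.0])
            direction /= np.hypot(*direction)
            bpts = base[None, :] + np.linspace(0, bl, 200)[:, None] * direction
            bdist = _dist_to_polyline(px, py, bpts)
            mask |= bdist <= widths[k] / 2.0
            blens["side"] = float(bl)
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError("tube leaves the canvas; enlarge the canvas")
        if noise > 0:
            flip = rng.random(mask.shape) < noise
            mask = np.logical_xor(mask, flip & ~_near_boundary(mask))
        frames[k] = mask.astype(np.uint8)
        true_branch_lengths.append(blens)

    gt = GroundTruth(
        params=dict(length0=length0, width0=width0,
                    length_growth=length_growth, width_growth=width_growth,
                    n_frames=n_frames, branching=branching,
                    pixel_size=pixel_size, noise=noise, seed=seed),
        values=dict(lengths_um=lengths.tolist(), widths_um=widths.tolist(),
                    branch_lengths=true_branch_lengths,
                    relative_length=float(lengths[-1] / lengths[0]),
                    relative_width=float(widths[-1] / widths[0])),
    )
    return frames, gt


def _polyline_length(pts: np.ndarray) -> float:
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _dist_to_polyline(px, py, pts):
    from scipy.spatial import cKDTree
    # densify so that nearest-sample distance approximates true distance
    seg = np.diff(pts, axis=0)
    ell = np.hypot(seg[:, 0], seg[:, 1])
    n_sub = np.maximum(1, np.ceil(ell / 0.2).astype(int))
    dense = [pts[:1]]
    for i, m in enumerate(n_sub):
        tt = np.linspace(0, 1, m + 1)[1:, None]
        dense.append(pts[i] + tt * seg[i])
    dense = np.vstack(dense)
    tree = cKDTree(dense)
    d, _ = tree.query(np.stack([px.ravel(), py.ravel()], axis=1), workers=-1)
    return d.reshape(px.shape)


def _near_boundary(mask):
    from scipy.ndimage import binary_dilation, binary_erosion
    return binary_dilation(mask, iterations=2) & ~binary_erosion(mask, iterations=2)
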