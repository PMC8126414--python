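"""Wall shear stress of fully developed laminar flow in tube lumens.

For an elliptical lumen the Hagen-Poiseuille solution is closed form: the
axial velocity is u(y, z) = u_max (1 - y^2/a^2 - z^2/b^2) with u_max = 2 ubar
and flow rate Q = pi a b ubar, giving a wall shear stress profile

    tau(theta) = 2 mu u_max sqrt(cos^2(theta)/a^2 + sin^2(theta)/b^2)

that is maximal on the flat minor-axis co-vertices and minimal at the
strongly curved major-axis vertices.  For arbitrary simple polygonal
cross-sections the fully developed axial-flow problem -lap(u) = G/mu with
no-slip walls is solved on a masked regular grid with Shortley-Weller
boundary correction; by linearity the solution is rescaled exactly to the
requested mean velocity or flow rate.  Defaults match the embryonic-lung
estimates: viscosity 0.016 Pa s and inlet mean velocity 0.364 um/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, sparse
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "EllipticalTube", "FlowSpec", "WallShearProfile", "FlowSolution",
    "ellipse_wall_shear", "solve_cross_section_flow", "rescale_section",
    "mean_velocity_from_tracks",
]


@dataclass
class EllipticalTube:
    semi_major: float   # a, um
    semi_minor: float   # b, um

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require a >= b > 0")


@dataclass
class FlowSpec:
    """Viscosity plus exactly one flow driver (mean velocity or flow rate)."""

    viscosity: float = 0.016             # Pa s
    mean_velocity: float | None = None   # um/s (defaults to 0.364 if no driver)
    flow_rate: float | None = None       # um^3/s

    def __post_init__(self):
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.mean_velocity is None and self.flow_rate is None:
            self.mean_velocity = 0.364   # measured inlet mean velocity
        if (self.mean_velocity is None) == (self.flow_rate is None):
            raise ValueError("provide exactly one of mean_velocity or flow_rate")
        driver = self.mean_velocity if self.flow_rate is None else self.flow_rate
        if driver <= 0:
            raise ValueError("flow driver must be positive")

    def mean_velocity_for(self, area: float) -> float:
        if self.mean_velocity is not None:
            return self.mean_velocity
        return self.flow_rate / area


@dataclass
class WallShearProfile:
    theta: np.ndarray
    tau: np.ndarray       # Pa
    tau_mean: float       # arc-length-weighted boundary average
    tau_max: float
    tau_min: float
    u_max: float          # um/s
    mean_velocity: float
    flow_rate: float


@dataclass
class FlowSolution:
    x: np.ndarray               # grid coordinates (um)
    y: np.ndarray
    u: np.ndarray               # axial velocity (um/s), 0 outside the lumen
    mask: np.ndarray            # interior mask
    boundary_xy: np.ndarray     # (m, 2) boundary sample points
    boundary_s: np.ndarray      # arc length of each sample
    tau_wall: np.ndarray        # (m,) Pa
    tau_mean: float
    tau_max: float
    tau_min: float
    mean_velocity: float
    flow_rate: float
    area: float


# ---------------------------------------------------------------------------
# closed form: elliptical lumen
# ---------------------------------------------------------------------------

def ellipse_wall_shear(tube: EllipticalTube, spec: FlowSpec,
                       n_theta: int = 720) -> WallShearProfile:
    """Closed-form wall shear profile for Hagen-Poiseuille flow in an ellipse.

    The arc-length-weighted boundary mean is computed with adaptive
    quadrature; ``n_theta`` only controls the sampling of the returned
    profile.
    """
    a, b = tube.semi_major, tube.semi_minor
    area = np.pi * a * b
    ubar = spec.mean_velocity_for(area)
    u_max = 2.0 * ubar
    mu = spec.viscosity

    def tau_of(theta):
        return 2.0 * mu * u_max * np.sqrt(np.cos(theta) ** 2 / a ** 2 +
                                          np.sin(theta) ** 2 / b ** 2)

    def ds_of(theta):
        return np.sqrt(a ** 2 * np.sin(theta) ** 2 + b ** 2 * np.cos(theta) ** 2)

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    tau = tau_of(theta)
    num, _ = integrate.quad(lambda t: tau_of(t) * ds_of(t), 0, np.pi / 2,
                            limit=200)
    den, _ = integrate.quad(ds_of, 0, np.pi / 2, limit=200)
    tau_mean = num / den
    return WallShearProfile(theta=theta, tau=tau, tau_mean=float(tau_mean),
                            tau_max=float(2 * mu * u_max / b),
                            tau_min=float(2 * mu * u_max / a),
                            u_max=u_max, mean_velocity=ubar,
                            flow_rate=area * ubar)


# ---------------------------------------------------------------------------
# numerical: arbitrary polygonal cross-section
# ---------------------------------------------------------------------------

def solve_cross_section_flow(section: np.ndarray, spec: FlowSpec,
                             resolution: int = 400) -> FlowSolution:
    """Fully developed axial flow through a simple polygonal cross-section.

    Solves -lap(u) = const on the polygon interior with u = 0 on the wall
    (finite differences on a regular grid, Shortley-Weller correction at the
    boundary), rescales u exactly to the requested mean velocity or flow
    rate, and evaluates the wall shear from the one-sided normal derivative
    of u (quadratic extrapolation through u = 0 at the wall).
    """
    poly = Polygon(np.asarray(section, float))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("section must be a simple polygon with positive area")
    minx, miny, maxx, maxy = poly.bounds
    major = max(maxx - minx, maxy - miny)
    h = major / resolution

    pad = 2 * h
    xs = np.arange(minx - pad, maxx + pad + h, h)
    ys = np.arange(miny - pad, maxy + pad + h, h)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    from shapely import contains_xy
    mask = contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)

    _check_opening(mask)

    ny, nx = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    ii, jj = np.nonzero(mask)
    idx[ii, jj] = np.arange(len(ii))
    n_unk = len(ii)

    boundary = poly.exterior
    rows, cols, vals, rhs = [], [], [], np.ones(n_unk)
    offsets = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    for k in range(n_unk):
        r, c = ii[k], jj[k]
        diag = 0.0
        hs = {}
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
                hs[(dr, dc)] = (h, idx[rr, cc])
            else:
                # irregular leg: distance from this node to the wall
                p0 = Point(gx[r, c], gy[r, c])
                p1 = Point(gx[r, c] + dc * 1.5 * h, gy[r, c] + dr * 1.5 * h)
                inter = boundary.intersection(LineString([p0, p1]))
                d = inter.distance(p0) if not inter.is_empty else h
                hs[(dr, dc)] = (max(d, 0.05 * h), -1)
        # Shortley-Weller for each axis
        for (dp, dm) in (((0, 1), (0, -1)), ((1, 0), (-1, 0))):
            hp, jp = hs[dp]
            hm, jm = hs[dm]
            f = 2.0 / (hp + hm)
            diag += f * (1.0 / hp + 1.0 / hm)
            for hh, jn in ((hp, jp), (hm, jm)):
                if jn >= 0:
                    rows.append(k)
                    cols.append(jn)
                    vals.append(-f / hh)
        rows.append(k)
        cols.append(k)
        vals.append(diag)
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))
    sol = spsolve(mat, rhs)

    u = np.zeros(mask.shape)
    u[ii, jj] = sol

    # exact linear rescale to the requested driver
    cell_area = h * h
    area = poly.area
    q_num = float(u.sum() * cell_area)
    ubar_target = spec.mean_velocity_for(area)
    q_target = ubar_target * area
    u *= q_target / q_num

    # wall shear from one-sided normal derivative at boundary samples
    per = boundary.length
    m = max(512, int(per / (h / 2)))
    svals = np.linspace(0, per, m, endpoint=False)
    pts = np.array([boundary.interpolate(s).coords[0] for s in svals])
    normals = _inward_normals(pts, poly)
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator((ys, xs), u, bounds_error=False,
                                     fill_value=0.0)
    d1 = 2.0 * h
    u1 = interp(np.stack([pts[:, 1] + d1 * normals[:, 1],
                          pts[:, 0] + d1 * normals[:, 0]], axis=1))
    u2 = interp(np.stack([pts[:, 1] + 2 * d1 * normals[:, 1],
                          pts[:, 0] + 2 * d1 * normals[:, 0]], axis=1))
    dudn = (4.0 * u1 - u2) / (2.0 * d1)
    tau = spec.viscosity * dudn

    tau_mean = float(np.mean(tau))   # samples are equally spaced in arc length
    return FlowSolution(x=xs, y=ys, u=u, mask=mask, boundary_xy=pts,
                        boundary_s=svals, tau_wall=tau,
                        tau_mean=tau_mean, tau_max=float(tau.max()),
                        tau_min=float(tau.min()),
                        mean_velocity=q_target / area, flow_rate=q_target,
                        area=area)


def _check_opening(mask: np.ndarray, min_cells: int = 20) -> None:
    """Require >= min_cells interior samples across the narrowest opening.

    The opening across a scanline is its longest interior run; the check
    takes the minimum over the central 80% of the occupied span along each
    axis so that the natural tapering at the tube ends (where the wall
    closes) is not mistaken for a narrow passage.
    """
    if not mask.any():
        raise ValueError("empty interior: refine the resolution")
    narrowest = np.inf
    for m in (mask, mask.T):
        occupied = np.nonzero(m.any(axis=1))[0]
        lo, hi = occupied[0], occupied[-1]
        margin = max(1, int(0.1 * (hi - lo + 1)))
        widths = []
        for line in m[lo + margin:hi - margin + 1]:
            d = np.diff(np.concatenate([[0], line.view(np.int8), [0]]))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            if len(starts):
                widths.append((ends - starts).max())
        if widths:
            narrowest = min(narrowest, min(widths))
    if narrowest < min_cells:
        raise ValueError(
            f"narrowest opening resolved by {int(narrowest)} cells "
            f"(< {min_cells}); increase the resolution")


def _inward_normals(pts: np.ndarray, poly: Polygon) -> np.ndarray:
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tang = nxt - prv
    tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    # orient into the polygon (CCW exterior ring -> left normal is inward)
    probe = pts + 1e-6 * max(poly.bounds[2] - poly.bounds[0], 1.0) * nrm
    from shapely import contains_xy
    inside = contains_xy(poly, probe[:, 0], probe[:, 1])
    nrm[~inside] *= -1.0
    return nrm


# ---------------------------------------------------------------------------
# geometry and tracks
# ---------------------------------------------------------------------------

def rescale_section(section: np.ndarray, factor: float,
                    axis: int = 1) -> np.ndarray:
    """Scale the polygon along one axis about its centroid (z-rescaling)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    section = np.asarray(section, float).copy()
    poly = Polygon(section)
    c = np.array(poly.centroid.coords[0])
    section[:, axis] = c[axis] + factor * (section[:, axis] - c[axis])
    if Polygon(section).area < 1e-12:
        raise ValueError("rescaled section is degenerate")
    return section


def mean_velocity_from_tracks(tracks: pd.DataFrame, smooth: bool = False
                              ) -> tuple[float, float]:
    """(u_max_observed, ubar_estimate) from bead-track tables.

    The per-track speed is the maximum consecutive-frame displacement over
    the time interval (the maximum-track-speed convention); the fastest track
    provides a lower bound on the true peak velocity u_max, and the mean
    velocity estimate follows from the parabolic profile, ubar = u_max / 2.
    With ``smooth`` a 3-point moving average is applied to positions first.
    """
    required = {"track_id", "t_s", "x_um", "y_um"}
    if not required.issubset(tracks.columns):
        raise ValueError(f"tracks table needs columns {sorted(required)}")
    best = 0.0
    n_valid = 0
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("t_s")
        if len(g) < 2:
            continue
        t = g["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing per track")
        xy = g[["x_um", "y_um"]].to_numpy(float)
        if smooth and len(g) >= 3:
            ker = np.array([1.0, 1.0, 1.0]) / 3.0
            xy = np.stack([np.convolve(xy[:, 0], ker, mode="valid"),
                           np.convolve(xy[:, 1], ker, mode="valid")], axis=1)
            t = t[1:-1]
        if len(xy) < 2:
            continue
        d = np.diff(xy, axis=0)
        speeds = np.hypot(d[:, 0], d[:, 1]) / np.diff(t)
        smax = float(speeds.max())
        if smax > 0:
            n_valid += 1
            best = max(best, smax)
    if n_valid == 0:
        raise ValueError("no valid (moving) tracks")
    return best, best / 2.0
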