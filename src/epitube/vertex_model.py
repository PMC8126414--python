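"""2D vertex model of a proliferating apical epithelial sheet.

Each cell k contributes an area-elasticity term lambda*(A_k - A0_k)^2 and a
perimeter (circumference) elasticity term beta*(C_k - C0_k)^2 to the tissue
potential energy; every edge contributes a line-tension term gamma*length,
with separate tension coefficients for cell-cell and tissue-boundary edges.
Vertices follow overdamped dynamics drag * dx/dt = -grad U + f_ext, with
external longitudinal forces of magnitude f applied to the vertices of the
differentiated top-most (+y) and bottom-most (-y) cell rows to emulate the
elongating pull of luminal shear stress on the tissue.

Cells grow by ramping their target area linearly from A0 to 2*A0 over a
sampled cell-cycle duration (the target circumference scales as the square
root of the target area).  A proliferative cell divides once its age exceeds
its sampled cycle duration *and* its area exceeds its sampled division
threshold; the division plane passes through the centroid along the shortest
principal axis of the polygon (Hertwig's rule).  Cycle durations and division
thresholds are Gaussian, which produces the broad apical-area distributions
seen in embryonic lung epithelium.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .mesh import TissueMesh, DegenerateCellError

__all__ = [
    "VertexModelParams", "CellStates", "DivisionRecord", "TissueStats",
    "EnergyBreakdown", "Snapshot", "SimulationResult",
    "potential_energy", "forces", "step", "divide_cell", "run_simulation",
    "compute_outgrowth_bias", "division_angle_histogram", "shape_statistics",
    "displacement_profile",
]


# Defaults: mechanical coefficients follow common vertex-model practice
# (area 100, perimeter 10, cell-cell tension 1, boundary tension 10, in a.u.
# with unit cell target area).  The Gaussian cycle/threshold parameters and
# the boundary-force scale are calibration products: they are chosen so the
# unforced tissue reproduces an apical area CV of 0.6 and ~30% hexagons, and
# so a boundary force of 1 a.u. yields the observed 2-fold elongation bias.
@dataclass
class VertexModelParams:
    lambda_area: float = 100.0
    beta_perimeter: float = 10.0
    gamma_cell_cell: float = 1.0
    gamma_boundary: float = 10.0
    drag: float = 10.0
    dt_max: float = 0.005
    t1_threshold_rel: float = 0.01     # fraction of the mean edge length
    t1_new_edge_factor: float = 1.5    # post-swap edge, in units of threshold
    t2_area_rel: float = 0.01          # triangle removal, fraction of mean area
    step_cap_rel: float = 0.5          # max displacement per step / t1 threshold
    boundary_force: float = 0.0        # magnitude f per boundary-row vertex (a.u.)
    force_scale: float = 4.0           # native force units per a.u. of f (calibrated)
    cycle_mean: float = 20.0
    cycle_sd: float = 10.0
    div_area_mean: float = 1.8
    div_area_sd: float = 1.1
    duration: float = 48.0
    seed: int = 0
    target_area: float = 1.0
    growth_factor: float = 2.0         # target area at nominal cycle end / A0
    growth_cap: float = 5.0            # saturation of the target-area ramp / A0
    aspect_threshold: float = 0.0      # >0: random axis below this aspect ratio
    relaxation_lead: float = 5.0       # quiescent lead-in before first divisions
    snapshot_interval: float = 4.0

    def t1_threshold(self, mean_edge: float) -> float:
        return self.t1_threshold_rel * mean_edge

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VertexModelParams":
        return cls(**d)


def _hexagon_perimeter(area: float) -> float:
    # regular hexagon: A = (3*sqrt(3)/2) s^2, C = 6 s
    s = np.sqrt(area / (1.5 * np.sqrt(3.0)))
    return 6.0 * s


@dataclass
class CellStates:
    """Structure-of-arrays per-cell state."""

    target_area: np.ndarray          # A0 (a.u.^2)
    target_perimeter: np.ndarray     # C0 (a.u.)
    age: np.ndarray                  # (a.u.)
    cycle_duration: np.ndarray       # sampled (a.u.)
    division_threshold: np.ndarray   # sampled area (a.u.^2)
    proliferative: np.ndarray        # bool
    boundary_row: np.ndarray         # +1 top row, -1 bottom row, 0 otherwise
    cell_id: np.ndarray              # persistent id
    root_id: np.ndarray              # id of the founding cell at t=0

    @classmethod
    def fresh(cls, n: int, params: VertexModelParams, rng: np.random.Generator,
              proliferative=None, boundary_row=None) -> "CellStates":
        cyc = _positive_normal(rng, params.cycle_mean, params.cycle_sd, n)
        thr = _positive_normal(rng, params.div_area_mean, params.div_area_sd, n)
        ids = np.arange(n, dtype=np.intp)
        # desynchronise the initial tissue, with a short quiescent lead-in
        # (no divisions during the first few time units) so the freshly
        # built lattice relaxes mechanically before mitoses are oriented
        # by cell shape
        head = np.maximum(cyc - params.relaxation_lead, 0.02 * cyc)
        return cls(
            target_area=np.full(n, params.target_area),
            target_perimeter=np.full(n, _hexagon_perimeter(params.target_area)),
            age=rng.uniform(0.0, head),
            cycle_duration=cyc,
            division_threshold=thr,
            proliferative=(np.ones(n, bool) if proliferative is None
                           else np.asarray(proliferative, bool).copy()),
            boundary_row=(np.zeros(n, np.intp) if boundary_row is None
                          else np.asarray(boundary_row, np.intp).copy()),
            cell_id=ids,
            root_id=ids.copy(),
        )

    @property
    def n(self) -> int:
        return len(self.target_area)

    def effective_targets(self, growth_factor: float,
                          growth_cap: float = np.inf,
                          overshoot: float = 1.1
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Target area/perimeter with the linear growth ramp applied.

        Each cell grows from its birth size towards its own sampled division
        area: the target ramps linearly (reaching ``growth_factor`` times the
        birth size at the nominal cycle end, continuing beyond it) and
        saturates at ``overshoot`` times the division area, so the realised
        area — which sits a few percent below the target in a crowded
        tissue — reliably crosses the division threshold.  ``growth_cap``
        bounds the ramp globally.  The target perimeter scales with the
        square root of the target area (shape-preserving growth).
        """
        ramp = 1.0 + (growth_factor - 1.0) * self.age / self.cycle_duration
        ramp = np.minimum(ramp, growth_cap)
        # proliferative cells grow to their sampled division area; the
        # differentiated rows are not size-regulated by the division
        # machinery and keep growing to the global cap
        cap = np.where(
            self.proliferative,
            overshoot * np.maximum(self.division_threshold, self.target_area),
            growth_cap * self.target_area)
        a0 = np.minimum(self.target_area * ramp, cap)
        c0 = self.target_perimeter * np.sqrt(a0 / self.target_area)
        return a0, c0

    def copy(self) -> "CellStates":
        return CellStates(**{k: v.copy() for k, v in self.__dict__.items()})

    def drop(self, idx: int) -> None:
        for k, v in self.__dict__.items():
            self.__dict__[k] = np.delete(v, idx, axis=0)


def _positive_normal(rng, mean, sd, n):
    """Normal samples truncated (by resampling) to be positive."""
    x = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = x <= max(1e-3, 0.02 * mean)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.abs(x)


@dataclass
class EnergyBreakdown:
    area: float
    perimeter: float
    line: float

    @property
    def total(self) -> float:
        return self.area + self.perimeter + self.line


@dataclass
class DivisionRecord:
    time: float
    mother: int
    daughters: tuple[int, int]
    division_angle: float  # degrees in [0, 90] to the longitudinal (y) axis


@dataclass
class TissueStats:
    elongation_bias: float
    area_cv: float
    polygon_class_histogram: dict[int, float]
    hexagon_fraction: float
    n_cells: int
    aspect_ratios: np.ndarray | None = None


@dataclass
class Snapshot:
    time: float
    mesh: TissueMesh
    centroids: np.ndarray
    areas: np.ndarray
    root_id: np.ndarray
    cell_id: np.ndarray


@dataclass
class SimulationResult:
    snapshots: list[Snapshot]
    divisions: list[DivisionRecord]
    stats: TissueStats
    mesh: TissueMesh
    states: CellStates
    params: VertexModelParams


# ---------------------------------------------------------------------------
# energy and forces
# ---------------------------------------------------------------------------

def potential_energy(mesh: TissueMesh, states: CellStates,
                     params: VertexModelParams) -> EnergyBreakdown:
    """Total potential energy U = U_A + U_C + U_L with retrievable terms."""
    areas = mesh.cell_areas()
    if np.any(areas <= 1e-12):
        k = int(np.argmin(areas))
        raise DegenerateCellError(f"cell {k} has non-positive area {areas[k]:.3g}")
    perims = mesh.cell_perimeters()
    a0, c0 = states.effective_targets(params.growth_factor, params.growth_cap)
    u_a = float(np.sum(params.lambda_area * (areas - a0) ** 2))
    u_c = float(np.sum(params.beta_perimeter * (perims - c0) ** 2))
    t = mesh.topology
    ell = mesh.edge_lengths()
    gamma = np.where(t.is_interior, params.gamma_cell_cell, params.gamma_boundary)
    u_l = float(np.sum(gamma * ell))
    return EnergyBreakdown(u_a, u_c, u_l)


def _boundary_row_vertices(mesh: TissueMesh, states: CellStates):
    t = mesh.topology
    row = states.boundary_row[t.cell_of]
    return (np.unique(t.flat[row > 0]), np.unique(t.flat[row < 0]))


def _accumulate(f: np.ndarray, idx: np.ndarray, val: np.ndarray) -> None:
    n = f.shape[0]
    f[:, 0] += np.bincount(idx, weights=val[:, 0], minlength=n)
    f[:, 1] += np.bincount(idx, weights=val[:, 1], minlength=n)


def forces(mesh: TissueMesh, states: CellStates,
           params: VertexModelParams) -> np.ndarray:
    """Per-vertex force -grad U plus external boundary-row forces."""
    t = mesh.topology
    v = mesh.vertices
    p = v[t.flat]
    q = v[t.nxt]
    r = v[t.prv]

    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    areas = 0.5 * np.add.reduceat(cross, t.cell_start)
    seg = q - p
    ell = np.hypot(seg[:, 0], seg[:, 1])
    perims = np.add.reduceat(ell, t.cell_start)
    a0, c0 = states.effective_targets(params.growth_factor, params.growth_cap)

    f = np.zeros_like(v)

    # area elasticity: dA/dv_i = 0.5 * (y_next - y_prev, x_prev - x_next)
    coef_a = (2.0 * params.lambda_area * (areas - a0))[t.cell_of]
    ga = 0.5 * np.stack([q[:, 1] - r[:, 1], r[:, 0] - q[:, 0]], axis=1)
    _accumulate(f, t.flat, -coef_a[:, None] * ga)

    # perimeter elasticity: dC/dv_i = unit(v_i - v_prev) + unit(v_i - v_next)
    d_prev = p - r
    ell_prev = np.hypot(d_prev[:, 0], d_prev[:, 1])
    d_next = p - q
    with np.errstate(invalid="ignore", divide="ignore"):
        u_prev = d_prev / ell_prev[:, None]
        u_next = d_next / ell[:, None]
    u_prev = np.nan_to_num(u_prev)
    u_next = np.nan_to_num(u_next)
    coef_c = (2.0 * params.beta_perimeter * (perims - c0))[t.cell_of]
    _accumulate(f, t.flat, -coef_c[:, None] * (u_prev + u_next))

    # line tension on undirected edges
    e = t.edges
    de = v[e[:, 0]] - v[e[:, 1]]
    le = np.hypot(de[:, 0], de[:, 1])
    gamma = np.where(t.is_interior, params.gamma_cell_cell, params.gamma_boundary)
    with np.errstate(invalid="ignore", divide="ignore"):
        ue = de / le[:, None]
    ue = np.nan_to_num(ue)
    _accumulate(f, e[:, 0], -gamma[:, None] * ue)
    _accumulate(f, e[:, 1], gamma[:, None] * ue)

    # external longitudinal forces on the differentiated rows
    fmag = params.boundary_force * params.force_scale
    if fmag != 0.0:
        top, bot = _boundary_row_vertices(mesh, states)
        f[top, 1] += fmag
        f[bot, 1] -= fmag

    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force encountered")
    return f


# ---------------------------------------------------------------------------
# topology transitions
# ---------------------------------------------------------------------------

def _find_cell_with_directed_edge(mesh: TissueMesh, a: int, b: int,
                                  exclude: int | None = None) -> int | None:
    for k, c in enumerate(mesh.cells):
        if k == exclude:
            continue
        n = len(c)
        for i in range(n):
            if c[i] == a and c[(i + 1) % n] == b:
                return k
    return None


def _cells_containing_vertex(mesh: TissueMesh, v: int) -> list[int]:
    return [k for k, c in enumerate(mesh.cells) if v in c]


def _remove_vertex_from_cell(loop: np.ndarray, v: int) -> np.ndarray:
    return loop[loop != v]


def _insert_after(loop: np.ndarray, anchor: int, new: int) -> np.ndarray:
    i = int(np.where(loop == anchor)[0][0])
    return np.insert(loop, i + 1, new)


def _insert_before(loop: np.ndarray, anchor: int, new: int) -> np.ndarray:
    i = int(np.where(loop == anchor)[0][0])
    return np.insert(loop, i, new)


def t1_swap(mesh: TissueMesh, states: CellStates, edge: tuple[int, int],
            new_length: float) -> bool:
    """Neighbour exchange on a short interior edge.

    The edge (a, b) shared by cells P and Q collapses; the two cells R and S
    that previously met P and Q only at a single vertex gain the reopened
    edge, which is placed perpendicular to the old one with length
    ``new_length``.  Returns False (no-op) when the local configuration does
    not admit a swap (boundary endpoint, adjacent triangle, >3-valent vertex).
    """
    a, b = int(edge[0]), int(edge[1])
    cells_a = _cells_containing_vertex(mesh, a)
    cells_b = _cells_containing_vertex(mesh, b)
    shared = [k for k in cells_a if k in cells_b]
    if len(shared) != 2 or len(cells_a) != 3 or len(cells_b) != 3:
        return False
    # orient: P contains directed edge a->b, Q contains b->a
    P = _find_cell_with_directed_edge(mesh, a, b)
    Q = _find_cell_with_directed_edge(mesh, b, a)
    if P is None or Q is None or P == Q:
        return False
    if len(mesh.cells[P]) <= 3 or len(mesh.cells[Q]) <= 3:
        return False
    R = next(k for k in cells_a if k not in (P, Q))
    S = next(k for k in cells_b if k not in (P, Q))
    if R == S:
        return False

    va, vb = mesh.vertices[a], mesh.vertices[b]
    m = 0.5 * (va + vb)
    e = vb - va
    norm = np.hypot(*e)
    if norm < 1e-14:
        tang = np.array([1.0, 0.0])
    else:
        tang = e / norm
    perp = np.array([-tang[1], tang[0]])  # points into P (CCW interior on left)
    mesh.vertices[a] = m + 0.5 * new_length * perp
    mesh.vertices[b] = m - 0.5 * new_length * perp

    # P keeps a (on its side), Q keeps b
    mesh.cells[P] = _remove_vertex_from_cell(mesh.cells[P], b)
    mesh.cells[Q] = _remove_vertex_from_cell(mesh.cells[Q], a)

    # R gains b adjacent to a, on the side of its edge shared with Q
    loop_r = mesh.cells[R]
    i = int(np.where(loop_r == a)[0][0])
    nxt_r = int(loop_r[(i + 1) % len(loop_r)])
    if nxt_r in mesh.cells[Q]:
        mesh.cells[R] = _insert_after(loop_r, a, b)
    else:
        mesh.cells[R] = _insert_before(loop_r, a, b)
    # S gains a adjacent to b, on the side of its edge shared with P
    loop_s = mesh.cells[S]
    j = int(np.where(loop_s == b)[0][0])
    nxt_s = int(loop_s[(j + 1) % len(loop_s)])
    if nxt_s in mesh.cells[P]:
        mesh.cells[S] = _insert_after(loop_s, b, a)
    else:
        mesh.cells[S] = _insert_before(loop_s, b, a)

    mesh.invalidate()
    return True


def t2_remove(mesh: TissueMesh, states: CellStates, cell_idx: int) -> None:
    """Remove a small triangular cell, merging its vertices into one."""
    loop = mesh.cells[cell_idx]
    assert len(loop) == 3
    centroid = mesh.vertices[loop].mean(axis=0)
    keep = int(loop[0])
    mesh.vertices[keep] = centroid
    drop = {int(loop[1]), int(loop[2])}
    new_cells = []
    for k, c in enumerate(mesh.cells):
        if k == cell_idx:
            continue
        c2 = np.array([keep if int(v) in drop else int(v) for v in c], dtype=np.intp)
        # collapse consecutive duplicates
        mask = np.ones(len(c2), bool)
        for i in range(len(c2)):
            if c2[i] == c2[(i + 1) % len(c2)]:
                mask[(i + 1) % len(c2)] = False
        new_cells.append(c2[mask])
    mesh.cells = new_cells
    states.drop(cell_idx)
    mesh.invalidate()


def collapse_boundary_edge(mesh: TissueMesh, states: CellStates,
                           edge: tuple[int, int]) -> bool:
    """Merge the endpoints of a short tissue-boundary edge.

    Boundary edges are under constant boundary tension and can shrink below
    the rearrangement threshold without any T1 partner; collapsing them to a
    single vertex (at the midpoint) removes the resulting force singularity.
    No-op (returns False) when the owning cell is a triangle.
    """
    a, b = int(edge[0]), int(edge[1])
    owner = _find_cell_with_directed_edge(mesh, a, b)
    if owner is None:
        owner = _find_cell_with_directed_edge(mesh, b, a)
    if owner is None or len(mesh.cells[owner]) <= 3:
        return False
    cells_a = _cells_containing_vertex(mesh, a)
    cells_b = _cells_containing_vertex(mesh, b)
    if len([k for k in cells_a if k in cells_b]) != 1:
        return False  # interior edge; T1 handles it
    new_loops = {}
    for k in cells_b:
        c = np.where(mesh.cells[k] == b, a, mesh.cells[k])
        keep = np.ones(len(c), bool)
        for i in range(len(c)):
            if c[i] == c[(i + 1) % len(c)]:
                keep[(i + 1) % len(c)] = False
        if keep.sum() < 3 or len(np.unique(c[keep])) != keep.sum():
            return False
        new_loops[k] = c[keep]
    mesh.vertices[a] = 0.5 * (mesh.vertices[a] + mesh.vertices[b])
    for k, loop in new_loops.items():
        mesh.cells[k] = loop
    mesh.invalidate()
    return True


def _apply_rearrangements(mesh: TissueMesh, states: CellStates,
                          params: VertexModelParams) -> None:
    mean_area = float(np.mean(mesh.cell_areas()))
    # T2 first: tiny triangles
    while True:
        areas = mesh.cell_areas()
        small = [k for k in range(mesh.n_cells)
                 if len(mesh.cells[k]) == 3 and areas[k] < params.t2_area_rel * mean_area]
        if not small:
            break
        t2_remove(mesh, states, small[0])
    # T1 swaps on short interior edges, collapse of short boundary edges
    # (one pass; conflicts resolved on subsequent steps)
    ell = mesh.edge_lengths()
    mean_edge = float(np.mean(ell))
    thr = params.t1_threshold(mean_edge)
    t = mesh.topology
    short = np.where(ell < thr)[0]
    if len(short) == 0:
        return
    order = np.argsort(ell[short])
    interior = t.is_interior[short][order]
    done: set[int] = set()
    edges = t.edges[short][order]
    # a contested edge can swap back and forth every few steps under a
    # biased force field; a short cooldown per vertex pair breaks the cycle
    cooldown: dict = getattr(mesh, "_t1_cooldown", {})
    for pair in list(cooldown):
        cooldown[pair] -= 1
        if cooldown[pair] <= 0:
            del cooldown[pair]
    for (a, b), is_int in zip(edges, interior):
        if int(a) in done or int(b) in done:
            continue
        pair = (int(min(a, b)), int(max(a, b)))
        if pair in cooldown:
            continue
        if is_int:
            ok = t1_swap(mesh, states, (int(a), int(b)),
                         params.t1_new_edge_factor * thr)
        else:
            ok = collapse_boundary_edge(mesh, states, (int(a), int(b)))
        cooldown[pair] = 50
        if ok:
            done.update((int(a), int(b)))
    mesh._t1_cooldown = cooldown


def step(mesh: TissueMesh, states: CellStates, params: VertexModelParams,
         dt: float | None = None) -> float:
    """One overdamped explicit update; returns the time step taken.

    The step is capped so that the largest vertex displacement does not
    exceed ``step_cap_rel`` times the T1 threshold, which keeps the dynamics
    from jumping across rearrangement events.
    """
    f = forces(mesh, states, params)
    speed = np.hypot(f[:, 0], f[:, 1]) / params.drag
    mean_edge = float(np.mean(mesh.edge_lengths()))
    cap = params.step_cap_rel * params.t1_threshold(mean_edge)
    if dt is None:
        # a handful of vertices (transients after a division or around a
        # pending rearrangement) can carry forces far above the bulk; the
        # step is sized for the 98th-percentile speed and the few outliers
        # are clipped to the displacement cap, which preserves the descent
        # direction per vertex and the T1-safety bound
        v_ref = float(np.percentile(speed, 98.0)) if len(speed) else 0.0
        dt = params.dt_max if v_ref * params.dt_max <= cap else cap / v_ref
    elif float(speed.max()) * dt > params.t1_threshold(mean_edge):
        raise ValueError(
            f"dt={dt:.3g} moves a vertex {float(speed.max()) * dt:.3g} "
            "> T1 threshold")
    disp = (dt / params.drag) * f
    norm = np.hypot(disp[:, 0], disp[:, 1])
    over = norm > cap
    if over.any():
        disp[over] *= (cap / norm[over])[:, None]
    mesh.vertices += disp
    states.age += dt
    _apply_rearrangements(mesh, states, params)
    return dt


# ---------------------------------------------------------------------------
# cell division
# ---------------------------------------------------------------------------

def polygon_second_moments(pts: np.ndarray) -> np.ndarray:
    """Area-normalised second central moment (covariance) tensor of a polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    x0, y0 = x - cx, y - cy
    xn0, yn0 = xn - cx, yn - cy
    cross0 = x0 * yn0 - xn0 * y0
    ixx = (cross0 * (x0 ** 2 + x0 * xn0 + xn0 ** 2)).sum() / 12.0
    iyy = (cross0 * (y0 ** 2 + y0 * yn0 + yn0 ** 2)).sum() / 12.0
    ixy = (cross0 * (2 * x0 * y0 + x0 * yn0 + xn0 * y0 + 2 * xn0 * yn0)).sum() / 24.0
    return np.array([[ixx, ixy], [ixy, iyy]]) / a


def shortest_axis(pts: np.ndarray, rng: np.random.Generator | None = None,
                  tie_tol: float = 1e-9) -> np.ndarray:
    """Unit vector along the shortest principal axis of the polygon.

    Degenerate (isotropic) moment tensors are broken by a uniform random
    angle drawn from ``rng``.
    """
    cov = polygon_second_moments(pts)
    w, vecs = np.linalg.eigh(cov)
    if abs(w[1] - w[0]) <= tie_tol * max(abs(w[1]), 1e-300):
        if rng is None:
            rng = np.random.default_rng()
        ang = rng.uniform(0.0, np.pi)
        return np.array([np.cos(ang), np.sin(ang)])
    return vecs[:, 0]  # eigenvector of the smaller moment


def cell_aspect_ratio(pts: np.ndarray) -> float:
    w = np.linalg.eigvalsh(polygon_second_moments(pts))
    w = np.clip(w, 1e-300, None)
    return float(np.sqrt(w[1] / w[0]))


def divide_cell(mesh: TissueMesh, states: CellStates, cell_idx: int,
                rng: np.random.Generator, params: VertexModelParams,
                time: float = 0.0) -> DivisionRecord:
    """Split a cell through its centroid along its shortest principal axis.

    New vertices are inserted on the two crossed edges (and into the
    neighbouring cells sharing them); both daughters inherit the mother's
    base targets, get age 0, and resample cycle duration and division
    threshold.  If the split line fails to produce two simple polygons the
    cut is retried with up to +-5 degrees of jitter.
    """
    loop = mesh.cells[cell_idx]
    pts = mesh.vertices[loop]
    axis = shortest_axis(pts, rng)
    if params.aspect_threshold > 0 and cell_aspect_ratio(pts) < params.aspect_threshold:
        ang = rng.uniform(0.0, np.pi)
        axis = np.array([np.cos(ang), np.sin(ang)])
    cx = pts[:, 0].mean()  # placeholder; real centroid below
    centroid = _polygon_centroid(pts)

    for jitter in (0.0, np.deg2rad(5.0), -np.deg2rad(5.0)):
        c, s = np.cos(jitter), np.sin(jitter)
        d = np.array([c * axis[0] - s * axis[1], s * axis[0] + c * axis[1]])
        ok = _try_split(mesh, states, cell_idx, centroid, d, rng, params, time)
        if ok is not None:
            return ok
    raise RuntimeError(f"division of cell {cell_idx} failed after jitter retries")


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    return np.array([((x + xn) * cross).sum(), ((y + yn) * cross).sum()]) / (6 * a)


def _try_split(mesh, states, cell_idx, centroid, d, rng, params, time):
    loop = mesh.cells[cell_idx]
    pts = mesh.vertices[loop]
    n = len(loop)
    normal = np.array([-d[1], d[0]])
    sd = (pts - centroid) @ normal
    scale = np.abs(sd).max()
    if scale == 0:
        return None
    eps = 1e-9 * scale
    if np.any(np.abs(sd) < eps):
        return None  # vertex on the cut line: jitter
    crossings = [i for i in range(n) if sd[i] * sd[(i + 1) % n] < 0]
    if len(crossings) != 2:
        return None
    new_ids = []
    cut_edges = []
    for i in crossings:
        j = (i + 1) % n
        t_par = sd[i] / (sd[i] - sd[j])
        pnew = pts[i] + t_par * (pts[j] - pts[i])
        # refuse cuts grazing an existing vertex
        if (np.linalg.norm(pnew - pts[i]) < 1e-6 or
                np.linalg.norm(pnew - pts[j]) < 1e-6):
            return None
        mesh.vertices = np.vstack([mesh.vertices, pnew[None, :]])
        new_ids.append(mesh.n_vertices - 1)
        cut_edges.append((int(loop[i]), int(loop[j])))

    (a1, b1), (a2, b2) = cut_edges
    p1, p2 = new_ids
    i1, i2 = crossings

    idx = list(map(int, loop))
    # daughter 1: p1, vertices i1+1..i2, p2 ; daughter 2: p2, vertices i2+1..i1, p1
    def walk(start, stop):
        out = []
        k = (start + 1) % n
        while True:
            out.append(idx[k])
            if k == stop:
                break
            k = (k + 1) % n
        return out

    d1 = np.array([p1] + walk(i1, i2) + [p2], dtype=np.intp)
    d2 = np.array([p2] + walk(i2, i1) + [p1], dtype=np.intp)
    if len(d1) < 3 or len(d2) < 3:
        mesh.vertices = mesh.vertices[:-2]
        return None

    # insert new vertices into the neighbours sharing the cut edges
    for (a, b), p in zip(cut_edges, new_ids):
        nb = _find_cell_with_directed_edge(mesh, b, a, exclude=cell_idx)
        if nb is not None:
            mesh.cells[nb] = _insert_after(mesh.cells[nb], b, p)

    mesh.cells[cell_idx] = d1
    mesh.cells.append(d2)
    mesh.invalidate()

    # states: daughter 1 replaces mother in-place, daughter 2 appended.
    # Size continuity at division: each daughter starts from half the
    # mother's effective (grown) target area, then grows along its own ramp.
    new_id_base = int(states.cell_id.max()) + 1
    mother_id = int(states.cell_id[cell_idx])
    root = int(states.root_id[cell_idx])
    ramp = min(1.0 + (params.growth_factor - 1.0) * states.age[cell_idx]
               / states.cycle_duration[cell_idx], params.growth_cap)
    a0_mother = min(float(states.target_area[cell_idx]) * ramp,
                    1.1 * max(float(states.division_threshold[cell_idx]),
                              float(states.target_area[cell_idx])))
    a0_daughter = 0.5 * a0_mother
    c0_daughter = _hexagon_perimeter(a0_daughter)
    for which, target in ((0, cell_idx), (1, None)):
        cyc = float(_positive_normal(rng, params.cycle_mean, params.cycle_sd, 1)[0])
        thr = float(_positive_normal(rng, params.div_area_mean, params.div_area_sd, 1)[0])
        if target is None:
            for key, val in (("target_area", a0_daughter),
                             ("target_perimeter", c0_daughter),
                             ("age", 0.0), ("cycle_duration", cyc),
                             ("division_threshold", thr),
                             ("proliferative", states.proliferative[cell_idx]),
                             ("boundary_row", states.boundary_row[cell_idx]),
                             ("cell_id", new_id_base + 1), ("root_id", root)):
                states.__dict__[key] = np.append(states.__dict__[key], val)
        else:
            states.age[target] = 0.0
            states.cycle_duration[target] = cyc
            states.division_threshold[target] = thr
            states.target_area[target] = a0_daughter
            states.target_perimeter[target] = c0_daughter
            states.cell_id[target] = new_id_base

    c1 = _polygon_centroid(mesh.vertices[d1])
    c2 = _polygon_centroid(mesh.vertices[d2])
    w = c1 - c2
    ang = np.degrees(np.arccos(np.clip(abs(w[1]) / (np.linalg.norm(w) + 1e-300), 0, 1)))
    return DivisionRecord(time=time, mother=mother_id,
                          daughters=(new_id_base, new_id_base + 1),
                          division_angle=float(ang))


# ---------------------------------------------------------------------------
# simulation driver and statistics
# ---------------------------------------------------------------------------

def run_simulation(mesh: TissueMesh, states: CellStates,
                   params: VertexModelParams,
                   progress: bool = False) -> SimulationResult:
    """Run the vertex model for ``params.duration`` a.u. (seeded, deterministic)."""
    rng = np.random.default_rng(params.seed)
    mesh = mesh.copy()
    states = states.copy()
    t = 0.0
    divisions: list[DivisionRecord] = []
    snapshots = [_snapshot(t, mesh, states)]
    next_snap = params.snapshot_interval
    while t < params.duration:
        dt = step(mesh, states, params)
        t += dt
        # divisions: age and area conditions must both hold
        areas = mesh.cell_areas()
        ready = np.where(states.proliferative &
                         (states.age >= states.cycle_duration) &
                         (areas >= states.division_threshold))[0]
        for k in sorted(ready, reverse=True):
            try:
                divisions.append(
                    divide_cell(mesh, states, int(k), rng, params, time=t))
            except RuntimeError:
                continue  # retry at a later step once the shape relaxes
        if t >= next_snap or t >= params.duration:
            snapshots.append(_snapshot(t, mesh, states))
            next_snap += params.snapshot_interval
    stats = shape_statistics(mesh)
    stats.elongation_bias = compute_outgrowth_bias(snapshots)
    return SimulationResult(snapshots, divisions, stats, mesh, states, params)


def _snapshot(t: float, mesh: TissueMesh, states: CellStates) -> Snapshot:
    return Snapshot(time=t, mesh=mesh.copy(),
                    centroids=mesh.cell_centroids(),
                    areas=mesh.cell_areas(),
                    root_id=states.root_id.copy(),
                    cell_id=states.cell_id.copy())


def compute_outgrowth_bias(snapshots: list[Snapshot]) -> float:
    """(L_f/L_0) / (W_f/W_0) with extents from the centroid bounding box."""
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    first, last = snapshots[0], snapshots[-1]

    def extents(c):
        return (c[:, 1].max() - c[:, 1].min(), c[:, 0].max() - c[:, 0].min())

    l0, w0 = extents(first.centroids)
    lf, wf = extents(last.centroids)
    if l0 <= 0 or w0 <= 0:
        raise ValueError("zero initial extent")
    return float((lf / l0) / (wf / w0))


def division_angle_histogram(records: list[DivisionRecord],
                             bin_width_deg: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram of division angles on [0, 90]."""
    if not records:
        raise ValueError("no division records")
    if 90.0 % bin_width_deg != 0:
        raise ValueError("bin width must divide 90")
    angles = np.array([r.division_angle for r in records])
    edges = np.arange(0.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    hist, _ = np.histogram(np.clip(angles, 0, 90 - 1e-9), bins=edges)
    return hist / hist.sum(), edges


def shape_statistics(mesh: TissueMesh) -> TissueStats:
    """Area CV (population SD / mean) and neighbour-count histogram."""
    areas = mesh.cell_areas()
    cv = float(np.std(areas) / np.mean(areas))
    counts = mesh.neighbor_counts()
    vals, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(c) / len(counts) for v, c in zip(vals, freq)}
    hexfrac = hist.get(6, 0.0)
    aspect = np.array([cell_aspect_ratio(mesh.vertices[c]) for c in mesh.cells])
    return TissueStats(elongation_bias=float("nan"), area_cv=cv,
                       polygon_class_histogram=hist, hexagon_fraction=hexfrac,
                       n_cells=mesh.n_cells, aspect_ratios=aspect)


def displacement_profile(snapshots: list[Snapshot]) -> np.ndarray:
    """Per-founder (initial axial position, relative axial displacement).

    Cells are tracked through divisions via their founding-cell id; a
    founder's position is the mean centroid of its living descendants.
    Displacements are normalised by the maximum absolute axial displacement;
    rows are sorted by initial axial position.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    first, last = snapshots[0], snapshots[-1]
    roots = np.unique(first.root_id)
    rows = []
    for r in roots:
        y0 = first.centroids[first.root_id == r, 1].mean()
        sel = last.root_id == r
        if not sel.any():
            continue  # lineage removed by T2
        yf = last.centroids[sel, 1].mean()
        rows.append((y0, yf - y0))
    arr = np.array(rows)
    mx = np.abs(arr[:, 1]).max()
    if mx > 0:
        arr[:, 1] /= mx
    return arr[np.argsort(arr[:, 0])]
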