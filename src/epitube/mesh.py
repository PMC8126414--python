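"""Planar polygonal tissue mesh for 2D vertex-model simulations.

A :class:`TissueMesh` stores shared vertices and per-cell counter-clockwise
vertex loops.  Interior edges are shared by exactly two cells, boundary edges
by one.  Derived topology (edge lists, adjacency, per-vertex cell valence) is
cached and invalidated whenever the cell loops change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateCellError(ValueError):
    """Raised when a cell polygon has (near-)zero area."""


@dataclass
class Topology:
    """Flattened, vectorisation-friendly view of the cell loops."""

    flat: np.ndarray          # (M,) vertex index of each loop entry, grouped by cell
    nxt: np.ndarray           # (M,) vertex index of the successor within the loop
    prv: np.ndarray           # (M,) vertex index of the predecessor
    cell_of: np.ndarray       # (M,) owning cell index
    cell_start: np.ndarray    # (n_cells,) offset of each cell in flat
    cell_len: np.ndarray      # (n_cells,)
    edges: np.ndarray         # (E,2) undirected edges (lo, hi)
    edge_cells: np.ndarray    # (E,2) adjacent cell ids, -1 where absent
    is_interior: np.ndarray   # (E,) True if shared by two cells


class TissueMesh:
    """Shared-vertex polygonal tessellation with per-cell CCW loops."""

    def __init__(self, vertices: np.ndarray, cells: list[np.ndarray]):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        self.cells = [np.asarray(c, dtype=np.intp).copy() for c in cells]
        self._topo: Topology | None = None

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def invalidate(self) -> None:
        self._topo = None

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.vertices, self.cells)

    @property
    def topology(self) -> Topology:
        if self._topo is None:
            self._topo = self._build_topology()
        return self._topo

    def _build_topology(self) -> Topology:
        lens = np.array([len(c) for c in self.cells], dtype=np.intp)
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]]) if len(lens) else np.zeros(0, np.intp)
        flat = (np.concatenate(self.cells) if self.cells
                else np.zeros(0, np.intp))
        nxt = np.empty_like(flat)
        prv = np.empty_like(flat)
        cell_of = np.empty_like(flat)
        for k, c in enumerate(self.cells):
            s, n = starts[k], lens[k]
            nxt[s:s + n] = np.roll(c, -1)
            prv[s:s + n] = np.roll(c, 1)
            cell_of[s:s + n] = k
        # undirected edge table
        a = np.minimum(flat, nxt)
        b = np.maximum(flat, nxt)
        keys = a.astype(np.int64) * (self.n_vertices + 1) + b
        order = np.argsort(keys, kind="stable")
        skeys = keys[order]
        uniq_mask = np.concatenate([[True], skeys[1:] != skeys[:-1]])
        uniq_idx = order[uniq_mask]
        edges = np.stack([a[uniq_idx], b[uniq_idx]], axis=1)
        n_e = len(uniq_idx)
        edge_cells = np.full((n_e, 2), -1, dtype=np.intp)
        inv = np.empty(len(keys), dtype=np.intp)
        inv[order] = np.cumsum(uniq_mask) - 1
        counts = np.zeros(n_e, dtype=np.intp)
        for i in range(len(flat)):
            e = inv[i]
            if counts[e] < 2:
                edge_cells[e, counts[e]] = cell_of[i]
            counts[e] += 1
        if np.any(counts > 2):
            bad = edges[counts > 2]
            raise ValueError(f"edge shared by more than two cells: {bad[0]}")
        return Topology(flat, nxt, prv, cell_of, starts, lens,
                        edges, edge_cells, counts == 2)

    # -- geometry ---------------------------------------------------------

    def cell_areas(self) -> np.ndarray:
        t = self.topology
        p = self.vertices[t.flat]
        q = self.vertices[t.nxt]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        return 0.5 * np.add.reduceat(cross, t.cell_start)

    def cell_perimeters(self) -> np.ndarray:
        t = self.topology
        seg = self.vertices[t.nxt] - self.vertices[t.flat]
        ell = np.hypot(seg[:, 0], seg[:, 1])
        return np.add.reduceat(ell, t.cell_start)

    def cell_centroids(self) -> np.ndarray:
        """Area centroids of the cell polygons."""
        t = self.topology
        p = self.vertices[t.flat]
        q = self.vertices[t.nxt]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        cx = np.add.reduceat((p[:, 0] + q[:, 0]) * cross, t.cell_start)
        cy = np.add.reduceat((p[:, 1] + q[:, 1]) * cross, t.cell_start)
        area = 0.5 * np.add.reduceat(cross, t.cell_start)
        area = np.where(np.abs(area) < 1e-300, np.nan, area)
        return np.stack([cx, cy], axis=1) / (6.0 * area[:, None])

    def edge_lengths(self) -> np.ndarray:
        t = self.topology
        seg = self.vertices[t.edges[:, 1]] - self.vertices[t.edges[:, 0]]
        return np.hypot(seg[:, 0], seg[:, 1])

    def neighbor_counts(self) -> np.ndarray:
        """Number of cells sharing at least one edge with each cell."""
        t = self.topology
        shared = t.edge_cells[t.is_interior]
        counts = np.zeros(self.n_cells, dtype=np.intp)
        if len(shared):
            pairs = np.unique(np.sort(shared, axis=1), axis=0)
            np.add.at(counts, pairs[:, 0], 1)
            np.add.at(counts, pairs[:, 1], 1)
        return counts

    def boundary_cell_mask(self) -> np.ndarray:
        """Cells owning at least one boundary (unshared) edge."""
        t = self.topology
        mask = np.zeros(self.n_cells, dtype=bool)
        bcells = t.edge_cells[~t.is_interior, 0]
        mask[bcells[bcells >= 0]] = True
        return mask

    def vertex_cell_count(self) -> np.ndarray:
        t = self.topology
        counts = np.zeros(self.n_vertices, dtype=np.intp)
        np.add.at(counts, t.flat, 1)
        return counts

    # -- validation -------------------------------------------------------

    def validate(self, check_overlap: bool = False, rng=None) -> None:
        """Check mesh invariants; raise ``ValueError`` on violation.

        With ``check_overlap`` a Monte-Carlo point-in-polygon test verifies
        that the sum of cell areas equals the area covered by the union
        (no overlaps or gaps); intended for small meshes in tests.
        """
        areas = self.cell_areas()
        if np.any(areas <= 0):
            k = int(np.argmin(areas))
            raise DegenerateCellError(
                f"cell {k} is degenerate or clockwise (signed area {areas[k]:.3g})")
        for k, c in enumerate(self.cells):
            if len(c) < 3:
                raise ValueError(f"cell {k} has fewer than 3 vertices")
            if len(np.unique(c)) != len(c):
                raise ValueError(f"cell {k} repeats a vertex")
            if not _is_simple_polygon(self.vertices[c]):
                raise ValueError(f"cell {k} is not a simple polygon")
        self.topology  # raises if an edge is over-shared
        if check_overlap:
            from shapely.geometry import Polygon
            from shapely.ops import unary_union
            polys = [Polygon(self.vertices[c]) for c in self.cells]
            union = unary_union(polys)
            if not np.isclose(union.area, float(np.sum(areas)), rtol=1e-6):
                raise ValueError(
                    f"cells overlap or leave gaps: union area {union.area:.6g} "
                    f"!= sum of areas {np.sum(areas):.6g}")


def _is_simple_polygon(pts: np.ndarray) -> bool:
    n = len(pts)
    if n < 3:
        return False
    # O(n^2) segment intersection test; cells are small polygons
    seg_a = pts
    seg_b = np.roll(pts, -1, axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_cross(seg_a[i], seg_b[i], seg_a[j], seg_b[j]):
                return False
    return True


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))
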