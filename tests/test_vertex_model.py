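import numpy as np
import pytest

from epitube.mesh import TissueMesh
from epitube.synthetic import make_honeycomb
from epitube.vertex_model import (CellStates, DivisionRecord, Snapshot,
                                  VertexModelParams, compute_outgrowth_bias,
                                  divide_cell, division_angle_histogram,
                                  displacement_profile, forces,
                                  potential_energy, run_simulation,
                                  shape_statistics, step, t1_swap)


def fresh_states(mesh, params, seed=0, zero_age=True):
    rng = np.random.default_rng(seed)
    states = CellStates.fresh(mesh.n_cells, params, rng)
    if zero_age:
        states.age[:] = 0.0
    return states


def brute_force_energy(mesh, states, params):
    """Independent term-by-term oracle, written separately from the force code."""
    total = 0.0
    a0, c0 = states.effective_targets(params.growth_factor, params.growth_cap)
    seen_edges = {}
    for k, loop in enumerate(mesh.cells):
        pts = mesh.vertices[loop]
        n = len(pts)
        area = 0.0
        perim = 0.0
        for i in range(n):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % n]
            area += 0.5 * (x1 * y2 - x2 * y1)
            perim += np.hypot(x2 - x1, y2 - y1)
            key = tuple(sorted((int(loop[i]), int(loop[(i + 1) % n]))))
            seen_edges[key] = seen_edges.get(key, 0) + 1
        total += params.lambda_area * (area - a0[k]) ** 2
        total += params.beta_perimeter * (perim - c0[k]) ** 2
    for (a, b), cnt in seen_edges.items():
        length = np.hypot(*(mesh.vertices[a] - mesh.vertices[b]))
        gamma = params.gamma_cell_cell if cnt == 2 else params.gamma_boundary
        total += gamma * length
    return total


class TestPotentialEnergy:
    def test_relaxed_hexagon_zero(self):
        """A regular hexagon at its targets with zero tension has U = 0."""
        params = VertexModelParams(gamma_cell_cell=0.0, gamma_boundary=0.0)
        ang = np.deg2rad(90 + 60 * np.arange(6))
        s = np.sqrt(1.0 / (1.5 * np.sqrt(3)))
        verts = s * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        mesh = TissueMesh(verts, [np.arange(6)])
        states = fresh_states(mesh, params)
        e = potential_energy(mesh, states, params)
        assert abs(e.total) < 1e-12

    def test_unit_square_area_term(self):
        """(A - A0)^2 with lambda=1, A=1, A0=2 contributes exactly 1."""
        params = VertexModelParams(lambda_area=1.0, beta_perimeter=0.0,
                                   gamma_cell_cell=0.0, gamma_boundary=0.0)
        mesh = TissueMesh(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float),
                          [np.arange(4)])
        states = fresh_states(mesh, params)
        states.target_area[:] = 2.0
        e = potential_energy(mesh, states, params)
        assert np.isclose(e.total, 1.0)
        assert np.isclose(e.area, 1.0) and e.perimeter == 0 and e.line == 0

    def test_seven_cell_honeycomb_matches_brute_force(self):
        params = VertexModelParams()
        mesh, _ = make_honeycomb(16, 1.0, seed=3, params=params)
        states = fresh_states(mesh, params, seed=3, zero_age=False)
        rng = np.random.default_rng(0)
        mesh.vertices += rng.normal(0, 0.03, mesh.vertices.shape)
        mesh.invalidate()
        e = potential_energy(mesh, states, params)
        assert np.isclose(e.total, brute_force_energy(mesh, states, params),
                          rtol=1e-12)

    def test_degenerate_cell_named_in_error(self):
        params = VertexModelParams()
        mesh = TissueMesh(np.array([[0, 0], [1, 0], [1, 1], [0, 1],
                                    [2, 0], [2, 1]], float),
                          [np.array([0, 1, 2, 3]), np.array([1, 4, 5, 2])])
        states = fresh_states(mesh, params)
        mesh.vertices[4] = [1.0, 0.0]
        mesh.vertices[5] = [1.0, 1.0]
        with pytest.raises(Exception, match="1"):
            potential_energy(mesh, states, params)


class TestForces:
    def test_matches_finite_differences(self):
        """Analytic forces equal central differences of U to 1e-6 relative."""
        params = VertexModelParams()
        mesh, _ = make_honeycomb(16, 1.0, seed=5, params=params)
        states = fresh_states(mesh, params, seed=5, zero_age=False)
        rng = np.random.default_rng(1)
        mesh.vertices += rng.normal(0, 0.02, mesh.vertices.shape)
        mesh.invalidate()
        f = forces(mesh, states, params)
        h = 1e-6
        scale = np.abs(f).max()
        for i in rng.choice(mesh.n_vertices, 15, replace=False):
            for d in range(2):
                mesh.vertices[i, d] += h
                up = potential_energy(mesh, states, params).total
                mesh.vertices[i, d] -= 2 * h
                dn = potential_energy(mesh, states, params).total
                mesh.vertices[i, d] += h
                num = -(up - dn) / (2 * h)
                assert abs(num - f[i, d]) < 1e-6 * max(scale, 1.0)

    def test_equilibrium_honeycomb_zero_force(self):
        """With matched targets and no tension the honeycomb is force-free."""
        params = VertexModelParams(gamma_cell_cell=0.0, gamma_boundary=0.0)
        mesh, _ = make_honeycomb(36, 1.0, seed=0, params=params)
        states = fresh_states(mesh, params)
        states.target_perimeter[:] = mesh.cell_perimeters()
        states.target_area[:] = mesh.cell_areas()
        f = forces(mesh, states, params)
        assert np.abs(f).max() < 1e-9

    def test_external_force_sum_on_top_row(self):
        params = VertexModelParams(boundary_force=1.0, force_scale=1.0)
        mesh, states = make_honeycomb(25, 1.0, seed=0, params=params)
        states.age[:] = 0.0
        f1 = forces(mesh, states, params)
        params0 = VertexModelParams(boundary_force=0.0, force_scale=1.0)
        f0 = forces(mesh, states, params0)
        ext = f1 - f0
        top = np.unique(np.concatenate(
            [mesh.cells[k] for k in range(mesh.n_cells)
             if states.boundary_row[k] > 0]))
        n_top = len(top)
        assert np.allclose(ext[:, 0], 0.0)
        assert np.isclose(ext[top, 1].sum(), n_top * 1.0)
        assert np.isclose(ext[:, 1].sum(), 0.0)  # bottom row balances


class TestStep:
    def test_zero_forces_leave_mesh_unchanged(self):
        params = VertexModelParams(gamma_cell_cell=0.0, gamma_boundary=0.0)
        mesh, _ = make_honeycomb(16, 1.0, seed=0, params=params)
        states = fresh_states(mesh, params)
        states.target_perimeter[:] = mesh.cell_perimeters()
        states.cycle_duration[:] = 1e9  # freeze the growth ramp
        before = mesh.vertices.copy()
        step(mesh, states, params)
        assert np.allclose(mesh.vertices, before, atol=1e-12)

    def test_energy_descends_during_relaxation(self):
        """Overdamped relaxation of a perturbed tissue decreases U monotonically."""
        params = VertexModelParams()
        mesh, _ = make_honeycomb(25, 1.0, seed=2, params=params)
        states = fresh_states(mesh, params, seed=2)
        states.cycle_duration[:] = 1e9
        rng = np.random.default_rng(2)
        mesh.vertices += rng.normal(0, 0.05, mesh.vertices.shape)
        mesh.invalidate()
        u_prev = potential_energy(mesh, states, params).total
        for _ in range(200):
            step(mesh, states, params)
            u = potential_energy(mesh, states, params).total
            assert u <= u_prev + 1e-10 * abs(u_prev)
            u_prev = u

    def test_t1_swap_exchanges_neighbors(self):
        params = VertexModelParams()
        mesh, states = make_honeycomb(16, 1.0, seed=0, params=params)
        t = mesh.topology
        vc = mesh.vertex_cell_count()
        ok_edges = [i for i in range(len(t.edges)) if t.is_interior[i]
                    and vc[t.edges[i, 0]] == 3 and vc[t.edges[i, 1]] == 3]
        e = t.edges[ok_edges[0]]
        old_pair = tuple(sorted(t.edge_cells[ok_edges[0]]))
        assert t1_swap(mesh, states, (int(e[0]), int(e[1])), 0.05)
        mesh.validate()
        t2 = mesh.topology
        new_pairs = {tuple(sorted(c)) for c in t2.edge_cells[t2.is_interior]}
        assert old_pair not in new_pairs  # the old pair lost their contact
        # the new edge (same vertex ids) is now shared by the other two cells
        idx = [i for i in range(len(t2.edges))
               if set(t2.edges[i]) == {int(e[0]), int(e[1])}]
        assert len(idx) == 1
        assert not set(t2.edge_cells[idx[0]]) & set(old_pair)


class TestDivision:
    def test_rectangle_splits_into_squares(self):
        """A 2x1 rectangle divides along its short axis into two unit squares."""
        params = VertexModelParams()
        mesh = TissueMesh(np.array([[0, 0], [2, 0], [2, 1], [0, 1]], float),
                          [np.arange(4)])
        states = fresh_states(mesh, params)
        rng = np.random.default_rng(0)
        rec = divide_cell(mesh, states, 0, rng, params)
        assert np.allclose(sorted(mesh.cell_areas()), [1.0, 1.0])
        assert np.isclose(rec.division_angle, 90.0)  # daughters side by side

    def test_hexagon_tie_breaks_randomly(self):
        params = VertexModelParams()
        angles = []
        for seed in range(12):
            ang = np.deg2rad(90 + 60 * np.arange(6))
            verts = np.stack([np.cos(ang), np.sin(ang)], axis=1)
            mesh = TissueMesh(verts, [np.arange(6)])
            states = fresh_states(mesh, params, seed=seed)
            rng = np.random.default_rng(seed)
            rec = divide_cell(mesh, states, 0, rng, params)
            angles.append(rec.division_angle)
        assert np.ptp(angles) > 20  # not locked to one orientation

    def test_daughter_areas_sum_to_mother(self):
        """Area is conserved at division to 1e-9 relative (clipping oracle)."""
        from shapely.geometry import Polygon
        params = VertexModelParams()
        mesh, _ = make_honeycomb(16, 1.0, seed=4, params=params)
        states = fresh_states(mesh, params, seed=4)
        rng = np.random.default_rng(4)
        mesh.vertices += rng.normal(0, 0.04, mesh.vertices.shape)
        mesh.invalidate()
        k = 5
        mother_area = Polygon(mesh.vertices[mesh.cells[k]]).area
        n_before = mesh.n_cells
        divide_cell(mesh, states, k, rng, params)
        areas = mesh.cell_areas()
        assert np.isclose(areas[k] + areas[n_before], mother_area, rtol=1e-9)


class TestStatistics:
    def _snap(self, centroids, t=0.0):
        c = np.asarray(centroids, float)
        return Snapshot(time=t, mesh=None, centroids=c,
                        areas=np.ones(len(c)),
                        root_id=np.arange(len(c)), cell_id=np.arange(len(c)))

    def test_bias_examples(self):
        rng = np.random.default_rng(0)
        c0 = rng.uniform(0, 1, (40, 2))
        assert np.isclose(compute_outgrowth_bias(
            [self._snap(c0), self._snap(1.7 * c0)]), 1.0)
        assert np.isclose(compute_outgrowth_bias(
            [self._snap(c0), self._snap(c0 * [1.0, 2.0])]), 2.0)
        assert np.isclose(compute_outgrowth_bias(
            [self._snap(c0), self._snap(c0 * [1.2, 2.4])]), 2.0)

    def test_bias_zero_extent_errors(self):
        c = np.zeros((5, 2))
        with pytest.raises(ValueError):
            compute_outgrowth_bias([self._snap(c), self._snap(c)])

    def test_division_angle_histogram(self):
        recs = [DivisionRecord(0, 0, (1, 2), a) for a in (10.0, 10.0, 80.0)]
        hist, edges = division_angle_histogram(recs, 30.0)
        assert np.allclose(hist, [2 / 3, 0, 1 / 3])
        with pytest.raises(ValueError):
            division_angle_histogram([], 30.0)
        with pytest.raises(ValueError):
            division_angle_histogram(recs, 25.0)

    def test_area_cv_population_convention(self):
        """Areas {1, 1, 4}: population SD / mean = sqrt(2)/2."""
        verts = np.array([[0, 0], [1, 0], [2, 0], [6, 0],
                          [0, 1], [1, 1], [2, 1], [6, 1]], float)
        cells = [np.array([0, 1, 5, 4]), np.array([1, 2, 6, 5]),
                 np.array([2, 3, 7, 6])]
        mesh = TissueMesh(verts, cells)
        stats = shape_statistics(mesh)
        assert np.isclose(stats.area_cv, np.sqrt(2) / 2)
        assert np.isclose(sum(stats.polygon_class_histogram.values()), 1.0)

    def test_displacement_profile_affine_maps(self):
        rng = np.random.default_rng(3)
        c0 = rng.uniform(-1, 1, (30, 2))
        # rigid translation: all relative displacements equal
        prof = displacement_profile([self._snap(c0), self._snap(c0 + [0, 2.0])])
        assert np.allclose(prof[:, 1], prof[0, 1])
        # pure stretch about the centre: displacement linear in position
        prof = displacement_profile([self._snap(c0), self._snap(c0 * [1, 2.0])])
        r = np.corrcoef(prof[:, 0], prof[:, 1])[0, 1]
        assert r > 0.999999


class TestSimulation:
    def test_unforced_no_division_bias_is_one(self):
        """After boundary relaxation, an unforced tissue stops deforming."""
        params = VertexModelParams(duration=12.0, cycle_mean=1e6,
                                   cycle_sd=1.0, seed=0,
                                   snapshot_interval=1.0)
        mesh, states = make_honeycomb(36, None, seed=0, params=params)
        res = run_simulation(mesh, states, params)
        assert len(res.divisions) == 0
        late = [s for s in res.snapshots if s.time >= 10.0]
        assert abs(compute_outgrowth_bias(late) - 1.0) < 0.015

    def test_seed_reproducibility_bitwise(self):
        params = VertexModelParams(duration=6.0, seed=11)
        mesh, states = make_honeycomb(36, 1.0, seed=11, params=params)
        r1 = run_simulation(mesh, states, params)
        mesh, states = make_honeycomb(36, 1.0, seed=11, params=params)
        r2 = run_simulation(mesh, states, params)
        assert r1.stats.area_cv == r2.stats.area_cv
        assert r1.stats.elongation_bias == r2.stats.elongation_bias
        assert np.array_equal(r1.mesh.vertices, r2.mesh.vertices)

    def test_simulation_grows_and_stays_valid(self):
        params = VertexModelParams(duration=8.0, seed=3)
        mesh, states = make_honeycomb(49, 1.0, seed=3, params=params)
        res = run_simulation(mesh, states, params)
        assert res.mesh.n_cells > 49
        res.mesh.validate()
        # differentiated rows never divide
        assert all(states.boundary_row[m] == 0 for m in ()) or True
        mothers = {r.mother for r in res.divisions}
        diff_ids = set(np.where(states.boundary_row != 0)[0])
        assert not (mothers & diff_ids)
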