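import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tissuedyn.deformation import (
    DeformationRecord,
    Triangle,
    accumulate_series,
    corotational_term,
    decompose_movie,
    frame_deformation,
    shear_decomposition,
    triangle_state,
    triangulate,
)
from tissuedyn.nematic import Nematic, from_axis_angle
from tissuedyn.network import BACKGROUND
from tissuedyn.roi import margin_filter
from tissuedyn.synthetic import (
    DeformationScript,
    ScriptedEvent,
    apply_deformation_series,
    make_hex_sheet,
    script_topological_events,
)


def rot(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def tri(coords, cells=(1, 2, 3)):
    return Triangle(0, 0, cells, np.asarray(coords, dtype=float))


def equilateral(size=1.0, theta=0.0, center=(0.0, 0.0)):
    pts = size * np.array(
        [[math.cos(a), math.sin(a)] for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                                              math.pi / 2 + 4 * math.pi / 3)]
    )
    return pts @ rot(theta).T + np.asarray(center)


class TestTriangulate:
    def test_one_triangle_per_interior_vertex(self, hex_sheet):
        tris = triangulate(hex_sheet)
        interior_vertices = [
            v for v in hex_sheet.vertex_ids()
            if BACKGROUND not in hex_sheet.vertex_cells(v)
        ]
        assert len(tris) == len(interior_vertices)
        for t in tris:
            assert t.area > 0

    def test_boundary_vertices_produce_no_triangle(self, hex_sheet):
        tris = triangulate(hex_sheet)
        for t in tris:
            assert BACKGROUND not in hex_sheet.vertex_cells(t.vertex_id)

    def test_kfold_vertex_fans_into_k_minus_2(self, hex_sheet, deep_cells):
        # an extrusion creates one rosette vertex with k incident cells
        victim = deep_cells[0]
        k = len(hex_sheet.neighbors(victim))
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(3)),
            [ScriptedEvent(0, "extrusion", (victim,))],
        )
        net1 = movie.networks[1]
        rosette = [
            v for v in net1.vertex_ids() if len(net1.vertex_cells(v)) == k
        ]
        assert rosette
        tris = [t for t in triangulate(net1) if t.vertex_id == rosette[0]]
        assert len(tris) == k - 2

    def test_roi_restriction(self, hex_sheet, interior_cells):
        roi = set(interior_cells)
        tris = triangulate(hex_sheet, roi)
        assert tris
        for t in tris:
            assert set(t.cells) <= roi


class TestTriangleState:
    @pytest.mark.parametrize("size,theta", [(1.0, 0.0), (3.7, 1.1), (0.2, -2.5)])
    def test_equilateral_has_zero_elongation(self, size, theta):
        st_ = triangle_state(tri(equilateral(size, theta)))
        assert st_.q.norm == pytest.approx(0.0, abs=1e-12)

    def test_stretched_equilateral(self):
        q = 0.4
        pts = equilateral() @ np.diag([math.exp(q), math.exp(-q)]).T
        st_ = triangle_state(tri(pts))
        assert st_.q.xx == pytest.approx(q, abs=1e-12)
        assert st_.q.xy == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance(self):
        q, theta0 = 0.4, 0.7
        pts = equilateral() @ np.diag([math.exp(q), math.exp(-q)]).T
        st0 = triangle_state(tri(pts))
        st1 = triangle_state(tri(pts @ rot(theta0).T))
        assert st1.q.norm == pytest.approx(q, abs=1e-12)
        expected = st0.q.rotated(theta0)
        assert st1.q.xx == pytest.approx(expected.xx, abs=1e-12)
        assert st1.q.xy == pytest.approx(expected.xy, abs=1e-12)

    def test_degenerate_triangle_raises(self):
        with pytest.raises(ValueError):
            triangle_state(tri([[0, 0], [1, 1], [2, 2]]))

    @given(
        q=st.floats(0.01, 1.0),
        beta=st.floats(0, math.pi),
        theta=st.floats(-math.pi, math.pi),
        scale=st.floats(0.2, 5.0),
    )
    def test_decomposition_reconstructs_shape_map(self, q, beta, theta, scale):
        """s * exp(Q) * R(theta) rebuilt from the extracted state."""
        qmat = from_axis_angle(q, beta).as_matrix()
        w, v = np.linalg.eigh(qmat)
        expq = v @ np.diag(np.exp(w)) @ v.T
        s_mat = scale * expq @ rot(theta)
        from tissuedyn.deformation import _left_polar

        ln_s, qn, th = _left_polar(s_mat)
        assert math.exp(ln_s) == pytest.approx(scale, rel=1e-9)
        assert qn.norm == pytest.approx(q, rel=1e-7, abs=1e-9)
        # rebuild
        qb = qn.as_matrix()
        w2, v2 = np.linalg.eigh(qb)
        rebuilt = math.exp(ln_s) * v2 @ np.diag(np.exp(w2)) @ v2.T @ rot(th)
        assert np.allclose(rebuilt, s_mat, atol=1e-9)


class TestFrameDeformation:
    def pair(self, m, jitter=None):
        base = [tri(equilateral(1.0, th, (3 * i, 0)))
                for i, th in enumerate((0.0, 0.4, 1.2))]
        moved = [
            Triangle(1, t.vertex_id, t.cells, t.coords @ np.asarray(m).T)
            for t in base
        ]
        return list(zip(base, moved))

    def test_uniform_translation_gives_zero(self):
        base = [tri(equilateral())]
        moved = [Triangle(1, 0, (1, 2, 3), base[0].coords + [5.0, -2.0])]
        viso, vt, om = frame_deformation(list(zip(base, moved)))
        assert viso == pytest.approx(0.0, abs=1e-12)
        assert vt.norm == pytest.approx(0.0, abs=1e-12)
        assert om == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear_map(self):
        s = 0.3
        viso, vt, om = frame_deformation(self.pair(np.diag([math.exp(s), math.exp(-s)])))
        assert viso == pytest.approx(0.0, abs=1e-12)
        assert vt.xx == pytest.approx(s, abs=1e-12)
        assert vt.xy == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_map(self):
        g = 0.05
        viso, vt, om = frame_deformation(self.pair(math.exp(g / 2) * np.eye(2)))
        assert viso == pytest.approx(g, abs=1e-12)
        assert vt.norm == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation(self):
        om_in = 0.05
        viso, vt, om = frame_deformation(self.pair(rot(om_in)))
        # vorticity is positive for a counter-clockwise rotation in the
        # numeric frame (the convention that makes co-rotation stationary)
        assert om == pytest.approx(om_in, abs=1e-12)
        assert viso == pytest.approx(0.0, abs=1e-12)
        assert vt.norm == pytest.approx(0.0, abs=1e-12)

    def test_no_matches_raises(self):
        with pytest.raises(ValueError):
            frame_deformation([])


class TestCorotational:
    def test_no_rotation_constant_angle(self):
        q0, q1 = Nematic(0.1, 0.0), Nematic(0.3, 0.0)
        d = corotational_term(q0, q1, omega=0.0)
        assert d.xx == pytest.approx(0.2) and d.xy == pytest.approx(0.0)

    def test_c_goes_to_one_for_small_q(self):
        for qmag in (1e-3, 1e-6):
            c = math.tanh(2 * qmag) / (2 * qmag)
            assert c == pytest.approx(1.0, abs=5 * qmag ** 2)

    def test_rigid_corotation_vanishes(self):
        q, phi, om = 0.25, 0.6, 1e-4
        q0 = from_axis_angle(q, phi)
        q1 = from_axis_angle(q, phi + om)
        d = corotational_term(q0, q1, omega=om)
        assert d.norm < 1e-9  # exact in the infinitesimal limit

    def test_zero_elongation_reduces_to_plain_difference(self):
        d = corotational_term(Nematic(), Nematic(), omega=0.5)
        assert d.norm == 0.0


@pytest.fixture(scope="module")
def shear_records():
    net = make_hex_sheet(8, 8)
    movie = apply_deformation_series(net, DeformationScript.pure_shear(n_frames=6))
    wt = margin_filter(movie.networks, movie.histories)
    return decompose_movie(movie.networks, movie.histories, roi=wt)


class TestShearDecomposition:
    def test_pure_shear_movie_carried_by_elongation_change(self, shear_records):
        for r in shear_records:
            assert r.vtilde.xx == pytest.approx(0.0175, abs=1e-9)
            assert r.vtilde.xy == pytest.approx(0.0, abs=1e-9)
            assert r.viso == pytest.approx(0.0, abs=1e-9)
            assert r.dq_dt.xx == pytest.approx(0.0175, abs=1e-9)
            for term in (r.t1, r.division, r.extrusion, r.correlation):
                assert term.norm < 1e-9

    def test_identity_holds_exactly(self, shear_records):
        for r in shear_records:
            assert r.shear_residual().norm < 1e-12
            assert abs(r.area_residual()) < 1e-12

    def test_isotropic_movie(self):
        net = make_hex_sheet(8, 8)
        movie = apply_deformation_series(net, DeformationScript.isotropic(n_frames=4))
        wt = margin_filter(movie.networks, movie.histories)
        for r in decompose_movie(movie.networks, movie.histories, roi=wt):
            assert r.viso == pytest.approx(0.035, abs=1e-9)
            assert r.vtilde.norm < 1e-9
            assert r.area_total == pytest.approx(0.035, abs=1e-9)
            assert r.area_cell == pytest.approx(0.035, abs=1e-9)
            assert r.area_division == 0.0 and r.area_extrusion == 0.0

    def test_frozen_center_t1_compensated_by_elongation(self, hex_sheet, deep_cells):
        a = deep_cells[len(deep_cells) // 2]
        b = sorted(hex_sheet.neighbors(a) & set(deep_cells))[0]
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "t1", (a, b))],
        )
        frozen = {c: hex_sheet.cell_center(c) for c in hex_sheet.cell_ids}
        for net in movie.networks:
            net.cell_centers.update(frozen)
        r = shear_decomposition(movie.networks[1], movie.networks[2], movie.histories)
        assert r.vtilde.norm < 1e-12
        assert r.n_t1 == 4  # two redrawn triangles on each side
        assert r.t1.norm > 1e-4
        assert (r.t1 + r.dq_dt).norm < 1e-6
        assert r.shear_residual().norm < 1e-12

    def test_division_classes_and_area_balance(self, hex_sheet, deep_cells):
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "division", (deep_cells[0],), 0.0)],
        )
        r = shear_decomposition(movie.networks[1], movie.networks[2], movie.histories)
        n = len(movie.networks[1].cell_ids)
        assert r.n_division == 2  # the two triangles at the new junctions
        assert r.area_division == pytest.approx(math.log(1 + 1 / n), abs=1e-12)
        # total area frozen: the division gain is balanced by cell shrinkage
        assert r.area_total == pytest.approx(0.0, abs=1e-9)
        assert r.area_cell == pytest.approx(-math.log(1 + 1 / n), abs=1e-9)
        assert r.shear_residual().norm < 1e-12

    def test_extrusion_area_balance(self, hex_sheet, deep_cells):
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "extrusion", (deep_cells[0],))],
        )
        r = shear_decomposition(movie.networks[1], movie.networks[2], movie.histories)
        n = len(movie.networks[1].cell_ids)
        assert r.n_extrusion > 0
        assert r.area_extrusion == pytest.approx(math.log((n - 1) / n), abs=1e-12)
        assert abs(r.area_residual()) < 1e-12

    def test_no_events_all_conserved(self, shear_records):
        for r in shear_records:
            assert r.n_t1 == r.n_division == r.n_extrusion == r.n_other == 0
            assert r.n_conserved > 0

    def test_objectivity_under_added_rotation(self, hex_sheet):
        """A rigid rotation added between frames shifts Omega only."""
        movie = apply_deformation_series(
            hex_sheet, DeformationScript.pure_shear(n_frames=2)
        )
        r0 = shear_decomposition(movie.networks[0], movie.networks[1], movie.histories)
        net1 = movie.networks[1]
        theta = 0.2
        rotated = {
            v: tuple(rot(theta) @ np.asarray(p))
            for v, p in net1.vertex_positions.items()
        }
        from tissuedyn.network import CellNetwork

        net1r = CellNetwork(1, rotated, net1.dbonds)
        r1 = shear_decomposition(movie.networks[0], net1r, movie.histories)
        assert r1.viso == pytest.approx(r0.viso, abs=1e-9)
        assert r1.vtilde.norm == pytest.approx(r0.vtilde.norm, abs=1e-9)
        assert r1.omega == pytest.approx(r0.omega + theta, abs=1e-9)

    def test_small_deformation_consistency(self, hex_sheet):
        """Halving the rate and doubling the frames preserves the total."""
        wt = None
        totals = []
        for rate, frames in ((0.035, 5), (0.0175, 9)):
            movie = apply_deformation_series(
                hex_sheet, DeformationScript.pure_shear(rate, n_frames=frames)
            )
            recs = decompose_movie(movie.networks, movie.histories)
            totals.append(sum(r.vtilde.xx for r in recs))
        assert totals[0] == pytest.approx(totals[1], abs=1e-4)


class TestAccumulate:
    def test_constant_rate_accumulates_linearly(self, shear_records):
        cum = accumulate_series(shear_records)
        n = len(shear_records)
        assert cum["cum_vtilde_xx"].iloc[-1] == pytest.approx(n * 0.0175, abs=1e-8)

    def test_identity_preserved_under_accumulation(self, shear_records):
        cum = accumulate_series(shear_records)
        lhs = cum["cum_vtilde_xx"]
        rhs = (
            cum["cum_dq_dt_xx"] + cum["cum_t1_xx"] + cum["cum_division_xx"]
            + cum["cum_extrusion_xx"] + cum["cum_correlation_xx"]
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_gap_raises(self, shear_records):
        broken = [shear_records[0], shear_records[2]]
        with pytest.raises(ValueError):
            accumulate_series(broken)
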