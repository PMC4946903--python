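import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tissuedyn.geometry import (
    cell_center_area,
    cell_elongation,
    grid_coarse_grain,
    neighbor_count,
    polygon_center_area,
)
from tissuedyn.nematic import Nematic
from tissuedyn.network import network_from_cell_polygons

# elongation of a regular hexagon stretched x2 along x, frozen from the
# adaptive polygon quadrature and cross-checked against a ~5e6-px sum
STRETCHED_HEX_EXX = 0.3390593


def regular_polygon(n, r=1.0, phase=0.0):
    ang = phase + 2 * math.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def pixel_oracle_elongation(poly, scale=300):
    """Brute-force pixel-sum of the elongation integrals."""
    from skimage.draw import polygon as draw_polygon

    off = -poly.min(axis=0) + 0.5
    rr, cc = draw_polygon((poly[:, 1] + off[1]) * scale, (poly[:, 0] + off[0]) * scale)
    p = np.stack([cc, rr], axis=1).astype(float)
    p -= p.mean(axis=0)
    r2 = (p ** 2).sum(axis=1)
    ok = r2 > 0
    exx = float(np.sum((p[ok, 0] ** 2 - p[ok, 1] ** 2) / r2[ok])) / len(p)
    exy = float(np.sum(2 * p[ok, 0] * p[ok, 1] / r2[ok])) / len(p)
    return exx, exy


class TestCenterArea:
    def test_unit_square(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        (cx, cy), a = cell_center_area(sq)
        assert (cx, cy) == pytest.approx((0.5, 0.5))
        assert a == pytest.approx(1.0)

    @given(dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_translation_equivariance(self, dx, dy):
        poly = regular_polygon(7, r=2.0)
        (cx, cy), a = polygon_center_area(poly)
        (cx2, cy2), a2 = polygon_center_area(poly + [dx, dy])
        assert cx2 - cx == pytest.approx(dx, abs=1e-9)
        assert cy2 - cy == pytest.approx(dy, abs=1e-9)
        assert a2 == pytest.approx(a, rel=1e-12)

    def test_random_12gon_matches_pixelation(self, rng):
        r = 1.0 + 0.5 * rng.random(12)
        ang = np.sort(rng.uniform(0, 2 * math.pi, 12))
        poly = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        (cx, cy), a = polygon_center_area(poly)
        from skimage.draw import polygon as draw_polygon

        scale = 700  # ~10^6 covered pixels
        off = -poly.min(axis=0) + 0.1
        rr, cc = draw_polygon((poly[:, 1] + off[1]) * scale, (poly[:, 0] + off[0]) * scale)
        a_pix = len(rr) / scale ** 2
        cx_pix = cc.mean() / scale - off[0]
        cy_pix = rr.mean() / scale - off[1]
        assert a == pytest.approx(a_pix, rel=5e-3)
        assert cx == pytest.approx(cx_pix, abs=5e-3)
        assert cy == pytest.approx(cy_pix, abs=5e-3)

    def test_zero_area_region_raises(self):
        with pytest.raises(ValueError):
            polygon_center_area(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with pytest.raises(ValueError):
            cell_center_area(np.empty((0, 2), dtype=int))


class TestElongation:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 12])
    def test_regular_polygons_have_zero_elongation(self, n):
        e = cell_elongation(regular_polygon(n, r=2.0, phase=0.3))
        assert e.norm == pytest.approx(0.0, abs=1e-9)

    def test_near_disk_zero(self):
        e = cell_elongation(regular_polygon(256))
        assert e.norm == pytest.approx(0.0, abs=1e-9)

    def test_stretched_hexagon_matches_frozen_oracle(self):
        poly = regular_polygon(6) * [2.0, 1.0]
        e = cell_elongation(poly)
        assert e.xy == pytest.approx(0.0, abs=1e-9)
        assert e.xx == pytest.approx(STRETCHED_HEX_EXX, abs=1e-6)

    def test_polygon_quadrature_agrees_with_pixel_sum(self):
        poly = regular_polygon(6) * [2.0, 1.0]
        exx, exy = pixel_oracle_elongation(poly)
        e = cell_elongation(poly)
        assert abs(e.xx - exx) < 1e-3
        assert abs(e.xy - exy) < 1e-3

    @given(theta=st.floats(0, math.pi), phase=st.floats(0, 1.0))
    def test_rotation_equivariance(self, theta, phase):
        poly = regular_polygon(6, phase=phase) * [2.0, 1.0]
        c, s = math.cos(theta), math.sin(theta)
        rot = poly @ np.array([[c, s], [-s, c]])
        e0 = cell_elongation(poly)
        e1 = cell_elongation(rot)
        assert e1.norm == pytest.approx(e0.norm, abs=1e-7)
        expected = e0.rotated(theta)
        assert e1.xx == pytest.approx(expected.xx, abs=1e-7)
        assert e1.xy == pytest.approx(expected.xy, abs=1e-7)

    def test_pixel_set_input(self):
        # a 200x100 pixel rectangle elongated along x
        xs, ys = np.meshgrid(np.arange(200), np.arange(100))
        pix = np.column_stack([xs.ravel(), ys.ravel()])
        e = cell_elongation(pix)
        assert e.xx > 0.1
        assert e.xy == pytest.approx(0.0, abs=1e-9)


class TestNeighborCount:
    def test_hex_interior_is_six(self, hex_sheet, interior_cells):
        assert neighbor_count(hex_sheet, interior_cells[0]) == 6

    def test_corner_cell_of_2x2_block(self):
        # 2x2 block of unit squares: each corner cell touches 2 others
        verts = {}
        k = 1
        for i in range(3):
            for j in range(3):
                verts[k] = (float(j), float(i))
                k += 1
        def vid(i, j):
            return 1 + 3 * i + j
        cycles = {}
        cid = 1
        for i in range(2):
            for j in range(2):
                cycles[cid] = [vid(i, j), vid(i, j + 1), vid(i + 1, j + 1), vid(i + 1, j)]
                cid += 1
        net = network_from_cell_polygons(cycles, verts)
        assert neighbor_count(net, 1) == 2

    def test_unknown_cell_raises(self, hex_sheet):
        with pytest.raises(KeyError):
            neighbor_count(hex_sheet, 10_000)


class TestGridCoarseGrain:
    def test_opposite_unit_nematics_cancel_under_sum(self):
        df = pd.DataFrame(
            {
                "frame": [0, 0],
                "x": [1.0, 2.0],
                "y": [1.0, 2.0],
                "xx": [1.0, -1.0],   # axes at 0 and pi/2
                "xy": [0.0, 0.0],
            }
        )
        g = grid_coarse_grain(df, box_size=10.0, mode="sum")
        assert g["xx"].abs().max() == pytest.approx(0.0)
        assert int(g["count"].sum()) == 2

    def test_single_nematic_identity(self):
        df = pd.DataFrame(
            {"frame": [0], "x": [1.0], "y": [1.0], "xx": [0.3], "xy": [-0.2]}
        )
        for mode in ("sum", "mean"):
            g = grid_coarse_grain(df, 5.0, mode=mode)
            assert g.loc[g["count"] == 1, "xx"].iloc[0] == pytest.approx(0.3)
            assert g.loc[g["count"] == 1, "xy"].iloc[0] == pytest.approx(-0.2)

    def test_uniform_field_mean(self, rng):
        pts = rng.uniform(0, 100, size=(200, 2))
        df = pd.DataFrame(
            {"frame": 0, "x": pts[:, 0], "y": pts[:, 1], "xx": 0.5, "xy": 0.1}
        )
        g = grid_coarse_grain(df, 33.0, mode="mean")
        nz = g[g["count"] > 0]
        assert np.allclose(nz["xx"], 0.5) and np.allclose(nz["xy"], 0.1)

    def test_empty_boxes_reported_with_zero(self):
        df = pd.DataFrame(
            {"frame": [0, 0], "x": [1.0, 99.0], "y": [1.0, 99.0],
             "xx": [1.0, 1.0], "xy": [0.0, 0.0]}
        )
        g = grid_coarse_grain(df, 10.0, mode="sum")
        empty = g[g["count"] == 0]
        assert len(empty) > 0
        assert empty["xx"].abs().max() == 0.0

    def test_bad_args(self):
        df = pd.DataFrame({"frame": [0], "x": [0.0], "y": [0.0], "xx": [0], "xy": [0]})
        with pytest.raises(ValueError):
            grid_coarse_grain(df, 0.0)
        with pytest.raises(ValueError):
            grid_coarse_grain(df, 1.0, mode="median")
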