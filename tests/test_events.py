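import math

import numpy as np
import pytest

from tissuedyn.events import (
    build_lineage,
    cell_cycle_lengths,
    detect_contact_changes,
    division_events,
    division_nematic,
    event_rates,
    t1_nematic,
)
from tissuedyn.network import AppearsBy, CellHistoryRecord, DisappearsBy
from tissuedyn.synthetic import (
    DeformationScript,
    ScriptedEvent,
    apply_deformation_series,
    make_hex_sheet,
    script_topological_events,
)


def record(cell, first, last, daughters=None, appears=AppearsBy.SEGMENTATION_START):
    if daughters:
        return CellHistoryRecord(
            cell, first, last, appears_by=appears,
            disappears_by=DisappearsBy.DIVISION,
            left_daughter_cell_id=daughters[0],
            right_daughter_cell_id=daughters[1],
        )
    return CellHistoryRecord(cell, first, last, appears_by=appears)


class TestLineage:
    def test_two_rounds_of_division(self):
        hist = {
            1: record(1, 0, 1, daughters=(2, 3)),
            2: record(2, 2, 3, daughters=(4, 5), appears=AppearsBy.DIVISION),
            3: record(3, 2, 5, appears=AppearsBy.DIVISION),
            4: record(4, 4, 5, appears=AppearsBy.DIVISION),
            5: record(5, 4, 5, appears=AppearsBy.DIVISION),
        }
        forest = build_lineage(hist)
        assert forest.generation == {1: 0, 2: 1, 3: 1, 4: 2, 5: 2}
        assert len(set(forest.lineage_group.values())) == 1
        forest.annotate(hist)
        assert hist[4].generation == 2

    def test_never_dividing_cell_is_gen0_singleton(self):
        forest = build_lineage({9: record(9, 0, 5)})
        assert forest.generation[9] == 0
        assert forest.group_members(9) == {9}

    def test_two_trees_get_distinct_groups(self):
        hist = {
            1: record(1, 0, 1, daughters=(2, 3)),
            2: record(2, 2, 5, appears=AppearsBy.DIVISION),
            3: record(3, 2, 5, appears=AppearsBy.DIVISION),
            7: record(7, 0, 5),
        }
        forest = build_lineage(hist)
        assert forest.lineage_group[1] == forest.lineage_group[2]
        assert forest.lineage_group[7] != forest.lineage_group[1]

    def test_double_mother_is_hard_error(self):
        hist = {
            1: record(1, 0, 1, daughters=(3, 4)),
            2: record(2, 0, 1, daughters=(3, 5)),
            3: record(3, 2, 5, appears=AppearsBy.DIVISION),
            4: record(4, 2, 5, appears=AppearsBy.DIVISION),
            5: record(5, 2, 5, appears=AppearsBy.DIVISION),
        }
        with pytest.raises(ValueError):
            build_lineage(hist)


class TestUnitNematics:
    @pytest.mark.parametrize(
        "phi,xx,xy",
        [(0.0, 1.0, 0.0), (math.pi / 4, 0.0, 1.0), (math.pi / 2, -1.0, 0.0)],
    )
    def test_division_nematic_angles(self, phi, xx, xy):
        p = np.array([0.0, 0.0])
        q = np.array([math.cos(phi), math.sin(phi)])
        n = division_nematic(p, q)
        assert n.xx == pytest.approx(xx, abs=1e-12)
        assert n.xy == pytest.approx(xy, abs=1e-12)
        assert n.norm == pytest.approx(1.0)

    def test_t1_loss_along_x(self):
        n = t1_nematic((0, 0), (1, 0), "loss")
        assert (n.xx, n.xy) == pytest.approx((1.0, 0.0))

    def test_t1_gain_along_y_is_perpendicular(self):
        # gain along y: nematic = -(cos pi, sin pi) = (1, 0), axis along x
        n = t1_nematic((0, 0), (0, 1), "gain")
        assert (n.xx, n.xy) == pytest.approx((1.0, 0.0))

    def test_loss_plus_gain_along_same_axis_cancels(self):
        a, b = (0.3, -0.2), (1.7, 2.2)
        s = t1_nematic(a, b, "loss") + t1_nematic(a, b, "gain")
        assert s.norm == 0.0

    def test_coincident_centers_error(self):
        with pytest.raises(ValueError):
            division_nematic((1, 1), (1, 1))
        with pytest.raises(ValueError):
            t1_nematic((1, 1), (1, 1), "loss")


@pytest.fixture(scope="module")
def t1_movie():
    net = make_hex_sheet(7, 7)
    interior = [
        c for c in net.cell_ids
        if 0 not in net.neighbors(c, include_background=True)
    ]
    deep = [c for c in interior if net.neighbors(c) <= set(interior)]
    a = deep[len(deep) // 2]
    b = sorted(net.neighbors(a) & set(deep))[0]
    movie = script_topological_events(
        apply_deformation_series(net, DeformationScript.identity(4)),
        [ScriptedEvent(1, "t1", (a, b))],
    )
    return movie, a, b


class TestContactChanges:
    def test_quartet_t1_yields_one_loss_one_gain(self, t1_movie):
        movie, a, b = t1_movie
        changes = detect_contact_changes(
            movie.networks[1], movie.networks[2], movie.histories
        )
        losses = [c for c in changes if c.kind == "loss"]
        gains = [c for c in changes if c.kind == "gain"]
        assert len(losses) == 1 and len(gains) == 1
        assert {losses[0].cell_a, losses[0].cell_b} == {a, b}
        assert {gains[0].cell_a, gains[0].cell_b} != {a, b}

    def test_gain_is_perpendicular_to_loss(self, t1_movie):
        movie, _, _ = t1_movie
        changes = detect_contact_changes(
            movie.networks[1], movie.networks[2], movie.histories
        )
        loss = next(c for c in changes if c.kind == "loss")
        gain = next(c for c in changes if c.kind == "gain")
        # a T1 swaps the contact axis by ~90 deg, so both nematics point
        # the same way and reinforce (they do not cancel)
        assert (loss.nematic + gain.nematic).norm > 1.5

    def test_quiet_pairs_have_no_events(self, t1_movie):
        movie, _, _ = t1_movie
        assert detect_contact_changes(
            movie.networks[0], movie.networks[1], movie.histories
        ) == []

    def test_division_masking_yields_zero_half_t1(self, hex_sheet, deep_cells):
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "division", (deep_cells[0],), 0.2)],
        )
        changes = detect_contact_changes(
            movie.networks[1], movie.networks[2], movie.histories
        )
        assert changes == []

    def test_extrusion_produces_no_half_t1(self, hex_sheet, deep_cells):
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "extrusion", (deep_cells[0],))],
        )
        changes = detect_contact_changes(
            movie.networks[1], movie.networks[2], movie.histories
        )
        assert changes == []

    def test_balance_gained_equals_lost_on_closed_fixture(self, hex_sheet, deep_cells):
        events = [
            ScriptedEvent(1, "t1", (deep_cells[0],
                                    sorted(hex_sheet.neighbors(deep_cells[0])
                                           & set(deep_cells))[0])),
            ScriptedEvent(2, "t1", (deep_cells[-1],
                                    sorted(hex_sheet.neighbors(deep_cells[-1])
                                           & set(deep_cells))[0])),
        ]
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(5)),
            events,
        )
        gains = losses = 0
        for f in range(movie.n_frames - 1):
            for ch in detect_contact_changes(
                movie.networks[f], movie.networks[f + 1], movie.histories
            ):
                if ch.kind == "gain":
                    gains += 1
                else:
                    losses += 1
        assert gains == losses == 2

    def test_division_event_orientation(self, hex_sheet, deep_cells):
        movie = script_topological_events(
            apply_deformation_series(hex_sheet, DeformationScript.identity(4)),
            [ScriptedEvent(1, "division", (deep_cells[0],), 0.0)],
        )
        evs = division_events(movie.networks, movie.histories)
        assert len(evs) == 1
        assert evs[0].nematic.norm == pytest.approx(1.0)
        # daughter separation axis was scripted along x
        assert evs[0].nematic.xx == pytest.approx(1.0, abs=0.05)


class TestRates:
    def test_ten_divisions_among_hundred_cells(self):
        times = [i * 360.0 for i in range(11)]  # one 1-h bin
        counts = {f: 100 for f in range(11)}
        df = event_rates([2] * 10, counts, times, bin_hours=1.0)
        assert df["rate"].iloc[0] == pytest.approx(0.1)

    def test_zero_events_zero_rate(self):
        times = [i * 600.0 for i in range(7)]
        df = event_rates([], {f: 50 for f in range(7)}, times)
        assert (df["rate"] == 0).all()

    def test_empty_roi_bin_is_missing(self):
        times = [0.0, 1800.0, 3600.0, 5400.0]
        df = event_rates([1], {f: 0 for f in range(4)}, times)
        assert df["rate"].isna().all()

    def test_poisson_rate_recovery(self, rng):
        """Binned counting recovers a scripted Poisson rate within 3 SE."""
        lam = 0.25  # events per cell per hour
        n_cells, hours, n_seeds = 100, 10, 20
        est = []
        for _ in range(n_seeds):
            n_ev = rng.poisson(lam * n_cells * hours)
            frames_per_hour = 6
            times = [i * 600.0 for i in range(hours * frames_per_hour + 1)]
            ev_frames = rng.integers(0, len(times) - 1, size=n_ev)
            df = event_rates(
                list(ev_frames), {f: n_cells for f in range(len(times))}, times
            )
            est.append(df["rate"].iloc[:hours].mean())
        est = np.asarray(est)
        se = est.std(ddof=1) / math.sqrt(n_seeds)
        assert abs(est.mean() - lam) < 3 * se + 1e-12


def test_cell_cycle_lengths():
    hist = {
        1: record(1, 0, 2, daughters=(2, 3)),
        2: record(2, 3, 8, daughters=(4, 5), appears=AppearsBy.DIVISION),
        3: record(3, 3, 10, appears=AppearsBy.DIVISION),
        4: record(4, 9, 10, appears=AppearsBy.DIVISION),
        5: record(5, 9, 10, appears=AppearsBy.DIVISION),
    }
    times = [i * 3600.0 for i in range(11)]
    med, mad, spans = cell_cycle_lengths(hist, times)
    assert spans == [5.0]
    assert med == 5.0 and mad == 0.0
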