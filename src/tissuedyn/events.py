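"""Cellular events: lineages, neighbor-exchange detection, event nematics.

Contact gains and losses ("half-T1s") are found by comparing neighbor
sets between consecutive frames.  Divisions are masked first — the
mother id is propagated onto its two daughters, which are fused into one
bookkeeping cell — and any pair involving an id that is absent in one of
the two frames (extrusion, cell moving in or out of view) is excluded,
so the remaining differences are genuine neighbor exchanges.

Orientation conventions (unit nematics):

* division: axis of the line connecting the daughter centers,
  ``(cos 2phi, sin 2phi)``;
* contact loss: axis of the line connecting the two separating centers,
  ``+(cos 2phi, sin 2phi)``;
* contact gain: ``-(cos 2phi, sin 2phi)`` of the connecting axis, i.e.
  the nematic lies perpendicular to it.  A contact lost and regained
  along the same axis therefore sums to the zero tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .nematic import Nematic
from .network import CellHistoryRecord, CellNetwork, DisappearsBy

__all__ = [
    "LineageForest",
    "ContactChange",
    "DivisionEvent",
    "build_lineage",
    "detect_contact_changes",
    "division_nematic",
    "t1_nematic",
    "event_rates",
    "cell_cycle_lengths",
]


@dataclass
class ContactChange:
    frame: int        # first frame of the pair (event between frame, frame+1)
    cell_a: int
    cell_b: int
    kind: str         # "gain" | "loss"
    nematic: Nematic
    position: tuple[float, float]  # midpoint of the two cell centers


@dataclass
class DivisionEvent:
    frame: int        # frame in which the daughters first appear
    mother: int
    daughter1: int
    daughter2: int
    nematic: Nematic
    position: tuple[float, float]  # center of combined daughter mass


class LineageForest:
    """Directed division forest with lineage groups and generations.

    Roots are the founder cells (generation 0); each division adds the
    two daughters one generation below their mother, and every connected
    component is one lineage group.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        if not nx.is_forest(graph.to_undirected(as_view=True)):
            raise ValueError("lineage graph contains a cycle or a double mother")
        for n in graph.nodes:
            if graph.in_degree(n) > 1:
                raise ValueError(f"cell {n} has more than one mother")
        self.generation: dict[int, int] = {}
        self.lineage_group: dict[int, int] = {}
        roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
        for group, root in enumerate(sorted(roots)):
            for cell, depth in nx.single_source_shortest_path_length(
                graph, root
            ).items():
                self.generation[cell] = depth
                self.lineage_group[cell] = group

    def daughters(self, cell: int) -> list[int]:
        return sorted(self.graph.successors(cell))

    def mother(self, cell: int) -> Optional[int]:
        pred = list(self.graph.predecessors(cell))
        return pred[0] if pred else None

    def ancestors(self, cell: int) -> set[int]:
        return nx.ancestors(self.graph, cell)

    def descendants(self, cell: int) -> set[int]:
        return nx.descendants(self.graph, cell)

    def group_members(self, cell: int) -> set[int]:
        g = self.lineage_group[cell]
        return {c for c, gg in self.lineage_group.items() if gg == g}

    def annotate(self, histories: dict[int, CellHistoryRecord]) -> None:
        """Write lineage_group and generation back onto history records."""
        for c, h in histories.items():
            h.lineage_group = self.lineage_group.get(c, -1)
            h.generation = self.generation.get(c, 0)


def build_lineage(histories: dict[int, CellHistoryRecord]) -> LineageForest:
    """Pool the mother-daughter links into a directed lineage forest."""
    g = nx.DiGraph()
    g.add_nodes_from(histories)
    for h in histories.values():
        if h.disappears_by == DisappearsBy.DIVISION:
            for d in (h.left_daughter_cell_id, h.right_daughter_cell_id):
                if d is not None:
                    g.add_edge(h.cell_id, d)
    return LineageForest(g)


# -------------------------------------------------------------------------- #
# unit nematics
# -------------------------------------------------------------------------- #
def _axis_nematic(p: np.ndarray, q: np.ndarray) -> Nematic:
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if not d.any():
        raise ValueError("coincident cell centers define no axis")
    phi = math.atan2(d[1], d[0])
    return Nematic(math.cos(2 * phi), math.sin(2 * phi))


def division_nematic(d1_center, d2_center) -> Nematic:
    """Unit nematic along the line connecting the two daughter centers."""
    return _axis_nematic(d1_center, d2_center)


def t1_nematic(center_a, center_b, kind: str) -> Nematic:
    """Unit nematic of a half-T1.

    ``kind="loss"`` points along the axis connecting the separating cell
    centers; ``kind="gain"`` is the negative of the connecting-axis
    nematic, i.e. perpendicular to it.
    """
    n = _axis_nematic(center_a, center_b)
    if kind == "loss":
        return n
    if kind == "gain":
        return -n
    raise ValueError(f"kind must be 'gain' or 'loss', got {kind!r}")


# -------------------------------------------------------------------------- #
# neighbor-exchange detection
# -------------------------------------------------------------------------- #
def _division_mask(
    histories: dict[int, CellHistoryRecord], frame: int
) -> dict[int, int]:
    """Map daughter -> mother for divisions whose daughters appear at frame+1."""
    mapping = {}
    for h in histories.values():
        if h.disappears_by == DisappearsBy.DIVISION and h.last_frame == frame:
            mapping[h.left_daughter_cell_id] = h.cell_id
            mapping[h.right_daughter_cell_id] = h.cell_id
    return mapping


def detect_contact_changes(
    net_f: CellNetwork,
    net_f1: CellNetwork,
    histories: dict[int, CellHistoryRecord],
) -> list[ContactChange]:
    """Half-T1 events between two consecutive frames.

    Neighbor-set differences are computed after masking divisions
    (daughters fused under the mother id) and after discarding any pair
    in which either id is not present in both frames.  Loss nematics use
    the centers in the first frame (where the contact still exists),
    gain nematics the centers in the second.
    """
    if net_f1.frame != net_f.frame + 1:
        raise ValueError("frames must be consecutive")
    mask = _division_mask(histories, net_f.frame)

    def neighbor_pairs(net: CellNetwork, apply_mask: bool) -> set[frozenset[int]]:
        pairs = set()
        for c in net.cell_ids:
            cm = mask.get(c, c) if apply_mask else c
            for n in net.neighbors(c):
                nm = mask.get(n, n) if apply_mask else n
                if cm != nm:
                    pairs.add(frozenset((cm, nm)))
        return pairs

    pairs_f = neighbor_pairs(net_f, apply_mask=False)
    pairs_f1 = neighbor_pairs(net_f1, apply_mask=True)
    cells_f = set(net_f.cell_ids)
    cells_f1 = {mask.get(c, c) for c in net_f1.cell_ids}
    alive_both = cells_f & cells_f1

    out: list[ContactChange] = []
    for pair in sorted(pairs_f - pairs_f1, key=sorted):
        a, b = sorted(pair)
        if a in alive_both and b in alive_both:
            ca, cb = np.asarray(net_f.cell_center(a)), np.asarray(net_f.cell_center(b))
            out.append(
                ContactChange(
                    net_f.frame, a, b, "loss",
                    t1_nematic(ca, cb, "loss"),
                    tuple(0.5 * (ca + cb)),
                )
            )
    def center_f1(c: int) -> np.ndarray:
        # a masked mother's position at f+1 is the combined daughter center
        if c in net_f1.cell_ids:
            return np.asarray(net_f1.cell_center(c))
        daughters = [d for d, m in mask.items() if m == c and d in net_f1.cell_ids]
        ws = [net_f1.cell_area(d) for d in daughters]
        ps = [np.asarray(net_f1.cell_center(d)) for d in daughters]
        return np.average(ps, axis=0, weights=ws)

    for pair in sorted(pairs_f1 - pairs_f, key=sorted):
        a, b = sorted(pair)
        if a in alive_both and b in alive_both:
            ca, cb = center_f1(a), center_f1(b)
            out.append(
                ContactChange(
                    net_f.frame, a, b, "gain",
                    t1_nematic(ca, cb, "gain"),
                    tuple(0.5 * (ca + cb)),
                )
            )
    return out


def division_events(
    movie_networks: Sequence[CellNetwork],
    histories: dict[int, CellHistoryRecord],
) -> list[DivisionEvent]:
    """One oriented event per division, positioned at the combined daughter mass."""
    nets = {net.frame: net for net in movie_networks}
    out = []
    for h in histories.values():
        if h.disappears_by != DisappearsBy.DIVISION:
            continue
        f1 = h.last_frame + 1
        net = nets.get(f1)
        if net is None:
            continue
        d1, d2 = h.left_daughter_cell_id, h.right_daughter_cell_id
        c1, c2 = np.asarray(net.cell_center(d1)), np.asarray(net.cell_center(d2))
        a1, a2 = net.cell_area(d1), net.cell_area(d2)
        pos = tuple((a1 * c1 + a2 * c2) / (a1 + a2))
        out.append(
            DivisionEvent(f1, h.cell_id, d1, d2, division_nematic(c1, c2), pos)
        )
    return sorted(out, key=lambda e: (e.frame, e.mother))


# -------------------------------------------------------------------------- #
# rates
# -------------------------------------------------------------------------- #
def event_rates(
    event_frames: Sequence[int],
    roi_counts: dict[int, int],
    times_sec: Sequence[float],
    bin_hours: float = 1.0,
) -> pd.DataFrame:
    """Events per cell per hour in discrete time bins.

    Parameters
    ----------
    event_frames:
        Frame index of each event (for frame-pair events, the first frame
        of the pair).  Events in the movie's first or last frame are kept
        by the caller's choice; this function only bins.
    roi_counts:
        Number of ROI cells per frame (the per-bin mean is the
        denominator).
    times_sec:
        Cumulative time per frame, seconds.
    bin_hours:
        Bin width in hours.

    Returns a frame with ``t_mid_hours, n_events, mean_cells, rate``
    (events per cell per hour); bins with no ROI cells get ``NaN``.
    """
    times_h = np.asarray(times_sec) / 3600.0
    t0 = times_h[0]
    frame_bin = ((times_h - t0) / bin_hours).astype(int)
    n_bins = int(frame_bin.max()) + 1
    rows = []
    ev_bins = [frame_bin[f] for f in event_frames]
    for b in range(n_bins):
        frames_in = [f for f in range(len(times_h)) if frame_bin[f] == b]
        counts = [roi_counts.get(f, 0) for f in frames_in]
        mean_cells = float(np.mean(counts)) if counts else 0.0
        n_ev = sum(1 for eb in ev_bins if eb == b)
        rate = (
            n_ev / mean_cells / bin_hours if mean_cells > 0 else float("nan")
        )
        rows.append(
            {
                "t_mid_hours": t0 + (b + 0.5) * bin_hours,
                "n_events": n_ev,
                "mean_cells": mean_cells,
                "rate": rate,
            }
        )
    return pd.DataFrame(rows)


def cell_cycle_lengths(
    histories: dict[int, CellHistoryRecord], times_sec: Sequence[float]
) -> tuple[float, float, list[float]]:
    """Median and MAD of mother-birth to mother-division intervals (hours).

    Only cells that themselves appeared by division and later divided
    contribute (the interval between two consecutive division rounds in
    one lineage).  Returns ``(median, median_absolute_deviation, all)``.
    """
    from .network import AppearsBy

    times_h = np.asarray(times_sec) / 3600.0
    spans = []
    for h in histories.values():
        if (
            h.appears_by == AppearsBy.DIVISION
            and h.disappears_by == DisappearsBy.DIVISION
        ):
            spans.append(float(times_h[h.last_frame] - times_h[h.first_frame]))
    if not spans:
        return float("nan"), float("nan"), []
    med = float(np.median(spans))
    mad = float(np.median(np.abs(np.asarray(spans) - med)))
    return med, mad, spans
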