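"""Half-edge representation of one frame of a tracked cell network.

A frame is modelled as a planar cell complex: *cells* bounded by *bonds*
(cell-cell interfaces) that meet at *vertices*.  Topology is stored as
*directed bonds*: each interface is owned twice, once by each adjacent
cell, ordered counter-clockwise along the owning cell's contour.  Every
directed bond knows its *conjugate* (the same interface seen from the
neighbouring cell) and its *left* directed bond (its counter-clockwise
follower within the same cell).

The exterior is represented by a single virtual background cell with the
reserved id ``BACKGROUND = 0`` which owns the outward-facing conjugate of
every margin bond, so the conjugate map is a total involution and margin
cells are exactly the cells adjacent to cell 0.

Orientation convention: "counter-clockwise" means positive shoelace area
in the numeric ``(x, y)`` frame of the input coordinates.  The same rule
is applied to vector-generated and raster-parsed data, which keeps
conjugate/left links, triangle orientation and angle signs mutually
consistent no matter whether the y axis points up (vector data) or down
(image data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from .nematic import Nematic

__all__ = [
    "BACKGROUND",
    "DBOND_STRIDE",
    "DirectedBond",
    "CellHistoryRecord",
    "AppearsBy",
    "DisappearsBy",
    "CellNetwork",
    "TopologyReport",
    "network_from_cell_polygons",
    "validate_topology",
]

BACKGROUND = 0
#: directed-bond ids are globally unique across frames: id = frame * STRIDE + n
DBOND_STRIDE = 10**9


class AppearsBy(str, Enum):
    DIVISION = "Division"
    MOVED_INTO_VIEW = "MovedIntoView"
    SEGMENTATION_START = "SegmentationStart"


class DisappearsBy(str, Enum):
    DIVISION = "Division"
    EXTRUSION = "Apoptosis/Extrusion"
    MOVED_OUT_OF_VIEW = "MovedOutOfView"
    SEGMENTATION_END = "SegmentationEnd"


@dataclass
class DirectedBond:
    dbond_id: int
    frame: int
    cell_id: int
    conj_dbond_id: int
    left_dbond_id: int
    bond_id: int
    vertex_id: int  # the vertex this directed bond leaves from


@dataclass
class CellHistoryRecord:
    cell_id: int
    first_frame: int
    last_frame: int
    appears_by: AppearsBy = AppearsBy.SEGMENTATION_START
    disappears_by: DisappearsBy = DisappearsBy.SEGMENTATION_END
    left_daughter_cell_id: Optional[int] = None
    right_daughter_cell_id: Optional[int] = None
    lineage_group: int = -1
    generation: int = 0

    def __post_init__(self) -> None:
        has_both = (
            self.left_daughter_cell_id is not None
            and self.right_daughter_cell_id is not None
        )
        if (self.disappears_by == DisappearsBy.DIVISION) != has_both:
            raise ValueError(
                f"cell {self.cell_id}: disappears_by=Division requires exactly "
                "two daughter ids (and vice versa)"
            )


class CellNetwork:
    """One frame's vectorized junctional network.

    Parameters
    ----------
    frame:
        Frame index.
    vertex_positions:
        ``{vertex_id: (x, y)}`` in frame coordinates.
    dbonds:
        ``{dbond_id: DirectedBond}`` including the background cell's.
    """

    def __init__(
        self,
        frame: int,
        vertex_positions: dict[int, tuple[float, float]],
        dbonds: dict[int, DirectedBond],
    ) -> None:
        self.frame = frame
        self.vertex_positions = vertex_positions
        self.dbonds = dbonds
        # optional pixel-based overrides written by the mask parser
        self.cell_centers: dict[int, tuple[float, float]] = {}
        self.cell_areas: dict[int, float] = {}
        self.cell_elongation: dict[int, Nematic] = {}
        self._cell_dbonds: Optional[dict[int, list[int]]] = None

    # ------------------------------------------------------------------ #
    # topology accessors
    # ------------------------------------------------------------------ #
    def _index(self) -> dict[int, list[int]]:
        if self._cell_dbonds is None:
            idx: dict[int, list[int]] = {}
            for d in self.dbonds.values():
                idx.setdefault(d.cell_id, []).append(d.dbond_id)
            self._cell_dbonds = idx
        return self._cell_dbonds

    @property
    def cell_ids(self) -> list[int]:
        """All real (non-background) cell ids in this frame."""
        return sorted(c for c in self._index() if c != BACKGROUND)

    def cell_dbond_cycle(self, cell_id: int) -> list[int]:
        """The cell's directed bonds in counter-clockwise contour order."""
        ids = self._index()[cell_id]
        start = min(ids)
        cycle = [start]
        d = self.dbonds[start].left_dbond_id
        while d != start:
            cycle.append(d)
            d = self.dbonds[d].left_dbond_id
            if len(cycle) > len(ids):
                raise RuntimeError(f"left-cycle of cell {cell_id} does not close")
        return cycle

    def cell_vertex_cycle(self, cell_id: int) -> list[int]:
        return [self.dbonds[d].vertex_id for d in self.cell_dbond_cycle(cell_id)]

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        """(n, 2) array of the cell's vertex coordinates in contour order."""
        return np.array(
            [self.vertex_positions[v] for v in self.cell_vertex_cycle(cell_id)]
        )

    def neighbors(self, cell_id: int, include_background: bool = False) -> set[int]:
        """Cells sharing at least one bond with ``cell_id``."""
        out = set()
        for d in self._index()[cell_id]:
            conj = self.dbonds[self.dbonds[d].conj_dbond_id]
            out.add(conj.cell_id)
        out.discard(cell_id)
        if not include_background:
            out.discard(BACKGROUND)
        return out

    def margin_cells(self) -> set[int]:
        """Cells adjacent to the background cell."""
        if BACKGROUND not in self._index():
            return set()
        return {
            self.dbonds[self.dbonds[d].conj_dbond_id].cell_id
            for d in self._index()[BACKGROUND]
        }

    def vertex_ids(self) -> list[int]:
        return sorted(self.vertex_positions)

    def bond_ids(self) -> list[int]:
        return sorted({d.bond_id for d in self.dbonds.values()})

    def bond_length(self, bond_id: int) -> float:
        for d in self.dbonds.values():
            if d.bond_id == bond_id:
                a = np.asarray(self.vertex_positions[d.vertex_id])
                head = self.dbonds[d.left_dbond_id].vertex_id
                b = np.asarray(self.vertex_positions[head])
                return float(np.linalg.norm(b - a))
        raise KeyError(bond_id)

    def vertex_cells(self, vertex_id: int) -> list[int]:
        """Cells incident to a vertex (background included), in cyclic order.

        The cyclic order follows the counter-clockwise order of the
        outgoing directed bonds around the vertex.
        """
        pos = np.asarray(self.vertex_positions[vertex_id])
        out = []
        for d in self.dbonds.values():
            if d.vertex_id == vertex_id:
                head = self.dbonds[d.left_dbond_id].vertex_id
                vec = np.asarray(self.vertex_positions[head]) - pos
                ang = math.atan2(vec[1], vec[0])
                out.append((ang, d.cell_id))
        out.sort()
        return [c for _, c in out]

    # ------------------------------------------------------------------ #
    # geometry helpers (polygon path; the mask parser overrides these
    # with pixel-based values)
    # ------------------------------------------------------------------ #
    def cell_area(self, cell_id: int) -> float:
        if cell_id in self.cell_areas:
            return self.cell_areas[cell_id]
        return abs(_shoelace(self.cell_polygon(cell_id)))

    def cell_center(self, cell_id: int) -> tuple[float, float]:
        if cell_id in self.cell_centers:
            return self.cell_centers[cell_id]
        return _polygon_centroid(self.cell_polygon(cell_id))


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def _polygon_centroid(poly: np.ndarray) -> tuple[float, float]:
    a = _shoelace(poly)
    if a == 0.0:
        raise ValueError("zero-area polygon has no centroid")
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return (cx, cy)


# ---------------------------------------------------------------------- #
# construction from per-cell vertex cycles
# ---------------------------------------------------------------------- #
def network_from_cell_polygons(
    cell_cycles: dict[int, list[int]],
    vertex_positions: dict[int, tuple[float, float]],
    frame: int = 0,
) -> CellNetwork:
    """Build a :class:`CellNetwork` from per-cell vertex cycles.

    ``cell_cycles`` maps every real cell id to the ordered list of its
    boundary vertex ids.  Cycles may be given in either orientation; they
    are normalized to counter-clockwise (positive shoelace).  Unmatched
    interfaces get a conjugate owned by the background cell, whose left
    links are recovered from the planar embedding (next edge around the
    exterior face = the counter-clockwise predecessor of the conjugate in
    the angular order of outgoing bonds at the head vertex).
    """
    if BACKGROUND in cell_cycles:
        raise ValueError("cell id 0 is reserved for the background cell")
    next_id = frame * DBOND_STRIDE + 1
    dbonds: dict[int, DirectedBond] = {}
    heads: dict[int, int] = {}  # dbond -> head vertex
    by_pair: dict[tuple[int, int], list[int]] = {}

    for cell_id, cycle in cell_cycles.items():
        if len(cycle) == 0:
            raise ValueError(f"cell {cell_id}: empty vertex cycle")
        if len(cycle) >= 3:
            poly = np.array([vertex_positions[v] for v in cycle])
            if _shoelace(poly) < 0:
                cycle = cycle[::-1]
        ids = []
        n = len(cycle)
        for i, v in enumerate(cycle):
            head = cycle[(i + 1) % n]
            d = DirectedBond(next_id, frame, cell_id, -1, -1, -1, v)
            dbonds[next_id] = d
            heads[next_id] = head
            by_pair.setdefault((v, head), []).append(next_id)
            ids.append(next_id)
            next_id += 1
        for i, did in enumerate(ids):
            dbonds[did].left_dbond_id = ids[(i + 1) % n]

    # conjugate matching
    for (a, b), lst in by_pair.items():
        if a == b:
            # self-loop interface (enclosed cell); pair the two loop dbonds
            while len(lst) >= 2:
                d1, d2 = lst.pop(), lst.pop()
                dbonds[d1].conj_dbond_id = d2
                dbonds[d2].conj_dbond_id = d1
            continue
        rev = by_pair.get((b, a), [])
        while lst and rev:
            d1, d2 = lst.pop(), rev.pop()
            dbonds[d1].conj_dbond_id = d2
            dbonds[d2].conj_dbond_id = d1

    # background conjugates for unmatched dbonds
    bg_ids = []
    for did in list(dbonds):
        d = dbonds[did]
        if d.conj_dbond_id == -1:
            g = DirectedBond(next_id, frame, BACKGROUND, did, -1, -1, heads[did])
            dbonds[next_id] = g
            heads[next_id] = d.vertex_id
            d.conj_dbond_id = next_id
            bg_ids.append(next_id)
            next_id += 1

    # left links of the background cell via the planar rotation rule
    if bg_ids:
        outgoing: dict[int, list[tuple[float, int]]] = {}
        for did, d in dbonds.items():
            v = d.vertex_id
            p = vertex_positions[v]
            q = vertex_positions[heads[did]]
            ang = math.atan2(q[1] - p[1], q[0] - p[0])
            outgoing.setdefault(v, []).append((ang, did))
        for v in outgoing:
            outgoing[v].sort()
        for g in bg_ids:
            head = heads[g]
            conj = dbonds[g].conj_dbond_id
            order = [did for _, did in outgoing[head]]
            if len(order) == 1:
                # dead-end vertex (self-loop contour): follower is itself
                dbonds[g].left_dbond_id = g if order[0] == conj else order[0]
                continue
            i = order.index(conj)
            # CCW predecessor of the conjugate at the head vertex
            nxt = order[i - 1]
            dbonds[g].left_dbond_id = nxt

    # handle lone self-loop cells (single-vertex cycles): left = itself
    for did, d in dbonds.items():
        if d.left_dbond_id == -1:
            d.left_dbond_id = did

    # bond ids: one per conjugate pair
    bond_counter = frame * DBOND_STRIDE + 1
    for did in sorted(dbonds):
        d = dbonds[did]
        if d.bond_id == -1:
            d.bond_id = bond_counter
            dbonds[d.conj_dbond_id].bond_id = bond_counter
            bond_counter += 1

    return CellNetwork(frame, dict(vertex_positions), dbonds)


# ---------------------------------------------------------------------- #
# validation
# ---------------------------------------------------------------------- #
@dataclass
class TopologyReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "OK" if self.ok else "\n".join(self.violations)


def validate_topology(net: CellNetwork) -> TopologyReport:
    """Check the structural invariants of a cell network.

    Reported violations (never raises):

    * conjugate involution ``conj(conj(d)) == d`` and ``conj(d) != d``;
    * the conjugate belongs to a different cell (or the background);
    * the left links of every real cell form a single closed cycle;
    * every bond is referenced by exactly two directed bonds;
    * Euler relation ``#vertices - #bonds + #cells == 1`` for a
      simply-connected patch (background excluded);
    * conjugate bonds connect the same vertex pair in opposite order.
    """
    rep = TopologyReport()
    for did, d in net.dbonds.items():
        c = net.dbonds.get(d.conj_dbond_id)
        if c is None:
            rep.violations.append(f"dbond {did}: dangling conjugate {d.conj_dbond_id}")
            continue
        if c.conj_dbond_id != did:
            rep.violations.append(f"dbond {did}: conjugate involution broken")
        if d.conj_dbond_id == did:
            rep.violations.append(f"dbond {did}: is its own conjugate")
        if c.cell_id == d.cell_id and d.cell_id != BACKGROUND:
            rep.violations.append(f"dbond {did}: conjugate within the same cell")

    idx: dict[int, list[int]] = {}
    for d in net.dbonds.values():
        idx.setdefault(d.cell_id, []).append(d.dbond_id)
    for cell_id, ids in idx.items():
        if cell_id == BACKGROUND:
            continue
        start = ids[0]
        seen = {start}
        d = net.dbonds[start].left_dbond_id
        while d != start and len(seen) <= len(ids):
            if net.dbonds[d].cell_id != cell_id:
                rep.violations.append(
                    f"cell {cell_id}: left link leaves the cell at dbond {d}"
                )
                break
            seen.add(d)
            d = net.dbonds[d].left_dbond_id
        if len(seen) != len(ids):
            rep.violations.append(
                f"cell {cell_id}: left links do not form a single closed cycle"
            )

    bond_refs: dict[int, int] = {}
    for d in net.dbonds.values():
        bond_refs[d.bond_id] = bond_refs.get(d.bond_id, 0) + 1
    for bond_id, n in bond_refs.items():
        if n != 2:
            rep.violations.append(f"bond {bond_id}: referenced by {n} directed bonds")

    # conjugates connect the same vertex pair, reversed
    for did, d in net.dbonds.items():
        c = net.dbonds.get(d.conj_dbond_id)
        if c is None or c.conj_dbond_id != did:
            continue
        head_d = net.dbonds[d.left_dbond_id].vertex_id
        head_c = net.dbonds[c.left_dbond_id].vertex_id
        # self-consistent only when left links are intact
        if (
            net.dbonds[d.left_dbond_id].cell_id == d.cell_id
            and net.dbonds[c.left_dbond_id].cell_id == c.cell_id
        ):
            if not (c.vertex_id == head_d and head_c == d.vertex_id):
                rep.violations.append(
                    f"dbond {did}: conjugate endpoints mismatch"
                )

    n_v = len(net.vertex_positions)
    n_b = len(bond_refs)
    n_c = len([c for c in idx if c != BACKGROUND])
    if n_v - n_b + n_c != 1:
        rep.violations.append(
            f"Euler relation violated: {n_v} - {n_b} + {n_c} = {n_v - n_b + n_c} != 1"
        )
    return rep
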