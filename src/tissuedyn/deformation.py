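"""Triangle method: exact decomposition of tissue deformation.

The junctional network is tiled with triangles, one per interior
three-fold vertex, whose corners are the centers of the three incident
cells (a k-fold vertex contributes k - 2 fan triangles).  Because the
triangles tile the tissue, tissue deformation between two frames is the
area-weighted average of per-triangle affine deformations, and the pure
shear rate can be decomposed exactly into cellular contributions::

    V~ = DQ~/Dt + T + C + E + D

where ``Q~`` is the area-weighted mean triangle elongation, ``T``, ``C``
and ``E`` are the shear contributed by T1 transitions, divisions and
extrusions (measured by swapping the affected triangles in and out at
frozen cell positions), ``D`` collects correlation effects and closes
the identity exactly, and ``DQ~/Dt`` is the corotational derivative

    DQ~/Dt = dQ~/dt - 2 (c Omega + [1 - c] dPhi/dt) e . Q~,

with ``c = tanh(2Q) / (2Q)``, ``e`` the rotation generator, and
``Q, Phi`` the magnitude and angle of the mean elongation.  The
isotropic part obeys the analogous scalar identity: relative tissue-area
change = mean relative cell-area change + cell gain by divisions - cell
loss by extrusions.

Matrix conventions.  A triangle's shape is the linear map ``S`` sending
an area-matched reference equilateral triangle to the observed one.  We
use the left polar form ``S = exp(Q~ + ln(s) I) . R(theta)`` so that the
elongation nematic ``Q~`` lives in the laboratory frame: rotating the
observed triangle rotates ``Q~`` by the same angle.  The per-triangle
deformation between frames, ``M = D_1 D_0^{-1}`` (edge-vector matrices),
is decomposed the same way; ``ln det M`` is the isotropic part, the
symmetric-traceless part of ``ln V`` (left stretch) the pure shear, and
the polar rotation angle the vorticity.  The vorticity sign is chosen so
that a rigidly co-rotating elongation (dPhi/dt = Omega, constant
magnitude) has a vanishing corotational derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .nematic import Nematic
from .network import BACKGROUND, CellHistoryRecord, CellNetwork, DisappearsBy

__all__ = [
    "Triangle",
    "TriangleState",
    "DeformationRecord",
    "triangulate",
    "triangle_state",
    "frame_deformation",
    "categorize_triangles",
    "shear_decomposition",
    "corotational_term",
    "area_decomposition",
    "accumulate_series",
    "decompose_movie",
]

_DEGENERATE_REL_AREA = 1e-12

# unit-area equilateral reference triangle (fixed orientation; the choice
# only shifts theta, never Q~)
_SIDE = math.sqrt(4.0 / math.sqrt(3.0))
_REF = _SIDE * np.array(
    [
        [0.0, 1.0 / math.sqrt(3.0)],
        [-0.5, -0.5 / math.sqrt(3.0)],
        [0.5, -0.5 / math.sqrt(3.0)],
    ]
)
_REF_EDGES = np.column_stack([_REF[1] - _REF[0], _REF[2] - _REF[0]])
_REF_EDGES_INV = np.linalg.inv(_REF_EDGES)


@dataclass(eq=False)
class Triangle:
    frame: int
    vertex_id: int                 # generating network vertex
    cells: tuple[int, int, int]    # counter-clockwise corner cells
    coords: np.ndarray             # (3, 2) cell-center coordinates

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(sorted(self.cells))

    @property
    def edge_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.coords[1] - self.coords[0], self.coords[2] - self.coords[0]]
        )

    @property
    def area(self) -> float:
        return 0.5 * float(np.linalg.det(self.edge_matrix))


@dataclass
class TriangleState:
    area: float
    q: Nematic
    theta: float


@dataclass
class DeformationRecord:
    """Per frame pair: total deformation and its cellular contributions."""

    frame: int                     # first frame of the pair
    viso: float = 0.0              # relative area growth, 1/frame
    vtilde: Nematic = field(default_factory=Nematic)   # pure shear rate
    omega: float = 0.0             # rotation rate
    dq_dt: Nematic = field(default_factory=Nematic)    # corotational DQ~/Dt
    t1: Nematic = field(default_factory=Nematic)       # T
    division: Nematic = field(default_factory=Nematic) # C
    extrusion: Nematic = field(default_factory=Nematic)  # E
    correlation: Nematic = field(default_factory=Nematic)  # D (exact closure)
    area_total: float = 0.0        # scalar identity: ln(A_{f+1}/A_f)
    area_cell: float = 0.0
    area_division: float = 0.0
    area_extrusion: float = 0.0
    n_conserved: int = 0
    n_t1: int = 0
    n_division: int = 0
    n_extrusion: int = 0
    n_other: int = 0

    def shear_residual(self) -> Nematic:
        return self.vtilde - (
            self.dq_dt + self.t1 + self.division + self.extrusion + self.correlation
        )

    def area_residual(self) -> float:
        return self.area_total - (
            self.area_cell + self.area_division + self.area_extrusion
        )


# -------------------------------------------------------------------------- #
# 2x2 matrix helpers (closed-form left polar decomposition)
# -------------------------------------------------------------------------- #
def _left_polar(m: np.ndarray) -> tuple[float, Nematic, float]:
    """Decompose ``m = exp(q + ln(s) I) R(theta)``; returns (ln s, q, theta).

    Requires ``det m > 0``.
    """
    det = float(np.linalg.det(m))
    if det <= 0:
        raise ValueError("degenerate or orientation-reversing map")
    c = m @ m.T
    w, v = np.linalg.eigh(c)          # ascending eigenvalues of m m^T
    lam1, lam2 = math.sqrt(w[1]), math.sqrt(w[0])
    beta = math.atan2(v[1, 1], v[0, 1])  # axis of the major stretch
    ln_s = 0.5 * math.log(lam1 * lam2)
    qmag = 0.5 * math.log(lam1 / lam2)
    q = Nematic(qmag * math.cos(2 * beta), qmag * math.sin(2 * beta))
    # V^{-1} m = R(theta)
    vinv = v @ np.diag([1.0 / lam2, 1.0 / lam1]) @ v.T
    r = vinv @ m
    theta = math.atan2(r[1, 0], r[0, 0])
    return ln_s, q, theta


def triangle_state(tri: Triangle) -> TriangleState:
    """Area, elongation nematic and rotation of a triangle's shape map.

    The shape map sends the unit-area reference equilateral (scaled to
    the observed area) to the observed triangle; an equilateral triangle
    of any size and orientation has exactly zero elongation.
    """
    d = tri.edge_matrix
    if abs(np.linalg.det(d)) < _DEGENERATE_REL_AREA:
        raise ValueError("degenerate (collinear) triangle")
    s = d @ _REF_EDGES_INV
    _, q, theta = _left_polar(s)
    return TriangleState(tri.area, q, theta)


# -------------------------------------------------------------------------- #
# triangulation
# -------------------------------------------------------------------------- #
def triangulate(
    net: CellNetwork, roi: Optional[set[int]] = None
) -> list[Triangle]:
    """One triangle per interior three-fold vertex of the network.

    Vertices incident to the background produce no triangle; a k-fold
    vertex (k > 3) produces k - 2 triangles by a deterministic fan over
    the cyclically ordered incident cells starting at the lowest cell
    id.  Degenerate (collinear-center) triangles are kept in the list
    with zero area; consumers skip them in averages.  If ``roi`` is
    given, only triangles whose three cells all belong to it are
    returned.
    """
    centers = {c: np.asarray(net.cell_center(c)) for c in net.cell_ids}
    out: list[Triangle] = []
    for v in net.vertex_ids():
        cells = net.vertex_cells(v)
        if BACKGROUND in cells or len(cells) < 3:
            continue
        if len(set(cells)) != len(cells):
            continue  # pinched vertex; ambiguous, skip
        k = cells.index(min(cells))
        ring = cells[k:] + cells[:k]
        for i in range(1, len(ring) - 1):
            tri_cells = (ring[0], ring[i], ring[i + 1])
            if roi is not None and not set(tri_cells) <= roi:
                continue
            coords = np.array([centers[c] for c in tri_cells])
            e = np.column_stack([coords[1] - coords[0], coords[2] - coords[0]])
            if np.linalg.det(e) < 0:
                tri_cells = (tri_cells[0], tri_cells[2], tri_cells[1])
                coords = coords[[0, 2, 1]]
            out.append(Triangle(net.frame, v, tri_cells, coords))
    return out


# -------------------------------------------------------------------------- #
# frame-pair kinematics
# -------------------------------------------------------------------------- #
def _match(
    tris_f: Sequence[Triangle],
    tris_f1: Sequence[Triangle],
    sub: dict[int, int],
) -> tuple[list[tuple[Triangle, Triangle]], list[Triangle], list[Triangle], list[Triangle]]:
    """Match triangles across a frame pair.

    Daughter cells are substituted by their mother before matching.
    Returns (matched pairs, disappearing, appearing, division_new) where
    ``division_new`` are the f+1 triangles that collapse under daughter
    fusion (they did not exist before the division).
    """
    by_key_f: dict[tuple, list[Triangle]] = {}
    for t in tris_f:
        by_key_f.setdefault(t.key, []).append(t)
    matched: list[tuple[Triangle, Triangle]] = []
    appearing: list[Triangle] = []
    division_new: list[Triangle] = []
    for t in tris_f1:
        subbed = {sub.get(c, c) for c in t.cells}
        if len(subbed) < 3:
            division_new.append(t)
            continue
        key = tuple(sorted(subbed))
        bucket = by_key_f.get(key)
        if bucket:
            t0 = bucket.pop(0)
            # align t's corners with t0's cell order (mothers stand in
            # for their daughters in t0)
            pos = {sub.get(c, c): (c, p) for c, p in zip(t.cells, t.coords)}
            cells1 = tuple(pos[c][0] for c in t0.cells)
            coords1 = np.array([pos[c][1] for c in t0.cells])
            matched.append((t0, Triangle(t.frame, t.vertex_id, cells1, coords1)))
        else:
            appearing.append(t)
    disappearing = [t for bucket in by_key_f.values() for t in bucket]
    return matched, disappearing, appearing, division_new


def frame_deformation(
    matched: Sequence[tuple[Triangle, Triangle]],
) -> tuple[float, Nematic, float]:
    """Tissue deformation (V_iso, V~, Omega) from matched triangle pairs.

    Each pair defines an affine map between the frames; its logarithmic
    decomposition (isotropic part, symmetric-traceless part of the left
    stretch, polar rotation) is averaged weighted by the triangle area in
    the first frame.  A uniform translation gives exactly (0, 0, 0); a
    uniform map ``diag(e^s, e^-s)`` gives V~ = (s, 0).
    """
    if not matched:
        raise ValueError("no matched triangles between the two frames")
    wsum = 0.0
    viso = 0.0
    vt = Nematic()
    om = 0.0
    for t0, t1 in matched:
        a0 = t0.area
        if a0 <= _DEGENERATE_REL_AREA or t1.area <= _DEGENERATE_REL_AREA:
            continue
        d0 = t0.edge_matrix
        d1 = t1.edge_matrix  # corners pre-aligned with t0's cell order
        m = d1 @ np.linalg.inv(d0)
        ln_s, q, theta = _left_polar(m)
        viso += a0 * 2.0 * ln_s
        vt += a0 * q
        om += a0 * theta
        wsum += a0
    if wsum == 0.0:
        raise ValueError("all matched triangles are degenerate")
    return viso / wsum, vt / wsum, om / wsum


def _mean_q(tris: Iterable[Triangle]) -> tuple[Nematic, float]:
    """Area-weighted mean triangle elongation (degenerates excluded)."""
    s = Nematic()
    w = 0.0
    for t in tris:
        a = t.area
        if a <= _DEGENERATE_REL_AREA:
            continue
        s += a * triangle_state(t).q
        w += a
    if w == 0.0:
        return Nematic(), 0.0
    return s / w, w


def corotational_term(
    q0: Nematic, q1: Nematic, omega: float, dt: float = 1.0
) -> Nematic:
    """Corotational derivative of the mean elongation over one interval.

    Finite-difference evaluation of
    ``DQ~/Dt = dQ~/dt - 2 (c Omega + [1 - c] dPhi/dt) e . Q~`` with
    ``c = tanh(2Q)/(2Q)`` (``c -> 1`` as ``Q -> 0``), the angle
    difference wrapped to (-pi/2, pi/2], and ``e . Q~`` evaluated at the
    midpoint elongation.
    """
    dq = (q1 - q0) / dt
    qm = 0.5 * (q0 + q1)
    qmag = qm.norm
    if qmag < 1e-300:
        return dq
    c = math.tanh(2.0 * qmag) / (2.0 * qmag) if qmag > 1e-12 else 1.0
    if q0.norm < 1e-12 or q1.norm < 1e-12:
        # the axis of a (numerically) zero tensor is undefined; the
        # angle-rate term vanishes with Q anyway
        dphi = 0.0
        return dq - 2.0 * c * omega * Nematic(-qm.xy, qm.xx)
    dphi = q1.angle - q0.angle
    while dphi > math.pi / 2:
        dphi -= math.pi
    while dphi <= -math.pi / 2:
        dphi += math.pi
    dphi /= dt
    e_dot_q = Nematic(-qm.xy, qm.xx)
    return dq - 2.0 * (c * omega + (1.0 - c) * dphi) * e_dot_q


# -------------------------------------------------------------------------- #
# event bookkeeping
# -------------------------------------------------------------------------- #
@dataclass
class PairEvents:
    """Topological events active between one frame pair."""

    sub: dict[int, int]            # daughter -> mother
    dividing: set[int]             # mothers
    extruded: set[int]
    extruded_neighbors: dict[int, set[int]]
    lost_pairs: list[frozenset[int]]
    gained_pairs: list[frozenset[int]]

    @classmethod
    def collect(
        cls,
        net_f: CellNetwork,
        net_f1: CellNetwork,
        histories: dict[int, CellHistoryRecord],
    ) -> "PairEvents":
        from .events import detect_contact_changes

        f = net_f.frame
        sub: dict[int, int] = {}
        dividing: set[int] = set()
        extruded: set[int] = set()
        for h in histories.values():
            if h.last_frame == f and h.disappears_by == DisappearsBy.DIVISION:
                sub[h.left_daughter_cell_id] = h.cell_id
                sub[h.right_daughter_cell_id] = h.cell_id
                dividing.add(h.cell_id)
            elif h.last_frame == f and h.disappears_by == DisappearsBy.EXTRUSION:
                extruded.add(h.cell_id)
        nbrs = {c: net_f.neighbors(c) for c in extruded if c in net_f.cell_ids}
        changes = detect_contact_changes(net_f, net_f1, histories)
        lost = [frozenset((c.cell_a, c.cell_b)) for c in changes if c.kind == "loss"]
        gained = [frozenset((c.cell_a, c.cell_b)) for c in changes if c.kind == "gain"]
        return cls(sub, dividing, extruded, nbrs, lost, gained)


def categorize_triangles(
    disappearing: Sequence[Triangle],
    appearing: Sequence[Triangle],
    division_new: Sequence[Triangle],
    ev: PairEvents,
) -> dict[str, dict[str, list[Triangle]]]:
    """Assign each redrawn triangle to exactly one event class.

    Classes: ``extrusion``, ``division``, ``t1`` and ``other`` (for
    example cells entering or leaving the analysis region), with
    precedence extrusion > division > T1 for triangles touched by
    several events.
    """
    def classify(t: Triangle, side: str) -> str:
        cells = set(t.cells)
        if side == "disappearing":
            if cells & ev.extruded:
                return "extrusion"
            if cells & ev.dividing:
                return "division"
            if any(p <= cells for p in ev.lost_pairs):
                return "t1"
        else:
            for nbrs in ev.extruded_neighbors.values():
                if cells <= nbrs:
                    return "extrusion"
            if cells & set(ev.sub):
                return "division"
            if any(p <= cells for p in ev.gained_pairs):
                return "t1"
        return "other"

    out = {
        "disappearing": {"extrusion": [], "division": [], "t1": [], "other": []},
        "appearing": {"extrusion": [], "division": [], "t1": [], "other": []},
    }
    for t in disappearing:
        out["disappearing"][classify(t, "disappearing")].append(t)
    for t in appearing:
        out["appearing"][classify(t, "appearing")].append(t)
    out["appearing"]["division"].extend(division_new)
    return out


# -------------------------------------------------------------------------- #
# the decomposition itself
# -------------------------------------------------------------------------- #
def shear_decomposition(
    net_f: CellNetwork,
    net_f1: CellNetwork,
    histories: dict[int, CellHistoryRecord],
    roi_f: Optional[set[int]] = None,
) -> DeformationRecord:
    """Decompose the tissue deformation of one frame pair.

    The shear identity ``V~ = DQ~/Dt + T + C + E + D`` and the scalar
    area identity hold to numerical precision by construction: the event
    terms are measured by swapping the affected triangles in and out at
    frozen cell positions, the elongation-change term from the change of
    the area-weighted mean triangle elongation with the corotational
    correction, and the correlation term ``D`` closes the identity.
    """
    ev = PairEvents.collect(net_f, net_f1, histories)
    roi_f1: Optional[set[int]] = None
    if roi_f is not None:
        roi_f1 = {c for c in roi_f if c in net_f1.cell_ids}
        for d, m in ev.sub.items():
            if m in roi_f and d in net_f1.cell_ids:
                roi_f1.add(d)
    tris_f = triangulate(net_f, roi_f)
    tris_f1 = triangulate(net_f1, roi_f1)
    matched, disappearing, appearing, division_new = _match(tris_f, tris_f1, ev.sub)
    classes = categorize_triangles(disappearing, appearing, division_new, ev)

    rec = DeformationRecord(frame=net_f.frame)
    rec.n_conserved = len(matched)
    rec.n_t1 = len(classes["disappearing"]["t1"]) + len(classes["appearing"]["t1"])
    rec.n_division = len(classes["appearing"]["division"])
    rec.n_extrusion = len(classes["disappearing"]["extrusion"])
    rec.n_other = (
        len(classes["disappearing"]["other"]) + len(classes["appearing"]["other"])
    )

    rec.viso, rec.vtilde, rec.omega = frame_deformation(matched)

    # ---- state chain at frozen geometry -----------------------------------
    centers_f = {c: np.asarray(net_f.cell_center(c)) for c in net_f.cell_ids}

    def at_f(t: Triangle) -> Optional[Triangle]:
        """Evaluate an f+1 triangle at frame-f positions (mothers for
        daughters); None if a corner does not exist at f."""
        cells = tuple(ev.sub.get(c, c) for c in t.cells)
        if len(set(cells)) < 3 or any(c not in centers_f for c in cells):
            return None
        coords = np.array([centers_f[c] for c in cells])
        return Triangle(net_f.frame, t.vertex_id, cells, coords)

    state0 = list(tris_f)
    q0, _ = _mean_q(state0)
    state1 = [t for t in state0 if t not in classes["disappearing"]["extrusion"]]
    qb, _ = _mean_q(state1)
    rec.extrusion = -(qb - q0)
    t1_new_at_f = [x for x in map(at_f, classes["appearing"]["t1"]) if x is not None]
    state2 = [
        t for t in state1 if t not in classes["disappearing"]["t1"]
    ] + t1_new_at_f
    qc, _ = _mean_q(state2)
    rec.t1 = -(qc - qb)

    # ---- division unfusing at frame f+1 -----------------------------------
    fused_centers = _fused_centers(net_f1, ev.sub)

    def fused(t: Triangle) -> Triangle:
        coords = np.array([fused_centers.get(c, p) for c, p in zip(t.cells, t.coords)])
        return Triangle(t.frame, t.vertex_id, t.cells, coords)

    q4, _ = _mean_q(tris_f1)
    q3, _ = _mean_q(fused(t) for t in tris_f1)
    rec.division = -(q4 - q3)

    rec.dq_dt = corotational_term(q0, q4, rec.omega)
    rec.correlation = rec.vtilde - (
        rec.dq_dt + rec.t1 + rec.division + rec.extrusion
    )

    # ---- scalar area identity ---------------------------------------------
    _area_terms(rec, net_f, net_f1, ev, roi_f, roi_f1)
    return rec


def _fused_centers(
    net_f1: CellNetwork, sub: dict[int, int]
) -> dict[int, np.ndarray]:
    """Daughter cells mapped to the combined (area-weighted) daughter center."""
    by_mother: dict[int, list[int]] = {}
    for d, m in sub.items():
        if d in net_f1.cell_ids:
            by_mother.setdefault(m, []).append(d)
    out: dict[int, np.ndarray] = {}
    for m, ds in by_mother.items():
        ws = np.array([net_f1.cell_area(d) for d in ds])
        ps = np.array([net_f1.cell_center(d) for d in ds])
        combined = (ws[:, None] * ps).sum(axis=0) / ws.sum()
        for d in ds:
            out[d] = combined
    return out


def _area_terms(
    rec: DeformationRecord,
    net_f: CellNetwork,
    net_f1: CellNetwork,
    ev: PairEvents,
    roi_f: Optional[set[int]],
    roi_f1: Optional[set[int]],
) -> None:
    cells_f = set(roi_f) if roi_f is not None else set(net_f.cell_ids)
    cells_f1 = set(roi_f1) if roi_f1 is not None else set(net_f1.cell_ids)
    a_f = sum(net_f.cell_area(c) for c in cells_f)
    a_f1 = sum(net_f1.cell_area(c) for c in cells_f1)
    n_f, n_f1 = len(cells_f), len(cells_f1)
    if n_f == 0 or n_f1 == 0 or a_f <= 0 or a_f1 <= 0:
        rec.area_total = rec.area_cell = float("nan")
        rec.area_division = rec.area_extrusion = float("nan")
        return
    d = len({m for m in ev.dividing if m in cells_f})
    rec.area_total = math.log(a_f1 / a_f)
    rec.area_cell = math.log((a_f1 / n_f1) / (a_f / n_f))
    rec.area_division = math.log((n_f + d) / n_f)
    rec.area_extrusion = math.log(n_f1 / (n_f + d))


def area_decomposition(
    net_f: CellNetwork,
    net_f1: CellNetwork,
    histories: dict[int, CellHistoryRecord],
    roi_f: Optional[set[int]] = None,
) -> dict[str, float]:
    """Scalar decomposition of relative tissue-area change for one pair.

    ``total = cell + division + extrusion`` exactly (logarithmic rates):
    the division term is ``ln((N + d)/N)`` for ``d`` divisions among
    ``N`` cells (about ``+d/N``), the extrusion term is the analogous
    negative contribution, and the mean-cell-area change carries the
    rest.
    """
    rec = shear_decomposition(net_f, net_f1, histories, roi_f)
    return {
        "total": rec.area_total,
        "cell": rec.area_cell,
        "division": rec.area_division,
        "extrusion": rec.area_extrusion,
    }


# -------------------------------------------------------------------------- #
# series
# -------------------------------------------------------------------------- #
_NEMATIC_COLS = ("vtilde", "dq_dt", "t1", "division", "extrusion", "correlation")
_SCALAR_COLS = ("viso", "omega", "area_total", "area_cell", "area_division",
                "area_extrusion")


def records_to_frame(records: Sequence[DeformationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, float] = {"frame": r.frame}
        for col in _SCALAR_COLS:
            row[col] = getattr(r, col)
        for col in _NEMATIC_COLS:
            n: Nematic = getattr(r, col)
            row[f"{col}_xx"] = n.xx
            row[f"{col}_xy"] = n.xy
        for col in ("n_conserved", "n_t1", "n_division", "n_extrusion", "n_other"):
            row[col] = getattr(r, col)
        rows.append(row)
    return pd.DataFrame(rows)


def accumulate_series(records: Sequence[DeformationRecord]) -> pd.DataFrame:
    """Cumulative sums of every deformation term over contiguous pairs.

    Frame pairs must be contiguous; a gap raises.  Positive accumulated
    ``vtilde_xx`` means net extension along the x axis.
    """
    frames = [r.frame for r in records]
    if any(b != a + 1 for a, b in zip(frames, frames[1:])):
        raise ValueError("gap in the frame-pair series")
    df = records_to_frame(records)
    out = df[["frame"]].copy()
    for col in df.columns:
        if col == "frame" or col.startswith("n_"):
            continue
        out[f"cum_{col}"] = df[col].cumsum()
    return out


def decompose_movie(
    networks: Sequence[CellNetwork],
    histories: dict[int, CellHistoryRecord],
    roi: Optional[dict[int, set[int]]] = None,
) -> list[DeformationRecord]:
    """Shear/area decomposition for every consecutive frame pair."""
    records = []
    for net_f, net_f1 in zip(networks, networks[1:]):
        roi_f = roi.get(net_f.frame) if roi is not None else None
        records.append(shear_decomposition(net_f, net_f1, histories, roi_f))
    return records
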