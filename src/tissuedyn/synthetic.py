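"""Ground-truth synthetic movies: hexagonal sheets under imposed deformation.

The generator produces tracked vector movies (sequences of
:class:`~tissuedyn.network.CellNetwork` with known histories) and,
optionally, rasterized label images in the same format the mask parser
consumes.  Deformations are purely kinematic: every vertex is mapped by a
per-frame 2x2 deformation gradient, so the imposed tissue deformation
rates are known exactly and can be compared with what the analysis
pipeline measures.

Presets follow the validation conditions used throughout the package:
a constant isotropic expansion rate of 3.50e-2 per frame (area growth,
per-frame gradient ``exp(g/2) * I``) and a constant pure shear rate of
1.75e-2 per frame along x (per-frame gradient ``diag(e^s, e^-s)``,
area-preserving).  Topological events (T1s, divisions, extrusions) can be
scripted between chosen frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .network import (
    BACKGROUND,
    AppearsBy,
    CellHistoryRecord,
    CellNetwork,
    DisappearsBy,
    network_from_cell_polygons,
)

__all__ = [
    "DeformationScript",
    "ScriptedEvent",
    "VectorMovie",
    "make_hex_sheet",
    "apply_deformation_series",
    "script_topological_events",
    "rasterize_labels",
    "write_movie",
    "ISO_EXPANSION_RATE",
    "PURE_SHEAR_RATE",
]

#: validation-movie rates (per frame)
ISO_EXPANSION_RATE = 3.50e-2
PURE_SHEAR_RATE = 1.75e-2


@dataclass
class DeformationScript:
    """Per-frame 2x2 deformation gradients applied between frames.

    ``gradients[k]`` maps frame ``k`` coordinates to frame ``k + 1``
    coordinates; a script with ``n`` gradients yields ``n + 1`` frames.
    """

    gradients: list[np.ndarray]

    def __post_init__(self) -> None:
        for i, g in enumerate(self.gradients):
            g = np.asarray(g, dtype=float)
            if g.shape != (2, 2) or np.linalg.det(g) <= 0:
                raise ValueError(f"gradient {i} must be 2x2 with positive determinant")
            self.gradients[i] = g

    @property
    def n_frames(self) -> int:
        return len(self.gradients) + 1

    @classmethod
    def identity(cls, n_frames: int) -> "DeformationScript":
        return cls([np.eye(2) for _ in range(n_frames - 1)])

    @classmethod
    def isotropic(cls, rate: float = ISO_EXPANSION_RATE, n_frames: int = 21) -> "DeformationScript":
        """Constant relative area growth ``rate`` per frame (no shear)."""
        f = math.exp(rate / 2.0) * np.eye(2)
        return cls([f.copy() for _ in range(n_frames - 1)])

    @classmethod
    def pure_shear(cls, rate: float = PURE_SHEAR_RATE, n_frames: int = 21) -> "DeformationScript":
        """Area-preserving stretch ``e^rate`` along x, ``e^-rate`` along y."""
        f = np.diag([math.exp(rate), math.exp(-rate)])
        return cls([f.copy() for _ in range(n_frames - 1)])

    @classmethod
    def rotation(cls, omega: float, n_frames: int) -> "DeformationScript":
        """Rigid rotation by ``omega`` radians per frame (counter-clockwise)."""
        c, s = math.cos(omega), math.sin(omega)
        f = np.array([[c, -s], [s, c]])
        return cls([f.copy() for _ in range(n_frames - 1)])


@dataclass
class ScriptedEvent:
    """One scripted topological event, applied between ``frame`` and ``frame + 1``.

    kind:
        ``"t1"`` needs ``cells = (a, b)`` (the pair losing contact);
        ``"division"`` needs ``cells = (mother,)`` and ``orientation`` (the
        axis, in radians, along which the daughter centers separate);
        ``"extrusion"`` needs ``cells = (cell,)``.
    """

    frame: int
    kind: str
    cells: tuple[int, ...]
    orientation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("t1", "division", "extrusion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "division" and self.orientation is None:
            raise ValueError("a scripted division needs an orientation")


@dataclass
class VectorMovie:
    """A generated movie: one network per frame plus ground-truth histories."""

    networks: list[CellNetwork]
    histories: dict[int, CellHistoryRecord]
    dt_sec: float = 1.0
    events: list[ScriptedEvent] = field(default_factory=list)
    # kept so events can be re-scripted on the same base movie
    base_net: Optional[CellNetwork] = None
    script: Optional[DeformationScript] = None
    jitter_sigma: float = 0.0
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return len(self.networks)

    @property
    def times_sec(self) -> list[float]:
        return [k * self.dt_sec for k in range(self.n_frames)]

    def divisions(self) -> list[tuple[int, int, int, int]]:
        """(first daughter frame, mother, daughter1, daughter2) tuples."""
        out = []
        for h in self.histories.values():
            if h.disappears_by == DisappearsBy.DIVISION:
                out.append(
                    (h.last_frame + 1, h.cell_id,
                     h.left_daughter_cell_id, h.right_daughter_cell_id)
                )
        return sorted(out)


# ---------------------------------------------------------------------- #
# hexagonal sheet
# ---------------------------------------------------------------------- #
def make_hex_sheet(rows: int, cols: int, edge_length: float = 1.0) -> CellNetwork:
    """A regular pointy-top hexagonal lattice of ``rows x cols`` cells.

    Interior cells have six neighbours and exactly zero elongation.  Cell
    ids start at 1 (0 is the background).  Coordinates are y-up with the
    lattice in the positive quadrant.
    """
    if rows < 3 or cols < 3:
        raise ValueError("need at least a 3x3 sheet")
    a = edge_length
    sx = math.sqrt(3.0) / 2.0 * a  # horizontal vertex-lattice pitch
    sy = 0.5 * a                   # vertical vertex-lattice pitch
    vertex_ids: dict[tuple[int, int], int] = {}
    positions: dict[int, tuple[float, float]] = {}
    cycles: dict[int, list[int]] = {}
    # pointy-top hexagon: vertices at 30 + 60 k degrees... use 90 + 60 k
    angles = [math.radians(90 + 60 * k) for k in range(6)]
    cell_id = 1
    for i in range(rows):
        for j in range(cols):
            cx = (2 * j + (i % 2)) * sx + 2 * sx
            cy = 1.5 * a * i + 2 * sy
            cyc = []
            for ang in angles:
                x = cx + a * math.cos(ang)
                y = cy + a * math.sin(ang)
                key = (round(x / sx), round(y / sy))
                if key not in vertex_ids:
                    vid = len(vertex_ids) + 1
                    vertex_ids[key] = vid
                    positions[vid] = (key[0] * sx, key[1] * sy)
                cyc.append(vertex_ids[key])
            cycles[cell_id] = cyc
            cell_id += 1
    return network_from_cell_polygons(cycles, positions, frame=0)


# ---------------------------------------------------------------------- #
# movie generation
# ---------------------------------------------------------------------- #
def _extract_cycles(net: CellNetwork) -> tuple[dict[int, list[int]], dict[int, tuple[float, float]]]:
    cycles = {c: net.cell_vertex_cycle(c) for c in net.cell_ids}
    return cycles, dict(net.vertex_positions)


def _centroid(cycle: Sequence[int], pos: dict[int, tuple[float, float]]) -> np.ndarray:
    poly = np.array([pos[v] for v in cycle])
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    return np.array([cx, cy])


def _poly_area(cycle: Sequence[int], pos: dict[int, tuple[float, float]]) -> float:
    poly = np.array([pos[v] for v in cycle])
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _replace_run(cycle: list[int], run: list[int], repl: list[int]) -> list[int]:
    """Replace the consecutive (cyclic) run ``run`` in ``cycle`` by ``repl``."""
    n = len(cycle)
    for start in range(n):
        if [cycle[(start + k) % n] for k in range(len(run))] == run:
            doubled = cycle + cycle
            rest = doubled[start + len(run): start + n]
            return repl + rest
    raise ValueError(f"run {run} not found in cycle {cycle}")


def _apply_t1(
    cycles: dict[int, list[int]],
    pos: dict[int, tuple[float, float]],
    a: int,
    b: int,
    next_vid: int,
    gap: float,
) -> int:
    """Collapse the a-b interface and re-expand it perpendicular."""
    ca, cb = cycles[a], cycles[b]
    shared = None
    n = len(ca)
    for i in range(n):
        v1, v2 = ca[i], ca[(i + 1) % n]
        for j in range(len(cb)):
            if cb[j] == v2 and cb[(j + 1) % len(cb)] == v1:
                shared = (v1, v2)
                break
        if shared:
            break
    if shared is None:
        raise ValueError(f"cells {a} and {b} share no bond")
    v1, v2 = shared
    p1, p2 = np.asarray(pos[v1]), np.asarray(pos[v2])
    m = 0.5 * (p1 + p2)
    u = p2 - p1
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    wa_id, wb_id = next_vid, next_vid + 1
    # put the vertex kept by cell a on a's side of the old interface
    side = np.sign(np.dot(_centroid(ca, pos) - m, perp)) or 1.0
    pos[wa_id] = tuple(m + 0.5 * gap * side * perp)
    pos[wb_id] = tuple(m - 0.5 * gap * side * perp)

    cycles[a] = _replace_run(ca, [v1, v2], [wa_id])
    cycles[b] = _replace_run(cb, [v2, v1], [wb_id])
    # the two end cells gain the new interface
    for vend in (v1, v2):
        owner = [c for c, cyc in cycles.items() if c not in (a, b) and vend in cyc]
        if not owner:
            continue  # the end vertex belongs to the background
        (c,) = owner
        for repl in ([wa_id, wb_id], [wb_id, wa_id]):
            cand = _replace_run(cycles[c], [vend], repl)
            if _poly_area(cand, pos) > 0 and not _self_intersects(cand, pos):
                cycles[c] = cand
                break
        else:
            raise RuntimeError(f"T1 surgery failed for end cell {c}")
    del pos[v1], pos[v2]
    return next_vid + 2


def _self_intersects(cycle: Sequence[int], pos: dict[int, tuple[float, float]]) -> bool:
    from shapely.geometry import Polygon

    return not Polygon([pos[v] for v in cycle]).is_valid


def _apply_division(
    cycles: dict[int, list[int]],
    pos: dict[int, tuple[float, float]],
    mother: int,
    axis: float,
    next_vid: int,
    next_cid: int,
) -> tuple[int, int, int, int]:
    """Split ``mother`` by a line through its centre perpendicular to ``axis``.

    ``axis`` is the direction along which the daughter centres separate,
    so the cut line is at ``axis + pi/2``.
    """
    cyc = cycles[mother]
    c0 = _centroid(cyc, pos)
    cut = np.array([math.cos(axis + math.pi / 2), math.sin(axis + math.pi / 2)])
    nrm = np.array([-cut[1], cut[0]])  # points along the separation axis

    def sd(v: int) -> float:
        return float(np.dot(np.asarray(pos[v]) - c0, nrm))

    n = len(cyc)
    crossings = []
    for i in range(n):
        v1, v2 = cyc[i], cyc[(i + 1) % n]
        s1, s2 = sd(v1), sd(v2)
        if s1 == 0.0 or s2 == 0.0:
            raise ValueError("division cut passes through a vertex; shift the axis")
        if s1 * s2 < 0:
            t = s1 / (s1 - s2)
            p = (1 - t) * np.asarray(pos[v1]) + t * np.asarray(pos[v2])
            crossings.append((i, tuple(p)))
    if len(crossings) != 2:
        raise ValueError(f"division cut crosses cell {mother} {len(crossings)} times")

    (i1, q1), (i2, q2) = crossings
    w1, w2 = next_vid, next_vid + 1
    pos[w1], pos[w2] = q1, q2
    # split the cycle: arc from i1+1..i2 plus w2..w1, and the complement
    arc1 = [cyc[k % n] for k in range(i1 + 1, i2 + 1)]
    arc2 = [cyc[k % n] for k in range(i2 + 1, i1 + 1 + n)]
    d1_cyc = [w1] + arc1 + [w2]
    d2_cyc = [w2] + arc2 + [w1]
    d1, d2 = next_cid, next_cid + 1
    del cycles[mother]
    cycles[d1], cycles[d2] = d1_cyc, d2_cyc

    # insert the cut vertices into the neighbours sharing the crossed edges
    for (i, _), w in (((i1, q1), w1), ((i2, q2), w2)):
        v1, v2 = cyc[i], cyc[(i + 1) % n]
        for c, ccyc in cycles.items():
            if c in (d1, d2):
                continue
            m = len(ccyc)
            for j in range(m):
                if ccyc[j] == v2 and ccyc[(j + 1) % m] == v1:
                    cycles[c] = _replace_run(ccyc, [v2, v1], [v2, w, v1])
                    break
            else:
                continue
            break
    return d1, d2, w1, w2


def _apply_extrusion(
    cycles: dict[int, list[int]],
    pos: dict[int, tuple[float, float]],
    cell: int,
    next_vid: int,
) -> int:
    """Shrink ``cell`` to a point; its neighbours seal around a new vertex."""
    gone = set(cycles[cell])
    vstar = next_vid
    pos[vstar] = tuple(_centroid(cycles[cell], pos))
    del cycles[cell]
    for c, cyc in list(cycles.items()):
        if not gone & set(cyc):
            continue
        mapped = [vstar if v in gone else v for v in cyc]
        collapsed: list[int] = []
        for v in mapped:
            if not collapsed or collapsed[-1] != v:
                collapsed.append(v)
        while len(collapsed) > 1 and collapsed[0] == collapsed[-1]:
            collapsed.pop()
        cycles[c] = collapsed
    for v in gone:
        used = any(v in cyc for cyc in cycles.values())
        if not used and v in pos:
            del pos[v]
    return next_vid + 1


def _generate(
    base: CellNetwork,
    script: DeformationScript,
    events: Sequence[ScriptedEvent],
    jitter_sigma: float,
    seed: Optional[int],
    dt_sec: float,
    t1_gap_frac: float = 0.3,
) -> VectorMovie:
    cycles, clean = _extract_cycles(base)
    rng = np.random.default_rng(seed)
    n_frames = script.n_frames
    last = n_frames - 1
    histories = {
        c: CellHistoryRecord(c, 0, last) for c in cycles
    }
    by_frame: dict[int, list[ScriptedEvent]] = {}
    for ev in events:
        if not (0 <= ev.frame < last):
            raise ValueError(f"event at frame {ev.frame} outside the movie")
        by_frame.setdefault(ev.frame, []).append(ev)
    for k, evs in by_frame.items():
        touched: set[int] = set()
        for ev in evs:
            if touched & set(ev.cells):
                raise ValueError(f"conflicting events on one cell at frame {k}")
            touched |= set(ev.cells)

    edge = _typical_edge(base)
    next_vid = max(clean) + 1
    next_cid = max(cycles) + 1
    networks: list[CellNetwork] = []
    for k in range(n_frames):
        posk = dict(clean)
        if jitter_sigma > 0:
            for v in posk:
                dx, dy = rng.normal(0.0, jitter_sigma, size=2)
                posk[v] = (posk[v][0] + dx, posk[v][1] + dy)
        networks.append(network_from_cell_polygons(cycles, posk, frame=k))
        if k == last:
            break
        f = script.gradients[k]
        clean = {v: tuple(f @ np.asarray(p)) for v, p in clean.items()}
        for ev in by_frame.get(k, []):
            if ev.kind == "t1":
                a, b = ev.cells
                next_vid = _apply_t1(cycles, clean, a, b, next_vid, t1_gap_frac * edge)
            elif ev.kind == "division":
                (mother,) = ev.cells
                d1, d2, *_ = _apply_division(
                    cycles, clean, mother, ev.orientation, next_vid, next_cid
                )
                next_vid += 2
                next_cid += 2
                h = histories[mother]
                h.last_frame = k
                h.disappears_by = DisappearsBy.DIVISION
                h.left_daughter_cell_id = d1
                h.right_daughter_cell_id = d2
                histories[d1] = CellHistoryRecord(
                    d1, k + 1, last, appears_by=AppearsBy.DIVISION
                )
                histories[d2] = CellHistoryRecord(
                    d2, k + 1, last, appears_by=AppearsBy.DIVISION
                )
            else:  # extrusion
                (cell,) = ev.cells
                next_vid = _apply_extrusion(cycles, clean, cell, next_vid)
                h = histories[cell]
                h.last_frame = k
                h.disappears_by = DisappearsBy.EXTRUSION
    return VectorMovie(
        networks=networks,
        histories=histories,
        dt_sec=dt_sec,
        events=list(events),
        base_net=base,
        script=script,
        jitter_sigma=jitter_sigma,
        seed=seed,
    )


def _typical_edge(net: CellNetwork) -> float:
    lengths = []
    for c in net.cell_ids[:20]:
        poly = net.cell_polygon(c)
        lengths.extend(np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1))
    return float(np.median(lengths))


def apply_deformation_series(
    net: CellNetwork,
    script: DeformationScript,
    jitter_sigma: float = 0.0,
    seed: Optional[int] = None,
    dt_sec: float = 1.0,
) -> VectorMovie:
    """Deform ``net`` frame by frame according to ``script``.

    Vertex coordinates are mapped by the cumulative deformation gradient;
    cell ids persist and no topological change occurs.  Optional Gaussian
    vertex jitter (``jitter_sigma``, same units as coordinates) emulates
    the positional noise of pixelated contours.
    """
    return _generate(net, script, [], jitter_sigma, seed, dt_sec)


def script_topological_events(
    movie: VectorMovie, events: Sequence[ScriptedEvent]
) -> VectorMovie:
    """Re-generate ``movie`` with scripted topological events added."""
    if movie.base_net is None or movie.script is None:
        raise ValueError("movie does not carry its generation state")
    return _generate(
        movie.base_net,
        movie.script,
        list(movie.events) + list(events),
        movie.jitter_sigma,
        movie.seed,
        movie.dt_sec,
    )


# ---------------------------------------------------------------------- #
# rasterization
# ---------------------------------------------------------------------- #
def rasterize_labels(
    movie: VectorMovie, pixels_per_edge: int, pad: int = 6
) -> list[np.ndarray]:
    """Render each frame as a label image with 1-px-wide boundaries.

    Cells are filled with their persistent integer id, boundaries (and the
    exterior) are 0.  All frames share one canvas sized to the movie's
    bounding box so the images form a movie in a fixed coordinate system.
    """
    from skimage.draw import polygon as draw_polygon

    if pixels_per_edge < 5:
        raise ValueError("pixels_per_edge must be >= 5")
    edge = _typical_edge(movie.networks[0])
    scale = pixels_per_edge / edge
    xs, ys = [], []
    for net in movie.networks:
        arr = np.array(list(net.vertex_positions.values()))
        xs += [arr[:, 0].min(), arr[:, 0].max()]
        ys += [arr[:, 1].min(), arr[:, 1].max()]
    x0, y0 = min(xs), min(ys)
    w = int(math.ceil((max(xs) - x0) * scale)) + 2 * pad + 1
    h = int(math.ceil((max(ys) - y0) * scale)) + 2 * pad + 1

    frames = []
    for net in movie.networks:
        img = np.zeros((h, w), dtype=np.int32)
        for c in net.cell_ids:
            poly = net.cell_polygon(c)
            px = (poly[:, 0] - x0) * scale + pad
            py = (poly[:, 1] - y0) * scale + pad
            if len(poly) >= 3:
                d = np.linalg.norm(poly.max(axis=0) - poly.min(axis=0))
                if d * scale < 3:
                    raise ValueError(f"cell {c} smaller than 3 px; raise resolution")
            rr, cc = draw_polygon(py, px, shape=img.shape)
            img[rr, cc] = c
        # carve the 1-px boundary where the label changes (one side only):
        # a pixel whose upper or left neighbour carries a different label
        # becomes a boundary pixel, which also outlines the tissue margin.
        diff = np.zeros_like(img, dtype=bool)
        diff[1:, :] |= img[1:, :] != img[:-1, :]
        diff[:, 1:] |= img[:, 1:] != img[:, :-1]
        img[diff] = 0
        frames.append(img)
    return frames


def write_movie(
    movie: VectorMovie,
    out_dir: str | Path,
    pixels_per_edge: int = 30,
) -> Path:
    """Write label TIFFs, ``cumultimesec.txt`` and a histories CSV."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = rasterize_labels(movie, pixels_per_edge)
    for k, img in enumerate(frames):
        tifffile.imwrite(out / f"frame_{k:04d}.tif", img.astype(np.int32))
    with open(out / "cumultimesec.txt", "w") as fh:
        for t in movie.times_sec:
            fh.write(f"{t:.6f}\n")
    from .db import histories_to_frame  # light import to share the schema

    histories_to_frame(movie.histories).to_csv(out / "cell_histories.csv", index=False)
    divs = movie.divisions()
    if divs:
        import pandas as pd

        pd.DataFrame(
            divs, columns=["frame", "mother_id", "daughter1_id", "daughter2_id"]
        ).to_csv(out / "divisions.csv", index=False)
    return out
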