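"""Convert tracked label-image movies into vectorized cell networks.

Input format: one integer label image per frame; every cell is filled
with a persistent positive id, cell-cell interfaces are 1-px-wide lines
of zeros, and the exterior is zero as well.  This is the output style of
interactive segmentation/tracking tools; the bundled synthetic rasterizer
emits the same format.

Parsing strategy
----------------
1. *Boundary pixels* (zeros with a positive 8-neighbour that are not part
   of the exterior) are assigned to an adjacent cell, producing a
   complete label tiling; the original pixel ownership is kept for the
   area bookkeeping.
2. *Vertices* are detected on the pixel-corner grid: a 2x2 corner where
   at least three distinct labels meet (the exterior counts as the
   background cell 0) is a junction; 8-connected junction corners are
   clustered into a single network vertex at their mean position, so a
   4-label corner yields one four-fold vertex, not two.
3. Each cell's contour is crack-traced along pixel edges; the junction
   corners encountered in order form the cell's vertex cycle, which
   feeds the half-edge builder (conjugate and left links, background
   cell closure).

Pixel-based geometry: the cell center is the mean of its member pixel
coordinates, the area is the member pixel count plus the cell's share of
adjacent boundary pixels (a boundary pixel touching k labels contributes
1/k to each), and the elongation nematic is an exact pixel sum.  A fully
enclosed cell with no junction on its contour gets one artificial vertex
so its single self-conjugate interface can be represented.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import cell_elongation
from .network import (
    AppearsBy,
    CellHistoryRecord,
    CellNetwork,
    DisappearsBy,
    network_from_cell_polygons,
)

__all__ = ["parse_frame", "infer_histories", "load_label_image"]

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_STRUCT8 = np.ones((3, 3), dtype=bool)


def load_label_image(path) -> np.ndarray:
    """Read a label frame from PNG/TIFF; RGB colors are mapped to integers."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # RGB(A) -> bijective integer encoding
        img = img.astype(np.int64)
        img = img[..., 0] * 65536 + img[..., 1] * 256 + img[..., 2]
    return img.astype(np.int64)


def _exterior_mask(labels: np.ndarray) -> np.ndarray:
    """Zero pixels with no positive neighbour, connected to the image border.

    Junction clusters inside the tissue can also contain zero pixels with
    no positive neighbour; those are not exterior.
    """
    pos = labels > 0
    deep = (labels == 0) & ~ndimage.binary_dilation(pos, _STRUCT8)
    dlab, _ = ndimage.label(deep, structure=_STRUCT8)
    border_ids = set(np.unique(np.concatenate([
        dlab[0, :], dlab[-1, :], dlab[:, 0], dlab[:, -1]
    ])))
    border_ids.discard(0)
    if not border_ids:
        return np.zeros_like(deep)
    return np.isin(dlab, list(border_ids))


def _fill_boundaries(labels: np.ndarray) -> np.ndarray:
    """Assign every non-exterior zero pixel to an adjacent cell.

    Uses the smallest adjacent positive label (deterministic) and
    iterates so that thick junction blobs are absorbed too.
    """
    filled = labels.astype(np.int64).copy()
    exterior = _exterior_mask(labels)
    todo = (filled == 0) & ~exterior
    big = np.int64(np.iinfo(np.int64).max)
    while todo.any():
        cand = np.where(filled > 0, filled, big)
        best = np.full_like(cand, big)
        for dr, dc in _EIGHT:
            shifted = np.full_like(cand, big)
            rs = slice(max(dr, 0), cand.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), cand.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), cand.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), cand.shape[1] + min(-dc, 0))
            shifted[rd, cd] = cand[rs, cs]
            best = np.minimum(best, shifted)
        assignable = todo & (best < big)
        if not assignable.any():
            break  # isolated zeros (should not happen); leave them
        filled[assignable] = best[assignable]
        todo &= ~assignable
    return filled


def _boundary_shares(labels: np.ndarray) -> tuple[dict[int, float], np.ndarray]:
    """Per-cell share of boundary pixels, and the boundary mask itself."""
    pos = labels > 0
    exterior = _exterior_mask(labels)
    boundary = (labels == 0) & ~exterior
    h, w = labels.shape
    share: dict[int, float] = {}
    rr, cc = np.nonzero(boundary)
    for r, c in zip(rr, cc):
        s = set()
        touches_bg = r in (0, h - 1) or c in (0, w - 1)
        for dr, dc in _EIGHT:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                v = labels[r2, c2]
                if v > 0:
                    s.add(int(v))
                elif exterior[r2, c2]:
                    touches_bg = True
            else:
                touches_bg = True
        if touches_bg:
            s.add(0)
        if s:
            frac = 1.0 / len(s)
            for cell in s:
                if cell > 0:
                    share[cell] = share.get(cell, 0.0) + frac
    return share, boundary


_TURN_PRIORITY = {
    (0, 1): [(1, 0), (0, 1), (-1, 0)],    # heading +x: right, straight, left
    (1, 0): [(0, -1), (1, 0), (0, 1)],
    (0, -1): [(-1, 0), (0, -1), (1, 0)],
    (-1, 0): [(0, 1), (-1, 0), (0, -1)],
}


def _trace_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Corner sequence of the region's outer crack boundary.

    ``mask`` must have a 1-px false margin.  Corners are (row, col) on the
    corner grid (corner (i, j) is the top-left corner of pixel (i, j)).
    Pinch corners are resolved by preferring the sharpest right turn,
    which keeps each loop simple.
    """
    cracks: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero(mask)):
        if not mask[r - 1, c]:
            cracks.setdefault((r, c), []).append((r, c + 1))
        if not mask[r, c + 1]:
            cracks.setdefault((r, c + 1), []).append((r + 1, c + 1))
        if not mask[r + 1, c]:
            cracks.setdefault((r + 1, c + 1), []).append((r + 1, c))
        if not mask[r, c - 1]:
            cracks.setdefault((r + 1, c), []).append((r, c))
    used: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    loops: list[list[tuple[int, int]]] = []
    starts = sorted(cracks)
    for start in starts:
        for first in cracks[start]:
            if (start, first) in used:
                continue
            loop = [start]
            cur, prev = first, start
            used.add((start, first))
            while cur != start:
                loop.append(cur)
                d = (cur[0] - prev[0], cur[1] - prev[1])
                options = cracks.get(cur, [])
                nxt = None
                if len(options) == 1:
                    nxt = options[0]
                else:
                    want = [
                        (cur[0] + t[0], cur[1] + t[1]) for t in _TURN_PRIORITY[d]
                    ]
                    for cand in want:
                        if cand in options and (cur, cand) not in used:
                            nxt = cand
                            break
                if nxt is None or (cur, nxt) in used:
                    break  # open path; malformed region
                used.add((cur, nxt))
                prev, cur = cur, nxt
            loops.append(loop)
    if not loops:
        raise ValueError("region has no boundary")
    return max(loops, key=len)


def parse_frame(labels: np.ndarray, frame: int = 0) -> CellNetwork:
    """Vectorize one label frame into a :class:`CellNetwork`.

    Raises ``ValueError`` for malformed segmentations.  A label split
    into disconnected regions triggers a tracking-error warning and only
    the largest region is kept.
    """
    labels = np.asarray(labels)
    labels = _drop_duplicate_regions(labels)
    filled = _fill_boundaries(labels)

    # compact ids so corner/bbox machinery works with arbitrary label values
    ids = np.array(sorted(int(v) for v in np.unique(filled) if v > 0))
    compact = np.searchsorted(ids, filled) + 1
    compact[filled == 0] = 0

    # corner grid on the padded tiling: distinct labels among the 4 pixels
    pad = np.zeros((compact.shape[0] + 2, compact.shape[1] + 2), dtype=np.int64)
    pad[1:-1, 1:-1] = compact
    a, b = pad[:-1, :-1], pad[:-1, 1:]
    c, d = pad[1:, :-1], pad[1:, 1:]
    distinct = (
        1
        + (b != a).astype(np.int8)
        + ((c != a) & (c != b)).astype(np.int8)
        + ((d != a) & (d != b) & (d != c)).astype(np.int8)
    )
    vmask = distinct >= 3
    vlab, n_vert = ndimage.label(vmask, structure=_STRUCT8)
    vertex_pos: dict[int, tuple[float, float]] = {}
    for vid in range(1, n_vert + 1):
        rr, cc = np.nonzero(vlab == vid)
        # vmask[i, j] is the corner between pixels (i-1, j-1)..(i, j) of the
        # original image, i.e. at (x, y) = (j - 0.5, i - 0.5)
        vertex_pos[vid] = (float(cc.mean()) - 0.5, float(rr.mean()) - 0.5)

    cell_ids = [int(v) for v in ids]
    objects = ndimage.find_objects(pad)
    cycles: dict[int, list[int]] = {}
    next_vid = n_vert + 1
    for k, cell in enumerate(cell_ids, start=1):
        sl = objects[k - 1]
        if sl is None:
            continue
        r0 = max(sl[0].start - 1, 0)
        c0 = max(sl[1].start - 1, 0)
        sub = pad[r0: sl[0].stop + 1, c0: sl[1].stop + 1] == k
        loop = _trace_contour(sub)
        cyc: list[int] = []
        for (ri, ci) in loop:
            # trace corners are top-left of sub pixels; vmask indices are
            # shifted by one (corner between pad pixels (i, j) and onward)
            v = vlab[r0 + ri - 1, c0 + ci - 1]
            if v > 0 and (not cyc or cyc[-1] != v):
                cyc.append(int(v))
        if len(cyc) > 1 and cyc[0] == cyc[-1]:
            cyc.pop()
        if len(cyc) == 0:
            # enclosed cell: one artificial vertex on its contour; pad
            # corner (i, j) sits at (x, y) = (j - 1.5, i - 1.5)
            ri, ci = loop[0]
            vertex_pos[next_vid] = (c0 + ci - 1.5, r0 + ri - 1.5)
            cyc = [next_vid]
            next_vid += 1
        cycles[cell] = cyc

    net = network_from_cell_polygons(cycles, vertex_pos, frame=frame)

    # pixel-based cell properties from the original label ownership
    share, _ = _boundary_shares(labels)
    for cell in cell_ids:
        rr, cc = np.nonzero(labels == cell)
        if len(rr) == 0:  # cell existed only as boundary-absorbed pixels
            rr, cc = np.nonzero(filled == cell)
        pix = np.stack([cc, rr], axis=1)
        center = (float(cc.mean()), float(rr.mean()))
        net.cell_centers[cell] = center
        net.cell_areas[cell] = float(len(rr)) + share.get(cell, 0.0)
        net.cell_elongation[cell] = cell_elongation(pix.astype(np.int64), center)
    return net


def _drop_duplicate_regions(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest region of any label split across components."""
    comp, _ = ndimage.label(labels > 0, structure=_STRUCT8)
    df = pd.DataFrame(
        {"label": labels[labels > 0].ravel(), "comp": comp[labels > 0].ravel()}
    )
    sizes = df.groupby(["label", "comp"]).size().reset_index(name="n")
    bad = sizes.groupby("label").size()
    bad = bad[bad > 1].index
    if len(bad) == 0:
        return labels
    labels = labels.copy()
    for lab in bad:
        warnings.warn(
            f"label {lab} split into disconnected regions; keeping the largest",
            stacklevel=2,
        )
        rows = sizes[sizes["label"] == lab].sort_values("n")
        for _, r in rows.iloc[:-1].iterrows():
            labels[(labels == lab) & (comp == r["comp"])] = 0
    return labels


# -------------------------------------------------------------------------- #
# history inference
# -------------------------------------------------------------------------- #
def infer_histories(
    frames: Sequence[np.ndarray],
    divisions: Optional[pd.DataFrame] = None,
) -> dict[int, CellHistoryRecord]:
    """Infer appearance/disappearance reasons from a label-image movie.

    A vanished cell is classified as dividing when at least two ids
    appearing in the next frame each have the majority (>50%) of their
    pixels inside the vanished cell's 1-px-dilated footprint; with more
    than two such candidates the case is ambiguous and the cell is
    excluded from the lineage (flagged by a warning).  A cell whose last
    footprint touches the image border or the exterior is classified as
    moving out of view; anything else is an extrusion.  Appearance is
    classified symmetrically.  An explicit division table (columns
    ``frame, mother_id, daughter1_id, daughter2_id``; ``frame`` is the
    first daughter frame) overrides overlap inference, as emitted by
    trackers that report divisions directly.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to infer histories")
    n = len(frames)
    present: dict[int, list[int]] = {}
    for k, img in enumerate(frames):
        for lab in np.unique(img):
            if lab > 0:
                present.setdefault(int(lab), []).append(k)
    recs = {
        c: CellHistoryRecord(c, min(ks), max(ks)) for c, ks in present.items()
    }

    explicit: dict[int, tuple[int, int]] = {}
    explicit_daughters: set[int] = set()
    if divisions is not None:
        for _, r in divisions.iterrows():
            d1, d2 = int(r["daughter1_id"]), int(r["daughter2_id"])
            explicit[int(r["mother_id"])] = (d1, d2)
            explicit_daughters |= {d1, d2}

    for cell, h in recs.items():
        f0, f1 = h.first_frame, h.last_frame
        if f1 == n - 1:
            h.disappears_by = DisappearsBy.SEGMENTATION_END
        elif cell in explicit:
            d1, d2 = explicit[cell]
            h.disappears_by = DisappearsBy.DIVISION
            h.left_daughter_cell_id, h.right_daughter_cell_id = d1, d2
        else:
            mother_mask = frames[f1] == cell
            foot = ndimage.binary_dilation(mother_mask, _STRUCT8)
            daughters = []
            for dd, hd in recs.items():
                if hd.first_frame != f1 + 1 or dd in explicit_daughters:
                    continue
                dm = frames[f1 + 1] == dd
                if foot[dm].sum() > 0.5 * dm.sum():
                    daughters.append(dd)
            if len(daughters) == 2:
                h.disappears_by = DisappearsBy.DIVISION
                h.left_daughter_cell_id, h.right_daughter_cell_id = sorted(daughters)
            elif len(daughters) > 2:
                warnings.warn(
                    f"cell {cell}: ambiguous {len(daughters)}-way overlap at "
                    f"frame {f1}; excluded from lineage",
                    stacklevel=2,
                )
                h.disappears_by = DisappearsBy.EXTRUSION
            elif _touches_border(frames[f1], cell):
                h.disappears_by = DisappearsBy.MOVED_OUT_OF_VIEW
            else:
                h.disappears_by = DisappearsBy.EXTRUSION
        if f0 == 0:
            h.appears_by = AppearsBy.SEGMENTATION_START
        else:
            h.appears_by = AppearsBy.MOVED_INTO_VIEW  # refined below

    for h in recs.values():
        if h.disappears_by == DisappearsBy.DIVISION:
            for dd in (h.left_daughter_cell_id, h.right_daughter_cell_id):
                if dd in recs:
                    recs[dd].appears_by = AppearsBy.DIVISION
    return recs


def _touches_border(img: np.ndarray, cell: int) -> bool:
    mask = img == cell
    rr, cc = np.nonzero(mask)
    h, w = img.shape
    if rr.min() <= 1 or cc.min() <= 1 or rr.max() >= h - 2 or cc.max() >= w - 2:
        return True
    near = ndimage.binary_dilation(mask, _STRUCT8, iterations=3)
    return bool((near & _exterior_mask(img)).any())
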