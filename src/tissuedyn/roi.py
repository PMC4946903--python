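"""Regions of interest: polygon anchoring, lineage propagation, margin filter.

An ROI is a named cell population.  It is anchored by a simple polygon
on one frame (cells whose center falls strictly inside), propagated
forward and backward in time through the lineage forest, made spatially
contiguous by reassigning enclosed non-member islands, and finally
subjected to the margin filter that defines the canonical populations:

* ``raw`` — every segmented and tracked cell;
* ``whole_tissue`` — the largest population whose entire lineage stays
  inside the field of view at all times: per frame, cells at the
  segmentation margin (adjacent to the background cell) and one more row
  of cells sharing a bond with them are discarded, and only cells whose
  full lineage survives this removal in every frame of its existence are
  kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .events import LineageForest
from .network import BACKGROUND, CellHistoryRecord, CellNetwork

__all__ = [
    "RoiDefinition",
    "cells_in_polygon",
    "propagate_roi",
    "reassign_lost_cells",
    "margin_filter",
    "read_roi_file",
]


@dataclass
class RoiDefinition:
    name: str
    anchor_frame: int
    polygon: np.ndarray  # (n, 2) vertex coordinates, pixels

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if len(self.polygon) < 3 or not Polygon(self.polygon).is_valid:
            raise ValueError(f"ROI {self.name!r}: polygon is not simple")


def read_roi_file(path: str | Path) -> list[RoiDefinition]:
    """Read ROI polygons from CSV with columns ``name, anchor_frame, x, y``."""
    df = pd.read_csv(path)
    out = []
    for (name, anchor), grp in df.groupby(["name", "anchor_frame"], sort=False):
        out.append(RoiDefinition(str(name), int(anchor), grp[["x", "y"]].to_numpy()))
    return out


def cells_in_polygon(net: CellNetwork, poly: np.ndarray) -> set[int]:
    """Cells whose center lies strictly inside the polygon.

    Centers exactly on the polygon edge are excluded (strict rule).
    """
    shp = Polygon(np.asarray(poly, dtype=float))
    if not shp.is_valid or shp.area == 0:
        raise ValueError("degenerate polygon")
    out = set()
    for c in net.cell_ids:
        if shp.contains(Point(net.cell_center(c))):
            out.add(c)
    return out


def propagate_roi(
    seed: set[int],
    anchor_frame: int,
    forest: LineageForest,
    histories: dict[int, CellHistoryRecord],
) -> dict[int, set[int]]:
    """Membership per frame obtained by browsing the lineage forest.

    Forward in time daughters inherit membership; backward, a mother is a
    member whenever any of its descendants alive at the anchor frame is a
    member.  Cells with no lineage path to the anchor frame (for example
    extruded before it) are not members; use
    :func:`reassign_lost_cells` to recover enclosed islands.
    """
    for c in seed:
        h = histories.get(c)
        if h is None or not (h.first_frame <= anchor_frame <= h.last_frame):
            raise ValueError(f"seed cell {c} does not exist at the anchor frame")
    member_ids: set[int] = set()
    for c in seed:
        member_ids.add(c)
        member_ids |= forest.descendants(c)
        member_ids |= forest.ancestors(c)
    frames = range(
        min(h.first_frame for h in histories.values()),
        max(h.last_frame for h in histories.values()) + 1,
    )
    out: dict[int, set[int]] = {}
    for f in frames:
        out[f] = {
            c
            for c in member_ids
            if c in histories
            and histories[c].first_frame <= f <= histories[c].last_frame
        }
    return out


def reassign_lost_cells(net: CellNetwork, members: set[int]) -> set[int]:
    """Merge every enclosed non-member island into the ROI.

    Non-member cells connected by bonds form an undirected graph; every
    connected component except the largest (the surrounding tissue) is
    reassigned to the ROI.  Ties for the largest are broken in favour of
    the component containing background-adjacent cells, then by lowest
    minimum cell id.  The operation is idempotent.
    """
    non_members = [c for c in net.cell_ids if c not in members]
    if not non_members:
        return set(members)
    g = nx.Graph()
    g.add_nodes_from(non_members)
    for c in non_members:
        for n in net.neighbors(c):
            if n not in members:
                g.add_edge(c, n)
    comps = list(nx.connected_components(g))
    if len(comps) <= 1:
        return set(members)
    margin = net.margin_cells()
    comps.sort(key=lambda comp: (-len(comp), -len(comp & margin), min(comp)))
    keep_out = comps[0]
    result = set(members)
    for comp in comps[1:]:
        result |= comp
    return result


def margin_filter(
    networks: Sequence[CellNetwork],
    histories: dict[int, CellHistoryRecord],
    forest: Optional[LineageForest] = None,
) -> dict[int, set[int]]:
    """The ``whole_tissue`` membership per frame.

    Per frame, remove cells adjacent to the background cell and cells
    sharing a bond with those; then keep only cells whose entire lineage
    (all ancestors and descendants present in the movie) survives the
    removal in every frame of its existence, and which neither move into
    nor out of the field of view.
    """
    from .events import build_lineage
    from .network import AppearsBy, DisappearsBy

    if forest is None:
        forest = build_lineage(histories)
    n0 = networks[0].frame
    survivors_per_frame: dict[int, set[int]] = {}
    bad: set[int] = set()
    for net in networks:
        margin = net.margin_cells()
        second = {
            c
            for c in net.cell_ids
            if c not in margin and (net.neighbors(c) & margin)
        }
        removed = margin | second
        survivors_per_frame[net.frame] = set(net.cell_ids) - removed
        bad |= removed
    first_frame = networks[0].frame
    last_frame = networks[-1].frame
    for c, h in histories.items():
        if h.appears_by == AppearsBy.MOVED_INTO_VIEW:
            bad.add(c)
        if h.disappears_by == DisappearsBy.MOVED_OUT_OF_VIEW:
            bad.add(c)
    # propagate badness through the lineage: a tainted ancestor or
    # descendant taints the whole line
    tainted = set(bad)
    for c in bad:
        if c in forest.generation:
            tainted |= forest.ancestors(c)
            tainted |= forest.descendants(c)
    out = {}
    for net in networks:
        out[net.frame] = {c for c in survivors_per_frame[net.frame] if c not in tainted}
        if not out[net.frame]:
            import warnings

            warnings.warn(
                f"whole_tissue is empty at frame {net.frame}; "
                "field of view too unstable",
                stacklevel=2,
            )
    return out
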