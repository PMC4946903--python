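"""End-to-end workflow: images -> database -> ROIs -> events -> deformation.

The pipeline mirrors the classic rule graph of tracked-movie analysis
(prepare, parse_tables, make_db, roi_tracking, tri_create,
shear_calculate, topo_countT1, polygon_class, lineage_colors) with a
small timestamp-based dependency runner: a stage is skipped when all of
its outputs are newer than all of its inputs, and deleting an
intermediate file re-runs only the downstream stages.

All tabular outputs are CSV; the database is a single SQLite file per
movie.  Time alignment (offset to a reference movie) and orientation
(rotation to a common axis) are applied to the exported tables, never to
the stored raw data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import db as tmdb
from .deformation import accumulate_series, decompose_movie, records_to_frame
from .events import (
    build_lineage,
    detect_contact_changes,
    division_events,
    event_rates,
)
from .geometry import grid_coarse_grain
from .mask_parser import infer_histories, load_label_image, parse_frame
from .nematic import Nematic
from .network import CellNetwork
from .roi import (
    cells_in_polygon,
    margin_filter,
    propagate_roi,
    read_roi_file,
    reassign_lost_cells,
)

log = logging.getLogger("tissuedyn")

__all__ = ["MovieConfig", "run_pipeline", "align_and_orient", "render_overlay"]


@dataclass
class MovieConfig:
    """Per-movie analysis configuration.

    The reference movie of a set has ``time_offset_sec = 0``; the other
    movies carry their offset relative to it.  ``rotation_deg`` rotates
    positions about the image center and nematic axes by the same angle
    so all movies share a common orientation.
    """

    name: str = "movie"
    micron_per_pixel: float = 1.0
    time_offset_sec: float = 0.0
    rotation_deg: float = 0.0
    roi_file: Optional[str] = None
    grid_box_microns: float = 33.0
    time_window_min: float = 50.0
    rate_bin_hours: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "MovieConfig":
        """Read a config from YAML or flat ``key = value`` text."""
        text = Path(path).read_text()
        data = None
        try:
            import yaml

            data = yaml.safe_load(text)
        except Exception:
            data = None
        if not isinstance(data, dict):
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line or "=" not in line:
                    continue
                k, v = (s.strip() for s in line.split("=", 1))
                data[k] = v
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in data:
                raw = data[f_.name]
                if f_.name in ("name", "roi_file"):
                    kwargs[f_.name] = None if raw in (None, "None", "") else str(raw)
                else:
                    kwargs[f_.name] = float(raw)
        return cls(**kwargs)


# -------------------------------------------------------------------------- #
# alignment / orientation
# -------------------------------------------------------------------------- #
def align_and_orient(
    tables: dict[str, pd.DataFrame],
    config: MovieConfig,
    image_center: tuple[float, float] = (0.0, 0.0),
) -> dict[str, pd.DataFrame]:
    """Apply the time offset and the orientation rotation to exported tables.

    ``time_hAPF = (time_sec + offset) / 3600`` is added wherever a
    ``time_sec`` column exists; any ``(center_x, center_y)``/(``x, y``)
    pair is rotated by ``rotation_deg`` about the image center, and any
    nematic component pair ``*_xx, *_xy`` rotates with twice the angle.
    """
    th = math.radians(config.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    cx, cy = image_center
    out = {}
    for name, df in tables.items():
        df = df.copy()
        if "time_sec" in df.columns:
            df["time_hAPF"] = (df["time_sec"] + config.time_offset_sec) / 3600.0
        for xcol, ycol in (("center_x", "center_y"), ("x", "y"), ("x_pos", "y_pos")):
            if xcol in df.columns and ycol in df.columns:
                x = df[xcol] - cx
                y = df[ycol] - cy
                df[xcol] = c * x - s * y + cx
                df[ycol] = s * x + c * y + cy
        for col in df.columns:
            if col.endswith("_xx") and col[:-3] + "_xy" in df.columns:
                xx = df[col].to_numpy(dtype=float)
                xy = df[col[:-3] + "_xy"].to_numpy(dtype=float)
                c2, s2 = math.cos(2 * th), math.sin(2 * th)
                df[col] = c2 * xx - s2 * xy
                df[col[:-3] + "_xy"] = s2 * xx + c2 * xy
        out[name] = df
    return out


# -------------------------------------------------------------------------- #
# rendering
# -------------------------------------------------------------------------- #
def render_overlay(
    net: CellNetwork,
    values: dict[int, float] | dict[int, Nematic],
    style: str = "fill",
    path: Optional[str | Path] = None,
    cmap: str = "viridis",
    colors: Optional[dict[int, str]] = None,
):
    """Draw per-cell values on the frame.

    ``style="fill"`` fills each cell polygon on a color scale (or with
    explicit ``colors``, e.g. the gain/loss/both event scheme);
    ``style="nematic-bar"`` draws a bar per cell with length
    proportional to the nematic norm and the nematic's axis angle.
    Cells without a value are left unfilled.  Returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection, PolyCollection

    fig, ax = plt.subplots(figsize=(7, 7))
    polys = [net.cell_polygon(c) for c in net.cell_ids]
    ax.add_collection(
        PolyCollection(polys, facecolors="none", edgecolors="0.6", linewidths=0.4)
    )
    if style == "fill":
        if colors is not None:
            filled = [net.cell_polygon(c) for c in colors]
            ax.add_collection(
                PolyCollection(
                    filled, facecolors=[colors[c] for c in colors],
                    edgecolors="0.3", linewidths=0.4,
                )
            )
        else:
            cells = [c for c in net.cell_ids if c in values]
            arr = np.array([float(values[c]) for c in cells])
            pc = PolyCollection(
                [net.cell_polygon(c) for c in cells], cmap=cmap,
                edgecolors="0.3", linewidths=0.4,
            )
            pc.set_array(arr)
            ax.add_collection(pc)
            fig.colorbar(pc, ax=ax, shrink=0.7)
    elif style == "nematic-bar":
        segs = []
        scale = _bar_scale(net)
        for c, n in values.items():
            if not isinstance(n, Nematic) or n.norm == 0:
                continue
            cx, cy = net.cell_center(c)
            dx = 0.5 * scale * n.norm * math.cos(n.angle)
            dy = 0.5 * scale * n.norm * math.sin(n.angle)
            segs.append([(cx - dx, cy - dy), (cx + dx, cy + dy)])
        ax.add_collection(LineCollection(segs, colors="crimson", linewidths=1.5))
    else:
        raise ValueError(f"unknown style {style!r}")
    ax.autoscale()
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention
    ax.set_title(f"frame {net.frame}")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _bar_scale(net: CellNetwork) -> float:
    areas = [net.cell_area(c) for c in net.cell_ids[:50]]
    return 2.0 * math.sqrt(float(np.median(areas)))


# -------------------------------------------------------------------------- #
# stages
# -------------------------------------------------------------------------- #
@dataclass
class Stage:
    name: str
    inputs: list[Path]
    outputs: list[Path]
    func: Callable[[], None]

    def up_to_date(self) -> bool:
        if not self.outputs or not all(p.exists() for p in self.outputs):
            return False
        ins = [p.stat().st_mtime for p in self.inputs if p.exists()]
        outs = [p.stat().st_mtime for p in self.outputs]
        return not ins or max(ins) <= min(outs)


def _movie_frames(input_dir: Path) -> list[Path]:
    exts = (".tif", ".tiff", ".png")
    frames = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in exts
    )
    if not frames:
        raise FileNotFoundError(f"no label images found in {input_dir}")
    return frames


def run_pipeline(
    config: MovieConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Run every analysis stage in dependency order.

    Stages whose outputs are newer than their inputs are skipped unless
    ``force`` is set.  Missing required inputs raise before any stage
    runs.
    """
    input_dir, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    time_file = input_dir / "cumultimesec.txt"
    if not time_file.exists():
        raise FileNotFoundError(f"missing required input {time_file}")
    frames = _movie_frames(input_dir)
    div_file = input_dir / "divisions.csv"
    db_path = out / f"{config.name}.sqlite"
    rois_path = out / "rois.csv"
    cells_path = out / "cells.csv"
    events_path = out / "events.csv"
    rates_path = out / "rates.csv"
    shear_path = out / "deformation.csv"
    cum_path = out / "deformation_cumulative.csv"
    poly_path = out / "polygon_class.csv"
    lincol_path = out / "lineage_colors.csv"
    grid_path = out / "t1_grid.csv"

    def make_db() -> None:
        images = [load_label_image(p) for p in frames]
        nets = [parse_frame(img, frame=k) for k, img in enumerate(images)]
        divisions = pd.read_csv(div_file) if div_file.exists() else None
        histories = infer_histories(images, divisions)
        forest = build_lineage(histories)
        forest.annotate(histories)
        tmdb.build_database(nets, histories, time_file, db_path)

    def _load_movie():
        n_frames = len(tmdb.load_frames_table(db_path))
        nets = [tmdb.load_frame(db_path, f) for f in range(n_frames)]
        histories = tmdb.load_histories(db_path)
        return nets, histories

    def roi_tracking() -> None:
        nets, histories = _load_movie()
        forest = build_lineage(histories)
        wt = margin_filter(nets, histories, forest)
        rows = []
        for net in nets:
            for c in net.cell_ids:
                rows.append({"frame": net.frame, "roi": "raw", "cell_id": c})
            for c in sorted(wt[net.frame]):
                rows.append({"frame": net.frame, "roi": "whole_tissue", "cell_id": c})
        if config.roi_file:
            for roi in read_roi_file(config.roi_file):
                anchor_net = nets[roi.anchor_frame]
                seed = cells_in_polygon(anchor_net, roi.polygon)
                membership = propagate_roi(seed, roi.anchor_frame, forest, histories)
                for net in nets:
                    m = reassign_lost_cells(net, membership.get(net.frame, set()))
                    m &= wt[net.frame]  # user ROIs are margin-filtered too
                    for c in sorted(m):
                        rows.append({"frame": net.frame, "roi": roi.name, "cell_id": c})
        pd.DataFrame(rows).to_csv(rois_path, index=False)

    def state_tables() -> None:
        import sqlite3

        con = sqlite3.connect(db_path)
        try:
            cells = pd.read_sql_query("SELECT * FROM cells", con)
            ftab = pd.read_sql_query("SELECT * FROM frames", con)
        finally:
            con.close()
        cells = cells.merge(ftab, on="frame")
        aligned = align_and_orient({"cells": cells}, config)
        aligned["cells"].to_csv(cells_path, index=False)

    def topo_count() -> None:
        nets, histories = _load_movie()
        rois = pd.read_csv(rois_path)
        wt = {
            f: set(g["cell_id"])
            for f, g in rois[rois["roi"] == "whole_tissue"].groupby("frame")
        }
        times = tmdb.load_frames_table(db_path)["time_sec"].tolist()
        ev_rows = []
        t1_frames = []
        for net_f, net_f1 in zip(nets, nets[1:]):
            for ch in detect_contact_changes(net_f, net_f1, histories):
                ev_rows.append(
                    {
                        "frame": ch.frame, "kind": ch.kind,
                        "cell_a": ch.cell_a, "cell_b": ch.cell_b,
                        "xx": ch.nematic.xx, "xy": ch.nematic.xy,
                        "x": ch.position[0], "y": ch.position[1],
                    }
                )
                t1_frames.append(ch.frame)
        for d in division_events(nets, histories):
            ev_rows.append(
                {
                    "frame": d.frame, "kind": "division",
                    "cell_a": d.daughter1, "cell_b": d.daughter2,
                    "xx": d.nematic.xx, "xy": d.nematic.xy,
                    "x": d.position[0], "y": d.position[1],
                }
            )
        ev = pd.DataFrame(
            ev_rows, columns=["frame", "kind", "cell_a", "cell_b", "xx", "xy", "x", "y"]
        )
        ev.to_csv(events_path, index=False)
        counts = {f: len(wt.get(f, ())) for f in range(len(nets))}
        rates = event_rates(t1_frames, counts, times, config.rate_bin_hours)
        rates.to_csv(rates_path, index=False)
        if len(ev):
            t1s = ev[ev["kind"].isin(["gain", "loss"])]
            if len(t1s):
                box_px = config.grid_box_microns / config.micron_per_pixel
                window = max(
                    1, int(round(config.time_window_min * 60.0 /
                                 max(np.diff(times).mean(), 1e-9)))
                )
                grid = grid_coarse_grain(t1s, box_px, mode="sum", time_window=window)
                grid.to_csv(grid_path, index=False)
                return
        pd.DataFrame(
            columns=["frame", "box_i", "box_j", "xx", "xy", "count"]
        ).to_csv(grid_path, index=False)

    def shear_calculate() -> None:
        nets, histories = _load_movie()
        rois = pd.read_csv(rois_path)
        wt = {
            f: set(g["cell_id"])
            for f, g in rois[rois["roi"] == "whole_tissue"].groupby("frame")
        }
        records = decompose_movie(nets, histories, roi=wt)
        records_to_frame(records).to_csv(shear_path, index=False)
        accumulate_series(records).to_csv(cum_path, index=False)

    def polygon_class() -> None:
        nets, _ = _load_movie()
        rows = []
        for net in nets:
            for c in net.cell_ids:
                rows.append(
                    {"frame": net.frame, "cell_id": c,
                     "neighbor_count": len(net.neighbors(c))}
                )
        pd.DataFrame(rows).to_csv(poly_path, index=False)

    def lineage_colors() -> None:
        import networkx as nx

        nets, histories = _load_movie()
        forest = build_lineage(histories)
        adj = nx.Graph()
        groups = forest.lineage_group
        adj.add_nodes_from(set(groups.values()))
        for net in nets:
            for c in net.cell_ids:
                for n in net.neighbors(c):
                    if groups.get(c) != groups.get(n):
                        adj.add_edge(groups.get(c), groups.get(n))
        coloring = nx.greedy_color(adj)
        pd.DataFrame(
            [{"lineage_group": g, "color_index": i} for g, i in coloring.items()]
        ).to_csv(lincol_path, index=False)

    stages = [
        Stage("make_db", [time_file, *frames], [db_path], make_db),
        Stage("roi_tracking", [db_path], [rois_path], roi_tracking),
        Stage("state_tables", [db_path], [cells_path], state_tables),
        Stage("topo_countT1", [db_path, rois_path],
              [events_path, rates_path, grid_path], topo_count),
        Stage("shear_calculate", [db_path, rois_path], [shear_path, cum_path],
              shear_calculate),
        Stage("polygon_class", [db_path], [poly_path], polygon_class),
        Stage("lineage_colors", [db_path], [lincol_path], lineage_colors),
    ]
    for st in stages:
        if not force and st.up_to_date():
            log.info("stage %-15s up to date, skipped", st.name)
            continue
        log.info("stage %-15s running", st.name)
        st.func()
    return out
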