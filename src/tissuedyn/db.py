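"""File-backed relational store: one SQLite database per movie.

Six tables hold the complete history of a tracked movie::

    frames(frame, time_sec)
    cells(frame, cell_id, center_x, center_y, area, elong_xx, elong_xy,
          neighbor_count)
    vertices(frame, vertex_id, x_pos, y_pos)
    bonds(frame, bond_id, bond_length)
    directed_bonds(frame, dbond_id, conj_dbond_id, left_dbond_id,
                   cell_id, vertex_id, bond_id)
    cell_histories(cell_id, first_occ, last_occ, appears_by, disappears_by,
                   left_daughter_cell_id, right_daughter_cell_id,
                   lineage_group, generation)

The schema is extensible: additional columns may be appended to any table
without affecting the relationships, and :func:`load_frame` only reads
the columns it knows about.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import cell_elongation
from .nematic import Nematic
from .network import (
    BACKGROUND,
    AppearsBy,
    CellHistoryRecord,
    CellNetwork,
    DirectedBond,
    DisappearsBy,
    validate_topology,
)

__all__ = [
    "build_database",
    "load_frame",
    "load_histories",
    "load_frames_table",
    "read_time_file",
    "histories_to_frame",
    "histories_from_frame",
]

_SCHEMA = """
CREATE TABLE frames (frame INTEGER PRIMARY KEY, time_sec REAL NOT NULL);
CREATE TABLE cells (
    frame INTEGER NOT NULL, cell_id INTEGER NOT NULL,
    center_x REAL, center_y REAL, area REAL,
    elong_xx REAL, elong_xy REAL, neighbor_count INTEGER,
    PRIMARY KEY (frame, cell_id)
);
CREATE TABLE vertices (
    frame INTEGER NOT NULL, vertex_id INTEGER NOT NULL,
    x_pos REAL NOT NULL, y_pos REAL NOT NULL,
    PRIMARY KEY (frame, vertex_id)
);
CREATE TABLE bonds (
    frame INTEGER NOT NULL, bond_id INTEGER NOT NULL, bond_length REAL,
    PRIMARY KEY (frame, bond_id)
);
CREATE TABLE directed_bonds (
    frame INTEGER NOT NULL, dbond_id INTEGER NOT NULL,
    conj_dbond_id INTEGER NOT NULL, left_dbond_id INTEGER NOT NULL,
    cell_id INTEGER NOT NULL, vertex_id INTEGER NOT NULL,
    bond_id INTEGER NOT NULL,
    PRIMARY KEY (frame, dbond_id)
);
CREATE TABLE cell_histories (
    cell_id INTEGER PRIMARY KEY, first_occ INTEGER NOT NULL,
    last_occ INTEGER NOT NULL, appears_by TEXT, disappears_by TEXT,
    left_daughter_cell_id INTEGER, right_daughter_cell_id INTEGER,
    lineage_group INTEGER, generation INTEGER
);
CREATE INDEX idx_cells_frame ON cells(frame);
CREATE INDEX idx_dbonds_frame ON directed_bonds(frame);
CREATE INDEX idx_vertices_frame ON vertices(frame);
"""


def read_time_file(path: Union[str, Path]) -> list[float]:
    """Read ``cumultimesec.txt``: one cumulative time (seconds) per line."""
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            times.append(float(line))
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("cumulative times must be strictly increasing")
    return times


def build_database(
    networks: Sequence[CellNetwork],
    histories: dict[int, CellHistoryRecord],
    times: Union[str, Path, Sequence[float]],
    db_path: Union[str, Path],
    compute_elongation: bool = True,
) -> Path:
    """Persist a movie (one network per frame plus histories) to SQLite.

    Cell centers, areas and elongations come from pixel-based values if
    the parser attached them, otherwise from the cell polygons.
    """
    if len(networks) == 0:
        raise ValueError("empty frame list")
    if isinstance(times, (str, Path)):
        times = read_time_file(times)
    if len(times) != len(networks):
        raise ValueError(
            f"frame-count/time-count mismatch: {len(networks)} frames, "
            f"{len(times)} time entries"
        )
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO frames VALUES (?, ?)",
            [(net.frame, t) for net, t in zip(networks, times)],
        )
        for net in networks:
            _check_foreign_keys(net)
            _insert_frame(con, net, compute_elongation)
        con.executemany(
            "INSERT INTO cell_histories VALUES (?,?,?,?,?,?,?,?,?)",
            [
                (
                    h.cell_id, h.first_frame, h.last_frame,
                    h.appears_by.value, h.disappears_by.value,
                    h.left_daughter_cell_id, h.right_daughter_cell_id,
                    h.lineage_group, h.generation,
                )
                for h in histories.values()
            ],
        )
        con.commit()
    finally:
        con.close()
    return db_path


def _check_foreign_keys(net: CellNetwork) -> None:
    for did, d in net.dbonds.items():
        if d.conj_dbond_id not in net.dbonds:
            raise ValueError(
                f"frame {net.frame}, directed_bonds row dbond_id={did}: "
                f"dangling conj_dbond_id={d.conj_dbond_id}"
            )
        if d.left_dbond_id not in net.dbonds:
            raise ValueError(
                f"frame {net.frame}, directed_bonds row dbond_id={did}: "
                f"dangling left_dbond_id={d.left_dbond_id}"
            )
        if d.vertex_id not in net.vertex_positions:
            raise ValueError(
                f"frame {net.frame}, directed_bonds row dbond_id={did}: "
                f"dangling vertex_id={d.vertex_id}"
            )


def _insert_frame(con: sqlite3.Connection, net: CellNetwork, elong: bool) -> None:
    f = net.frame
    con.executemany(
        "INSERT INTO vertices VALUES (?,?,?,?)",
        [(f, v, p[0], p[1]) for v, p in net.vertex_positions.items()],
    )
    # bond lengths from vertex positions (one row per conjugate pair)
    bond_rows = {}
    for d in net.dbonds.values():
        if d.bond_id in bond_rows:
            continue
        a = np.asarray(net.vertex_positions[d.vertex_id])
        b = np.asarray(net.vertex_positions[net.dbonds[d.left_dbond_id].vertex_id])
        bond_rows[d.bond_id] = float(np.linalg.norm(b - a))
    con.executemany(
        "INSERT INTO bonds VALUES (?,?,?)",
        [(f, b, l) for b, l in bond_rows.items()],
    )
    con.executemany(
        "INSERT INTO directed_bonds VALUES (?,?,?,?,?,?,?)",
        [
            (f, d.dbond_id, d.conj_dbond_id, d.left_dbond_id,
             d.cell_id, d.vertex_id, d.bond_id)
            for d in net.dbonds.values()
        ],
    )
    cell_rows = []
    for c in net.cell_ids:
        cx, cy = net.cell_center(c)
        area = net.cell_area(c)
        if c in net.cell_elongation:
            e = net.cell_elongation[c]
        elif elong:
            e = cell_elongation(net.cell_polygon(c), (cx, cy), area)
        else:
            e = Nematic(float("nan"), float("nan"))
        cell_rows.append(
            (f, c, cx, cy, area, e.xx, e.xy, len(net.neighbors(c)))
        )
    con.executemany("INSERT INTO cells VALUES (?,?,?,?,?,?,?,?)", cell_rows)


def load_frame(db_path: Union[str, Path], frame: int) -> CellNetwork:
    """Reconstruct one frame's :class:`CellNetwork` from the database."""
    con = sqlite3.connect(db_path)
    try:
        row = con.execute(
            "SELECT COUNT(*) FROM frames WHERE frame = ?", (frame,)
        ).fetchone()
        if row[0] == 0:
            raise KeyError(f"frame {frame} not in database")
        verts = {
            v: (x, y)
            for v, x, y in con.execute(
                "SELECT vertex_id, x_pos, y_pos FROM vertices WHERE frame = ?",
                (frame,),
            )
        }
        dbonds = {}
        for did, conj, left, cell, vert, bond in con.execute(
            "SELECT dbond_id, conj_dbond_id, left_dbond_id, cell_id, "
            "vertex_id, bond_id FROM directed_bonds WHERE frame = ?",
            (frame,),
        ):
            dbonds[did] = DirectedBond(did, frame, cell, conj, left, bond, vert)
        net = CellNetwork(frame, verts, dbonds)
        for c, cx, cy, area, exx, exy in con.execute(
            "SELECT cell_id, center_x, center_y, area, elong_xx, elong_xy "
            "FROM cells WHERE frame = ?",
            (frame,),
        ):
            net.cell_centers[c] = (cx, cy)
            net.cell_areas[c] = area
            if exx is not None and not np.isnan(exx):
                net.cell_elongation[c] = Nematic(exx, exy)
        return net
    finally:
        con.close()


def load_histories(db_path: Union[str, Path]) -> dict[int, CellHistoryRecord]:
    con = sqlite3.connect(db_path)
    try:
        df = pd.read_sql_query("SELECT * FROM cell_histories", con)
    finally:
        con.close()
    return histories_from_frame(df)


def load_frames_table(db_path: Union[str, Path]) -> pd.DataFrame:
    con = sqlite3.connect(db_path)
    try:
        return pd.read_sql_query("SELECT * FROM frames ORDER BY frame", con)
    finally:
        con.close()


def histories_to_frame(histories: dict[int, CellHistoryRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": h.cell_id,
            "first_occ": h.first_frame,
            "last_occ": h.last_frame,
            "appears_by": h.appears_by.value,
            "disappears_by": h.disappears_by.value,
            "left_daughter_cell_id": h.left_daughter_cell_id,
            "right_daughter_cell_id": h.right_daughter_cell_id,
            "lineage_group": h.lineage_group,
            "generation": h.generation,
        }
        for h in histories.values()
    ]
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def histories_from_frame(df: pd.DataFrame) -> dict[int, CellHistoryRecord]:
    out = {}
    for _, r in df.iterrows():
        ld = r["left_daughter_cell_id"]
        rd = r["right_daughter_cell_id"]
        out[int(r["cell_id"])] = CellHistoryRecord(
            cell_id=int(r["cell_id"]),
            first_frame=int(r["first_occ"]),
            last_frame=int(r["last_occ"]),
            appears_by=AppearsBy(r["appears_by"]),
            disappears_by=DisappearsBy(r["disappears_by"]),
            left_daughter_cell_id=None if pd.isna(ld) else int(ld),
            right_daughter_cell_id=None if pd.isna(rd) else int(rd),
            lineage_group=int(r["lineage_group"]),
            generation=int(r["generation"]),
        )
    return out
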