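"""Delimited-text output: per-time summaries, per-cell snapshots, VTK export.

Floats are written with ``repr`` so that reading a file back reproduces the
values bit-exactly.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .lineage import CellCollection, TYPE_NAMES

__all__ = ["write_timeseries", "read_timeseries", "write_snapshot",
           "read_snapshot", "write_vtk_polydata"]

TIMESERIES_COLUMNS = ["time_h", "n_stem", "n_paneth", "n_enterocyte",
                      "n_goblet", "niche_height_cd"]
SNAPSHOT_COLUMNS = ["cell_id", "type", "x", "y", "z", "n_elements",
                    "wnt", "notch", "bmp"]


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_timeseries(records, sink) -> int:
    """Write time-ordered per-time summaries as CSV; returns rows written."""
    rows = 0
    with open(sink, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TIMESERIES_COLUMNS)
        for rec in records:
            w.writerow([_fmt(rec[c]) for c in TIMESERIES_COLUMNS])
            rows += 1
    return rows


def read_timeseries(source) -> pd.DataFrame:
    return pd.read_csv(source)


def write_snapshot(coll: CellCollection, time_h: float, sink) -> int:
    """One row per live cell, ordered by cell_id; returns rows written."""
    order = np.argsort(coll.cell_id, kind="stable")
    cents = coll.centroids()
    rows = 0
    with open(sink, "w", newline="") as fh:
        w = csv.writer(fh)
        fh.write(f"# time_h={_fmt(float(time_h))}\n")
        w.writerow(SNAPSHOT_COLUMNS)
        for i in order:
            w.writerow([int(coll.cell_id[i]), TYPE_NAMES[int(coll.type[i])],
                        _fmt(cents[i, 0]), _fmt(cents[i, 1]), _fmt(cents[i, 2]),
                        int(coll.counts[i]), _fmt(coll.I_wnt[i]),
                        _fmt(coll.I_notch[i]), _fmt(coll.I_bmp[i])])
            rows += 1
    return rows


def read_snapshot(source) -> pd.DataFrame:
    return pd.read_csv(source, comment="#")


def write_vtk_polydata(coll: CellCollection, sink) -> None:
    """Legacy-ASCII VTK point cloud of element positions with cell-type labels."""
    pos = coll.pos
    types = coll.type_of_el
    with open(sink, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncrypt elements\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pos)} double\n")
        for p in pos:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"\nPOINT_DATA {len(pos)}\nSCALARS cell_type int 1\n"
                 "LOOKUP_TABLE default\n")
        for t in types:
            fh.write(f"{int(t)}\n")
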