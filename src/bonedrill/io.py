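"""Plain-text output writers: legacy ASCII VTK, CSV tables, probe series."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .solver import FieldHistory


def write_vtk_structured(path, history: FieldHistory, snapshot_index: int = -1) -> None:
    """Write one snapshot as a legacy ASCII VTK structured grid.

    The axisymmetric (r, z) slice is emitted as a flat 2-D structured grid
    (y = 0) with point data ``temperature_C`` and ``bone_mask``; any VTK
    reader (ParaView etc.) can revolve or slice it further.
    """
    grid = history.grid
    T = history.fields_c[snapshot_index]
    mask = history.masks[snapshot_index]
    r = grid.r_centers_mm
    z = grid.z_centers_mm
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"bonedrill snapshot t={history.times_s[snapshot_index]:.6f} s\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {grid.nr} {grid.nz} 1\n")
        fh.write(f"POINTS {grid.nr * grid.nz} float\n")
        for j in range(grid.nz):
            for i in range(grid.nr):
                fh.write(f"{r[i]:.6f} {z[j]:.6f} 0.0\n")
        fh.write(f"POINT_DATA {grid.nr * grid.nz}\n")
        fh.write("SCALARS temperature_C float 1\nLOOKUP_TABLE default\n")
        for j in range(grid.nz):
            for i in range(grid.nr):
                fh.write(f"{T[j, i]:.4f}\n")
        fh.write("SCALARS bone_mask int 1\nLOOKUP_TABLE default\n")
        for j in range(grid.nz):
            for i in range(grid.nr):
                fh.write(f"{int(mask[j, i])}\n")


def write_vtk_series(outdir, history: FieldHistory, stride: int = 1) -> list[str]:
    """Write every ``stride``-th snapshot; returns the file paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i in range(0, len(history.fields_c), stride):
        p = os.path.join(outdir, f"field_{i:04d}.vtk")
        write_vtk_structured(p, history, i)
        paths.append(p)
    return paths


def field_long_table(history: FieldHistory) -> pd.DataFrame:
    """Long CSV-ready table (time, r, z, T, bone) over all snapshots."""
    grid = history.grid
    rr, zz = np.meshgrid(grid.r_centers_mm, grid.z_centers_mm)
    frames = []
    for t, T, m in zip(history.times_s, history.fields_c, history.masks):
        frames.append(pd.DataFrame({
            "time_s": t, "r_mm": rr.ravel(), "z_mm": zz.ravel(),
            "temperature_c": T.ravel(), "bone": m.ravel().astype(int)}))
    return pd.concat(frames, ignore_index=True)


def probe_table(history: FieldHistory) -> pd.DataFrame:
    """Wide probe-series table: time plus one column per recorded probe."""
    data = {"time_s": history.probe_times_s}
    for i, (x, z) in enumerate(history.probe_points_mm):
        data[f"T_x{x:g}mm_z{z:g}mm_c"] = history.probe_series_c[:, i]
    return pd.DataFrame(data)
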