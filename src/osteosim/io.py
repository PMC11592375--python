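"""Export of voxel models and simulation fields.

Voxel fields go to legacy-ASCII VTK structured-points files (readable by
ParaView and meshio alike); the scaffold surface goes to STL via marching
cubes; tabular traces and reports go to CSV/JSON through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import RegionLabel, VoxelModel


def write_vtk_cells(
    path: str | Path,
    shape: tuple[int, int, int],
    spacing: float,
    cell_fields: dict,
    title: str = "osteosim voxel fields",
) -> None:
    """Legacy VTK STRUCTURED_POINTS file with per-voxel (cell) data fields."""
    nx, ny, nz = shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in cell_fields.items():
        arr = np.asarray(arr)
        if arr.shape != (nx, ny, nz):
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {shape}")
        flat = arr.transpose(2, 1, 0).ravel()  # VTK expects x fastest
        if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(map(str, chunk)) for chunk in _chunks(flat.astype(int), 9))
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(
                " ".join(f"{v:.6g}" for v in chunk) for chunk in _chunks(flat, 9)
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _chunks(arr, n):
    for i in range(0, len(arr), n):
        yield arr[i : i + n]


def model_fields(model: VoxelModel, healing_values: dict | None = None) -> dict:
    """Cell fields of a model: region labels plus optional healing-element fields.

    ``healing_values`` maps field names to 1-D arrays over healing elements
    (in C-scan order of the healing voxels); other voxels receive NaN.
    """
    fields = {"region": model.labels.astype(np.int32)}
    if healing_values:
        healing = model.labels == RegionLabel.HEALING
        for name, vals in healing_values.items():
            full = np.full(model.labels.shape, np.nan)
            full[healing] = np.asarray(vals, dtype=float)
            fields[name] = full
    return fields


def write_scaffold_stl(path: str | Path, solid: np.ndarray, spacing: float) -> None:
    """Triangulated scaffold surface by marching cubes (binary STL via trimesh)."""
    from skimage import measure
    import trimesh

    padded = np.pad(solid.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * spacing
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(str(path))


def write_trace_csv(path: str | Path, trace) -> None:
    """Per-iteration tissue fractions and event counts to CSV."""
    import pandas as pd

    from .regulation import Event, TISSUES

    n = trace.tissue_fractions.shape[0]
    data = {"iteration": np.arange(1, n + 1)}
    for i, t in enumerate(TISSUES):
        data[t] = trace.tissue_fractions[:, i]
    for ev in Event:
        data[f"n_{ev.name.lower()}"] = trace.event_counts[:, int(ev)]
    pd.DataFrame(data).to_csv(path, index=False)


def write_run_metadata(path: str | Path, config, trace) -> None:
    """Config echo plus stopping iteration and convergence flag to JSON."""
    meta = {
        "config": config.to_dict(),
        "stop_iteration": int(trace.stop_iteration),
        "converged": bool(trace.converged),
        "bone_samples": [float(v) for v in trace.bone_samples],
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=float) + "\n")
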