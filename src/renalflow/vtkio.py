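"""Minimal legacy-VTK (ASCII) writers for surfaces and tetrahedral fields.

Covers what the pipeline exports: triangulated surfaces (PolyData) and
tetrahedral meshes with optional nodal point-data arrays (UnstructuredGrid),
readable by ParaView/VisIt.  Plain text by design.
"""

from __future__ import annotations

import numpy as np

_VTK_TETRA = 10
_VTK_TRIANGLE = 5


def _write_points(f, points: np.ndarray) -> None:
    f.write(f"POINTS {len(points)} double\n")
    np.savetxt(f, np.asarray(points, dtype=float), fmt="%.10g")


def write_polydata(path: str, points: np.ndarray, triangles: np.ndarray) -> None:
    """Write a triangulated surface as legacy-VTK PolyData."""
    triangles = np.asarray(triangles, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nrenalflow surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        _write_points(f, points)
        f.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        block = np.column_stack([np.full(len(triangles), 3), triangles])
        np.savetxt(f, block, fmt="%d")


def write_unstructured_grid(
    path: str,
    points: np.ndarray,
    tets: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a tetrahedral mesh (and optional nodal/cell arrays) as legacy VTK.

    ``point_data`` values may be scalar (n,) or vector (n, 3) arrays.
    """
    tets = np.asarray(tets, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nrenalflow volume mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(f, points)
        f.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        block = np.column_stack([np.full(len(tets), 4), tets])
        np.savetxt(f, block, fmt="%d")
        f.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(f, np.full(len(tets), _VTK_TETRA, dtype=int), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(points)}\n")
            _write_data_arrays(f, point_data)
        if cell_data:
            f.write(f"CELL_DATA {len(tets)}\n")
            _write_data_arrays(f, cell_data)


def _write_data_arrays(f, arrays: dict[str, np.ndarray]) -> None:
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt="%.10g")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, arr, fmt="%.10g")
        else:
            raise ValueError(f"unsupported array shape for '{name}': {arr.shape}")
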