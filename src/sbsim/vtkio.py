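"""Minimal legacy-ASCII VTK export for meshes and solution fields."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk"]


def _write_array(f, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if arr.ndim == 1:
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in arr:
            f.write(f"{v:.9g}\n")
    elif arr.ndim == 2 and arr.shape[1] == 3:
        f.write(f"VECTORS {name} double\n")
        for v in arr:
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    elif arr.ndim == 3 and arr.shape[1:] == (3, 3):
        f.write(f"TENSORS {name} double\n")
        for t in arr:
            for row in t:
                f.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
            f.write("\n")
    else:
        raise ValueError(f"cannot export array {name!r} of shape {arr.shape}")


def write_vtk(path, nodes, elements, point_data=None, cell_data=None, title="sbsim mesh"):
    """Write a triangle mesh plus attached fields as legacy VTK (ASCII).

    String-valued cell arrays (e.g. region labels) are encoded as integer
    codes with the mapping recorded in the header comment line.
    """
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, int)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})

    legend = []
    for name, arr in list(cell_data.items()):
        arr = np.asarray(arr)
        if arr.dtype.kind in "OU":
            labels, codes = np.unique(arr, return_inverse=True)
            cell_data[name] = codes.astype(float)
            legend.append(name + ":" + ",".join(f"{i}={l}" for i, l in enumerate(labels)))
    title = (title + (" | " + "; ".join(legend) if legend else ""))[:255]

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(title + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"\nCELLS {len(elements)} {4 * len(elements)}\n")
        for tri in elements:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        f.write(f"\nCELL_TYPES {len(elements)}\n")
        f.write("\n".join(["5"] * len(elements)) + "\n")
        if point_data:
            f.write(f"\nPOINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                _write_array(f, name, np.nan_to_num(np.asarray(arr, float), nan=-1.0))
        if cell_data:
            f.write(f"\nCELL_DATA {len(elements)}\n")
            for name, arr in cell_data.items():
                _write_array(f, name, np.asarray(arr, float))
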