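"""Legacy-ASCII VTK and JSON export of trees, graphs and tissue fields.

Writers emit VTK DataFile 2.0 text files: polydata with line cells for
trees and transport graphs (radius/flow as cell data, concentration as
point data) and structured points for the tissue grid (masks, labels and
concentration fields as cell data).  Minimal readers are provided for
round-trip testing; they parse only the subset these writers produce.
"""

from __future__ import annotations

import numpy as np


def _write_header(fh, title, dataset):
    fh.write("# vtk DataFile Version 2.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _write_array(fh, name, values):
    values = np.asarray(values, dtype=float)
    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    np.savetxt(fh, values.reshape(-1), fmt="%.9g")


def write_polylines_vtk(path, points, lines, cell_data=None, point_data=None,
                        title="coroperf polydata"):
    """Write 2D/3D points and 2-point line cells as legacy VTK polydata."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    lines = np.asarray(lines, dtype=int)
    with open(path, "w") as fh:
        _write_header(fh, title, "POLYDATA")
        fh.write(f"POINTS {len(points)} float\n")
        np.savetxt(fh, points, fmt="%.9g")
        fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(lines), 2), lines]), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {len(lines)}\n")
            for name, values in cell_data.items():
                _write_array(fh, name, values)
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, values in point_data.items():
                _write_array(fh, name, values)


def write_tree_vtk(path, tree, cell_data=None):
    """Arterial tree as polydata: one line cell per segment."""
    n = tree.n_segments
    points = np.vstack([np.asarray(tree.prox), np.asarray(tree.dist)])
    lines = np.column_stack([np.arange(n), np.arange(n) + n])
    data = {"radius_mm": np.asarray(tree.radius), "length_mm": tree.lengths()}
    if cell_data:
        data.update(cell_data)
    write_polylines_vtk(path, points, lines, cell_data=data, title="arterial tree")


def write_graph_vtk(path, graph, point_data=None):
    """Transport graph as polydata: nodes as points, edges as lines."""
    data = {"concentration": graph.C, "radius_mm": graph.radius,
            "node_type": graph.ntype.astype(float)}
    if point_data:
        data.update(point_data)
    write_polylines_vtk(
        path, graph.pos, np.column_stack([graph.src, graph.dst]),
        cell_data={"velocity_mm_s": graph.vel, "face_area_mm2": graph.area},
        point_data=data, title="transport graph",
    )


def write_image_vtk(path, domain, cell_data, title="tissue grid"):
    """Masked tissue grid as legacy structured points with cell arrays.

    Arrays are written in VTK's x-fastest cell order; 2D (ix, iy) arrays
    are transposed accordingly.
    """
    nx, ny = domain.grid_shape
    with open(path, "w") as fh:
        _write_header(fh, title, "STRUCTURED_POINTS")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 2\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {domain.cell_size} {domain.cell_size} 1\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, values in cell_data.items():
            _write_array(fh, name, np.asarray(values, dtype=float).T)


def write_domain_vtk(path, domain):
    write_image_vtk(
        path, domain,
        {
            "mask": domain.mask,
            "perfusion_region": domain.perfusion_region,
            "fibrosis": domain.fibrosis_mask,
            "roi_damaged": domain.roi_damaged,
            "roi_remote": domain.roi_remote,
        },
        title="myocardial domain",
    )


# ---------------------------------------------------------------------- readers

def _read_scalar_blocks(tokens, i, n_items):
    data = {}
    while i < len(tokens) and tokens[i] == "SCALARS":
        name = tokens[i + 1]
        i += 4  # SCALARS name float 1
        i += 2  # LOOKUP_TABLE default
        vals = np.asarray(tokens[i:i + n_items], dtype=float)
        data[name] = vals
        i += n_items
    return data, i


def read_polylines_vtk(path):
    """Read back a polydata file produced by :func:`write_polylines_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n_pts = int(tokens[i + 1])
    i += 3
    points = np.asarray(tokens[i:i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 * n_pts
    assert tokens[i] == "LINES"
    n_lines = int(tokens[i + 1])
    i += 3
    raw = np.asarray(tokens[i:i + 3 * n_lines], dtype=int).reshape(n_lines, 3)
    lines = raw[:, 1:]
    i += 3 * n_lines
    cell_data, point_data = {}, {}
    while i < len(tokens):
        if tokens[i] == "CELL_DATA":
            i += 2
            cell_data, i = _read_scalar_blocks(tokens, i, n_lines)
        elif tokens[i] == "POINT_DATA":
            i += 2
            point_data, i = _read_scalar_blocks(tokens, i, n_pts)
        else:  # pragma: no cover
            i += 1
    return points, lines, cell_data, point_data


def read_image_vtk(path):
    """Read back a structured-points file; returns (nx, ny, spacing, cell arrays)."""
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("DIMENSIONS")
    nx, ny = int(tokens[i + 1]) - 1, int(tokens[i + 2]) - 1
    i = tokens.index("SPACING")
    spacing = float(tokens[i + 1])
    i = tokens.index("CELL_DATA")
    i += 2
    data, _ = _read_scalar_blocks(tokens, i, nx * ny)
    return nx, ny, spacing, {k: v.reshape(ny, nx).T for k, v in data.items()}
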