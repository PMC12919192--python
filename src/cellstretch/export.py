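"""Plain-text mesh and field export: ASCII VTU (VTK unstructured grid) and
Gmsh 2.2 ``.msh``. Region labels ride along as cell data / physical tags."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem import FieldHistory
from .meshing import LabeledMesh

__all__ = ["write_vtu", "write_msh", "write_vtu_series"]


def _fmt(arr: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(arr).ravel()
    chunks = [
        " ".join(f"{v:.9g}" for v in flat[i : i + per_line])
        for i in range(0, len(flat), per_line)
    ]
    return "\n".join(chunks)


def write_vtu(
    path,
    mesh: LabeledMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh (+ optional nodal/cell fields) as an ASCII .vtu file."""
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = {"region": mesh.region, **(cell_data or {})}
    n_pts, n_cells = mesh.n_vertices, mesh.n_tets

    def data_arrays(data, n_items):
        out = []
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            assert len(arr) == n_items, f"field {name} length mismatch"
            out.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{_fmt(arr)}\n</DataArray>"
            )
        return "\n".join(out)

    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_fmt(mesh.vertices)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_fmt(mesh.tets, 8)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_fmt(np.arange(1, n_cells + 1) * 4, 12)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_fmt(np.full(n_cells, 10), 24)}
</DataArray>
</Cells>
<PointData>
{data_arrays(point_data, n_pts)}
</PointData>
<CellData>
{data_arrays(cell_data, n_cells)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)
    return path


def write_msh(path, mesh: LabeledMesh) -> Path:
    """Write a Gmsh 2.2 ASCII mesh: tets tagged by region, boundary triangles
    tagged 11 (basal) / 12 (membrane)."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_vertices)]
    for i, p in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append("$EndNodes")
    n_elem = mesh.n_tets + len(mesh.basal_facets) + len(mesh.membrane_facets)
    lines += ["$Elements", str(n_elem)]
    eid = 1
    for tag, facets in ((11, mesh.basal_facets), (12, mesh.membrane_facets)):
        for f in facets:
            lines.append(f"{eid} 2 2 {tag} {tag} {f[0]+1} {f[1]+1} {f[2]+1}")
            eid += 1
    for t, reg in zip(mesh.tets, mesh.region):
        lines.append(
            f"{eid} 4 2 {int(reg)} {int(reg)} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}"
        )
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vtu_series(
    directory, history: FieldHistory, steps, prefix: str = "snapshot"
) -> list[Path]:
    """Export displacement/strain/stress snapshots for a subset of steps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    eps_all = history.strain_series()
    sig_all = history.stress_series()
    for s in steps:
        eps, sig = eps_all[s], sig_all[s]
        paths.append(
            write_vtu(
                directory / f"{prefix}_{s:05d}.vtu",
                history.mesh,
                point_data={"displacement_um": history.displacements[s]},
                cell_data={"strain": eps, "stress_pa": sig},
            )
        )
    return paths
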