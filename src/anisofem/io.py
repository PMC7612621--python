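"""Mesh serialization: ASCII VTU (VTK unstructured grid) and Gmsh MSH v4.1.

VTU files embed everything the :class:`~anisofem.meshing.Mesh` carries:
coordinates, connectivity, per-cell fiber triads and scalar cell data as
``CellData`` arrays, and boundary facet tags as ``FieldData`` integer arrays
(one array per tag, one row per facet).  Floats are written with shortest
round-trip ``repr`` so a write/read cycle reproduces the mesh bit-identically.

MSH output targets interoperability with Gmsh: nodes, volume elements, and
tagged surface elements under ``$PhysicalNames``.  The MSH format has no
slot for per-cell vector data, so fiber fields are not serialized there.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .elements import HEX8, TET4
from .meshing import FiberField, Mesh

__all__ = ["write_mesh", "read_mesh", "FormatError"]

_VTK_TYPE = {TET4: 10, HEX8: 12}
_KIND_FROM_VTK = {10: TET4, 12: HEX8}


class FormatError(ValueError):
    pass


def _fmt_floats(arr: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def _fmt_ints(arr: np.ndarray) -> str:
    return " ".join(str(int(v)) for v in np.asarray(arr).ravel())


# --- VTU -------------------------------------------------------------------


def _write_vtu(mesh: Mesh, path: Path) -> None:
    N, M = mesh.n_nodes, mesh.n_cells
    npc = mesh.nodes_per_cell
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
    ]
    lines.append("<FieldData>")
    for tag, facets in mesh.facet_tags.items():
        facets = np.asarray(facets)
        lines.append(
            f'<DataArray type="Int64" Name="facet_tag:{tag}" '
            f'NumberOfComponents="{facets.shape[1] if facets.size else npc - 1}" '
            f'NumberOfTuples="{len(facets)}" format="ascii">'
        )
        lines.append(_fmt_ints(facets))
        lines.append("</DataArray>")
    lines.append("</FieldData>")
    lines.append(f'<Piece NumberOfPoints="{N}" NumberOfCells="{M}">')
    lines.append("<Points>")
    lines.append(
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">'
    )
    lines.append(_fmt_floats(mesh.nodes))
    lines.append("</DataArray>")
    lines.append("</Points>")
    lines.append("<Cells>")
    lines.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    lines.append(_fmt_ints(mesh.cells))
    lines.append("</DataArray>")
    lines.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    lines.append(_fmt_ints(npc * np.arange(1, M + 1)))
    lines.append("</DataArray>")
    lines.append('<DataArray type="UInt8" Name="types" format="ascii">')
    lines.append(_fmt_ints(np.full(M, _VTK_TYPE[mesh.cell_kind])))
    lines.append("</DataArray>")
    lines.append("</Cells>")
    lines.append("<CellData>")
    if mesh.fibers is not None:
        for name in ("f0", "s0", "n0"):
            lines.append(
                f'<DataArray type="Float64" Name="{name}" '
                'NumberOfComponents="3" format="ascii">'
            )
            lines.append(_fmt_floats(getattr(mesh.fibers, name)))
            lines.append("</DataArray>")
    for name, data in mesh.cell_data.items():
        data = np.asarray(data)
        kind = "Int64" if np.issubdtype(data.dtype, np.integer) else "Float64"
        fmt = _fmt_ints if kind == "Int64" else _fmt_floats
        lines.append(
            f'<DataArray type="{kind}" Name="celldata:{name}" format="ascii">'
        )
        lines.append(fmt(data))
        lines.append("</DataArray>")
    lines.append("</CellData>")
    lines.append("</Piece>")
    lines.append("</UnstructuredGrid>")
    lines.append("</VTKFile>")
    path.write_text("\n".join(lines) + "\n")


def _require(parent, match, path):
    el = parent.find(match)
    if el is None:
        raise FormatError(f"{path}: missing required section {match!r}")
    return el


def _read_vtu(path: Path) -> Mesh:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    grid = _require(root, "UnstructuredGrid", path)
    piece = _require(grid, "Piece", path)
    pts = _require(_require(piece, "Points", path), "DataArray", path)
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    cells_el = _require(piece, "Cells", path)
    arrays = {a.get("Name"): a for a in cells_el.findall("DataArray")}
    for need in ("connectivity", "offsets", "types"):
        if need not in arrays:
            raise FormatError(f"{path}: Cells section lacks {need!r}")
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=np.int64)
    vtk_t = int(types[0]) if len(types) else 10
    if vtk_t not in _KIND_FROM_VTK or not np.all(types == vtk_t):
        raise FormatError(f"{path}: unsupported or mixed cell types")
    kind = _KIND_FROM_VTK[vtk_t]
    npc = 4 if kind == TET4 else 8
    cells = conn.reshape(-1, npc)
    mesh = Mesh(nodes=nodes, cells=cells, cell_kind=kind)

    fib = {}
    cd = piece.find("CellData")
    if cd is not None:
        for a in cd.findall("DataArray"):
            name = a.get("Name")
            if name in ("f0", "s0", "n0"):
                fib[name] = np.fromstring(a.text, sep=" ").reshape(-1, 3)
            elif name and name.startswith("celldata:"):
                if a.get("type") == "Int64":
                    mesh.cell_data[name[9:]] = np.fromstring(
                        a.text, sep=" ", dtype=np.int64
                    )
                else:
                    mesh.cell_data[name[9:]] = np.fromstring(a.text, sep=" ")
    if len(fib) == 3:
        mesh.fibers = FiberField(**fib)

    fd = grid.find("FieldData")
    if fd is not None:
        for a in fd.findall("DataArray"):
            name = a.get("Name") or ""
            if name.startswith("facet_tag:"):
                width = int(a.get("NumberOfComponents", npc - 1))
                text = a.text or ""
                data = np.fromstring(text, sep=" ", dtype=np.int64)
                mesh.facet_tags[name[10:]] = data.reshape(-1, width)
    return mesh


# --- MSH v4.1 --------------------------------------------------------------

_MSH_VOL = {TET4: 4, HEX8: 5}
_MSH_SURF = {3: 2, 4: 3}  # tri, quad
_KIND_FROM_MSH = {4: TET4, 5: HEX8}
_SURF_WIDTH = {2: 3, 3: 4}


def _write_msh(mesh: Mesh, path: Path) -> None:
    tags = list(mesh.facet_tags)
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    out += ["$PhysicalNames", str(len(tags) + 1)]
    for i, t in enumerate(tags, start=1):
        out.append(f'2 {i} "{t}"')
    out.append(f'3 {len(tags) + 1} "domain"')
    out.append("$EndPhysicalNames")
    # minimal entities: one surface per tag, one volume
    out += ["$Entities", f"0 0 {len(tags)} 1"]
    for i, _ in enumerate(tags, start=1):
        out.append(f"{i} 0 0 0 0 0 0 1 {i} 0")
    out.append(f"1 0 0 0 0 0 0 1 {len(tags) + 1} 0")
    out.append("$EndEntities")
    N = mesh.n_nodes
    out += ["$Nodes", f"1 {N} 1 {N}", f"3 1 0 {N}"]
    out += [str(i + 1) for i in range(N)]
    out += [
        " ".join(repr(float(v)) for v in row) for row in mesh.nodes
    ]
    out.append("$EndNodes")
    n_surf = sum(len(f) for f in mesh.facet_tags.values())
    M = mesh.n_cells
    total = n_surf + M
    out += ["$Elements", f"{len(tags) + 1} {total} 1 {total}"]
    eid = 1
    for i, t in enumerate(tags, start=1):
        facets = mesh.facet_tags[t]
        width = facets.shape[1] if facets.size else mesh.nodes_per_cell - 1
        out.append(f"2 {i} {_MSH_SURF[width]} {len(facets)}")
        for f in facets:
            out.append(f"{eid} " + " ".join(str(int(v) + 1) for v in f))
            eid += 1
    out.append(f"3 1 {_MSH_VOL[mesh.cell_kind]} {M}")
    for c in mesh.cells:
        out.append(f"{eid} " + " ".join(str(int(v) + 1) for v in c))
        eid += 1
    out.append("$EndElements")
    path.write_text("\n".join(out) + "\n")


def _read_msh(path: Path) -> Mesh:
    lines = path.read_text().splitlines()
    idx = {}
    for i, ln in enumerate(lines):
        if ln.startswith("$") and not ln.startswith("$End"):
            idx[ln.strip()] = i
    for need in ("$MeshFormat", "$Nodes", "$Elements"):
        if need not in idx:
            raise FormatError(f"{path}: missing section {need}")
    phys = {}
    if "$PhysicalNames" in idx:
        i = idx["$PhysicalNames"] + 1
        n = int(lines[i])
        for ln in lines[i + 1 : i + 1 + n]:
            parts = ln.split(maxsplit=2)
            phys[int(parts[1])] = parts[2].strip().strip('"')
    # surface entity -> physical tag map
    ent_surf_phys = {}
    if "$Entities" in idx:
        i = idx["$Entities"] + 1
        np_, nc, ns, nv = map(int, lines[i].split())
        j = i + 1 + np_ + nc
        for ln in lines[j : j + ns]:
            parts = ln.split()
            if int(parts[7]) >= 1:
                ent_surf_phys[int(parts[0])] = int(parts[8])
    i = idx["$Nodes"] + 1
    nblocks, nnodes = int(lines[i].split()[0]), int(lines[i].split()[1])
    coords = np.empty((nnodes, 3))
    j = i + 1
    for _ in range(nblocks):
        bn = int(lines[j].split()[3])
        tags_ = [int(lines[j + 1 + k]) for k in range(bn)]
        for k in range(bn):
            coords[tags_[k] - 1] = np.fromstring(
                lines[j + 1 + bn + k], sep=" "
            )[:3]
        j += 1 + 2 * bn
    i = idx["$Elements"] + 1
    nblocks = int(lines[i].split()[0])
    j = i + 1
    cells = None
    kind = None
    facet_tags: dict[str, list] = {}
    for _ in range(nblocks):
        dim, ent, etype, bn = map(int, lines[j].split())
        rows = [
            np.fromstring(lines[j + 1 + k], sep=" ", dtype=np.int64)[1:] - 1
            for k in range(bn)
        ]
        if dim == 3:
            if etype not in _KIND_FROM_MSH:
                raise FormatError(f"{path}: unsupported volume element {etype}")
            kind = _KIND_FROM_MSH[etype]
            block = np.array(rows, dtype=np.int64)
            cells = block if cells is None else np.vstack([cells, block])
        elif dim == 2:
            name = phys.get(ent_surf_phys.get(ent, -1), f"surface_{ent}")
            facet_tags.setdefault(name, []).extend(rows)
        j += 1 + bn
    if cells is None:
        raise FormatError(f"{path}: no volume elements found")
    mesh = Mesh(nodes=coords, cells=cells, cell_kind=kind)
    mesh.facet_tags = {
        k: np.array(v, dtype=np.int64) for k, v in facet_tags.items()
    }
    return mesh


# --- dispatch --------------------------------------------------------------


def write_mesh(mesh: Mesh, path, fmt: str | None = None) -> None:
    """Write a mesh as ``.vtu`` or ``.msh`` (format inferred from the suffix
    unless given explicitly)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtu":
        _write_vtu(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")


def read_mesh(path, fmt: str | None = None) -> Mesh:
    """Read a ``.vtu`` or ``.msh`` mesh written by :func:`write_mesh`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtu":
        return _read_vtu(path)
    if fmt == "msh":
        return _read_msh(path)
    raise FormatError(f"unknown mesh format {fmt!r}")
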