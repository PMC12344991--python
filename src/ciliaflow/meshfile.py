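"""Reading and writing labeled meshes (XDMF and Gmsh MSH 4.1).

Both formats are written as plain text.  XDMF files use inline ASCII
DataItems (ParaView-compatible) with two grids: the tetrahedral mesh with one
0/1 cell attribute per named cell set, and a triangle grid of the labeled
boundary facets.  MSH 4.1 files group boundary triangles into one discrete
surface entity per facet label and tetrahedra into one volume entity per ROI
(plus a bulk entity), with physical names matching the label enums.

File coordinates are micrometres (the field's natural unit at this scale);
the in-memory :class:`~ciliaflow.mesh.LabeledMesh` is SI and records the
conversion in its coordinate-convention string.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import (
    COORDINATE_CONVENTION,
    UM,
    FacetLabel,
    LabeledMesh,
    MeshError,
    PHOTOCONVERSION,
    ROI_NAMES,
)

_BULK_TAG = 100


def save_labeled_mesh(mesh: LabeledMesh, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "xdmf":
        _write_xdmf(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def load_labeled_mesh(path: str | Path, fmt: str | None = None) -> LabeledMesh:
    """Load and validate a labeled mesh; raises :class:`MeshError` when label
    fields are missing or carry unknown values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "xdmf":
        mesh = _read_xdmf(path)
    elif fmt == "msh":
        mesh = _read_msh(path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    mesh.validate()
    return mesh


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return {"xdmf": "xdmf", "xmf": "xdmf", "msh": "msh"}.get(suffix, suffix)


# ---------------------------------------------------------------------------
# XDMF
# ---------------------------------------------------------------------------


def _array_text(arr: np.ndarray) -> str:
    if np.issubdtype(arr.dtype, np.integer):
        return "\n".join(" ".join(str(v) for v in row) for row in np.atleast_2d(arr))
    return "\n".join(" ".join(f"{v:.10g}" for v in row) for row in np.atleast_2d(arr))


def _data_item(parent, arr: np.ndarray):
    arr2 = np.atleast_2d(arr)
    item = ET.SubElement(
        parent,
        "DataItem",
        Dimensions=" ".join(str(d) for d in arr2.shape),
        Format="XML",
        NumberType="Int" if np.issubdtype(arr.dtype, np.integer) else "Float",
    )
    item.text = "\n" + _array_text(arr) + "\n"
    return item


def _write_xdmf(mesh: LabeledMesh, path: Path) -> None:
    root = ET.Element("Xdmf", Version="3.0")
    domain = ET.SubElement(root, "Domain")
    info = ET.SubElement(domain, "Information", Name="units", Value="um")
    info.text = mesh.coordinate_convention

    grid = ET.SubElement(domain, "Grid", Name="mesh")
    topo = ET.SubElement(
        grid, "Topology", TopologyType="Tetrahedron",
        NumberOfElements=str(mesh.num_cells),
    )
    _data_item(topo, mesh.cells)
    geom = ET.SubElement(grid, "Geometry", GeometryType="XYZ")
    _data_item(geom, mesh.points / UM)
    for name, idx in mesh.cell_sets.items():
        indicator = np.zeros(mesh.num_cells, dtype=np.int64)
        indicator[np.asarray(idx, dtype=int)] = 1
        attr = ET.SubElement(
            grid, "Attribute", Name=f"cellset:{name}", Center="Cell",
            AttributeType="Scalar",
        )
        _data_item(attr, indicator[:, None])

    bf = mesh.boundary_facets
    fgrid = ET.SubElement(domain, "Grid", Name="facets")
    ftopo = ET.SubElement(
        fgrid, "Topology", TopologyType="Triangle", NumberOfElements=str(len(bf))
    )
    _data_item(ftopo, mesh.facets[bf])
    fgeom = ET.SubElement(fgrid, "Geometry", GeometryType="XYZ")
    _data_item(fgeom, mesh.points / UM)
    fattr = ET.SubElement(
        fgrid, "Attribute", Name="facet_labels", Center="Cell", AttributeType="Scalar"
    )
    labels = np.array([mesh.facet_labels.get(int(f), 0) for f in bf], dtype=np.int64)
    _data_item(fattr, labels[:, None])

    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode"))


def _parse_item(node) -> np.ndarray:
    numbers = node.text.split()
    dims = [int(d) for d in node.get("Dimensions").split()]
    dtype = np.int64 if node.get("NumberType", "Float") == "Int" else float
    return np.array(numbers, dtype=dtype).reshape(dims)


def _read_xdmf(path: Path) -> LabeledMesh:
    root = ET.parse(path).getroot()
    domain = root.find("Domain")
    grids = {g.get("Name"): g for g in domain.findall("Grid")}
    if "mesh" not in grids:
        raise MeshError(f"{path}: no tetrahedral grid named 'mesh'")
    grid = grids["mesh"]
    cells = _parse_item(grid.find("Topology/DataItem"))
    points = _parse_item(grid.find("Geometry/DataItem")) * UM
    cell_sets = {}
    for attr in grid.findall("Attribute"):
        name = attr.get("Name", "")
        if name.startswith("cellset:"):
            indicator = _parse_item(attr.find("DataItem")).ravel()
            cell_sets[name.removeprefix("cellset:")] = np.nonzero(indicator)[0]

    mesh = LabeledMesh(points=points, cells=cells, cell_sets=cell_sets)
    if "facets" not in grids:
        raise MeshError(
            f"{path}: unlabeled boundary: no facet grid; "
            f"{len(mesh.boundary_facets)} boundary facets carry no label"
        )
    fgrid = grids["facets"]
    tris = _parse_item(fgrid.find("Topology/DataItem"))
    fattr = next(
        (a for a in fgrid.findall("Attribute") if a.get("Name") == "facet_labels"),
        None,
    )
    if fattr is None:
        raise MeshError(
            f"{path}: unlabeled boundary: facet grid lacks a 'facet_labels' field; "
            f"{len(mesh.boundary_facets)} boundary facets carry no label"
        )
    labels = _parse_item(fattr.find("DataItem")).ravel()
    mesh.facet_labels = _match_facets(mesh, tris, labels, path)
    info = domain.find("Information")
    if info is not None and info.text:
        mesh.coordinate_convention = info.text.strip()
    return mesh


def _match_facets(mesh, tris, labels, path) -> dict[int, int]:
    key = np.sort(np.asarray(tris), axis=1)
    lookup = {tuple(t): i for i, t in enumerate(mesh.facets)}
    out: dict[int, int] = {}
    for row, lab in zip(key, labels):
        idx = lookup.get(tuple(row))
        if idx is None:
            raise MeshError(f"{path}: labeled facet {row.tolist()} not found in mesh")
        if int(lab) not in set(FacetLabel):
            raise MeshError(f"{path}: unknown facet label value {int(lab)}")
        out[idx] = int(lab)
    return out


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII)
# ---------------------------------------------------------------------------


def _write_msh(mesh: LabeledMesh, path: Path) -> None:
    bf = mesh.boundary_facets
    facet_by_label: dict[int, np.ndarray] = {}
    labels = np.array([mesh.facet_labels.get(int(f), 0) for f in bf])
    for lab in np.unique(labels):
        facet_by_label[int(lab)] = mesh.facets[bf[labels == lab]]

    cell_tag = np.full(mesh.num_cells, _BULK_TAG, dtype=int)
    for i, name in enumerate(ROI_NAMES, start=1):
        if name in mesh.cell_sets:
            cell_tag[np.asarray(mesh.cell_sets[name], dtype=int)] = i
    vol_tags = sorted(set(cell_tag.tolist()))

    lines: list[str] = []
    lines += ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    phys = [(2, lab, FacetLabel(lab).name) for lab in facet_by_label]
    phys += [
        (3, t, ROI_NAMES[t - 1] if t != _BULK_TAG else "BULK") for t in vol_tags
    ]
    lines.append("$PhysicalNames")
    lines.append(str(len(phys)))
    lines += [f'{dim} {tag} "{name}"' for dim, tag, name in phys]
    lines.append("$EndPhysicalNames")

    lo = mesh.points.min(axis=0) / UM
    hi = mesh.points.max(axis=0) / UM
    box = " ".join(f"{v:.10g}" for v in (*lo, *hi))
    lines.append("$Entities")
    lines.append(f"0 0 {len(facet_by_label)} {len(vol_tags)}")
    for lab in facet_by_label:
        lines.append(f"{lab} {box} 1 {lab} 0")
    for tag in vol_tags:
        lines.append(f"{tag} {box} 1 {tag} 0")
    lines.append("$EndEntities")

    npts = len(mesh.points)
    lines.append("$Nodes")
    lines.append(f"1 {npts} 1 {npts}")
    lines.append(f"3 {vol_tags[0]} 0 {npts}")
    lines += [str(i) for i in range(1, npts + 1)]
    lines += [
        " ".join(f"{v:.10g}" for v in p) for p in mesh.points / UM
    ]
    lines.append("$EndNodes")

    blocks: list[tuple[int, int, int, np.ndarray]] = []
    for lab, tris in facet_by_label.items():
        blocks.append((2, lab, 2, tris))
    for tag in vol_tags:
        blocks.append((3, tag, 4, mesh.cells[cell_tag == tag]))
    nelem = sum(len(b[3]) for b in blocks)
    lines.append("$Elements")
    lines.append(f"{len(blocks)} {nelem} 1 {nelem}")
    eid = 1
    for dim, tag, etype, conn in blocks:
        lines.append(f"{dim} {tag} {etype} {len(conn)}")
        for row in conn:
            lines.append(f"{eid} " + " ".join(str(v + 1) for v in row))
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> LabeledMesh:
    text = path.read_text().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1

    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshError(f"{path}: missing $Nodes or $Elements section")

    phys_names: dict[tuple[int, int], str] = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.strip().split(maxsplit=2)
            if len(parts) == 3:
                phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')

    # entity -> physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    if "Entities" in sections:
        counts = [int(v) for v in sections["Entities"][0].split()]
        idx = 1
        for dim, cnt in zip((0, 1, 2, 3), counts):
            for _ in range(cnt):
                parts = sections["Entities"][idx].split()
                idx += 1
                tag = int(parts[0])
                off = 4 if dim == 0 else 7
                nphys = int(parts[off])
                if nphys > 0:
                    ent_phys[(dim, tag)] = int(parts[off + 1])

    body = sections["Nodes"]
    nblocks = int(body[0].split()[0])
    nnodes = int(body[0].split()[1])
    idx = 1
    tags: list[int] = []
    coords: list[list[float]] = []
    for _ in range(nblocks):
        bn = int(body[idx].split()[3])
        idx += 1
        tags += [int(body[idx + k].split()[0]) for k in range(bn)]
        coords += [
            [float(v) for v in body[idx + bn + k].split()[:3]] for k in range(bn)
        ]
        idx += 2 * bn
    order = np.argsort(tags)
    tag_arr = np.asarray(tags)[order]
    points = np.asarray(coords)[order] * UM
    renumber = {int(t): k for k, t in enumerate(tag_arr)}
    if len(points) != nnodes:
        raise MeshError(f"{path}: node count mismatch")

    body = sections["Elements"]
    nblocks = int(body[0].split()[0])
    idx = 1
    cells: list[np.ndarray] = []
    cell_phys: list[int] = []
    tri_rows: list[np.ndarray] = []
    tri_phys: list[int] = []
    for _ in range(nblocks):
        dim, etag, etype, ne = (int(v) for v in body[idx].split())
        idx += 1
        phys = ent_phys.get((dim, etag), etag)
        for k in range(ne):
            parts = [int(v) for v in body[idx + k].split()[1:]]
            nodes = np.array([renumber[t] for t in parts])
            if etype == 4:
                cells.append(nodes)
                cell_phys.append(phys)
            elif etype == 2:
                tri_rows.append(nodes)
                tri_phys.append(phys)
        idx += ne
    if not cells:
        raise MeshError(f"{path}: no tetrahedra found")

    mesh = LabeledMesh(points=points, cells=np.asarray(cells))
    if not tri_rows:
        raise MeshError(
            f"{path}: unlabeled boundary: no labeled surface elements; "
            f"{len(mesh.boundary_facets)} boundary facets carry no label"
        )
    mesh.facet_labels = _match_facets(
        mesh, np.asarray(tri_rows), np.asarray(tri_phys), path
    )
    cell_phys_arr = np.asarray(cell_phys)
    cell_sets: dict[str, np.ndarray] = {}
    for tag in np.unique(cell_phys_arr):
        name = phys_names.get((3, int(tag)), f"volume_{tag}")
        if name.startswith("ROI"):
            cell_sets[name] = np.nonzero(cell_phys_arr == tag)[0]
    if "ROI_1" in cell_sets:
        cell_sets[PHOTOCONVERSION] = cell_sets["ROI_1"].copy()
    mesh.cell_sets = cell_sets
    mesh.coordinate_convention = COORDINATE_CONVENTION
    return mesh
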