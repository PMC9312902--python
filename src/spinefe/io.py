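"""Readers and writers for the on-disk formats.

* NIfTI (.nii/.nii.gz) for CT volumes and label masks (via nibabel); the
  affine encodes the package frame (x anterior, y left, z superior, mm).
* VTK unstructured-grid XML (.vtu), ASCII, for meshes and solutions -
  readable back for round-tripping.
* Abaqus .inp export (write-only) with C3D4 elements; heterogeneous bone is
  binned into element sets with one material card each, engineering-constants
  elasticity, for cross-checking in external solvers.
* JSON for configs, geometry and subject records; CSV for curves and tables.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ct import CTVolume, LabelMask
from .errors import SpineFEError
from .materials import (
    DISC_CONSTANTS,
    EX_RATIO,
    GXY_RATIO,
    GXZ_RATIO,
    MaterialCard,
    NU_XY,
    NU_XZ,
    REGION_ANNULUS,
    REGION_NUCLEUS,
)
from .meshing import TetMesh

VTK_TET = 10


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_nifti(obj: CTVolume | LabelMask, path) -> None:
    img = nib.Nifti1Image(np.asarray(obj.data), _affine(obj.spacing, obj.origin))
    img.header.set_zooms(tuple(obj.spacing))
    nib.save(img, str(path))


def load_ct(path) -> CTVolume:
    img = nib.load(str(path))
    aff = img.affine
    return CTVolume(
        data=np.asarray(img.dataobj, dtype=np.float32),
        spacing=np.diag(aff)[:3].copy(),
        origin=aff[:3, 3].copy(),
    )


def load_mask(path) -> LabelMask:
    img = nib.load(str(path))
    aff = img.affine
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise SpineFEError(f"{path}: label mask has non-integer values")
        data = rounded
    return LabelMask(
        data=data.astype(np.int16),
        spacing=np.diag(aff)[:3].copy(),
        origin=aff[:3, 3].copy(),
    )


# ---------------------------------------------------------------------------
# VTK .vtu (ASCII XML)
# ---------------------------------------------------------------------------

def write_vtu(
    path,
    mesh: TetMesh,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a tetrahedral mesh (plus optional element/nodal fields)."""
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    n, m = mesh.n_nodes, mesh.n_elements

    def arr_text(a, fmt="{:.17g}"):
        a = np.asarray(a)
        return " ".join(fmt.format(v) for v in a.ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        " <UnstructuredGrid>",
        f'  <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "   <Points>",
        '    <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr_text(mesh.nodes),
        "    </DataArray>",
        "   </Points>",
        "   <Cells>",
        '    <DataArray type="Int64" Name="connectivity" format="ascii">',
        arr_text(mesh.elems, "{:d}"),
        "    </DataArray>",
        '    <DataArray type="Int64" Name="offsets" format="ascii">',
        arr_text(4 * np.arange(1, m + 1), "{:d}"),
        "    </DataArray>",
        '    <DataArray type="UInt8" Name="types" format="ascii">',
        arr_text(np.full(m, VTK_TET), "{:d}"),
        "    </DataArray>",
        "   </Cells>",
    ]
    for tag, data in (("CellData", cell_data), ("PointData", point_data or {})):
        lines.append(f"   <{tag}>")
        for name, values in data.items():
            values = np.asarray(values)
            ncomp = 1 if values.ndim == 1 else values.shape[1]
            is_int = np.issubdtype(values.dtype, np.integer)
            dtype = "Int64" if is_int else "Float64"
            fmt = "{:d}" if is_int else "{:.17g}"
            lines.append(
                f'    <DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            lines.append(arr_text(values, fmt))
            lines.append("    </DataArray>")
        lines.append(f"   </{tag}>")
    lines += ["  </Piece>", " </UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def read_vtu(path):
    """Read an ASCII .vtu back into (TetMesh, cell_data, point_data)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as err:
        raise SpineFEError(
            f"{path}: corrupt VTU (parse error at line {err.position[0]}, "
            f"column {err.position[1]})"
        ) from err
    piece = root.find(".//Piece")
    if piece is None:
        raise SpineFEError(f"{path}: no <Piece> element")

    def parse_array(el, dtype):
        return np.fromstring(el.text.replace("\n", " "), sep=" ", dtype=dtype)

    pts = parse_array(piece.find("./Points/DataArray"), float).reshape(-1, 3)
    cells = {a.get("Name"): a for a in piece.findall("./Cells/DataArray")}
    types = parse_array(cells["types"], int)
    if not np.all(types == VTK_TET):
        raise SpineFEError(f"{path}: only tetrahedral cells are supported")
    conn = parse_array(cells["connectivity"], int).reshape(-1, 4)

    def read_fields(tag):
        out = {}
        sec = piece.find(f"./{tag}")
        if sec is None:
            return out
        for a in sec.findall("./DataArray"):
            dtype = int if a.get("type", "").startswith("Int") else float
            vals = parse_array(a, dtype)
            ncomp = int(a.get("NumberOfComponents", "1"))
            if ncomp > 1:
                vals = vals.reshape(-1, ncomp)
            out[a.get("Name")] = vals
        return out

    cell_data = read_fields("CellData")
    point_data = read_fields("PointData")
    region = cell_data.get("region", np.ones(len(conn), dtype=int))
    mesh = TetMesh(
        nodes=pts, elems=conn, region=np.asarray(region, dtype=int),
        inferior_nodes=np.empty(0, dtype=int),
        superior_nodes=np.empty(0, dtype=int),
    )
    return mesh, cell_data, point_data


def write_solution_vtu(path, mesh: TetMesh, solution,
                       card: MaterialCard | None = None) -> None:
    """Export a static solution: displacements as point data, principal
    stresses (and damage/material state when available) as cell data."""
    principal = solution.principal
    cell_data = {
        "sigma_I": principal[:, 0],
        "sigma_III": principal[:, 2],
    }
    if solution.damage is not None:
        cell_data["damage"] = solution.damage
    if card is not None:
        cell_data["hu"] = card.hu
        cell_data["Ez"] = card.Ez
        cell_data["sigma_max"] = card.sigma_max
    write_vtu(path, mesh, cell_data=cell_data,
              point_data={"displacement": solution.u})


# ---------------------------------------------------------------------------
# Abaqus .inp export (write-only)
# ---------------------------------------------------------------------------

def write_inp(path, mesh: TetMesh, card: MaterialCard | None = None,
              n_bins: int = 50) -> None:
    """Export mesh (+ materials) as an Abaqus input deck.

    Bone elements are grouped into ``n_bins`` element sets by Ez, each with
    one transversely isotropic material (engineering constants); annulus and
    nucleus get their constant isotropic materials.  Node sets mark the fixed
    inferior and loaded superior surfaces.  One-based ids, C3D4 elements.
    """
    out = ["*HEADING", "spinefe lumbar model export", "*NODE"]
    for i, p in enumerate(mesh.nodes, start=1):
        out.append(f"{i}, {p[0]:.8g}, {p[1]:.8g}, {p[2]:.8g}")

    groups: dict[str, np.ndarray] = {}
    if card is None:
        groups["ALL"] = np.arange(mesh.n_elements)
        mats = {"ALL": ("iso", 1000.0, 0.3)}
    else:
        mats = {}
        bone = card.is_bone
        if bone.any():
            ez = card.Ez[bone]
            edges = np.quantile(ez, np.linspace(0, 1, n_bins + 1))
            edges = np.unique(edges)
            which = np.clip(np.searchsorted(edges, ez, side="right") - 1,
                            0, len(edges) - 2)
            bone_ids = np.flatnonzero(bone)
            for b in range(len(edges) - 1):
                sel = bone_ids[which == b]
                if sel.size == 0:
                    continue
                name = f"BONE_{b:03d}"
                groups[name] = sel
                mats[name] = ("bone", float(card.Ez[sel].mean()), None)
        for code, label in ((REGION_ANNULUS, "ANNULUS"), (REGION_NUCLEUS, "NUCLEUS")):
            sel = np.flatnonzero(card.region == code)
            if sel.size:
                groups[label] = sel
                p = DISC_CONSTANTS[code]
                mats[label] = ("iso", p["E"], p["nu"])

    for name, ids in groups.items():
        out.append(f"*ELEMENT, TYPE=C3D4, ELSET={name}")
        for e in ids:
            n = mesh.elems[e] + 1
            out.append(f"{e + 1}, {n[0]}, {n[1]}, {n[2]}, {n[3]}")

    def nset(name, ids):
        out.append(f"*NSET, NSET={name}")
        ids = np.asarray(ids) + 1
        for i in range(0, len(ids), 8):
            out.append(", ".join(str(v) for v in ids[i: i + 8]))

    if len(mesh.inferior_nodes):
        nset("INFERIOR_FIXED", mesh.inferior_nodes)
    if len(mesh.superior_nodes):
        nset("SUPERIOR_LOAD", mesh.superior_nodes)

    for name, (kind, E, nu) in mats.items():
        out.append(f"*SOLID SECTION, ELSET={name}, MATERIAL=MAT_{name}")
        out.append(f"*MATERIAL, NAME=MAT_{name}")
        if kind == "iso":
            out.append("*ELASTIC")
            out.append(f"{E:.6g}, {nu}")
        else:
            ez = E
            ex = EX_RATIO * ez
            gxy, gxz = GXY_RATIO * ez, GXZ_RATIO * ez
            out.append("*ELASTIC, TYPE=ENGINEERING CONSTANTS")
            # E1, E2, E3, nu12, nu13, nu23, G12, G13 / G23
            out.append(
                f"{ex:.6g}, {ex:.6g}, {ez:.6g}, {NU_XY}, {NU_XZ}, {NU_XZ}, "
                f"{gxy:.6g}, {gxz:.6g}"
            )
            out.append(f"{gxz:.6g}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# records / curves
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    """SubjectRecord list -> tidy outcomes DataFrame."""
    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    for row in rows:
        row.pop("provenance", None)
    return pd.DataFrame(rows)


def save_records(records, path) -> None:
    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    Path(path).write_text(json.dumps(rows, indent=1, sort_keys=True))


def load_records(path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))


def save_curve_csv(curve, path) -> None:
    """Load-displacement or moment-angle curve -> two-column CSV."""
    if hasattr(curve, "displacement"):
        df = pd.DataFrame({
            "displacement_mm": curve.displacement, "force_N": curve.force,
        })
    else:
        df = pd.DataFrame({
            "moment_Nm": curve.moment, "angle_deg": curve.angle,
        })
    df.to_csv(path, index=False)
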