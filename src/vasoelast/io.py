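"""Documented text file formats for pipeline artifacts.

Meshes and displacement fields use a diffable whitespace format with a
header carrying version, units and counts; tabular artifacts (cohorts,
station areas, tracked grids, statistics) are CSV.  Every reader
validates structure and cross-references and reports the offending
line/row on failure; write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vasoelast.geometry import TriMesh
from vasoelast.fem import DisplacementField
from vasoelast.histology import COMPARTMENTS, SectionAreas
from vasoelast.tracking import DisplacementGrid

MESH_MAGIC = "# vasoelast mesh v1 (units: mm)"
FIELD_MAGIC = "# vasoelast field v1 (units: mm)"


class FormatError(ValueError):
    """Malformed pipeline file."""


# -- mesh ------------------------------------------------------------------

def write_mesh(mesh: TriMesh, path) -> None:
    lines = [MESH_MAGIC]
    lines.append(
        f"counts {mesh.n_nodes} {mesh.n_elements} "
        f"{mesh.inner_edges.shape[0]} {mesh.outer_edges.shape[0]}"
    )
    lines.append("nodes")
    lines += [f"{x:.17g} {y:.17g}" for x, y in mesh.nodes]
    lines.append("elements")
    lines += [
        f"{a} {b} {c} {r}" for (a, b, c), r in zip(mesh.elements, mesh.region)
    ]
    lines.append("inner_edges")
    lines += [f"{a} {b}" for a, b in mesh.inner_edges]
    lines.append("outer_edges")
    lines += [f"{a} {b}" for a, b in mesh.outer_edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path) -> TriMesh:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != MESH_MAGIC:
        raise FormatError(f"{path}:1: not a vasoelast mesh v1 file")
    try:
        _, *counts = lines[1].split()
        n_nodes, n_elem, n_in, n_out = map(int, counts)
    except Exception as exc:
        raise FormatError(f"{path}:2: bad counts line: {exc}") from exc
    idx = 2

    def expect(tag: str) -> None:
        nonlocal idx
        if idx >= len(lines) or lines[idx] != tag:
            raise FormatError(f"{path}:{idx + 1}: expected section {tag!r}")
        idx += 1

    expect("nodes")
    nodes = np.array(
        [list(map(float, lines[idx + i].split())) for i in range(n_nodes)]
    )
    idx += n_nodes
    expect("elements")
    elements, region = [], []
    for i in range(n_elem):
        parts = lines[idx + i].split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{idx + i + 1}: element needs 3 ids + region")
        elements.append([int(p) for p in parts[:3]])
        region.append(parts[3])
    idx += n_elem
    expect("inner_edges")
    inner = np.array([list(map(int, lines[idx + i].split())) for i in range(n_in)])
    idx += n_in
    expect("outer_edges")
    outer = np.array([list(map(int, lines[idx + i].split())) for i in range(n_out)])
    mesh = TriMesh(nodes, np.array(elements), np.array(region, dtype="U16"), inner, outer)
    mesh.validate()
    return mesh


# -- displacement field ----------------------------------------------------

def write_field(field: DisplacementField, path) -> None:
    lines = [FIELD_MAGIC, f"provenance {field.provenance}", f"count {field.values.shape[0]}"]
    lines += [f"{ux:.17g} {uy:.17g}" for ux, uy in field.values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_field(path, mesh: TriMesh | None = None) -> DisplacementField:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != FIELD_MAGIC:
        raise FormatError(f"{path}:1: not a vasoelast field v1 file")
    provenance = lines[1].split(maxsplit=1)[1]
    n = int(lines[2].split()[1])
    vals = np.array([list(map(float, lines[3 + i].split())) for i in range(n)])
    if mesh is not None and n != mesh.n_nodes:
        raise FormatError(
            f"{path}: field has {n} nodes but mesh has {mesh.n_nodes}"
        )
    return DisplacementField(vals, provenance=provenance)


# -- tracked grid ----------------------------------------------------------

def write_grid(grid: DisplacementGrid, path) -> None:
    zz, xx = np.meshgrid(
        grid.axial_stations_um, grid.lateral_stations_um, indexing="ij"
    )
    df = pd.DataFrame(
        {
            "axial_um": zz.reshape(-1),
            "lateral_um": xx.reshape(-1),
            "u_axial_um": grid.u_axial_um.reshape(-1),
            "u_lateral_um": grid.u_lateral_um.reshape(-1),
            "correlation": grid.correlation.reshape(-1),
        }
    )
    df.to_csv(path, index=False)


def read_grid(path) -> DisplacementGrid:
    df = pd.read_csv(path)
    za = np.unique(df["axial_um"])
    xa = np.unique(df["lateral_um"])
    shape = (za.size, xa.size)
    if len(df) != shape[0] * shape[1]:
        raise FormatError(f"{path}: stations do not form a regular grid")
    order = np.lexsort((df["lateral_um"], df["axial_um"]))
    return DisplacementGrid(
        axial_stations_um=za,
        lateral_stations_um=xa,
        u_axial_um=df["u_axial_um"].to_numpy()[order].reshape(shape),
        u_lateral_um=df["u_lateral_um"].to_numpy()[order].reshape(shape),
        correlation=df["correlation"].to_numpy()[order].reshape(shape),
    )


# -- histology station areas ----------------------------------------------

def write_areas(areas: SectionAreas, path) -> None:
    df = pd.DataFrame({"station_um": areas.stations_um})
    for name in COMPARTMENTS:
        if name in areas.areas_um2:
            df[f"{name}_um2"] = areas.areas_um2[name]
    df.to_csv(path, index=False)


def read_areas(path) -> SectionAreas:
    df = pd.read_csv(path)
    if "station_um" not in df:
        raise FormatError(f"{path}: missing 'station_um' column")
    areas = {}
    for name in COMPARTMENTS:
        col = f"{name}_um2"
        if col in df:
            vals = df[col].to_numpy(dtype=float)
            neg = np.where(np.isfinite(vals) & (vals < 0))[0]
            if neg.size:
                raise FormatError(
                    f"{path}: row {neg[0] + 2}, column {col}: negative area"
                )
            areas[name] = vals
    return SectionAreas(df["station_um"].to_numpy(dtype=float), areas)


# -- cohort tables / json --------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


_READERS = {
    "mesh": read_mesh,
    "field": read_field,
    "grid": read_grid,
    "areas": read_areas,
    "table": read_table,
    "json": read_json,
}
_WRITERS = {
    "mesh": write_mesh,
    "field": write_field,
    "grid": write_grid,
    "areas": write_areas,
    "table": write_table,
    "json": write_json,
}


def read_write_formats(path, kind: str, obj=None):
    """Dispatch read (``obj is None``) or write for a documented format."""
    if kind not in _READERS:
        raise FormatError(f"unknown artifact kind {kind!r}")
    if obj is None:
        return _READERS[kind](path)
    _WRITERS[kind](obj, path)
    return obj
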