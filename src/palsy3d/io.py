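"""Mesh and template-bundle I/O.

PLY (binary and ASCII) and OBJ are handled through :mod:`trimesh`.  Vertex
order is semantic for corresponded meshes, so all loads disable processing
and vertex merging; round-trips preserve the ordering exactly.

A template bundle is a mesh file plus a JSON sidecar holding the symmetry
pairing, midline set, landmark indices and axis convention.  Mesh files
store float32 coordinates (~1e-5 mm quantisation on a face-sized mesh), so
the loader restores the template's exact mirror symmetry by averaging each
vertex with its reflected pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .mesh import GenericTemplate, TriangleMesh

_SUPPORTED = {".ply", ".obj"}


def save_mesh(mesh: TriangleMesh, path: str | Path, *, ascii_ply: bool = False) -> Path:
    """Write a mesh as PLY (binary by default, ASCII on request) or OBJ."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .ply or .obj)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".ply":
        data = tm.export(file_type="ply", encoding="ascii" if ascii_ply else "binary")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        tm.export(path)
    return path


def load_mesh(path: str | Path) -> TriangleMesh:
    """Read a PLY/OBJ mesh, preserving vertex order."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .ply or .obj)")
    tm = trimesh.load(path, process=False, maintain_order=True, force="mesh")
    return TriangleMesh(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces))


def save_template(template: GenericTemplate, mesh_path: str | Path) -> tuple[Path, Path]:
    """Write a template bundle: mesh file + ``<stem>.template.json`` sidecar."""
    mesh_path = Path(mesh_path)
    save_mesh(template.mesh, mesh_path)
    sidecar = mesh_path.with_suffix(".template.json")
    sidecar.write_text(
        json.dumps(
            {
                "symmetry_pairs": template.symmetry_pairs.tolist(),
                "midline_vertices": sorted(template.midline_vertices),
                "landmark_indices": list(template.landmark_indices),
                "axis_convention": template.axis_convention,
            }
        )
    )
    return mesh_path, sidecar


def load_template(mesh_path: str | Path) -> GenericTemplate:
    """Read a template bundle written by :func:`save_template`.

    Exact mirror symmetry is re-imposed after the float32 mesh round-trip by
    averaging each vertex with the reflection of its symmetric partner.
    """
    mesh_path = Path(mesh_path)
    sidecar = mesh_path.with_suffix(".template.json")
    meta = json.loads(sidecar.read_text())
    mesh = load_mesh(mesh_path)
    pairs = np.asarray(meta["symmetry_pairs"], dtype=np.int64)
    v = mesh.vertices
    flip = np.array([-1.0, 1.0, 1.0])
    sym = 0.5 * (v + v[pairs] * flip)
    mesh = TriangleMesh(sym, mesh.faces)
    return GenericTemplate(
        mesh=mesh,
        symmetry_pairs=pairs,
        landmark_indices=tuple(meta["landmark_indices"]),
        midline_vertices=frozenset(meta["midline_vertices"]),
        axis_convention=meta["axis_convention"],
    )
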