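"""Multi-solid ASCII STL interchange.

The restoration arrives as a single STL holding three named solids:
``surface`` (external surface), ``distal`` and ``mesial`` (the two lumen
surfaces).  Binary STL cannot carry sub-solid names, so ASCII multi-solid
is the canonical format here; single meshes may still be written binary
through trimesh's exporter.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .geometry import make_mesh


def write_multi_stl(path, meshes: dict[str, trimesh.Trimesh]) -> None:
    """Write named solids into one ASCII STL file."""
    with open(path, "w") as fh:
        for name, mesh in meshes.items():
            fh.write(f"solid {name}\n")
            tri = mesh.triangles
            nrm = mesh.face_normals
            for t, n in zip(tri, nrm):
                fh.write(
                    f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n"
                    "    outer loop\n"
                )
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")


def read_multi_stl(path) -> dict[str, trimesh.Trimesh]:
    """Read named solids from an ASCII STL file, welding duplicated
    vertices within each solid."""
    solids: dict[str, trimesh.Trimesh] = {}
    name = None
    tris: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("solid"):
                name = s[5:].strip() or f"solid_{len(solids)}"
                tris = []
            elif s.startswith("vertex"):
                parts = s.split()
                tris.append([float(parts[1]), float(parts[2]), float(parts[3])])
            elif s.startswith("endsolid"):
                if name is None:
                    raise ValueError("malformed STL: endsolid before solid")
                solids[name] = _mesh_from_tris(np.array(tris), name)
                name = None
    if name is not None:
        raise ValueError("malformed STL: unterminated solid")
    if not solids:
        raise ValueError("no solids found in STL file")
    return solids


def _mesh_from_tris(verts: np.ndarray, name: str) -> trimesh.Trimesh:
    if len(verts) == 0 or len(verts) % 3:
        raise ValueError(f"solid {name!r} has a non-triangular vertex count")
    # weld exactly coincident vertices so boundary topology is recovered
    key = np.round(verts * 1e9).astype(np.int64)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    first = np.zeros(len(uniq), dtype=np.int64)
    first[inv[::-1]] = np.arange(len(verts))[::-1]
    points = verts[first]
    faces = inv.reshape(-1, 3)
    return make_mesh(points, faces, name=name)
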