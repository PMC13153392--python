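"""Readers and writers for meshes, reference organs, and registrations.

Mesh formats: OFF (the collision-detection working format) and binary GLB.
OFF output is written by this module with fixed number formatting so that
identical meshes serialize to byte-identical files; GLB goes through
trimesh's native glTF exporter. A reference organ on disk is a directory of
per-structure mesh files plus a ``manifest.csv`` with columns
``file, as_id, as_label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import InvalidGeometryError
from .geometry import ExtractionSite, ReferenceOrgan, make_mesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "write_off",
    "read_off",
    "glb_to_off",
    "load_reference_organ",
    "save_reference_organ",
    "read_extraction_sites",
    "write_extraction_sites",
]


def read_off(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), file_type="off", process=False)
    return _single_mesh(mesh, Path(path).stem)


def write_off(mesh: trimesh.Trimesh, path) -> None:
    """Deterministic OFF writer: fixed '%.9g' formatting, no comments."""
    lines = ["OFF", f"{len(mesh.vertices)} {len(mesh.faces)} 0"]
    lines += [
        f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in np.asarray(mesh.vertices, float)
    ]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in np.asarray(mesh.faces)]
    Path(path).write_text("\n".join(lines) + "\n")


def _single_mesh(loaded, fallback_id: str) -> trimesh.Trimesh:
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            raise InvalidGeometryError(
                f"expected one mesh per file, found {len(geoms)}"
            )
        loaded = geoms[0]
    if not isinstance(loaded, trimesh.Trimesh):
        raise InvalidGeometryError(f"not a triangle mesh: {type(loaded)}")
    loaded.metadata.setdefault("id", fallback_id)
    loaded.metadata.setdefault("label", fallback_id)
    return loaded


def read_mesh(path) -> trimesh.Trimesh:
    """Read a single mesh from OFF or GLB, inferring the format from the
    file extension."""
    path = Path(path)
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in {"off", "glb"}:
        raise InvalidGeometryError(f"unsupported mesh format: {path.suffix!r}")
    loaded = trimesh.load(str(path), file_type=suffix, process=False)
    return _single_mesh(loaded, path.stem)


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as OFF or GLB by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        write_off(mesh, path)
    elif suffix == ".glb":
        path.write_bytes(mesh.export(file_type="glb"))
    else:
        raise InvalidGeometryError(f"unsupported mesh format: {path.suffix!r}")


def glb_to_off(glb_path, off_path) -> trimesh.Trimesh:
    """Convert a GLB mesh file to OFF; returns the mesh."""
    mesh = read_mesh(glb_path)
    write_off(mesh, off_path)
    return mesh


def save_reference_organ(organ: ReferenceOrgan, directory, file_format: str = "off") -> None:
    """Write one mesh file per structure plus ``manifest.csv`` and
    ``organ.json`` (id and sex)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for as_id in sorted(organ.structures):
        mesh = organ.structures[as_id]
        fname = f"{as_id}.{file_format}"
        write_mesh(mesh, directory / fname)
        rows.append(
            {"file": fname, "as_id": as_id, "as_label": mesh.metadata.get("label", as_id)}
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    (directory / "organ.json").write_text(
        json.dumps({"id": organ.id, "sex": organ.sex}, indent=2) + "\n"
    )


def load_reference_organ(directory) -> ReferenceOrgan:
    directory = Path(directory)
    meta = json.loads((directory / "organ.json").read_text())
    manifest = pd.read_csv(directory / "manifest.csv", dtype=str)
    organ = ReferenceOrgan(id=meta["id"], sex=meta["sex"])
    for row in manifest.itertuples():
        mesh = read_mesh(directory / row.file)
        mesh.metadata["id"] = row.as_id
        mesh.metadata["label"] = row.as_label
        organ.add(mesh)
    return organ


def read_extraction_sites(path) -> list[ExtractionSite]:
    """Read registration records (a JSON list of site objects)."""
    records = json.loads(Path(path).read_text())
    if isinstance(records, dict):
        records = [records]
    return [ExtractionSite.from_dict(r) for r in records]


def write_extraction_sites(sites: list[ExtractionSite], path) -> None:
    Path(path).write_text(
        json.dumps([s.to_dict() for s in sites], indent=2) + "\n"
    )


def mesh_from_arrays(vertices, faces, label: str = "", id: str = "") -> trimesh.Trimesh:
    """Convenience re-export of :func:`hrapop.geometry.make_mesh`."""
    return make_mesh(vertices, faces, label=label, id=id)
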