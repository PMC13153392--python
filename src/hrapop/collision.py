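"""Collision detection between extraction sites and anatomical structures.

Two stages, mirroring the registration workflow: a cheap axis-aligned
bounding-box broad phase (:func:`bbox_collisions`) followed by exact
narrow-phase intersection-volume computation (:func:`mesh_collisions`).
Intersection percentages are always expressed relative to the extraction
site's volume, on a 0–100 scale.

The narrow phase computes intersection volumes exactly for convex operand
pairs (half-space enumeration); for non-convex structures it falls back to
the voxel oracle and flags the record accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import NotClosedError, OrganMismatchError
from .geometry import (
    ExtractionSite,
    ReferenceOrgan,
    convex_intersection_volume,
    cuboid_to_mesh,
    is_convex,
    validate_mesh,
    voxel_intersection_volume,
)

__all__ = [
    "CollisionRecord",
    "bbox_collisions",
    "mesh_collisions",
    "as_tags",
    "detect_reference_overlaps",
    "intersection_volume",
]

# below this fraction of the site volume a contact is treated as
# zero-volume touching, not a collision
_CONTACT_EPS = 1e-12


@dataclass(frozen=True)
class CollisionRecord:
    """One site-AS intersection: absolute volume and percentage of the
    extraction-site volume."""

    as_id: str
    as_label: str
    organ_id: str
    intersection_volume: float  # mm^3
    percentage_of_site: float  # 0-100
    exact: bool = True  # False when the voxel fallback produced the volume


def intersection_volume(
    mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh
) -> tuple[float, bool]:
    """Intersection volume of two closed meshes.

    Returns ``(volume_mm3, exact)``: exact convex-pair computation when both
    operands are convex, voxel-oracle estimate (``exact=False``) otherwise.
    """
    # quick reject on bounding boxes
    if (mesh_a.bounds[1] <= mesh_b.bounds[0]).any() or (
        mesh_b.bounds[1] <= mesh_a.bounds[0]
    ).any():
        return 0.0, True
    if is_convex(mesh_a) and is_convex(mesh_b):
        return convex_intersection_volume(mesh_a, mesh_b), True
    return voxel_intersection_volume(mesh_a, mesh_b), False


def _check_target(site: ExtractionSite, organ: ReferenceOrgan) -> None:
    if site.target_organ and site.target_organ != organ.id:
        raise OrganMismatchError(
            f"site {site.id!r} targets organ {site.target_organ!r}, "
            f"got {organ.id!r}"
        )


def bbox_collisions(site: ExtractionSite, organ: ReferenceOrgan) -> list[str]:
    """AS ids whose axis-aligned bounding box overlaps the site's.

    A superset of the mesh-based hits: the broad phase never rejects a true
    collision. Results are sorted by AS id for determinism.
    """
    _check_target(site, organ)
    lo_s, hi_s = cuboid_to_mesh(site).bounds
    hits = []
    for as_id in sorted(organ.structures):
        lo_a, hi_a = organ.structures[as_id].bounds
        if (hi_s > lo_a).all() and (hi_a > lo_s).all():
            hits.append(as_id)
    return hits


def mesh_collisions(
    site: ExtractionSite, organ: ReferenceOrgan
) -> list[CollisionRecord]:
    """Exact site-AS intersections, sorted by descending volume.

    AS meshes must be closed; meshes with simple holes are filled before
    the volume computation, anything worse raises :class:`NotClosedError`
    naming the structure. Zero-volume face contact is not a collision.
    Ties in the sort are broken lexicographically by AS id.
    """
    site_mesh = cuboid_to_mesh(site)
    site_volume = site.volume
    records = []
    for as_id in bbox_collisions(site, organ):
        as_mesh = organ.structures[as_id]
        try:
            _, as_mesh = validate_mesh(as_mesh, fill=True)
        except Exception as exc:
            raise NotClosedError(f"AS {as_id!r} is not a closed mesh: {exc}") from exc
        volume, exact = intersection_volume(site_mesh, as_mesh)
        if volume <= _CONTACT_EPS * site_volume:
            continue
        records.append(
            CollisionRecord(
                as_id=as_id,
                as_label=organ.label_of(as_id),
                organ_id=organ.id,
                intersection_volume=volume,
                percentage_of_site=100.0 * volume / site_volume,
                exact=exact,
            )
        )
    records.sort(key=lambda r: (-r.intersection_volume, r.as_id))
    return records


def as_tags(site: ExtractionSite, organ: ReferenceOrgan) -> list[str]:
    """AS labels of the mesh-based collisions, largest intersection first."""
    return [r.as_label for r in mesh_collisions(site, organ)]


def detect_reference_overlaps(
    organ: ReferenceOrgan,
) -> list[tuple[str, str, float]]:
    """All unordered AS pairs of an organ that share positive volume.

    Reference structures are supposed to tile the organ without overlap;
    this reports violations as ``(as_id_a, as_id_b, shared_mm3)`` with
    ``as_id_a < as_id_b``, sorted by id pair.
    """
    ids = sorted(organ.structures)
    overlaps = []
    for i, a in enumerate(ids):
        mesh_a = organ.structures[a]
        for b in ids[i + 1 :]:
            mesh_b = organ.structures[b]
            if (mesh_a.bounds[1] <= mesh_b.bounds[0]).any() or (
                mesh_b.bounds[1] <= mesh_a.bounds[0]
            ).any():
                continue
            vol, _ = intersection_volume(mesh_a, mesh_b)
            ref = min(abs(mesh_a.volume), abs(mesh_b.volume))
            if vol > _CONTACT_EPS * max(ref, 1.0):
                overlaps.append((a, b, vol))
    return overlaps


def collisions_to_frame(records: list[CollisionRecord]):
    """Collision records as a DataFrame with the CSV column layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "as_id": r.as_id,
                "as_label": r.as_label,
                "organ_id": r.organ_id,
                "intersection_volume_mm3": r.intersection_volume,
                "percentage_of_site": r.percentage_of_site,
            }
            for r in records
        ],
        columns=[
            "as_id",
            "as_label",
            "organ_id",
            "intersection_volume_mm3",
            "percentage_of_site",
        ],
    )
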