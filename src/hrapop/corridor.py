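"""Corridors: the 3D region of plausible extraction-site placements.

A corridor answers "where else could this tissue block have come from?"
It is the set of placements of the fixed-size, fixed-rotation cuboid that
reproduce the observed intersection volumes with the collided anatomical
structures within a relative tolerance (default 10%).

Construction follows a filter/search scheme:

* **filter** — each collided structure is approximated by its axis-aligned
  bounding box; the search area Omega is the set of cuboid-center
  translations whose bounding box can still reach every target box
  (a Minkowski expansion of each box by the site's half-extents).
* **search** — a sliding-window brute-force scan of Omega at a fixed step
  size; a candidate is feasible when every target's re-measured
  intersection volume is within tolerance of the observed one.

Three cases map collisions to corridor geometry: one collided structure
returns that structure's mesh verbatim; exactly two triggers the
filter/search and an offset alpha-wrap of the union of feasible cuboids;
three or more pins the block in place, returning the site cuboid itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.signal import fftconvolve
from skimage import measure

from .collision import mesh_collisions
from .errors import (
    InfeasibleDomainError,
    InvalidParameterError,
    NoCollisionError,
)
from .geometry import (
    ExtractionSite,
    ReferenceOrgan,
    convex_halfspaces,
    convex_intersection_volume,
    cuboid_to_mesh,
    is_axis_aligned_box,
)

__all__ = [
    "CorridorParams",
    "SearchDomain",
    "FeasibleSearch",
    "search_domain",
    "feasible_placements",
    "feasible_search",
    "build_corridor",
]


@dataclass(frozen=True)
class CorridorParams:
    """Search parameters.

    step:
        Sliding-window step in mm. ``None`` selects 10% of the smallest
        site dimension.
    tolerance:
        Relative feasibility tolerance on each target intersection volume.
    wrap_offset:
        Outward offset of the alpha-wrap surface, mm. ``None`` selects
        ``step / 2``.
    """

    step: float | None = None
    tolerance: float = 0.1
    wrap_offset: float | None = None

    def resolve(self, site: ExtractionSite) -> tuple[float, float, float]:
        step = self.step if self.step is not None else 0.1 * min(site.dimensions)
        wrap = self.wrap_offset if self.wrap_offset is not None else step / 2.0
        if step <= 0:
            raise InvalidParameterError(f"step must be positive, got {step}")
        if not 0 <= self.tolerance < 1:
            raise InvalidParameterError(
                f"tolerance must be in [0, 1), got {self.tolerance}"
            )
        if wrap < 0:
            raise InvalidParameterError(f"wrap_offset must be >= 0, got {wrap}")
        return step, self.tolerance, wrap


@dataclass(frozen=True)
class SearchDomain:
    """Axis-aligned box of candidate center translations (Omega)."""

    lower: np.ndarray
    upper: np.ndarray

    def contains(self, point, atol: float = 1e-9) -> bool:
        p = np.asarray(point, float)
        return bool((p >= self.lower - atol).all() and (p <= self.upper + atol).all())


@dataclass
class FeasibleSearch:
    """Result of the sliding-window search."""

    translations: np.ndarray  # (N, 3) feasible center translations
    inconsistent_targets: bool = False
    # per-placement ids of structures newly intersected beyond the targets
    # (not constrained, reported for diagnostics)
    extra_hits: list[list[str]] = field(default_factory=list)


def search_domain(
    site: ExtractionSite, target_as_meshes: list[trimesh.Trimesh]
) -> SearchDomain:
    """Omega: translations whose site bounding box can reach every target.

    Each target bounding box is expanded by the site's half-extents
    (a Minkowski sum); Omega is the intersection of the expanded boxes.
    Raises :class:`InfeasibleDomainError` when it is empty.
    """
    if not target_as_meshes:
        raise InfeasibleDomainError("no target structures")
    half = cuboid_to_mesh(site).extents / 2.0
    lower = np.full(3, -np.inf)
    upper = np.full(3, np.inf)
    for mesh in target_as_meshes:
        lo, hi = mesh.bounds
        lower = np.maximum(lower, lo - half)
        upper = np.minimum(upper, hi + half)
    if (lower > upper).any():
        raise InfeasibleDomainError(
            "target bounding boxes are farther apart than the site can span"
        )
    return SearchDomain(lower=lower, upper=upper)


def _grid(domain: SearchDomain, step: float) -> np.ndarray:
    axes = []
    for lo, hi in zip(domain.lower, domain.upper):
        n = int(np.floor((hi - lo) / step + 1e-9))
        axes.append(lo + step * np.arange(n + 1))
    return np.array(list(itertools.product(*axes)))


def _box_overlap_volumes(
    centers: np.ndarray, half: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Vectorized overlap volume of axis-aligned boxes (centers +- half)
    with the fixed box [lo, hi]."""
    lo_overlap = np.maximum(centers - half, lo)
    hi_overlap = np.minimum(centers + half, hi)
    edges = np.clip(hi_overlap - lo_overlap, 0.0, None)
    return edges.prod(axis=1)


def feasible_search(
    site: ExtractionSite,
    organ: ReferenceOrgan,
    targets: dict[str, float],
    params: CorridorParams = CorridorParams(),
) -> FeasibleSearch:
    """Brute-force sliding-window search of feasible placements.

    ``targets`` maps AS id to the observed intersection volume (mm^3) from
    a prior collision run. Rotation and dimensions stay fixed; only the
    center translation moves, on a regular grid over Omega at spacing
    ``step``. A candidate is feasible iff for every target
    ``|V(candidate) - V*| <= tolerance * V*``. The original translation is
    always included. Only the original targets constrain feasibility;
    structures newly intersected by a feasible placement are reported in
    ``extra_hits`` but not constrained.
    """
    step, tolerance, _ = params.resolve(site)
    target_meshes = {as_id: organ.structures[as_id] for as_id in targets}
    domain = search_domain(site, list(target_meshes.values()))
    original = np.asarray(site.translation, float)

    if any(v > site.volume * (1 + 1e-9) for v in targets.values()):
        # no placement can intersect more than the site's own volume
        return FeasibleSearch(
            translations=original[None, :], inconsistent_targets=True
        )

    candidates = _grid(domain, step)
    site_half = cuboid_to_mesh(site).extents / 2.0

    fast = all(r == 0 for r in site.rotation) and all(
        is_axis_aligned_box(m) for m in target_meshes.values()
    )
    feasible = np.ones(len(candidates), dtype=bool)
    if fast:
        half = np.asarray(site.dimensions, float) / 2.0
        for as_id, v_star in targets.items():
            lo, hi = target_meshes[as_id].bounds
            vols = _box_overlap_volumes(candidates, half, lo, hi)
            feasible &= np.abs(vols - v_star) <= tolerance * v_star
    else:
        base = cuboid_to_mesh(site)
        A_site, b_site = convex_halfspaces(base)
        for as_id, v_star in targets.items():
            mesh = target_meshes[as_id]
            lo, hi = mesh.bounds
            # bbox overlap is an upper bound on the true volume: prune
            upper = _box_overlap_volumes(
                candidates[feasible], site_half, lo, hi
            )
            keep_idx = np.flatnonzero(feasible)
            feasible[keep_idx[upper < (1 - tolerance) * v_star]] = False
        idx = np.flatnonzero(feasible)
        for i in idx:
            shifted = base.copy()
            shifted.apply_translation(candidates[i] - original)
            for as_id, v_star in targets.items():
                vol = convex_intersection_volume(shifted, target_meshes[as_id])
                if abs(vol - v_star) > tolerance * v_star:
                    feasible[i] = False
                    break

    placements = candidates[feasible]
    if not any(np.allclose(p, original, atol=1e-12) for p in placements):
        placements = np.vstack([placements, original[None, :]])

    # diagnostics: structures outside the target set that a feasible
    # placement would newly intersect (bounding-box level)
    extra_hits: list[list[str]] = []
    others = {
        as_id: organ.structures[as_id].bounds
        for as_id in sorted(organ.structures)
        if as_id not in targets
    }
    for p in placements:
        hits = [
            as_id
            for as_id, (lo, hi) in others.items()
            if ((p + site_half) > lo).all() and (hi > (p - site_half)).all()
        ]
        extra_hits.append(hits)
    return FeasibleSearch(
        translations=placements, inconsistent_targets=False, extra_hits=extra_hits
    )


def feasible_placements(
    site: ExtractionSite,
    organ: ReferenceOrgan,
    targets: dict[str, float],
    params: CorridorParams = CorridorParams(),
) -> np.ndarray:
    """Feasible center translations, shape (N, 3). See :func:`feasible_search`."""
    return feasible_search(site, organ, targets, params).translations


def _cuboid_kernel(site: ExtractionSite, pitch: float) -> np.ndarray:
    """Odd-sized voxel raster of the (rotated) site cuboid centered at the
    origin, with a half-voxel occupancy margin so the cuboid is covered."""
    base = cuboid_to_mesh(site.with_translation((0.0, 0.0, 0.0)))
    A, b = convex_halfspaces(base)
    half_extent = base.extents / 2.0
    k = np.ceil(half_extent / pitch).astype(int) + 1
    axes = [np.arange(-ki, ki + 1) * pitch for ki in k]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    # expand each face plane by half the voxel diagonal: every point of the
    # cuboid is then within an occupied voxel center's cell
    margin = pitch * np.sqrt(3.0) / 2.0
    inside = ((pts @ A.T + b) <= margin).all(axis=1)
    return inside.reshape(grid.shape[:3])


def _ball_kernel(radius_vox: int) -> np.ndarray:
    r = radius_vox
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x**2 + y**2 + z**2) <= r**2 + 1e-9


def _wrap_union(
    site: ExtractionSite,
    placements: np.ndarray,
    pitch: float,
    wrap_offset: float,
) -> trimesh.Trimesh:
    """Offset alpha-wrap of the union of cuboids at the given placements:
    voxel union (FFT convolution of the placement raster with a cuboid
    kernel), outward dilation by the wrap offset, marching-cubes surface."""
    kernel = _cuboid_kernel(site, pitch)
    dilate_vox = int(np.ceil(wrap_offset / pitch)) + 1
    half_kernel = (np.array(kernel.shape) // 2 + dilate_vox + 2) * pitch
    lo = placements.min(axis=0) - half_kernel
    hi = placements.max(axis=0) + half_kernel
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    raster = np.zeros(shape, dtype=float)
    idx = np.round((placements - lo) / pitch).astype(int)
    raster[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0

    occ = fftconvolve(raster, kernel.astype(float), mode="same") > 0.5
    occ = fftconvolve(
        occ.astype(float), _ball_kernel(dilate_vox).astype(float), mode="same"
    ) > 0.5

    padded = np.pad(occ, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * pitch + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def build_corridor(
    site: ExtractionSite,
    organ: ReferenceOrgan,
    params: CorridorParams = CorridorParams(),
) -> trimesh.Trimesh:
    """Corridor mesh for an extraction site.

    * one collided AS  -> that AS mesh, verbatim;
    * two collided ASs -> offset alpha-wrap of the union of all feasible
      cuboid placements found by the filter/search;
    * three or more    -> the block is pinned: the site cuboid itself.

    Raises :class:`NoCollisionError` when the site hits nothing.
    """
    records = mesh_collisions(site, organ)
    if not records:
        raise NoCollisionError(f"site {site.id!r} collides with no structure")
    if len(records) == 1:
        corridor = organ.structures[records[0].as_id].copy()
    elif len(records) >= 3:
        corridor = cuboid_to_mesh(site)
    else:
        step, _, wrap_offset = params.resolve(site)
        targets = {r.as_id: r.intersection_volume for r in records}
        search = feasible_search(site, organ, targets, params)
        corridor = _wrap_union(
            site, search.translations, pitch=step / 2.0, wrap_offset=wrap_offset
        )
    corridor.metadata["id"] = site.id
    corridor.metadata["label"] = f"corridor of {site.id}"
    return corridor
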