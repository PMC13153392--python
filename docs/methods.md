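# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind the package, and what the synthetic fixtures do
and do not show about real data.

## Coordinate and placement conventions

All geometry lives in a right-handed millimeter frame matching the
reference-organ mesh space. An extraction site is a cuboid defined by edge
lengths `(dx, dy, dz)`, a rotation, and a translation. Registration
conventions vary between tools and are rarely fully specified; this
package fixes one and applies it consistently everywhere, including the
fixtures: rotation is intrinsic X-then-Y-then-Z in degrees about the
cuboid *center*, followed by translation of the center. Volumes are
reported in mm³ and intersection percentages on a 0–100 scale with the
**site volume** as denominator.

## Intersection volumes

The narrow-phase intersection between a site cuboid and an AS mesh is
computed exactly for convex operand pairs: both polytopes are converted to
outward face half-spaces (via the convex hull, which deduplicates coplanar
triangles), a Chebyshev center is found by linear programming, and the
half-space intersection is enumerated with Qhull; its hull volume is the
intersection volume. A Chebyshev radius ≤ 1e-12 is treated as empty, which
also makes zero-volume face contact a non-collision by construction.

For non-convex structures the package falls back to the brute-force voxel
estimate and flags the record (`exact=False`). The voxel oracle samples
voxel centers over the axis-aligned overlap region of the two bounding
boxes in two passes: a first pass at 1/40 of the smallest overlap-box
edge, then a refinement at 1/40 of the measured intersection's
volume-equivalent edge, capped at ~3·10⁷ voxels. The refinement keeps
sliver-shaped intersections accurate; on convex fixtures the two-route
disagreement (exact vs voxel) stays around or below 2% relative, which is
also what the acceptance script measures. Point-in-mesh queries use the
generalized winding number (van Oosterom–Strackee solid angles), which is
robust for watertight meshes and needs no ray-casting acceleration
structure.

Mesh validation checks watertightness and winding consistency; hole
filling is limited to simple holes (delegated to trimesh's fan filling)
and anything unrepairable raises rather than guessing.

## Corridors

A corridor is the set of placements of the fixed-size, fixed-rotation site
that reproduce the observed intersection volume with every originally
collided AS within a relative tolerance τ (default 0.1, i.e. the deviation
may not exceed 10% of the true intersection volume). Construction follows
a filter/search scheme:

1. **Filter.** Each target AS is replaced by its bounding box expanded by
   the site's half-extents (a Minkowski sum). The intersection Ω of the
   expanded boxes is the set of center translations from which the site
   can still reach every target; an empty Ω is an error.
2. **Search.** A regular grid over Ω at step `s` (default 10% of the
   smallest site dimension) is scanned; a candidate is feasible iff every
   target volume is reproduced within τ. The original translation is
   always included. Only the original targets constrain feasibility;
   structures newly grazed by a feasible placement are reported as
   diagnostics but not constrained.

Three cases map collisions to geometry: one collided AS returns that AS
mesh verbatim (deliberately ignoring the partial intersection — the whole
structure is the plausible origin); exactly two trigger the search and an
offset wrap of the feasible union; three or more over-constrain the block,
which is returned pinned in place as the site cuboid itself.

The wrap is realized as a voxel union: feasible centers are rasterized at
pitch `s/2` and convolved (FFT) with a voxel kernel of the site cuboid
whose faces carry a half-voxel-diagonal margin, guaranteeing the union
covers every feasible cuboid; the union is then dilated by a ball of
radius `ceil(offset/pitch) + 1` voxels (offset default `s/2`) and surfaced
with marching cubes. Any backend meeting the containment-and-closedness
contract would do; this one is fully deterministic, so identical inputs
yield byte-identical OFF files (the OFF writer uses fixed `%.9g`
formatting).

Candidate evaluation uses a vectorized interval-arithmetic fast path when
the site is unrotated and every target is an axis-aligned box (true for
all shipped fixtures); otherwise each surviving candidate (after a
bounding-box-volume upper-bound prune) is evaluated with the exact convex
intersection. The general path is O(ms) per candidate, so rotated-site
searches should use coarser steps.

## Populations

Cell-type populations are per-owner (dataset / extraction site / AS),
per-tool tables of `(ct_id, ct_label, count, percentage)` with percentages
summing to 100 ± 1e-6, enforced at construction. Tools are never mixed
within one population; the preferred annotation per dataset follows the
order azimuth > celltypist > popv, with author-annotated proteomics as its
own tool.

- **Crosswalks** map `(tool, source_label)` to ontology terms with
  `exact` or `narrow` (more general class) match semantics, stored
  verbatim; no ontology reasoning is performed. Labels sharing a target
  merge (counts summed); unmapped labels are retained, flagged, and
  reported — total cells are conserved exactly.
- **Markers.** Per cell type, genes are ranked by standardized mean
  difference (pooled-SD denominator, stabilized by +1e-9) between
  in-group and rest-of-dataset expression after per-cell normalization to
  10,000 counts and log1p. The statistic is fixed here for
  reproducibility; equal scores break lexicographically by gene symbol.
  Mean in-group and rest expressions are recorded on the transformed
  scale for the top-n (default 10) genes. Raw counts are taken from the
  raw layer when a dataset carries both raw and processed matrices.
- **QC.** Ribosomal genes are symbols prefixed `RPS`/`RPL`, mitochondrial
  ones `MT-`; per-cell percentages of total counts are summarized as
  mean/median/SD per dataset, excluding (but counting) all-zero cells.
- **Rollup** to high-level classes buckets crosswalked types without a
  parent as `no_mapped_parent` and never-crosswalked labels as
  `not_crosswalked`.
- **Similarity.** Weighted cosine over the union of ct ids using
  percentage vectors; default weights are 1 (the weighting is an open
  choice and accepted as input); zero-norm vectors give 0. Origin
  prediction sorts candidates by descending similarity, ties broken by
  id.
- **Z-scores** standardize each cell-type row of a mean-percentage matrix
  with the population SD; constant rows map to 0.

## Aggregation

Extraction-site populations are plain sums of their datasets' counts. AS
populations scale each site's counts by its intersection percentage / 100
before summing; weighted counts stay fractional (rounding is left to the
presentation layer). Aggregation is grouped strictly by (AS, organ sex,
tool). Whether production systems aggregate raw counts (as here) or
per-dataset percentages across unequal datasets is an open design choice;
raw counts were chosen so that cell conservation
(`AS counts = dataset counts × p`, exact to 1e-9) holds.

The quality gate treats failures as data, not errors. Age must be strictly
greater than 18; missing age or sex fails C4, except for sources
attested adult-only via an explicit per-source flag (covering portals that
publish only age ranges). The minimum-cell rule (≥ 100 cells) is applied
before any population is computed. Duplicate dataset ids are rejected; no
cross-portal duplicate detection is attempted.

## Synthetic fixtures

Generators are pure functions of (spec, seed). Organs are rows of convex
structures (boxes, icospheres, triangular prisms) of 10 mm size with 2 mm
gaps (0 for straddle fixtures, making boxes share faces); convexity keeps
the interval and voxel oracles exact or tightly bounded. Sites are placed
unrotated with analytic intersection truth from 1D interval overlaps.
Cells draw labels from a specified mixture (multinomial, so the recorded
truth is the exact draw) and counts from a negative binomial (dispersion
2.0) with type-exclusive marker genes at mean 20 vs background 0.5 —
chosen to give clearly separable signatures at realistic overdispersion,
not to mimic any particular assay. Default dataset size is 500–1,000
cells with 2–6 types, small enough that the full pipeline and its tests
run in minutes on one CPU; the acceptance script uses 50 random geometry
fixtures and 3-structure organs for the same reason.

Passing tests on these fixtures demonstrates the correctness of the
computations (collision volumes, gating logic, weighted aggregation,
ranking, determinism) — not robustness to the messiness of real data:
non-convex anatomy, imperfect meshes beyond simple holes, ambiguous
labels, batch effects, or annotation-tool disagreement are all out of
fixture scope.

## Known limitations

- Exact intersection requires convex operands; non-convex structures use
  the flagged voxel fallback.
- Reference structures are assumed non-overlapping for the sum-bound
  invariant; actual overlaps are detectable (`detect_reference_overlaps`)
  and both structures then receive full records.
- Corridor search explores translations only (rotation and size fixed),
  and case distinctions follow the collided-structure count literally
  (two vs three or more).
- Hole filling handles simple planar holes only.
- No portal clients, annotation-tool execution, or knowledge-graph
  publication: inputs are local files in the documented formats.
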