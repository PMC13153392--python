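"""Deterministic synthetic data: organs, sites, cells, crosswalks.

Every generator is a pure function of its spec and seed, and every fixture
carries machine-readable ground truth so end-to-end tests can verify
recovery without magic numbers:

* reference organs are grids of disjoint convex structures (boxes,
  icospheres, triangular prisms) laid out along the x axis, optionally
  with one deliberately overlapping pair;
* extraction sites are placed with known analytic intersection volumes
  (interval arithmetic on axis-aligned boxes);
* cell datasets draw type labels from a specified mixture and synthesize
  overdispersed (negative-binomial) counts with type-exclusive marker
  genes, plus a few ribosomal/mitochondrial genes for QC exercises;
* crosswalks map raw tool labels onto toy ontology ids with exact and
  narrow matches and a controllable unmapped fraction.

The geometry is deliberately convex so the interval and voxel oracles used
in tests are exact or tightly bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import InvalidParameterError
from .geometry import ExtractionSite, ReferenceOrgan, make_mesh
from .pipeline import AtlasInputs, DatasetRecord
from .populations import CellTable, CrosswalkTable, DonorMetadata

__all__ = [
    "OrganSpec",
    "DatasetSpec",
    "SiteTruth",
    "AtlasFixture",
    "make_reference_organ",
    "make_extraction_sites",
    "make_cell_dataset",
    "make_crosswalk",
    "make_atlas_fixture",
]

SHAPES = ("box", "sphere", "prism")


@dataclass(frozen=True)
class OrganSpec:
    """Layout of a synthetic reference organ.

    Structures of edge/diameter ``size`` mm are placed along the x axis
    with ``gap`` mm between cells; ``gap=0`` makes neighboring boxes share
    a face (used by straddling-site fixtures). ``overlap_pairs=1`` appends
    one extra structure that overlaps the first by a 1 mm slab.
    """

    n_structures: int = 3
    shapes: tuple[str, ...] = ("box",)
    size: float = 10.0
    gap: float = 2.0
    sex: str = "female"
    organ_id: str = "organ-fixture"
    overlap_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_structures < 1:
            raise InvalidParameterError("n_structures must be >= 1")
        bad = set(self.shapes) - set(SHAPES)
        if bad:
            raise InvalidParameterError(f"unknown shapes: {sorted(bad)}")


@dataclass(frozen=True)
class DatasetSpec:
    """Cell-level generator settings for one dataset.

    ``mixture`` maps cell-type name to fraction (must sum to 1). Each type
    gets ``markers_per_ct`` exclusive genes with negative-binomial counts
    of mean ``marker_mean`` inside the type and ``background_mean``
    elsewhere; ``dispersion`` is the NB shape parameter (smaller = noisier).
    """

    mixture: dict[str, float] = field(
        default_factory=lambda: {"ct1": 0.6, "ct2": 0.4}
    )
    cells_per_dataset: int = 500
    markers_per_ct: int = 3
    n_housekeeping: int = 4
    marker_mean: float = 20.0
    background_mean: float = 0.5
    dispersion: float = 2.0
    tool: str = "azimuth"
    age_range: tuple[int, int] = (25, 70)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"mixture sums to {total}, expected 1")


@dataclass
class SiteTruth:
    """A generated site with its analytic intersection ground truth."""

    site: ExtractionSite
    expected: dict[str, tuple[float, float]]  # as_id -> (volume mm^3, pct of site)


# --------------------------------------------------------------------------
# geometry fixtures
# --------------------------------------------------------------------------


def _structure_mesh(shape: str, size: float, center: np.ndarray) -> trimesh.Trimesh:
    if shape == "box":
        mesh = trimesh.creation.box(extents=(size, size, size))
        mesh.apply_translation(center)
    elif shape == "sphere":
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=0.45 * size)
        mesh.apply_translation(center)
    else:  # prism: triangle in xy extruded along z, convex
        h = size / 2.0
        tri = np.array([[-h, -h], [h, -h], [0.0, h]])
        pts = np.vstack(
            [np.column_stack([tri, np.full(3, -h)]), np.column_stack([tri, np.full(3, h)])]
        )
        mesh = trimesh.convex.convex_hull(pts + center)
    return mesh


def make_reference_organ(spec: OrganSpec) -> tuple[ReferenceOrgan, pd.DataFrame]:
    """Generate a reference organ of disjoint convex structures.

    Returns the organ and a manifest DataFrame (file, as_id, as_label);
    the ``file`` column is filled when the organ is saved to disk.
    """
    organ = ReferenceOrgan(id=spec.organ_id, sex=spec.sex)
    pitch = spec.size + spec.gap
    rows = []
    for i in range(spec.n_structures):
        shape = spec.shapes[i % len(spec.shapes)]
        center = np.array([i * pitch + spec.size / 2.0, spec.size / 2.0, spec.size / 2.0])
        mesh = _structure_mesh(shape, spec.size, center)
        as_id = f"AS{i + 1}"
        mesh.metadata["id"] = as_id
        mesh.metadata["label"] = f"structure {i + 1} ({shape})"
        organ.add(mesh)
        rows.append({"file": f"{as_id}.off", "as_id": as_id, "as_label": mesh.metadata["label"]})
    for j in range(spec.overlap_pairs):
        # a thin box overlapping structure j+1 by a 1 mm slab in x and
        # reaching 1 mm into the gap (never touching the next structure)
        mesh = trimesh.creation.box(extents=(2.0, spec.size, spec.size))
        mesh.apply_translation(
            [j * pitch + spec.size, spec.size / 2.0, spec.size / 2.0]
        )
        as_id = f"AS-overlap-{j + 1}"
        mesh.metadata["id"] = as_id
        mesh.metadata["label"] = f"overlapping structure {j + 1}"
        organ.add(mesh)
        rows.append({"file": f"{as_id}.off", "as_id": as_id, "as_label": mesh.metadata["label"]})
    return organ, pd.DataFrame(rows)


def _box_overlap(site: ExtractionSite, lo: np.ndarray, hi: np.ndarray) -> float:
    """Interval-arithmetic overlap of an unrotated site with a box."""
    c = np.asarray(site.translation)
    h = np.asarray(site.dimensions) / 2.0
    edges = np.clip(np.minimum(c + h, hi) - np.maximum(c - h, lo), 0.0, None)
    return float(edges.prod())


def _truth_for(site: ExtractionSite, organ: ReferenceOrgan) -> dict[str, tuple[float, float]]:
    """Analytic intersections of an unrotated site with box structures;
    non-box structures are only used in full-containment placements where
    the intersection is the whole site."""
    expected = {}
    for as_id in sorted(organ.structures):
        mesh = organ.structures[as_id]
        vol = _box_overlap(site, *mesh.bounds)
        bbox_is_exact = abs(abs(mesh.volume) - float(np.prod(mesh.extents))) < 1e-6
        if vol > 1e-12 and bbox_is_exact:
            expected[as_id] = (vol, 100.0 * vol / site.volume)
    return expected


def make_extraction_sites(
    organ: ReferenceOrgan,
    n: int,
    containment: str = "full",
    seed: int = 0,
    site_fraction: float = 0.5,
) -> list[SiteTruth]:
    """Place ``n`` unrotated cuboid sites with known analytic truth.

    containment:
        ``full`` — each site sits wholly inside one structure (round-robin);
        ``straddle2`` — sites span the shared face of adjacent boxes 50/50
        (requires ``gap=0`` box organs);
        ``straddle3`` — long sites spanning three consecutive boxes;
        ``outside`` — sites placed far from every structure.
    """
    ids = sorted(k for k in organ.structures if not k.startswith("AS-overlap"))
    rng = np.random.default_rng(seed)
    out: list[SiteTruth] = []
    for i in range(n):
        if containment == "full":
            as_id = ids[i % len(ids)]
            mesh = organ.structures[as_id]
            center = mesh.bounds.mean(axis=0)
            # inscribed cube edge: safe for box, sphere and prism fixtures
            edge = site_fraction * mesh.extents.min() / np.sqrt(3.0)
            site = ExtractionSite(
                id=f"site-{containment}-{i + 1}",
                dimensions=(edge, edge, edge),
                translation=tuple(center),
                target_organ=organ.id,
                organ_sex=organ.sex,
            )
            expected = {as_id: (site.volume, 100.0)}
        elif containment == "straddle2":
            a = ids[i % (len(ids) - 1)]
            b = ids[i % (len(ids) - 1) + 1]
            hi_a = organ.structures[a].bounds[1]
            lo_b = organ.structures[b].bounds[0]
            if abs(hi_a[0] - lo_b[0]) > 1e-9:
                raise InvalidParameterError(
                    "straddle2 needs adjacent boxes (organ gap = 0)"
                )
            extent = organ.structures[a].extents
            edge = site_fraction * extent.min()
            center = organ.structures[a].bounds.mean(axis=0).copy()
            center[0] = hi_a[0]  # on the shared face: exact 50/50 split
            site = ExtractionSite(
                id=f"site-{containment}-{i + 1}",
                dimensions=(edge, edge, edge),
                translation=tuple(center),
                target_organ=organ.id,
                organ_sex=organ.sex,
            )
            expected = _truth_for(site, organ)
        elif containment == "straddle3":
            j = 1 + (i % max(len(ids) - 2, 1))
            mid = organ.structures[ids[j]]
            extent = mid.extents
            center = mid.bounds.mean(axis=0)
            edge = site_fraction * extent.min()
            dims = (extent[0] * 1.5, edge, edge)
            site = ExtractionSite(
                id=f"site-{containment}-{i + 1}",
                dimensions=dims,
                translation=tuple(center),
                target_organ=organ.id,
                organ_sex=organ.sex,
            )
            expected = _truth_for(site, organ)
        elif containment == "outside":
            edge = 2.0
            offset = rng.uniform(50.0, 80.0)
            site = ExtractionSite(
                id=f"site-{containment}-{i + 1}",
                dimensions=(edge, edge, edge),
                translation=(0.0, -offset, -offset),
                target_organ=organ.id,
                organ_sex=organ.sex,
            )
            expected = {}
        else:
            raise InvalidParameterError(f"unknown containment mode {containment!r}")
        out.append(SiteTruth(site=site, expected=expected))
    return out


# --------------------------------------------------------------------------
# cell fixtures
# --------------------------------------------------------------------------

QC_GENES = ("RPS1", "RPL1", "MT-ND1")


def _nb_counts(rng, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def make_cell_dataset(
    spec: DatasetSpec, site: ExtractionSite, dataset_id: str | None = None
) -> tuple[CellTable, DonorMetadata, dict[str, int]]:
    """Synthesize one annotated dataset for a site.

    Returns ``(cells, donor, truth_counts)`` where ``truth_counts`` are the
    exact per-type cell counts drawn from the mixture (the generator's
    ground-truth population). Labels in the table are raw tool labels
    (``<ct>-raw``) to exercise the crosswalk.
    """
    rng = np.random.default_rng(spec.seed)
    cts = sorted(spec.mixture)
    fractions = np.array([spec.mixture[c] for c in cts])
    counts = rng.multinomial(spec.cells_per_dataset, fractions)
    labels = np.repeat(cts, counts)
    rng.shuffle(labels)
    dataset_id = dataset_id or f"ds-{site.id}-{spec.seed}"

    obs = pd.DataFrame(
        {
            "cell_id": [f"{dataset_id}-c{i:05d}" for i in range(len(labels))],
            "ct_label": [f"{c}-raw" for c in labels],
            "tool": spec.tool,
        }
    )

    marker_genes = [
        f"MK-{c}-{j + 1}" for c in cts for j in range(spec.markers_per_ct)
    ]
    hk_genes = [f"HK-{j + 1}" for j in range(spec.n_housekeeping)]
    genes = marker_genes + hk_genes + list(QC_GENES)
    X = _nb_counts(
        rng, spec.background_mean, spec.dispersion, (len(labels), len(genes))
    ).astype(float)
    for k, c in enumerate(cts):
        rows = np.flatnonzero(labels == c)
        for j in range(spec.markers_per_ct):
            col = k * spec.markers_per_ct + j
            X[rows, col] = _nb_counts(
                rng, spec.marker_mean, spec.dispersion, len(rows)
            )
    # housekeeping + QC genes: moderate uniform expression everywhere
    hk_cols = np.arange(len(marker_genes), len(genes))
    X[:, hk_cols] = _nb_counts(rng, 3.0, spec.dispersion, (len(labels), len(hk_cols)))

    donor = DonorMetadata(
        donor_id=f"donor-{dataset_id}",
        age=int(rng.integers(spec.age_range[0], spec.age_range[1] + 1)),
        sex=site.organ_sex,
        bmi=float(np.round(rng.uniform(18.0, 35.0), 1)),
        race="unknown",
    )
    truth = {f"{c}-raw": int(n) for c, n in zip(cts, counts)}
    cells = CellTable(obs=obs, matrix=X, var_names=genes)
    return cells, donor, truth


def make_crosswalk(
    cts: list[str],
    unmapped_fraction: float = 0.0,
    seed: int = 0,
    tools: tuple[str, ...] = ("azimuth", "celltypist", "popv", "sc_proteomics"),
) -> tuple[CrosswalkTable, dict[str, str], dict[str, str]]:
    """Toy crosswalk, parent map, and gene-id lookup for fixture types.

    The first ``round(unmapped_fraction * len(cts))`` types are omitted
    from the crosswalk (deterministic), so they surface in unmapped
    reports. Two extra child labels map narrowly onto the first mapped
    type's target to exercise merge-on-crosswalk.
    """
    n_unmapped = int(round(unmapped_fraction * len(cts)))
    mapped = cts[n_unmapped:]
    rows = []
    for tool in tools:
        for k, ct in enumerate(mapped):
            rows.append(
                {
                    "tool": tool,
                    "source_label": f"{ct}-raw",
                    "source_id": "",
                    "target_id": f"CL:{k + 1:07d}",
                    "target_label": ct,
                    "match_type": "exact",
                }
            )
        if mapped:
            for child in ("a", "b"):
                rows.append(
                    {
                        "tool": tool,
                        "source_label": f"{mapped[0]}-child-{child}-raw",
                        "source_id": "",
                        "target_id": "CL:0000001",
                        "target_label": mapped[0],
                        "match_type": "narrow",
                    }
                )
    table = CrosswalkTable(rows=pd.DataFrame(rows))
    parent_map = {
        f"CL:{k + 1:07d}": ("CL:HIGH-A" if k % 2 == 0 else "CL:HIGH-B")
        for k in range(len(mapped))
    }
    gene_lookup = {f"ENSF{i + 1:06d}": f"GENE{chr(65 + i)}" for i in range(5)}
    return table, parent_map, gene_lookup


# --------------------------------------------------------------------------
# atlas presets
# --------------------------------------------------------------------------


@dataclass
class AtlasFixture:
    """A complete synthetic atlas input with its ground truth."""

    inputs: AtlasInputs
    site_truths: list[SiteTruth]
    dataset_truth: dict[str, dict[str, int]]  # dataset_id -> raw label -> count
    label_to_target: dict[str, str]  # raw label -> CL id
    expected_as_counts: dict[tuple[str, str, str], dict[str, float]]


def _expected_as_counts(fixture_sites, datasets, truths, label_to_target, sex):
    """Analytic ASpop oracle: dataset counts x intersection fraction,
    summed per (AS, sex, tool) over crosswalked ids."""
    by_site: dict[str, list[DatasetRecord]] = {}
    for ds in datasets:
        by_site.setdefault(ds.extraction_site_id, []).append(ds)
    expected: dict[tuple[str, str, str], dict[str, float]] = {}
    for st in fixture_sites:
        for ds in by_site.get(st.site.id, []):
            tool = ds.cells.obs["tool"].iloc[0]
            for as_id, (_, pct) in st.expected.items():
                key = (as_id, sex, tool)
                bucket = expected.setdefault(key, {})
                for raw_label, count in truths[ds.dataset_id].items():
                    target = label_to_target.get(raw_label, raw_label)
                    bucket[target] = bucket.get(target, 0.0) + count * pct / 100.0
    return expected


def make_atlas_fixture(preset: str = "small", seed: int = 0) -> AtlasFixture:
    """Build a ready-to-run synthetic atlas.

    ``small``: 3 disjoint box structures, 6 datasets on fully contained
    sites (two per structure), all passing the gate. ``straddle``: adjacent
    boxes with 50/50 straddling sites. ``kidney-like``: 5 mixed-shape
    structures, 8 datasets, full containment.
    """
    if preset == "small":
        organ_spec = OrganSpec(n_structures=3, shapes=("box",), seed=seed)
        n_datasets, containment = 6, "full"
    elif preset == "straddle":
        organ_spec = OrganSpec(n_structures=3, shapes=("box",), gap=0.0, seed=seed)
        n_datasets, containment = 4, "straddle2"
    elif preset == "kidney-like":
        organ_spec = OrganSpec(
            n_structures=5, shapes=("box", "sphere", "prism"), seed=seed
        )
        n_datasets, containment = 8, "full"
    else:
        raise InvalidParameterError(f"unknown preset {preset!r}")

    organ, _ = make_reference_organ(organ_spec)
    n_sites = max(2, n_datasets // 2)
    site_truths = make_extraction_sites(
        organ, n_sites, containment=containment, seed=seed
    )

    as_ids = sorted(organ.structures)
    mixtures = {
        as_id: {
            f"ct{2 * k + 1}": 0.7,
            f"ct{2 * k + 2}": 0.3,
        }
        for k, as_id in enumerate(as_ids)
    }
    all_cts = sorted({c for m in mixtures.values() for c in m})
    crosswalk, parent_map, _ = make_crosswalk(all_cts, seed=seed)
    label_to_target = {
        row.source_label: row.target_id
        for row in crosswalk.rows[crosswalk.rows["tool"] == "azimuth"].itertuples()
    }

    datasets: list[DatasetRecord] = []
    truths: dict[str, dict[str, int]] = {}
    for i in range(n_datasets):
        st = site_truths[i % len(site_truths)]
        # mixture of the structure holding (or dominating) the site
        primary = max(st.expected, key=lambda a: st.expected[a][0])
        spec = DatasetSpec(mixture=mixtures[primary], seed=seed * 1000 + i)
        dataset_id = f"ds-{i + 1:03d}"
        cells, donor, truth = make_cell_dataset(spec, st.site, dataset_id)
        truths[dataset_id] = truth
        datasets.append(
            DatasetRecord(
                dataset_id=dataset_id,
                donor=donor,
                modality="sc_transcriptomics",
                source="portal_with_qc",
                extraction_site_id=st.site.id,
                cells=cells,
            )
        )

    inputs = AtlasInputs(
        organs=[organ],
        sites=[st.site for st in site_truths],
        datasets=datasets,
        crosswalk=crosswalk,
        parent_map=parent_map,
    )
    expected = _expected_as_counts(
        site_truths, datasets, truths, label_to_target, organ.sex
    )
    return AtlasFixture(
        inputs=inputs,
        site_truths=site_truths,
        dataset_truth=truths,
        label_to_target=label_to_target,
        expected_as_counts=expected,
    )
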