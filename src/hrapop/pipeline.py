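"""End-to-end atlas construction: gate, collide, aggregate, report.

The workflow takes annotated datasets, their registered extraction sites,
and the reference-organ meshes, and produces:

* **DESpop** — populations of every passing dataset and extraction site;
* **ASpop** — populations of anatomical structures, aggregated across the
  colliding sites weighted by each site's intersection percentage;
* reports — quality-gate outcomes, collision records, unmapped labels,
  and count tables.

A dataset enters the atlas only when it passes the quality gate:

* C1 — it has a registered 3D extraction site with at least one AS tag;
* C2 — it has a cell-type population;
* C3 — it comes from a QC'd portal or a peer-reviewed publication;
* C4 — healthy adult donor: disease-free status, sex recorded, and age
  recorded and strictly greater than 18 (sources attested adult-only may
  omit the exact age);

plus the minimum-cell rule: datasets with fewer than 100 cells are
excluded before any population is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .collision import CollisionRecord, mesh_collisions
from .errors import EmptyInputError, InvalidParameterError, ProvenanceError
from .geometry import ExtractionSite, ReferenceOrgan
from .populations import (
    CellTable,
    CellTypePopulation,
    CrosswalkTable,
    DonorMetadata,
    apply_crosswalk,
    population_from_cell_table,
    populations_to_csv,
)

__all__ = [
    "DatasetRecord",
    "GateResult",
    "AtlasInputs",
    "AtlasResult",
    "min_cell_filter",
    "check_criteria",
    "aggregate_extraction_site",
    "aggregate_as_population",
    "select_tool",
    "build_atlas",
    "report_counts",
    "DEFAULT_TOOL_PREFERENCE",
    "MIN_CELLS",
]

MIN_CELLS = 100
DEFAULT_TOOL_PREFERENCE = ("azimuth", "celltypist", "popv")

VALID_SOURCES = frozenset({"portal_with_qc", "publication", "other"})


@dataclass
class DatasetRecord:
    """One experimental dataset with its donor and provenance metadata."""

    dataset_id: str
    donor: DonorMetadata
    modality: str = "sc_transcriptomics"
    source: str = "portal_with_qc"
    extraction_site_id: str | None = None
    cells: CellTable | None = None
    disease_status: str = "healthy"  # healthy / other / missing
    adult_only_source: bool = False  # source attests adult donors (age ranges only)

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise InvalidParameterError(
                f"source must be one of {sorted(VALID_SOURCES)}, got {self.source!r}"
            )


@dataclass(frozen=True)
class GateResult:
    dataset_id: str
    passed: bool
    failed_criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_criteria) == 0)


def min_cell_filter(cells: CellTable | None, threshold: int = MIN_CELLS) -> bool:
    """True when the dataset has at least ``threshold`` cells."""
    return cells is not None and len(cells) >= threshold


def check_criteria(
    ds: DatasetRecord,
    site_tags: Mapping[str, Sequence[str]],
    populations: Mapping[str, Sequence[CellTypePopulation]],
    min_cells: int = MIN_CELLS,
) -> GateResult:
    """Evaluate the quality gate for one dataset.

    ``site_tags`` maps extraction-site id to its AS tags (from collision
    detection); ``populations`` maps dataset id to its available
    populations. Failures are data, not errors.
    """
    failed: list[str] = []
    tags = site_tags.get(ds.extraction_site_id) if ds.extraction_site_id else None
    if ds.extraction_site_id is None or tags is None or len(tags) == 0:
        failed.append("C1")
    if not populations.get(ds.dataset_id):
        failed.append("C2")
    if ds.source not in ("portal_with_qc", "publication"):
        failed.append("C3")
    donor = ds.donor
    age_ok = (donor.age is not None and donor.age > 18) or ds.adult_only_source
    if ds.disease_status != "healthy" or donor.sex is None or not age_ok:
        failed.append("C4")
    if not min_cell_filter(ds.cells, min_cells):
        failed.append("MIN_CELLS")
    return GateResult(
        dataset_id=ds.dataset_id, passed=not failed, failed_criteria=tuple(failed)
    )


def select_tool(
    pops: Sequence[CellTypePopulation],
    preference: Sequence[str] = DEFAULT_TOOL_PREFERENCE,
) -> CellTypePopulation:
    """Pick one population per dataset by tool preference order; falls back
    to the lexicographically first remaining tool (covers sc-proteomics)."""
    if not pops:
        raise EmptyInputError("no populations to select from")
    by_tool = {p.tool: p for p in pops}
    for tool in preference:
        if tool in by_tool:
            return by_tool[tool]
    return by_tool[sorted(by_tool)[0]]


def aggregate_extraction_site(
    pops: Sequence[CellTypePopulation], tool: str, site_id: str
) -> CellTypePopulation:
    """Sum dataset populations sharing one extraction site and tool."""
    pops = [p for p in pops if p.tool == tool]
    if not pops:
        raise EmptyInputError(f"no {tool!r} populations for site {site_id!r}")
    frames = [p.entries[["ct_id", "ct_label", "count", "crosswalked"]] for p in pops]
    merged = (
        pd.concat(frames)
        .groupby("ct_id", sort=True)
        .agg(
            ct_label=("ct_label", "first"),
            count=("count", "sum"),
            crosswalked=("crosswalked", "first"),
        )
        .reset_index()
    )
    total = merged["count"].sum()
    merged["percentage"] = 100.0 * merged["count"] / total
    return CellTypePopulation(
        owner_id=site_id,
        owner_kind="extraction_site",
        tool=tool,
        modality=pops[0].modality,
        entries=merged[["ct_id", "ct_label", "count", "percentage", "crosswalked"]],
        provenance=sorted({d for p in pops for d in p.provenance}),
        sex=pops[0].sex,
    )


def aggregate_as_population(
    site_pops: Sequence[tuple[CellTypePopulation, CollisionRecord]],
    tool: str,
    sex: str,
    as_id: str,
    as_label: str = "",
) -> CellTypePopulation:
    """Aggregate site populations into one AS population.

    Each site's counts are scaled by its intersection percentage with the
    AS (percentage_of_site / 100) before summation; weighted counts stay
    fractional. Raises :class:`ProvenanceError` when a record is missing or
    names a different AS.
    """
    if not site_pops:
        raise EmptyInputError(f"no site populations for AS {as_id!r}")
    frames = []
    provenance: set[str] = set()
    for pop, record in site_pops:
        if record is None or record.as_id != as_id:
            raise ProvenanceError(
                f"site {pop.owner_id!r} has no collision record for AS {as_id!r}"
            )
        scaled = pop.entries[["ct_id", "ct_label", "count", "crosswalked"]].copy()
        scaled["count"] = scaled["count"] * (record.percentage_of_site / 100.0)
        frames.append(scaled)
        provenance.update(pop.provenance)
    merged = (
        pd.concat(frames)
        .groupby("ct_id", sort=True)
        .agg(
            ct_label=("ct_label", "first"),
            count=("count", "sum"),
            crosswalked=("crosswalked", "first"),
        )
        .reset_index()
    )
    total = merged["count"].sum()
    merged["percentage"] = 100.0 * merged["count"] / total
    pop = CellTypePopulation(
        owner_id=as_id,
        owner_kind="anatomical_structure",
        tool=tool,
        modality=site_pops[0][0].modality,
        entries=merged[["ct_id", "ct_label", "count", "percentage", "crosswalked"]],
        provenance=sorted(provenance),
        sex=sex,
        organ_id=site_pops[0][1].organ_id,
    )
    return pop


# --------------------------------------------------------------------------
# end-to-end build
# --------------------------------------------------------------------------


@dataclass
class AtlasInputs:
    organs: list[ReferenceOrgan]
    sites: list[ExtractionSite]
    datasets: list[DatasetRecord]
    crosswalk: CrosswalkTable | None = None
    parent_map: dict[str, str] = field(default_factory=dict)
    tool_preference: tuple[str, ...] = DEFAULT_TOOL_PREFERENCE
    min_cells: int = MIN_CELLS


@dataclass
class AtlasResult:
    as_pops: list[CellTypePopulation]
    site_pops: list[CellTypePopulation]
    dataset_pops: list[CellTypePopulation]
    gate_results: list[GateResult]
    collisions: dict[str, list[CollisionRecord]]
    unmapped: pd.DataFrame
    log: list[str]


def _dataset_populations(
    ds: DatasetRecord, crosswalk: CrosswalkTable | None
) -> tuple[list[CellTypePopulation], pd.DataFrame]:
    """One population per annotation tool found in the cell table."""
    if ds.cells is None or len(ds.cells) == 0:
        return [], pd.DataFrame(columns=["tool", "source_label", "count"])
    obs = ds.cells.obs
    tools = sorted(obs["tool"].unique()) if "tool" in obs.columns else ["sc_proteomics"]
    pops, reports = [], []
    for tool in tools:
        sub = obs[obs["tool"] == tool] if "tool" in obs.columns else obs
        table = CellTable(obs=sub.reset_index(drop=True))
        pop = population_from_cell_table(
            table, tool=tool, owner_id=ds.dataset_id, modality=ds.modality
        )
        pop.sex = ds.donor.sex
        pop.provenance = [ds.dataset_id]
        if crosswalk is not None:
            pop, report = apply_crosswalk(pop, crosswalk)
            reports.append(report)
        pops.append(pop)
    unmapped = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["tool", "source_label", "count"])
    )
    return pops, unmapped


def build_atlas(inputs: AtlasInputs, out_dir=None) -> AtlasResult:
    """Deterministic end-to-end run: gate -> crosswalk -> collide ->
    aggregate per (AS, sex, tool); optionally writes all outputs under
    ``out_dir``."""
    log: list[str] = []
    organs = {o.id: o for o in inputs.organs}
    sites = {s.id: s for s in inputs.sites}
    log.append(f"organs={len(organs)} sites={len(sites)} datasets={len(inputs.datasets)}")

    # collide every referenced site once
    collisions: dict[str, list[CollisionRecord]] = {}
    for site_id in sorted(sites):
        site = sites[site_id]
        organ = organs.get(site.target_organ)
        if organ is None:
            raise InvalidParameterError(
                f"site {site_id!r} targets unknown organ {site.target_organ!r}"
            )
        collisions[site_id] = mesh_collisions(site, organ)
    site_tags = {sid: [r.as_label for r in recs] for sid, recs in collisions.items()}
    log.append(
        f"collisions: {sum(len(r) for r in collisions.values())} records over "
        f"{sum(bool(r) for r in collisions.values())} colliding sites"
    )

    # per-dataset populations (crosswalked), min-cell rule applied first
    dataset_pops: dict[str, list[CellTypePopulation]] = {}
    unmapped_frames = []
    for ds in sorted(inputs.datasets, key=lambda d: d.dataset_id):
        if not min_cell_filter(ds.cells, inputs.min_cells):
            continue
        pops, unmapped = _dataset_populations(ds, inputs.crosswalk)
        if pops:
            dataset_pops[ds.dataset_id] = pops
        if len(unmapped):
            unmapped_frames.append(unmapped)
    log.append(f"populations computed for {len(dataset_pops)} datasets")

    # quality gate
    gate_results = [
        check_criteria(ds, site_tags, dataset_pops, inputs.min_cells)
        for ds in sorted(inputs.datasets, key=lambda d: d.dataset_id)
    ]
    passing = {g.dataset_id for g in gate_results if g.passed}
    log.append(f"gate: {len(passing)} of {len(gate_results)} datasets passed")

    ds_by_id = {d.dataset_id: d for d in inputs.datasets}

    # DESpop: dataset + extraction-site populations for passing datasets
    atlas_dataset_pops = [
        p for did in sorted(passing) for p in dataset_pops[did]
    ]
    site_pops: list[CellTypePopulation] = []
    per_site_tool: dict[tuple[str, str], list[CellTypePopulation]] = {}
    for did in sorted(passing):
        site_id = ds_by_id[did].extraction_site_id
        for p in dataset_pops[did]:
            per_site_tool.setdefault((site_id, p.tool), []).append(p)
    for (site_id, tool) in sorted(per_site_tool):
        pop = aggregate_extraction_site(per_site_tool[(site_id, tool)], tool, site_id)
        pop.sex = sites[site_id].organ_sex
        site_pops.append(pop)
    log.append(f"DESpop: {len(atlas_dataset_pops)} dataset + {len(site_pops)} site populations")

    # ASpop: aggregate site populations per (AS, sex, tool) weighted by
    # intersection percentage
    per_as: dict[tuple[str, str, str], list[tuple[CellTypePopulation, CollisionRecord]]] = {}
    for pop in site_pops:
        for record in collisions[pop.owner_id]:
            key = (record.as_id, pop.sex, pop.tool)
            per_as.setdefault(key, []).append((pop, record))
    as_pops = []
    for (as_id, sex, tool) in sorted(per_as):
        label = per_as[(as_id, sex, tool)][0][1].as_label
        as_pops.append(
            aggregate_as_population(per_as[(as_id, sex, tool)], tool, sex, as_id, label)
        )
    log.append(f"ASpop: {len(as_pops)} populations")

    unmapped = (
        pd.concat(unmapped_frames, ignore_index=True)
        .groupby(["tool", "source_label"], as_index=False)["count"]
        .sum()
        if unmapped_frames
        else pd.DataFrame(columns=["tool", "source_label", "count"])
    )

    result = AtlasResult(
        as_pops=as_pops,
        site_pops=site_pops,
        dataset_pops=atlas_dataset_pops,
        gate_results=gate_results,
        collisions=collisions,
        unmapped=unmapped,
        log=log,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: AtlasResult, out_dir) -> None:
    """Serialize all atlas products: JSON populations, flat CSVs, reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "aspop.json").write_text(
        json.dumps([p.to_dict() for p in result.as_pops], indent=2) + "\n"
    )
    (out / "despop.json").write_text(
        json.dumps(
            [p.to_dict() for p in result.dataset_pops + result.site_pops], indent=2
        )
        + "\n"
    )
    populations_to_csv(result.as_pops, out / "cell-types-per-as.csv")
    populations_to_csv(result.site_pops, out / "cell-types-per-extraction-site.csv")
    populations_to_csv(result.dataset_pops, out / "cell-types-per-dataset.csv")
    pd.DataFrame(
        [
            {
                "dataset_id": g.dataset_id,
                "passed": g.passed,
                "failed_criteria": ";".join(g.failed_criteria),
            }
            for g in result.gate_results
        ]
    ).to_csv(out / "gate-report.csv", index=False)
    rows = []
    for site_id in sorted(result.collisions):
        for r in result.collisions[site_id]:
            rows.append(
                {
                    "site_id": site_id,
                    "as_id": r.as_id,
                    "as_label": r.as_label,
                    "organ_id": r.organ_id,
                    "intersection_volume_mm3": r.intersection_volume,
                    "percentage_of_site": r.percentage_of_site,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "site_id", "as_id", "as_label", "organ_id",
            "intersection_volume_mm3", "percentage_of_site",
        ],
    ).to_csv(out / "collision-report.csv", index=False, float_format="%.10g")
    result.unmapped.to_csv(out / "unmapped-report.csv", index=False)
    (out / "run-log.txt").write_text("\n".join(result.log) + "\n")


def report_counts(result: AtlasResult) -> pd.DataFrame:
    """Atlas count table: datasets, extraction sites, ASs, and organs,
    split by sex / tool / modality (the 'all' row is the unsplit total)."""
    rows = []

    def _count(pops_sites, pops_as, datasets, label):
        organs = {p.organ_id for p in pops_as if p.organ_id}
        rows.append(
            {
                "group": label,
                "datasets": len(datasets),
                "extraction_sites": len({p.owner_id for p in pops_sites}),
                "anatomical_structures": len({p.owner_id for p in pops_as}),
                "organs": len(organs),
            }
        )

    all_datasets = {d for p in result.dataset_pops for d in p.provenance}
    _count(result.site_pops, result.as_pops, all_datasets, "all")
    for sex in sorted({p.sex for p in result.as_pops if p.sex}):
        sp = [p for p in result.site_pops if p.sex == sex]
        ap = [p for p in result.as_pops if p.sex == sex]
        ds = {d for p in result.dataset_pops if p.sex == sex for d in p.provenance}
        _count(sp, ap, ds, f"sex={sex}")
    for tool in sorted({p.tool for p in result.as_pops}):
        sp = [p for p in result.site_pops if p.tool == tool]
        ap = [p for p in result.as_pops if p.tool == tool]
        ds = {d for p in result.dataset_pops if p.tool == tool for d in p.provenance}
        _count(sp, ap, ds, f"tool={tool}")
    for modality in sorted({p.modality for p in result.as_pops}):
        sp = [p for p in result.site_pops if p.modality == modality]
        ap = [p for p in result.as_pops if p.modality == modality]
        ds = {
            d
            for p in result.dataset_pops
            if p.modality == modality
            for d in p.provenance
        }
        _count(sp, ap, ds, f"modality={modality}")
    return pd.DataFrame(rows)
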