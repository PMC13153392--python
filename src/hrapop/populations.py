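"""Cell-type populations: construction, ontology crosswalking, marker
ranking, QC summaries, rollups, and similarity analytics.

A *cell-type population* is the unit record of the atlas: for one owner
(a dataset, an extraction site, or an anatomical structure) and exactly one
annotation tool, the list of ontology-mapped cell types with their cell
counts and percentages (summing to 100). Dataset populations may also carry
the top-n marker genes per cell type with mean in-group and rest-of-dataset
expressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    DuplicateCellError,
    EmptyInputError,
    InvalidParameterError,
    NoContrastError,
)

__all__ = [
    "CellTable",
    "CellTypePopulation",
    "CrosswalkTable",
    "DonorMetadata",
    "population_from_cell_table",
    "apply_crosswalk",
    "rank_markers",
    "normalize_gene_ids",
    "qc_gene_percentages",
    "rollup_to_parents",
    "weighted_cosine",
    "predict_origin",
    "zscore_matrix",
]

NOT_CROSSWALKED = "not_crosswalked"
NO_MAPPED_PARENT = "no_mapped_parent"

ENTRY_COLUMNS = ["ct_id", "ct_label", "count", "percentage", "crosswalked"]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DonorMetadata:
    """Demographics of a tissue donor; missing values are None."""

    donor_id: str
    age: int | None = None
    sex: str | None = None  # "male" / "female" / None
    bmi: float | None = None
    race: str | None = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise InvalidParameterError(f"age must be >= 0, got {self.age}")


@dataclass
class CellTable:
    """Annotated cells of one dataset.

    ``obs`` holds one row per cell with columns ``cell_id``, ``ct_label``,
    optional ``ct_id``, ``tool``. ``matrix`` is an optional cells x genes
    raw-count matrix (dense or sparse) aligned with ``obs`` rows;
    ``var_names`` are the gene identifiers of its columns.
    """

    obs: pd.DataFrame
    matrix: np.ndarray | sp.spmatrix | None = None
    var_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.obs["cell_id"].duplicated().any():
            dupes = self.obs.loc[self.obs["cell_id"].duplicated(), "cell_id"]
            raise DuplicateCellError(
                f"duplicate cell ids: {sorted(set(dupes))[:5]} ..."
            )
        if self.matrix is not None:
            if self.matrix.shape[0] != len(self.obs):
                raise InvalidParameterError("matrix rows != number of cells")
            if self.var_names is None or len(self.var_names) != self.matrix.shape[1]:
                raise InvalidParameterError("var_names must match matrix columns")

    def __len__(self) -> int:
        return len(self.obs)

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m, dtype=float)

    @classmethod
    def from_csv(cls, path) -> "CellTable":
        obs = pd.read_csv(path, dtype=str)
        required = {"cell_id", "ct_label"}
        if not required.issubset(obs.columns):
            raise InvalidParameterError(
                f"cell table needs columns {sorted(required)}, got {list(obs.columns)}"
            )
        return cls(obs=obs)

    @classmethod
    def from_anndata(cls, adata) -> "CellTable":
        """Build from an AnnData object; prefers the raw counts layer when
        both raw and processed matrices exist."""
        obs = pd.DataFrame(
            {
                "cell_id": adata.obs_names.astype(str),
                "ct_label": adata.obs["ct_label"].astype(str).values,
            }
        )
        if "tool" in adata.obs:
            obs["tool"] = adata.obs["tool"].astype(str).values
        if adata.raw is not None:
            matrix, var = adata.raw.X, list(adata.raw.var_names)
        elif "counts" in adata.layers:
            matrix, var = adata.layers["counts"], list(adata.var_names)
        else:
            matrix, var = adata.X, list(adata.var_names)
        return cls(obs=obs, matrix=matrix, var_names=[str(v) for v in var])

    @classmethod
    def from_h5ad(cls, path) -> "CellTable":
        import anndata

        return cls.from_anndata(anndata.read_h5ad(path))

    @classmethod
    def from_mtx(cls, obs_csv, mtx_path, genes_path) -> "CellTable":
        """Cells from an obs CSV plus a Matrix-Market counts triplet
        (cells x genes) and a one-gene-per-line symbol file."""
        from scipy.io import mmread

        table = cls.from_csv(obs_csv)
        matrix = mmread(str(mtx_path)).tocsr()
        genes = Path(genes_path).read_text().split()
        return cls(obs=table.obs, matrix=matrix, var_names=genes)

    def to_csv(self, path) -> None:
        self.obs.to_csv(path, index=False)


@dataclass
class CellTypePopulation:
    """Cell counts and percentages per cell type for one owner and tool."""

    owner_id: str
    owner_kind: str  # dataset / extraction_site / anatomical_structure
    tool: str  # azimuth / celltypist / popv / sc_proteomics
    modality: str  # sc_transcriptomics / sc_proteomics
    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ENTRY_COLUMNS)
    )
    markers: dict[str, list[tuple[str, float, float]]] | None = None
    provenance: list[str] = field(default_factory=list)
    sex: str | None = None
    organ_id: str | None = None

    def __post_init__(self) -> None:
        e = self.entries
        if len(e):
            if (e["count"] < 0).any():
                raise InvalidParameterError("negative cell count")
            if e["ct_id"].duplicated().any():
                raise InvalidParameterError(
                    f"duplicate ct_id in population {self.owner_id!r}"
                )
            total = e["percentage"].sum()
            if abs(total - 100.0) > 1e-6:
                raise InvalidParameterError(
                    f"percentages sum to {total}, expected 100"
                )

    @property
    def total_cells(self) -> float:
        return float(self.entries["count"].sum()) if len(self.entries) else 0.0

    def percentage_vector(self) -> pd.Series:
        return self.entries.set_index("ct_id")["percentage"].astype(float)

    def to_dict(self) -> dict:
        d = {
            "owner": self.owner_id,
            "owner_kind": self.owner_kind,
            "annotation_method": self.tool,
            "modality": self.modality,
            "sex": self.sex,
            "organ_id": self.organ_id,
            "entries": self.entries[ENTRY_COLUMNS].to_dict(orient="records"),
            "provenance": list(self.provenance),
        }
        if self.markers is not None:
            d["markers"] = {
                ct: [
                    {"gene": g, "mean_in_group": mi, "mean_rest": mr}
                    for g, mi, mr in genes
                ]
                for ct, genes in self.markers.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellTypePopulation":
        entries = pd.DataFrame(d.get("entries", []), columns=ENTRY_COLUMNS)
        markers = None
        if "markers" in d:
            markers = {
                ct: [(m["gene"], m["mean_in_group"], m["mean_rest"]) for m in genes]
                for ct, genes in d["markers"].items()
            }
        return cls(
            owner_id=d["owner"],
            owner_kind=d["owner_kind"],
            tool=d["annotation_method"],
            modality=d["modality"],
            entries=entries,
            markers=markers,
            provenance=list(d.get("provenance", [])),
            sex=d.get("sex"),
            organ_id=d.get("organ_id"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CellTypePopulation":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CrosswalkTable:
    """Mapping from tool/author cell-type labels to ontology terms.

    Rows: ``tool, source_label, source_id, target_id, target_label,
    match_type`` with match_type in {exact, narrow} (exact match vs mapping
    onto a more general class).
    """

    rows: pd.DataFrame

    MATCH_TYPES = frozenset({"exact", "narrow"})

    def __post_init__(self) -> None:
        r = self.rows
        bad = set(r["match_type"]) - self.MATCH_TYPES
        if bad:
            raise InvalidParameterError(f"unknown match types: {sorted(bad)}")
        if r.duplicated(subset=["tool", "source_label"]).any():
            raise InvalidParameterError("duplicate (tool, source_label) rows")

    @classmethod
    def from_csv(cls, path) -> "CrosswalkTable":
        return cls(rows=pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def lookup(self, tool: str) -> dict[str, tuple[str, str, str]]:
        sub = self.rows[self.rows["tool"] == tool]
        return {
            row.source_label: (row.target_id, row.target_label, row.match_type)
            for row in sub.itertuples()
        }


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def _normalize(entries: pd.DataFrame) -> pd.DataFrame:
    entries = entries.copy()
    total = entries["count"].sum()
    entries["percentage"] = 100.0 * entries["count"] / total if total > 0 else 0.0
    return entries


def population_from_cell_table(
    cells: CellTable,
    tool: str,
    owner_id: str = "",
    modality: str = "sc_transcriptomics",
) -> CellTypePopulation:
    """Count cells per type label and normalize to percentages."""
    if len(cells) == 0:
        raise EmptyInputError("cell table has no cells")
    obs = cells.obs
    key = "ct_id" if "ct_id" in obs.columns and obs["ct_id"].notna().all() else "ct_label"
    grouped = (
        obs.groupby(key, sort=True)
        .agg(label=("ct_label", "first"), count=("cell_id", "size"))
        .reset_index()
    )
    grouped.columns = ["ct_id", "ct_label", "count"]
    grouped["count"] = grouped["count"].astype(float)
    entries = _normalize(grouped.assign(crosswalked=False))
    return CellTypePopulation(
        owner_id=owner_id,
        owner_kind="dataset",
        tool=tool,
        modality=modality,
        entries=entries[ENTRY_COLUMNS],
    )


def apply_crosswalk(
    pop: CellTypePopulation, table: CrosswalkTable
) -> tuple[CellTypePopulation, pd.DataFrame]:
    """Re-key population entries to ontology terms.

    Source labels sharing one target term are merged (counts summed).
    Labels absent from the crosswalk are retained under their original key
    with ``crosswalked=False`` and listed in the returned unmapped report.
    Total cell count is conserved exactly.
    """
    mapping = table.lookup(pop.tool)
    rows = []
    unmapped = []
    for entry in pop.entries.itertuples():
        hit = mapping.get(entry.ct_label)
        if hit is None:
            rows.append(
                {
                    "ct_id": entry.ct_id,
                    "ct_label": entry.ct_label,
                    "count": entry.count,
                    "crosswalked": False,
                }
            )
            unmapped.append(
                {"tool": pop.tool, "source_label": entry.ct_label, "count": entry.count}
            )
        else:
            target_id, target_label, match_type = hit
            rows.append(
                {
                    "ct_id": target_id,
                    "ct_label": target_label,
                    "count": entry.count,
                    "crosswalked": True,
                    "match_type": match_type,
                }
            )
    merged = (
        pd.DataFrame(rows)
        .groupby("ct_id", sort=True)
        .agg(
            ct_label=("ct_label", "first"),
            count=("count", "sum"),
            crosswalked=("crosswalked", "first"),
        )
        .reset_index()
    )
    entries = _normalize(merged)
    new_pop = replace(pop, entries=entries[ENTRY_COLUMNS], markers=pop.markers)
    report = pd.DataFrame(unmapped, columns=["tool", "source_label", "count"])
    return new_pop, report


def _log_cp10k(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(matrix / totals * 1e4)


def rank_markers(
    cells: CellTable, n: int = 10
) -> dict[str, list[tuple[str, float, float]]]:
    """Top-n marker genes per cell type.

    Per-cell counts are normalized to 10,000 total and log1p-transformed;
    genes are then ranked per cell type by the standardized mean difference
    between in-group and rest-of-dataset expression (pooled SD). Ties break
    lexicographically by gene symbol. Returns, per cell type, a list of
    ``(gene, mean_in_group, mean_rest)`` on the transformed scale.
    """
    if cells.matrix is None:
        raise InvalidParameterError("rank_markers requires an expression matrix")
    labels = cells.obs["ct_label"].to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise NoContrastError("marker ranking needs at least two cell-type groups")
    X = _log_cp10k(cells.dense())
    genes = np.asarray(cells.var_names)
    markers: dict[str, list[tuple[str, float, float]]] = {}
    for g in groups:
        mask = labels == g
        in_g, rest = X[mask], X[~mask]
        m1, m0 = in_g.mean(axis=0), rest.mean(axis=0)
        v1 = in_g.var(axis=0, ddof=1) if mask.sum() > 1 else np.zeros(X.shape[1])
        v0 = rest.var(axis=0, ddof=1) if (~mask).sum() > 1 else np.zeros(X.shape[1])
        n1, n0 = mask.sum(), (~mask).sum()
        dof = max(n1 + n0 - 2, 1)
        pooled = np.sqrt(((max(n1 - 1, 0)) * v1 + (max(n0 - 1, 0)) * v0) / dof)
        score = (m1 - m0) / (pooled + 1e-9)
        order = np.lexsort((genes, -score))[: min(n, len(genes))]
        markers[str(g)] = [
            (str(genes[i]), float(m1[i]), float(m0[i])) for i in order
        ]
    return markers


def normalize_gene_ids(
    genes: list[str], lookup: dict[str, str]
) -> tuple[list[str], list[str]]:
    """Replace stable gene ids with approved symbols via a lookup table.

    Ids found in the lookup are replaced; already-approved symbols pass
    through silently; anything else passes through and is reported as
    unmatched. Returns ``(normalized, unmatched)``.
    """
    approved = set(lookup.values())
    normalized, unmatched = [], []
    for g in genes:
        if g in lookup:
            normalized.append(lookup[g])
        else:
            normalized.append(g)
            if g not in approved:
                unmatched.append(g)
    return normalized, unmatched


def qc_gene_percentages(cells: CellTable) -> dict[str, float]:
    """Per-dataset QC summary of ribosomal / mitochondrial content.

    Ribosomal genes are symbols prefixed ``RPS``/``RPL``; mitochondrial
    ones are prefixed ``MT-``. Per cell, the percentage of total counts in
    each class is computed; all-zero cells are excluded from the
    percentages and counted in ``n_zero_cells``. Reports mean, median and
    SD of both percentages plus mean genes-with-positive-counts and mean
    total counts per cell.
    """
    if cells.matrix is None:
        raise InvalidParameterError("qc_gene_percentages requires a matrix")
    X = cells.dense()
    genes = np.asarray(cells.var_names)
    ribo = np.char.startswith(genes.astype(str), "RPS") | np.char.startswith(
        genes.astype(str), "RPL"
    )
    mito = np.char.startswith(genes.astype(str), "MT-")
    totals = X.sum(axis=1)
    nonzero = totals > 0
    pct_ribo = 100.0 * X[nonzero][:, ribo].sum(axis=1) / totals[nonzero]
    pct_mito = 100.0 * X[nonzero][:, mito].sum(axis=1) / totals[nonzero]

    def _stats(x):
        if len(x) == 0:
            return 0.0, 0.0, 0.0
        return float(np.mean(x)), float(np.median(x)), float(np.std(x))

    ribo_mean, ribo_median, ribo_sd = _stats(pct_ribo)
    mito_mean, mito_median, mito_sd = _stats(pct_mito)
    return {
        "pct_ribosomal_mean": ribo_mean,
        "pct_ribosomal_median": ribo_median,
        "pct_ribosomal_sd": ribo_sd,
        "pct_mitochondrial_mean": mito_mean,
        "pct_mitochondrial_median": mito_median,
        "pct_mitochondrial_sd": mito_sd,
        "genes_with_positive_counts_mean": float((X > 0).sum(axis=1).mean()),
        "total_counts_mean": float(totals.mean()),
        "n_cells": int(len(X)),
        "n_zero_cells": int((~nonzero).sum()),
    }


def rollup_to_parents(
    pop: CellTypePopulation, parent_map: dict[str, str]
) -> CellTypePopulation:
    """Aggregate a population to high-level parent cell types.

    Crosswalked types missing from the parent map land in the
    ``no_mapped_parent`` bucket; types never crosswalked land in
    ``not_crosswalked``. Counts are conserved exactly.
    """
    rows = []
    for entry in pop.entries.itertuples():
        if not entry.crosswalked:
            key, label = NOT_CROSSWALKED, NOT_CROSSWALKED
        elif entry.ct_id in parent_map:
            key = parent_map[entry.ct_id]
            label = key
        else:
            key, label = NO_MAPPED_PARENT, NO_MAPPED_PARENT
        rows.append(
            {"ct_id": key, "ct_label": label, "count": entry.count,
             "crosswalked": entry.crosswalked}
        )
    merged = (
        pd.DataFrame(rows)
        .groupby("ct_id", sort=True)
        .agg(
            ct_label=("ct_label", "first"),
            count=("count", "sum"),
            crosswalked=("crosswalked", "first"),
        )
        .reset_index()
    )
    entries = _normalize(merged)
    return replace(pop, entries=entries[ENTRY_COLUMNS], markers=None)


def weighted_cosine(
    pop_a: CellTypePopulation,
    pop_b: CellTypePopulation,
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted cosine similarity of two populations' percentage vectors.

    Vectors are formed over the union of cell-type ids (missing types are
    zero). With unit weights this is the ordinary cosine similarity;
    returns 0 when either vector has zero norm.
    """
    if len(pop_a.entries) == 0 or len(pop_b.entries) == 0:
        raise EmptyInputError("populations must be non-empty")
    u = pop_a.percentage_vector()
    v = pop_b.percentage_vector()
    ids = sorted(set(u.index) | set(v.index))
    uu = u.reindex(ids, fill_value=0.0).to_numpy()
    vv = v.reindex(ids, fill_value=0.0).to_numpy()
    if weights is None:
        w = np.ones(len(ids))
    else:
        w = np.array([float(weights.get(i, 1.0)) for i in ids])
        if (w < 0).any():
            raise InvalidParameterError("weights must be nonnegative")
    dot = float(np.sum(w * uu * vv))
    norm_u = float(np.sqrt(np.sum(w * uu * uu)))
    norm_v = float(np.sqrt(np.sum(w * vv * vv)))
    if norm_u == 0.0 or norm_v == 0.0:
        return 0.0
    return dot / (norm_u * norm_v)


def predict_origin(
    pop: CellTypePopulation,
    candidates: list[tuple[str, CellTypePopulation]],
    weights: dict[str, float] | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate origins by similarity to a query population.

    Descending similarity; ties break lexicographically by candidate id.
    """
    if not candidates:
        raise EmptyInputError("at least one candidate required")
    scored = [
        (cid, weighted_cosine(pop, cpop, weights)) for cid, cpop in candidates
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def zscore_matrix(mean_pct: pd.DataFrame) -> pd.DataFrame:
    """Standardize a cell-type x structure matrix of mean percentages.

    Each cell-type row is scaled to Z = (x - mu) / sigma with mu, sigma the
    row mean and *population* standard deviation; constant rows (sigma = 0)
    map to all zeros.
    """
    x = mean_pct.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, ddof=0, keepdims=True)
    z = np.zeros_like(x)
    nz = sigma[:, 0] > 0
    z[nz] = (x[nz] - mu[nz]) / sigma[nz]
    return pd.DataFrame(z, index=mean_pct.index, columns=mean_pct.columns)


def populations_to_csv(pops: list[CellTypePopulation], path) -> None:
    """Flat CSV serialization: one row per (owner, tool, cell type)."""
    rows = []
    for pop in pops:
        for entry in pop.entries.itertuples():
            rows.append(
                {
                    "owner_id": pop.owner_id,
                    "owner_kind": pop.owner_kind,
                    "sex": pop.sex or "",
                    "tool": pop.tool,
                    "modality": pop.modality,
                    "ct_id": entry.ct_id,
                    "ct_label": entry.ct_label,
                    "count": entry.count,
                    "percentage": entry.percentage,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "owner_id", "owner_kind", "sex", "tool", "modality",
            "ct_id", "ct_label", "count", "percentage",
        ],
    ).to_csv(path, index=False, float_format="%.10g")
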