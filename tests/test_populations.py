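"""Population construction, crosswalking, markers, QC, similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrapop.errors import (
    DuplicateCellError,
    EmptyInputError,
    InvalidParameterError,
    NoContrastError,
)
from hrapop.fixtures import DatasetSpec, make_cell_dataset, make_crosswalk
from hrapop.geometry import ExtractionSite
from hrapop.populations import (
    NO_MAPPED_PARENT,
    NOT_CROSSWALKED,
    CellTable,
    CellTypePopulation,
    CrosswalkTable,
    apply_crosswalk,
    normalize_gene_ids,
    population_from_cell_table,
    predict_origin,
    qc_gene_percentages,
    rank_markers,
    rollup_to_parents,
    weighted_cosine,
    zscore_matrix,
)


def _table(labels, prefix="c"):
    return CellTable(
        obs=pd.DataFrame(
            {
                "cell_id": [f"{prefix}{i}" for i in range(len(labels))],
                "ct_label": labels,
            }
        )
    )


def _pop(percentages: dict, owner="p", tool="azimuth") -> CellTypePopulation:
    total = sum(percentages.values())
    entries = pd.DataFrame(
        [
            {
                "ct_id": ct,
                "ct_label": ct,
                "count": v,
                "percentage": 100.0 * v / total,
                "crosswalked": True,
            }
            for ct, v in sorted(percentages.items())
        ]
    )
    return CellTypePopulation(
        owner_id=owner, owner_kind="dataset", tool=tool,
        modality="sc_transcriptomics", entries=entries,
    )


class TestPopulationFromCellTable:
    def test_simple_counting(self):
        pop = population_from_cell_table(_table(["A", "A", "B"]), tool="azimuth")
        got = pop.entries.set_index("ct_id")
        assert got.loc["A", "count"] == 2 and got.loc["B", "count"] == 1
        assert got.loc["A", "percentage"] == pytest.approx(66.6667, abs=1e-3)
        assert got.loc["B", "percentage"] == pytest.approx(33.3333, abs=1e-3)

    def test_single_label_is_100pct(self):
        pop = population_from_cell_table(_table(["X"] * 5), tool="popv")
        assert pop.entries["percentage"].tolist() == [100.0]

    def test_counts_match_independent_tally(self):
        rng = np.random.default_rng(42)
        labels = rng.choice([f"ct{i}" for i in range(5)], size=10_000)
        pop = population_from_cell_table(_table(list(labels)), tool="celltypist")
        tally: dict[str, int] = {}
        for lab in labels:  # brute-force oracle
            tally[lab] = tally.get(lab, 0) + 1
        got = dict(zip(pop.entries["ct_id"], pop.entries["count"]))
        assert got == {k: float(v) for k, v in tally.items()}

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyInputError):
            population_from_cell_table(_table([]), tool="azimuth")

    def test_duplicate_cell_id_rejected(self):
        obs = pd.DataFrame({"cell_id": ["c1", "c1"], "ct_label": ["A", "B"]})
        with pytest.raises(DuplicateCellError):
            CellTable(obs=obs)


class TestCrosswalk:
    @pytest.fixture()
    def xwalk(self):
        rows = pd.DataFrame(
            [
                ("azimuth", "alpha-like", "", "CL:X1", "alpha", "exact"),
                ("azimuth", "alpha-ish", "", "CL:X1", "alpha", "narrow"),
                ("azimuth", "beta-like", "", "CL:X2", "beta", "exact"),
            ],
            columns=["tool", "source_label", "source_id", "target_id",
                     "target_label", "match_type"],
        )
        return CrosswalkTable(rows=rows)

    def test_exact_match_rekeys_entry(self, xwalk):
        pop = population_from_cell_table(_table(["alpha-like"] * 3), tool="azimuth")
        mapped, report = apply_crosswalk(pop, xwalk)
        assert mapped.entries["ct_id"].tolist() == ["CL:X1"]
        assert mapped.entries["ct_label"].tolist() == ["alpha"]
        assert len(report) == 0

    def test_two_sources_merge_counts(self, xwalk):
        pop = population_from_cell_table(
            _table(["alpha-like"] * 3 + ["alpha-ish"] * 7), tool="azimuth"
        )
        mapped, _ = apply_crosswalk(pop, xwalk)
        assert mapped.entries["count"].tolist() == [10.0]
        assert mapped.entries["percentage"].tolist() == [100.0]

    def test_unmapped_label_retained_and_reported(self, xwalk):
        pop = population_from_cell_table(
            _table(["alpha-like"] * 2 + ["mystery"] * 2), tool="azimuth"
        )
        mapped, report = apply_crosswalk(pop, xwalk)
        row = mapped.entries.set_index("ct_id").loc["mystery"]
        assert not row["crosswalked"]
        assert report["source_label"].tolist() == ["mystery"]

    def test_total_cells_conserved(self, xwalk):
        labels = ["alpha-like"] * 3 + ["alpha-ish"] * 4 + ["beta-like"] * 2 + ["zz"] * 5
        pop = population_from_cell_table(_table(labels), tool="azimuth")
        mapped, _ = apply_crosswalk(pop, xwalk)
        assert mapped.total_cells == pytest.approx(pop.total_cells, abs=1e-9)
        assert mapped.entries["percentage"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_invalid_match_type_rejected(self):
        rows = pd.DataFrame(
            [("azimuth", "x", "", "CL:1", "x", "broad")],
            columns=["tool", "source_label", "source_id", "target_id",
                     "target_label", "match_type"],
        )
        with pytest.raises(InvalidParameterError):
            CrosswalkTable(rows=rows)


class TestRankMarkers:
    def _cells(self, matrix, labels, genes):
        return CellTable(
            obs=pd.DataFrame(
                {"cell_id": [f"c{i}" for i in range(len(labels))], "ct_label": labels}
            ),
            matrix=np.asarray(matrix, float),
            var_names=genes,
        )

    def test_exclusive_gene_ranks_first(self):
        # g1 expressed only in group A
        matrix = [[50, 1], [40, 2], [0, 1], [0, 2]]
        cells = self._cells(matrix, ["A", "A", "B", "B"], ["g1", "g2"])
        markers = rank_markers(cells, n=2)
        assert markers["A"][0][0] == "g1"

    def test_n_larger_than_gene_count_returns_all(self):
        matrix = [[5, 1, 0], [4, 2, 0], [0, 1, 9], [0, 2, 8]]
        cells = self._cells(matrix, ["A", "A", "B", "B"], ["g1", "g2", "g3"])
        markers = rank_markers(cells, n=10)
        assert len(markers["A"]) == 3 and len(markers["B"]) == 3

    def test_ranking_matches_bruteforce_scores(self):
        rng = np.random.default_rng(5)
        matrix = rng.poisson(3.0, size=(40, 5)).astype(float)
        labels = ["A"] * 22 + ["B"] * 18
        genes = ["g1", "g2", "g3", "g4", "g5"]
        cells = self._cells(matrix, labels, genes)
        markers = rank_markers(cells, n=5)

        # independent oracle: explicit per-gene standardized mean difference
        totals = matrix.sum(axis=1, keepdims=True)
        X = np.log1p(matrix / totals * 1e4)
        mask = np.array([l == "A" for l in labels])
        scores = []
        for j in range(5):
            a, b = X[mask, j], X[~mask, j]
            pooled = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            scores.append((a.mean() - b.mean()) / (pooled + 1e-9))
        expected = [genes[j] for j in np.lexsort((genes, -np.array(scores)))]
        assert [g for g, _, _ in markers["A"]] == expected

    def test_single_group_rejected(self):
        cells = self._cells([[1, 2], [3, 4]], ["A", "A"], ["g1", "g2"])
        with pytest.raises(NoContrastError):
            rank_markers(cells)

    def test_planted_fixture_markers_recovered(self):
        site = ExtractionSite(id="s", dimensions=(1, 1, 1))
        spec = DatasetSpec(mixture={"ct1": 0.5, "ct2": 0.5}, seed=9)
        cells, _, _ = make_cell_dataset(spec, site)
        markers = rank_markers(cells, n=10)
        for ct in ("ct1", "ct2"):
            top = {g for g, _, _ in markers[f"{ct}-raw"]}
            planted = {f"MK-{ct}-{j + 1}" for j in range(spec.markers_per_ct)}
            assert planted <= top


class TestNormalizeGeneIds:
    LOOKUP = {"ENSF000001": "GENEA", "ENSF000002": "GENEB"}

    def test_known_id_mapped(self):
        out, unmatched = normalize_gene_ids(["ENSF000001"], self.LOOKUP)
        assert out == ["GENEA"] and unmatched == []

    def test_approved_symbol_passes_silently(self):
        out, unmatched = normalize_gene_ids(["GENEB"], self.LOOKUP)
        assert out == ["GENEB"] and unmatched == []

    def test_unknown_id_passes_and_reported(self):
        out, unmatched = normalize_gene_ids(["ENSF999999"], self.LOOKUP)
        assert out == ["ENSF999999"] and unmatched == ["ENSF999999"]


class TestQcGenePercentages:
    def _cells(self, matrix, genes):
        n = len(matrix)
        return CellTable(
            obs=pd.DataFrame(
                {"cell_id": [f"c{i}" for i in range(n)], "ct_label": ["A"] * n}
            ),
            matrix=np.asarray(matrix, float),
            var_names=genes,
        )

    def test_all_mitochondrial_cell_is_100pct(self):
        cells = self._cells([[0, 10]], ["HK-1", "MT-ND1"])
        qc = qc_gene_percentages(cells)
        assert qc["pct_mitochondrial_mean"] == pytest.approx(100.0)
        assert qc["pct_ribosomal_mean"] == 0.0

    def test_absent_classes_are_zero(self):
        cells = self._cells([[3, 4]], ["HK-1", "HK-2"])
        qc = qc_gene_percentages(cells)
        assert qc["pct_ribosomal_mean"] == 0.0
        assert qc["pct_mitochondrial_mean"] == 0.0

    def test_mixed_fixture_matches_hand_ratios(self):
        matrix = [[2, 3, 5], [1, 0, 9]]
        cells = self._cells(matrix, ["RPS9", "MT-CO1", "HK-1"])
        qc = qc_gene_percentages(cells)
        ribo = [100 * 2 / 10, 100 * 1 / 10]
        mito = [100 * 3 / 10, 100 * 0 / 10]
        assert qc["pct_ribosomal_mean"] == pytest.approx(np.mean(ribo))
        assert qc["pct_ribosomal_median"] == pytest.approx(np.median(ribo))
        assert qc["pct_mitochondrial_mean"] == pytest.approx(np.mean(mito))
        assert qc["genes_with_positive_counts_mean"] == pytest.approx(2.5)
        assert qc["total_counts_mean"] == pytest.approx(10.0)

    def test_zero_cell_excluded_and_counted(self):
        cells = self._cells([[0, 0], [5, 5]], ["RPS9", "HK-1"])
        qc = qc_gene_percentages(cells)
        assert qc["n_zero_cells"] == 1
        assert qc["pct_ribosomal_mean"] == pytest.approx(50.0)


class TestRollup:
    PARENTS = {"CL:1": "CL:HIGH", "CL:2": "CL:HIGH"}

    def _pop(self, rows):
        entries = pd.DataFrame(rows, columns=["ct_id", "ct_label", "count", "crosswalked"])
        total = entries["count"].sum()
        entries["percentage"] = 100.0 * entries["count"] / total
        return CellTypePopulation(
            owner_id="d", owner_kind="dataset", tool="azimuth",
            modality="sc_transcriptomics",
            entries=entries[["ct_id", "ct_label", "count", "percentage", "crosswalked"]],
        )

    def test_children_sum_under_parent(self):
        pop = self._pop([("CL:1", "a", 3.0, True), ("CL:2", "b", 7.0, True)])
        rolled = rollup_to_parents(pop, self.PARENTS)
        assert rolled.entries["ct_id"].tolist() == ["CL:HIGH"]
        assert rolled.entries["count"].tolist() == [10.0]

    def test_no_mapped_parent_bucket(self):
        pop = self._pop([("CL:1", "a", 4.0, True), ("CL:9", "z", 6.0, True)])
        rolled = rollup_to_parents(pop, self.PARENTS)
        got = dict(zip(rolled.entries["ct_id"], rolled.entries["count"]))
        assert got == {"CL:HIGH": 4.0, NO_MAPPED_PARENT: 6.0}

    def test_not_crosswalked_bucket_and_conservation(self):
        pop = self._pop([("raw-x", "raw-x", 5.0, False), ("CL:1", "a", 5.0, True)])
        rolled = rollup_to_parents(pop, self.PARENTS)
        got = dict(zip(rolled.entries["ct_id"], rolled.entries["count"]))
        assert got == {NOT_CROSSWALKED: 5.0, "CL:HIGH": 5.0}
        assert rolled.total_cells == pytest.approx(pop.total_cells, abs=1e-9)
        assert rolled.entries["percentage"].sum() == pytest.approx(100.0, abs=1e-6)


class TestWeightedCosine:
    def test_identical_populations_similarity_one(self):
        a = _pop({"x": 30, "y": 70})
        assert weighted_cosine(a, a) == pytest.approx(1.0)

    def test_disjoint_populations_similarity_zero(self):
        assert weighted_cosine(_pop({"x": 100}), _pop({"y": 100})) == 0.0

    def test_direct_formula_case(self):
        # u = (1,1,0), v = (1,0,1) scaled to percentages: cosine 0.5
        u = _pop({"a": 1, "b": 1})
        v = _pop({"a": 1, "c": 1})
        assert weighted_cosine(u, v) == pytest.approx(0.5)

    def test_weights_change_similarity(self):
        u = _pop({"a": 1, "b": 1})
        v = _pop({"a": 1, "c": 1})
        # zero weight on the shared type removes all similarity
        assert weighted_cosine(u, v, weights={"a": 0.0}) == pytest.approx(0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            weighted_cosine(_pop({"a": 1}), _pop({"a": 1}), weights={"a": -1.0})

    def test_empty_population_rejected(self):
        empty = CellTypePopulation(
            owner_id="e", owner_kind="dataset", tool="azimuth",
            modality="sc_transcriptomics",
        )
        with pytest.raises(EmptyInputError):
            weighted_cosine(empty, _pop({"a": 1}))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts_a=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6),
        counts_b=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    def test_symmetry_bounds_scale_invariance(self, counts_a, counts_b, scale):
        a = _pop({f"ct{i}": c for i, c in enumerate(counts_a)})
        b = _pop({f"ct{i}": c for i, c in enumerate(counts_b, start=len(counts_a) // 2)})
        s_ab = weighted_cosine(a, b)
        assert 0.0 <= s_ab <= 1.0 + 1e-12
        assert s_ab == pytest.approx(weighted_cosine(b, a), abs=1e-12)
        scaled = _pop({f"ct{i}": c * scale for i, c in enumerate(counts_a)})
        assert weighted_cosine(scaled, b) == pytest.approx(s_ab, abs=1e-9)


class TestPredictOrigin:
    def test_identical_candidate_ranks_first(self):
        query = _pop({"x": 60, "y": 40})
        ranked = predict_origin(
            query, [("other", _pop({"z": 100})), ("same", _pop({"x": 60, "y": 40}))]
        )
        assert ranked[0] == ("same", pytest.approx(1.0))

    def test_generating_structure_is_nearest(self):
        site = ExtractionSite(id="s", dimensions=(1, 1, 1))
        spec = DatasetSpec(mixture={"ct1": 0.7, "ct2": 0.3}, seed=3)
        cells, _, _ = make_cell_dataset(spec, site)
        query = population_from_cell_table(cells, tool="azimuth")
        candidates = [
            ("generator", _pop({"ct1-raw": 70, "ct2-raw": 30})),
            ("inverted", _pop({"ct1-raw": 30, "ct2-raw": 70})),
            ("unrelated", _pop({"ct9-raw": 100})),
        ]
        assert predict_origin(query, candidates)[0][0] == "generator"

    def test_orthogonal_ties_break_lexicographically(self):
        query = _pop({"q": 100})
        ranked = predict_origin(
            query, [("b", _pop({"x": 100})), ("a", _pop({"y": 100}))]
        )
        assert [r[0] for r in ranked] == ["a", "b"]
        assert all(s == 0.0 for _, s in ranked)

    def test_no_candidates_rejected(self):
        with pytest.raises(EmptyInputError):
            predict_origin(_pop({"a": 1}), [])


class TestZscore:
    def test_constant_row_maps_to_zero(self):
        z = zscore_matrix(pd.DataFrame([[5.0, 5.0, 5.0]], index=["ct"]))
        assert (z.to_numpy() == 0).all()

    def test_two_point_row(self):
        z = zscore_matrix(pd.DataFrame([[0.0, 10.0]], index=["ct"]))
        assert z.to_numpy().tolist() == [[-1.0, 1.0]]

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(0, 50, size=(6, 8)))
        z = zscore_matrix(m).to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)


class TestCellTableIO:
    def test_h5ad_round_trip_prefers_raw_layer(self, tmp_path):
        import anndata

        X = np.array([[1.0, 0.5], [0.2, 3.0]])
        raw = np.array([[2, 1], [0, 6]], dtype=float)
        adata = anndata.AnnData(
            X=X,
            obs=pd.DataFrame(
                {"ct_label": ["A", "B"]}, index=["cell1", "cell2"]
            ),
            var=pd.DataFrame(index=["g1", "g2"]),
            layers={"counts": raw},
        )
        path = tmp_path / "cells.h5ad"
        adata.write_h5ad(path)
        table = CellTable.from_h5ad(path)
        assert table.obs["cell_id"].tolist() == ["cell1", "cell2"]
        assert table.var_names == ["g1", "g2"]
        assert np.array_equal(table.dense(), raw)

    def test_mtx_triplet(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        obs = pd.DataFrame({"cell_id": ["c1", "c2"], "ct_label": ["A", "B"]})
        obs.to_csv(tmp_path / "obs.csv", index=False)
        mmwrite(tmp_path / "m.mtx", csr_matrix([[1, 0, 2], [0, 3, 0]]))
        (tmp_path / "genes.txt").write_text("g1\ng2\ng3\n")
        table = CellTable.from_mtx(
            tmp_path / "obs.csv", tmp_path / "m.mtx", tmp_path / "genes.txt"
        )
        assert table.dense().tolist() == [[1, 0, 2], [0, 3, 0]]
        assert table.var_names == ["g1", "g2", "g3"]


class TestCrosswalkFixture:
    def test_unmapped_fraction_exact(self):
        cts = [f"ct{i}" for i in range(10)]
        table, _, _ = make_crosswalk(cts, unmapped_fraction=0.2)
        labels = set(table.rows[table.rows["tool"] == "azimuth"]["source_label"])
        unmapped = [c for c in cts if f"{c}-raw" not in labels]
        assert len(unmapped) == 2

    def test_narrow_children_merge_to_one_target(self):
        table, _, _ = make_crosswalk(["ct1", "ct2"])
        narrow = table.rows[table.rows["match_type"] == "narrow"]
        assert narrow["target_id"].nunique() == 1
        pop = population_from_cell_table(
            _table(["ct1-child-a-raw"] * 3 + ["ct1-child-b-raw"] * 7), tool="azimuth"
        )
        mapped, _ = apply_crosswalk(pop, table)
        assert mapped.entries["count"].tolist() == [10.0]
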