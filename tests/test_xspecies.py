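"""Ortholog alignment, lineage assignment, conservation categories and MNN."""

import numpy as np
import pandas as pd
import pytest

from emblineage.qc import NormalizedMatrix
from emblineage.xspecies import (
    UNEXPRESSED,
    OrthologTable,
    align_orthologs,
    assign_lineage,
    classify_conservation,
    conservation_category,
    mnn_pairs,
    stage_correspondence,
)
from emblineage.oracles import oracle_knn_pairs


def nm_from(values, genes, cells=None):
    a = np.asarray(values, dtype=float)
    cells = cells or [f"c{j}" for j in range(a.shape[1])]
    return NormalizedMatrix(pd.DataFrame(a, index=genes, columns=cells), 1e4)


def ot_from(rows):
    return OrthologTable(pd.DataFrame(rows, columns=["gene_a", "gene_b", "homology_type"]))


class TestAlignOrthologs:
    def test_identity_mapping_keeps_everything(self):
        genes = ["g1", "g2", "g3"]
        nm = nm_from(np.arange(6).reshape(3, 2), genes)
        ot = ot_from([(g, g, "ortholog_one2one") for g in genes])
        a, b, mapping = align_orthologs(nm, nm, ot)
        assert sorted(mapping["gene_a"]) == genes
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_one2many_records_excluded(self):
        nm_a = nm_from([[1.0], [2.0]], ["a1", "a2"])
        nm_b = nm_from([[1.0], [2.0]], ["b1", "b2"])
        ot = ot_from(
            [("a1", "b1", "ortholog_one2one"), ("a2", "b2", "ortholog_one2many")]
        )
        _, _, mapping = align_orthologs(nm_a, nm_b, ot)
        assert list(mapping["gene_a"]) == ["a1"]

    def test_planted_80_of_100(self):
        genes_a = [f"a{i}" for i in range(100)]
        genes_b = [f"b{i}" for i in range(100)]
        rows = [(f"a{i}", f"b{i}", "ortholog_one2one") for i in range(80)]
        rows += [(f"a{i}", f"b{i}", "ortholog_one2many") for i in range(80, 100)]
        nm_a = nm_from(np.zeros((100, 2)), genes_a)
        nm_b = nm_from(np.zeros((100, 2)), genes_b)
        a, b, mapping = align_orthologs(nm_a, nm_b, ot_from(rows))
        assert len(mapping) == 80 and a.shape[0] == 80

    def test_empty_intersection_is_an_error(self):
        nm_a = nm_from([[1.0]], ["a1"])
        nm_b = nm_from([[1.0]], ["b1"])
        with pytest.raises(ValueError):
            align_orthologs(nm_a, nm_b, ot_from([("zz", "yy", "ortholog_one2one")]))


class TestAssignLineage:
    def _tables(self, means, fracs, genes):
        cols = ["prelineage", "ICM", "EPI", "PE", "TE"]
        pb = pd.DataFrame(means, index=genes, columns=cols)
        pct = pd.DataFrame(fracs, index=genes, columns=cols)
        return pb, pct

    def test_exclusive_expression(self):
        pb, pct = self._tables([[0, 0, 5.0, 0, 0]], [[0, 0, 0.9, 0, 0]], ["g"])
        out = assign_lineage(pb, pct, "gp")
        assert out.loc["g", "lineage"] == "EPI"

    def test_low_detection_means_unexpressed(self):
        """Highest in TE but detected in only 8% of TE cells -> unexpressed."""
        pb, pct = self._tables([[0.1, 0.1, 0.1, 0.1, 5.0]], [[0.5, 0.5, 0.5, 0.5, 0.08]], ["g"])
        out = assign_lineage(pb, pct, "gp")
        assert out.loc["g", "lineage"] == UNEXPRESSED

    def test_all_zero_gene_unexpressed(self):
        pb, pct = self._tables([[0.0] * 5], [[0.0] * 5], ["g"])
        assert assign_lineage(pb, pct, "gp").loc["g", "lineage"] == UNEXPRESSED

    def test_exact_tie_flagged_and_ordered(self):
        pb, pct = self._tables([[0, 2.0, 2.0, 0, 0]], [[0, 0.9, 0.9, 0, 0]], ["g"])
        out = assign_lineage(pb, pct, "gp")
        assert out.loc["g", "tied"] and out.loc["g", "lineage"] == "ICM"

    def test_planted_argmax_recovered(self):
        rng = np.random.default_rng(0)
        cols = ["prelineage", "ICM", "EPI", "PE", "TE"]
        genes = [f"g{i}" for i in range(200)]
        target = [cols[i % 5] for i in range(200)]
        means = rng.uniform(0.1, 0.5, (200, 5))
        for i, t in enumerate(target):
            means[i, cols.index(t)] = 3.0
        pct = np.full((200, 5), 0.8)
        out = assign_lineage(
            pd.DataFrame(means, index=genes, columns=cols),
            pd.DataFrame(pct, index=genes, columns=cols),
            "gp",
        )
        assert list(out["lineage"]) == target


# hand-derived truth table over {EPI, TE, unexpressed}^3 for (human, mouse, gp)
_TRUTH = {}
for h in ("EPI", "TE", UNEXPRESSED):
    for m in ("EPI", "TE", UNEXPRESSED):
        for g in ("EPI", "TE", UNEXPRESSED):
            if h == m == g and h != UNEXPRESSED:
                cat = "all_three"
            elif h == g != UNEXPRESSED and m != h:
                cat = "human_gp_only"
            elif m == g != UNEXPRESSED and h != m:
                cat = "mouse_gp_only"
            elif h == m != UNEXPRESSED and g != h:
                cat = "human_mouse_only"
            else:
                cat = "none"
            _TRUTH[(h, m, g)] = cat


class TestConservation:
    def test_all_same_lineage(self):
        assert conservation_category("EPI", "EPI", "EPI") == "all_three"

    def test_absent_in_mouse(self):
        assert conservation_category("EPI", UNEXPRESSED, "EPI") == "human_gp_only"

    @pytest.mark.parametrize("triple,expected", sorted(_TRUTH.items()))
    def test_exhaustive_truth_table(self, triple, expected):
        assert conservation_category(*triple) == expected

    def test_partition_property(self):
        """Every ortholog key lands in exactly one category; counts sum."""
        rng = np.random.default_rng(1)
        lineages = ["EPI", "TE", "PE", UNEXPRESSED]
        keys = [f"og{i}" for i in range(100)]
        assignments = {
            sp: pd.Series(rng.choice(lineages, 100), index=keys)
            for sp in ("human", "mouse", "gp")
        }
        records, counts = classify_conservation(assignments)
        assert len(records) == 100
        assert sum(counts.values()) == 100

    def test_missing_key_treated_as_unexpressed(self):
        assignments = {
            "human": pd.Series({"og1": "EPI"}),
            "mouse": pd.Series({"og1": "EPI"}),
            "gp": pd.Series(dtype=object),
        }
        records, _ = classify_conservation(assignments)
        assert records.loc["og1", "category"] == "human_mouse_only"


class TestMNN:
    def test_identity_dataset_k1(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(size=(10, 8)), columns=[f"x{i}" for i in range(8)])
        b = a.copy()
        b.columns = [f"y{i}" for i in range(8)]
        pairs = mnn_pairs(a, b, k=1)
        assert [(p.cell_a, p.cell_b) for p in pairs] == [
            (f"x{i}", f"y{i}") for i in range(8)
        ]
        assert all(p.distance == 0 and p.pearson_r == pytest.approx(1.0) for p in pairs)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(12, 30)), columns=[f"a{i}" for i in range(30)])
        b = pd.DataFrame(rng.normal(size=(12, 25)), columns=[f"b{i}" for i in range(25)])
        ab = {(p.cell_a, p.cell_b) for p in mnn_pairs(a, b, k=4)}
        ba = {(p.cell_b, p.cell_a) for p in mnn_pairs(b, a, k=4)}
        assert ab == ba

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = pd.DataFrame(rng.normal(size=(15, 40)), columns=[f"a{i}" for i in range(40)])
            b = pd.DataFrame(rng.normal(size=(15, 40)), columns=[f"b{i}" for i in range(40)])
            got = {(int(p.cell_a[1:]), int(p.cell_b[1:])) for p in mnn_pairs(a, b, k=6)}
            assert got == oracle_knn_pairs(a.to_numpy(), b.to_numpy(), 6)

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.normal(size=(10, 20)), columns=[f"a{i}" for i in range(20)])
        b = pd.DataFrame(rng.normal(size=(10, 20)), columns=[f"b{i}" for i in range(20)])
        base = {(p.cell_a, p.cell_b) for p in mnn_pairs(a, b, k=5)}
        perm = rng.permutation(20)
        again = {(p.cell_a, p.cell_b) for p in mnn_pairs(a.iloc[:, perm], b, k=5)}
        assert base == again

    def test_k_capped_with_warning(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        b = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        with pytest.warns(UserWarning, match="capped"):
            mnn_pairs(a, b, k=10)


class TestStageCorrespondence:
    def _meta(self, mapping):
        return pd.DataFrame(
            {"stage": pd.Series(mapping)}, index=list(mapping)
        )

    def test_single_pair(self):
        from emblineage.xspecies import MNNPair

        pairs = [MNNPair("a0", "b0", 1.0, 0.5)]
        tab = stage_correspondence(
            pairs, self._meta({"a0": "EB"}), self._meta({"b0": "E5"})
        )
        assert tab.loc["EB", "E5"] == 1 and tab.to_numpy().sum() == 1

    def test_total_equals_pair_count(self):
        from emblineage.xspecies import MNNPair

        rng = np.random.default_rng(0)
        stages_a = ["8C", "EB", "LB"]
        stages_b = ["E3", "E5", "E7"]
        meta_a = self._meta({f"a{i}": stages_a[i % 3] for i in range(30)})
        meta_b = self._meta({f"b{i}": stages_b[i % 3] for i in range(30)})
        pairs = [
            MNNPair(f"a{rng.integers(30)}", f"b{rng.integers(30)}", 1.0, 0.0)
            for _ in range(57)
        ]
        tab = stage_correspondence(pairs, meta_a, meta_b)
        assert tab.to_numpy().sum() == 57

    def test_unknown_cell_is_an_error(self):
        from emblineage.xspecies import MNNPair

        with pytest.raises(KeyError):
            stage_correspondence(
                [MNNPair("a0", "zz", 1.0, 0.0)],
                self._meta({"a0": "EB"}),
                self._meta({"b0": "E5"}),
            )
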