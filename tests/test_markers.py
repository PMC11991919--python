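"""Rank-sum testing, fold changes, pseudo-bulk and marker calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from emblineage.markers import (
    find_markers,
    log2_fold_change,
    pseudo_bulk,
    wilcoxon_test,
)
from emblineage.qc import NormalizedMatrix, log_normalize


def nm_from(values, genes=None, cells=None):
    a = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    cells = cells or [f"c{j}" for j in range(a.shape[1])]
    return NormalizedMatrix(pd.DataFrame(a, index=genes, columns=cells), 1e4)


class TestWilcoxon:
    def test_most_extreme_split_of_six(self):
        """(1,2,3) vs (4,5,6): 2 of the C(6,3)=20 rank splits are as extreme,
        so the exact two-sided p is 0.10."""
        assert wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_test([1, 2, 2, 5], [1, 2, 2, 5]) == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=6),
        st.lists(st.integers(0, 9), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, x, y):
        assert wilcoxon_test(x, y) == pytest.approx(wilcoxon_test(y, x))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_test([], [1.0])

    def test_approximation_close_to_exact_small_samples(self):
        """Moment-corrected approximation within 0.01 of exact enumeration on
        500 random continuous cases with group sizes 5-6."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(500):
            n1, n2 = rng.integers(5, 7, 2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            worst = max(
                worst,
                abs(wilcoxon_test(x, y, "exact") - wilcoxon_test(x, y, "asymptotic")),
            )
        assert worst <= 0.01

    def test_agrees_with_scipy_at_moderate_n(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(0.3, 1.0, size=45)
            ours = wilcoxon_test(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            # small expected deviation: ours carries higher-moment corrections
            assert ours == pytest.approx(ref, abs=5e-3)


class TestFoldChange:
    def test_identical_groups_zero(self):
        v = np.log1p([2.0, 3.0, 4.0])
        assert log2_fold_change(v, v) == 0

    def test_closed_form(self):
        v_in = np.log1p([3.0, 3.0])
        v_out = np.log1p([1.0, 1.0])
        assert log2_fold_change(v_in, v_out) == pytest.approx(1.0)

    @given(st.floats(0.0, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_in_group(self, bump):
        v_in = np.log1p(np.array([1.0, 2.0]))
        v_out = np.log1p(np.array([1.5, 1.5]))
        base = log2_fold_change(v_in, v_out)
        raised = log2_fold_change(v_in + bump, v_out)
        assert raised >= base


class TestPseudoBulk:
    def test_single_cell_group_identity(self, small_norm):
        groups = pd.Series(
            {"c1": "A", "c2": "B", "c3": "B"}
        )
        pb = pseudo_bulk(small_norm, groups)
        assert np.allclose(
            pb["A"].to_numpy(),
            np.expm1(small_norm.data["c1"].to_numpy()),
        )

    def test_mean_of_two_cells(self):
        nm = nm_from(np.log1p([[2.0, 4.0]]))
        pb = pseudo_bulk(nm, pd.Series({"c0": "A", "c1": "A"}))
        assert pb.loc["g0", "A"] == pytest.approx(3.0)

    def test_cell_order_invariance(self, small_norm):
        groups = pd.Series({"c1": "A", "c2": "B", "c3": "A"})
        pb1 = pseudo_bulk(small_norm, groups)
        shuffled = NormalizedMatrix(small_norm.data[["c3", "c1", "c2"]], 1e4)
        pb2 = pseudo_bulk(shuffled, groups)
        assert np.allclose(pb1.to_numpy(), pb2.to_numpy())


class TestFindMarkers:
    def _groups(self, n_a, n_b):
        return pd.Series(
            ["A"] * n_a + ["B"] * n_b,
            index=[f"c{j}" for j in range(n_a + n_b)],
        )

    def test_null_gene_absent(self):
        rng = np.random.default_rng(0)
        vals = np.log1p(rng.poisson(5.0, (20, 40)).astype(float))
        recs = find_markers(nm_from(vals), self._groups(20, 20))
        assert recs == []

    def test_small_group_is_an_error(self):
        vals = np.log1p(np.ones((3, 4)))
        groups = pd.Series(["A", "B", "B", "B"], index=[f"c{j}" for j in range(4)])
        with pytest.raises(ValueError, match="A"):
            find_markers(nm_from(vals), groups)

    def test_planted_markers_recovered(self, marker_study):
        data = marker_study.species["gp"]
        nm = log_normalize(data.counts)
        groups = data.meta.loc[nm.data.columns, "lineage"]
        recs = find_markers(nm, groups)
        truth = {
            (lineage, f"GP_{g}")
            for lineage, genes in marker_study.manifest["markers"].items()
            for g in genes
        }
        found = {(r.group, r.gene_id) for r in recs}
        assert truth <= found  # sensitivity 1.0 on the planted design

    def test_bonferroni_uses_gene_universe(self, marker_study):
        data = marker_study.species["gp"]
        nm = log_normalize(data.counts)
        groups = data.meta.loc[nm.data.columns, "lineage"]
        recs = find_markers(nm, groups)
        n_genes = nm.data.shape[0]
        for r in recs[:20]:
            assert r.p_adj == pytest.approx(min(1.0, r.p * n_genes))

    def test_pairwise_contrast_reports_both_signs(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(3.0, (30, 40)).astype(float)
        base[0, :20] += 30  # up in A
        base[1, 20:] += 30  # up in B
        nm = nm_from(np.log1p(base))
        recs = find_markers(nm, self._groups(20, 20), contrast=("A", "B"))
        by_gene = {r.gene_id: r for r in recs}
        assert by_gene["g0"].group == "A" and by_gene["g0"].log2fc > 0
        assert by_gene["g1"].group == "B" and by_gene["g1"].log2fc > 0

    def test_bonferroni_monotone_in_gene_count(self):
        """Adding genes to the tested matrix never decreases any p_adj."""
        rng = np.random.default_rng(8)
        base = rng.poisson(3.0, (30, 60)).astype(float)
        base[0, :30] += 8
        small = nm_from(np.log1p(base))
        big = nm_from(np.log1p(np.vstack([base, rng.poisson(3.0, (30, 60))])))
        groups = self._groups(30, 30)
        p_small = {r.gene_id: r.p_adj for r in find_markers(small, groups)}
        p_big = {r.gene_id: r.p_adj for r in find_markers(big, groups)}
        for g, pa in p_small.items():
            if g in p_big:
                assert p_big[g] >= pa - 1e-12
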