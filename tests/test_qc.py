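"""Cell/gene QC, normalization, variable-gene ranking and scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emblineage.qc import (
    CountMatrix,
    GeneSets,
    NormalizedMatrix,
    QCThresholds,
    compute_qc_metrics,
    filter_cells,
    filter_genes,
    log_normalize,
    scale_data,
    select_variable_genes,
    variable_gene_scores,
)


def cm(array, genes=None, cells=None):
    a = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    cells = cells or [f"c{j}" for j in range(a.shape[1])]
    return CountMatrix(pd.DataFrame(a, index=genes, columns=cells))


class TestMetrics:
    def test_plain_cell_has_zero_fractions(self):
        m = cm(np.ones((5, 1), dtype=int))
        r = compute_qc_metrics(m, GeneSets())
        assert r.loc["c0", "n_genes"] == 5
        assert r.loc["c0", "mito_frac"] == 0 and r.loc["c0", "stress_frac"] == 0

    def test_mito_fraction_arithmetic(self):
        counts = np.array([[50], [950]])
        m = cm(counts, genes=["MT1", "g1"])
        r = compute_qc_metrics(m, GeneSets(mito_genes={"MT1"}))
        assert r.loc["c0", "mito_frac"] == pytest.approx(0.05)

    def test_all_zero_cell_fails_everything(self):
        m = cm(np.zeros((4, 1), dtype=int))
        r = compute_qc_metrics(m, GeneSets())
        assert r.loc["c0", "n_genes"] == 0
        assert r.loc["c0", "mito_frac"] == 1 and r.loc["c0", "stress_frac"] == 1


class TestFilterCells:
    def _matrix_with(self, n_genes_detected, mito=0.0, stress=0.0, n=5000):
        col = np.zeros(n, dtype=int)
        col[: n_genes_detected] = 10
        total = col.sum()
        col[-1] = int(mito / (1 - mito) * total) if mito else 0
        col[-2] = int(stress / (1 - stress) * (total + col[-1])) if stress else 0
        genes = [f"g{i}" for i in range(n - 2)] + ["SG1", "MT1"]
        return CountMatrix(pd.DataFrame(col[:, None], index=genes, columns=["c0"]))

    def test_thresholds_are_strict(self):
        gs = GeneSets(mito_genes={"MT1"}, stress_genes={"SG1"})
        ok = self._matrix_with(3001, mito=0.049, stress=0.084)
        kept, _ = filter_cells(ok, gs)
        assert kept.shape[1] == 1
        boundary = self._matrix_with(3000)
        with pytest.warns(UserWarning, match="no cells pass"):
            kept, _ = filter_cells(boundary, gs)
        assert kept.shape[1] == 0  # exactly 3000 genes is not 'more than 3,000'

    def test_planted_pass_fail_counts(self, qc_study):
        data = qc_study.species["gp"]
        kept, report = filter_cells(data.counts, data.gene_sets)
        statuses = qc_study.manifest["qc"]["gp"]
        expected = [c for c, s in statuses.items() if s == "pass"]
        assert list(kept.cell_ids) == expected
        # each failing cell violates exactly the designated criterion
        th = QCThresholds()
        for cid, status in statuses.items():
            row = report.loc[cid]
            fails = {
                "low_genes": row["n_genes"] <= th.min_genes,
                "mito": row["mito_frac"] >= th.max_mito_frac,
                "stress": row["stress_frac"] >= th.max_stress_frac,
            }
            if status == "pass":
                assert not any(fails.values())
            else:
                assert fails.pop(status) and not any(fails.values())

    def test_idempotence(self, qc_study):
        data = qc_study.species["gp"]
        once, _ = filter_cells(data.counts, data.gene_sets)
        twice, _ = filter_cells(once, data.gene_sets)
        assert list(twice.cell_ids) == list(once.cell_ids)

    def test_all_zero_matrix_keeps_nothing(self):
        with pytest.warns(UserWarning):
            kept, _ = filter_cells(cm(np.zeros((10, 3), dtype=int)), GeneSets())
        assert kept.shape[1] == 0


class TestFilterGenes:
    def test_detection_threshold_inclusive(self):
        a = np.array([[1, 1, 0, 0], [1, 1, 1, 0], [5, 0, 0, 0]])
        kept = filter_genes(cm(a), min_cells=3)
        assert kept.gene_ids == ["g1"]

    def test_min_cells_zero_is_identity(self):
        a = np.array([[0, 0], [1, 0]])
        assert filter_genes(cm(a), min_cells=0).shape == (2, 2)


class TestLogNormalize:
    def test_zero_count_stays_zero(self, small_norm):
        assert (small_norm.data.to_numpy() == 0).sum() == 4

    def test_single_gene_cell_closed_form(self):
        m = cm(np.array([[7], [0]]))
        nm = log_normalize(m)
        assert nm.data.iloc[0, 0] == pytest.approx(np.log(1 + 1e4), abs=1e-6)

    @given(st.integers(2, 20))
    @settings(max_examples=20, deadline=None)
    def test_depth_invariance(self, factor):
        a = np.array([[3, 1], [0, 2], [5, 9]])
        v1 = log_normalize(cm(a)).data.to_numpy()
        v2 = log_normalize(cm(a * factor)).data.to_numpy()
        assert np.allclose(v1, v2)

    def test_monotone_within_cell(self):
        a = np.array([[1], [2], [10]])
        v = log_normalize(cm(a)).data.to_numpy().ravel()
        assert v[0] < v[1] < v[2]

    def test_all_zero_cell_is_an_error(self):
        with pytest.raises(ValueError, match="filter_cells"):
            log_normalize(cm(np.array([[1, 0], [2, 0]])))


class TestVariableGenes:
    def test_identical_genes_get_identical_scores(self):
        rng = np.random.default_rng(0)
        row = rng.poisson(5, 50)
        a = np.vstack([row, row, rng.poisson(5, 50), rng.poisson(2, 50)])
        scores = variable_gene_scores(cm(a))
        assert scores.iloc[0] == pytest.approx(scores.iloc[1])

    def test_constant_gene_scores_zero(self):
        a = np.vstack([np.full(30, 4), np.random.default_rng(1).poisson(4, (20, 30))])
        scores = variable_gene_scores(cm(a))
        assert scores.iloc[0] == 0

    def test_planted_high_dispersion_gene_ranks_first(self):
        """A 10x-dispersion NB gene outranks equal-mean constant-dispersion
        genes in every seeded replicate."""
        n_cells, theta_bg, theta_hot = 80, 20.0, 2.0
        bg_means = np.geomspace(1.0, 50.0, 60)  # trend identifiable over a mean range
        for seed in range(100):
            rng = np.random.default_rng(seed)
            bg = rng.negative_binomial(
                theta_bg, theta_bg / (theta_bg + bg_means)[:, None], (60, n_cells)
            )
            hot = rng.negative_binomial(theta_hot, theta_hot / (theta_hot + 10.0), (1, n_cells))
            m = cm(np.vstack([hot, bg]))
            nm = log_normalize(m)
            top = select_variable_genes(nm, n=1)
            assert top == ["g0"]


class TestScaleData:
    def test_zscore_closed_form(self):
        nm = NormalizedMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")), 1e4
        )
        out = scale_data(nm)
        assert np.allclose(out.to_numpy(), [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_perfect_covariate_fit_leaves_zeros(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0])
        nm = NormalizedMatrix(
            pd.DataFrame([2 * cov + 1], index=["g"], columns=list("abcd")), 1e4
        )
        out = scale_data(nm, covariate=cov)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_outliers_clip_at_ten(self):
        vals = np.concatenate([np.zeros(400), [400.0]])
        nm = NormalizedMatrix(
            pd.DataFrame([vals], index=["g"], columns=[f"c{i}" for i in range(401)]), 1e4
        )
        assert scale_data(nm).to_numpy().max() == 10.0
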