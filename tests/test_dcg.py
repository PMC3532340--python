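import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from coexrif import (
    SimulationSpec,
    bh_adjust,
    condition_correlations,
    correlation_matrix,
    dcg_analysis,
    filter_links,
    gene_dc_statistic,
    permutation_pvalues,
    select_dcgs,
    simulate,
)
from coexrif.dcg import _gene_dc_vector

from conftest import make_dataset


class TestCorrelations:
    def test_perfect_linear_pairs(self):
        X = np.array([[1.0, 2, 3], [2, 4, 6], [3, 2, 1]])
        R, zero = correlation_matrix(X)
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        assert not zero.any()

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        R, _ = correlation_matrix(np.vstack([x, y]))
        # cov*n = 4, var*n = 5 for both -> r = 4/5
        assert R[0, 1] == pytest.approx(0.8, abs=1e-12)
        assert R[0, 1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_variance_gene_warns_and_scores_zero_correlation(self):
        values = np.vstack([np.arange(6.0), np.full(6, 3.0), np.arange(6.0)[::-1]])
        ds = make_dataset(values, 3, 3)
        with pytest.warns(UserWarning, match="zero-variance"):
            R1, R2 = condition_correlations(ds)
        assert R1[0, 1] == 0.0 and R1[1, 2] == 0.0
        assert R1[1, 1] == 1.0  # unit diagonal kept


class TestLinkFilter:
    def test_q_one_retains_every_link(self):
        rng = np.random.default_rng(0)
        A, _ = correlation_matrix(rng.normal(size=(4, 8)))
        B, _ = correlation_matrix(rng.normal(size=(4, 8)))
        mask = filter_links(A, B, q=1.0)
        assert mask.sum() == 4 * 3  # symmetric count of all 6 links

    def test_matches_bruteforce_quantile_on_toy(self):
        # 5 genes -> 10 links; known correlation entries
        rng = np.random.default_rng(1)
        A, _ = correlation_matrix(rng.normal(size=(5, 10)))
        B, _ = correlation_matrix(rng.normal(size=(5, 10)))
        q = 0.25
        iu = np.triu_indices(5, 1)
        pooled = np.concatenate([np.abs(A[iu]), np.abs(B[iu])])
        thr = np.quantile(pooled, 1 - q)
        expected = np.maximum(np.abs(A[iu]), np.abs(B[iu])) >= thr
        mask = filter_links(A, B, q)
        np.testing.assert_array_equal(mask[iu], expected)

    def test_all_equal_correlations_tie_rule_retains_all(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        mask = filter_links(A, A, q=0.25)
        assert mask.sum() == 3 * 2  # >= at the threshold keeps ties

    def test_q_out_of_range_rejected(self):
        A = np.eye(3)
        with pytest.raises(ValueError):
            filter_links(A, A, q=0.0)


class TestGeneStatistic:
    def test_identical_correlations_score_zero(self):
        assert gene_dc_statistic([0.3, -0.2], [0.3, -0.2]) == 0.0

    def test_two_fully_flipped_links(self):
        assert gene_dc_statistic([1.0, -1.0], [-1.0, 1.0]) == pytest.approx(2.0)

    def test_single_strongly_flipped_link(self):
        # a +0.970975 / -0.88501 sign flip gives |r1 - r2| exactly
        assert gene_dc_statistic([0.970975], [-0.88501]) == pytest.approx(1.855985, abs=5e-7)

    def test_vectorized_statistic_matches_scalar(self):
        rng = np.random.default_rng(2)
        A, _ = correlation_matrix(rng.normal(size=(6, 12)))
        B, _ = correlation_matrix(rng.normal(size=(6, 12)))
        mask = filter_links(A, B, 0.5)
        dC = _gene_dc_vector(A, B, mask)
        for g in range(6):
            links = np.flatnonzero(mask[g])
            expected = gene_dc_statistic(A[g, links], B[g, links]) if links.size else 0.0
            assert dC[g] == pytest.approx(expected, abs=1e-12)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected, atol=1e-12)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 60))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_preserving_under_input_permutation(self, p):
        p = np.array(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestPermutation:
    def test_pvalue_floor_is_add_one_bound_and_planted_gene_reaches_it(self):
        spec = SimulationSpec(
            n_genes=30, n_samples_per_condition=20, n_modules=1, module_size=6,
            rho1=0.9, rho2=-0.9, seed=3,
        )
        ds, truth = simulate(spec)
        p, dC = permutation_pvalues(ds, n_perm=200, seed=3)
        assert np.all(p >= 1 / 201) and np.all(p <= 1.0)
        anchor = ds.gene_ids.index(truth.planted_tf_of_module[0])
        assert p[anchor] == pytest.approx(1 / 201)
        assert dC[anchor] > np.median(dC)

    def test_statistic_and_pvalues_invariant_under_condition_swap(self):
        rng = np.random.default_rng(4)
        values = rng.normal(8, 2, size=(12, 12))
        ds = make_dataset(values, 6, 6)
        swapped = make_dataset(values, 6, 6)
        swapped.condition_of = {s: 3 - c for s, c in ds.condition_of.items()}
        p1, d1 = permutation_pvalues(ds, n_perm=150, seed=5)
        p2, d2 = permutation_pvalues(swapped, n_perm=150, seed=5)
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        np.testing.assert_array_equal(p1, p2)

    def test_relabeling_samples_within_condition_leaves_dc_unchanged(self):
        rng = np.random.default_rng(6)
        values = rng.normal(8, 2, size=(10, 10))
        ds = make_dataset(values, 5, 5)
        shuffled = make_dataset(values[:, [3, 0, 4, 1, 2, 8, 6, 9, 5, 7]], 5, 5)
        _, d1 = permutation_pvalues(ds, n_perm=100, seed=0)
        _, d2 = permutation_pvalues(shuffled, n_perm=100, seed=0)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_too_few_permutations_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            permutation_pvalues(tiny_dataset, n_perm=50)


class TestSelection:
    def test_fdr_exactly_at_cutoff_is_not_selected(self):
        import pandas as pd

        table = pd.DataFrame({"gene": ["a", "b"], "fdr": [0.25, 0.249]})
        links = pd.DataFrame({"gene_a": [], "gene_b": []})
        dcgs, _ = select_dcgs(table, links, fdr_cutoff=0.25)
        assert dcgs == {"b"}

    def test_complete_triangle_of_dcgs_gives_three_dc_links(self):
        import pandas as pd

        table = pd.DataFrame({"gene": ["a", "b", "c", "d"], "fdr": [0.1, 0.1, 0.1, 0.9]})
        links = pd.DataFrame(
            {"gene_a": ["a", "a", "b", "a"], "gene_b": ["b", "c", "c", "d"]}
        )
        dcgs, dc = select_dcgs(table, links)
        assert dcgs == {"a", "b", "c"}
        assert len(dc) == 3

    def test_no_dcgs_gives_no_dc_links(self):
        import pandas as pd

        table = pd.DataFrame({"gene": ["a", "b"], "fdr": [0.9, 0.9]})
        links = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        dcgs, dc = select_dcgs(table, links)
        assert dcgs == set() and len(dc) == 0


def test_dcg_analysis_recovers_planted_module_quickly():
    spec = SimulationSpec(
        n_genes=40, n_samples_per_condition=20, n_modules=1, module_size=6,
        rho1=0.9, rho2=-0.9, seed=8,
    )
    ds, truth = simulate(spec)
    res = dcg_analysis(ds, n_perm=200, seed=8)
    assert truth.dc_genes <= res.dcgs
    # canonical link ordering
    assert (res.links["gene_a"] < res.links["gene_b"]).all()
    # dC bounded by construction
    assert res.table["dC"].between(0, 2).all()
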