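import numpy as np
import pytest

from coexrif import (
    RIFInput,
    SimulationSpec,
    build_companions,
    build_network,
    build_rif_input,
    condition_means,
    dcg_analysis,
    rank_tfs,
    rif_score,
    simulate,
)

from conftest import make_dataset


def _random_input(rng, n=None):
    n = n or int(rng.integers(1, 15))
    return RIFInput(
        tf="tf",
        target_set=[f"t{i}" for i in range(n)],
        e1=rng.uniform(1, 12, n),
        e2=rng.uniform(1, 12, n),
        r1=rng.uniform(-1, 1, n),
        r2=rng.uniform(-1, 1, n),
    )


class TestConditionMeans:
    def test_flat_per_condition_values(self):
        ds = make_dataset(np.array([[2.0, 2, 2, 4, 4, 4]]), 3, 3)
        assert condition_means(ds, "g1") == (2.0, 4.0)

    def test_identical_conditions(self):
        ds = make_dataset(np.array([[1.0, 2, 3, 1, 2, 3]]), 3, 3)
        assert condition_means(ds, "g1") == (2.0, 2.0)

    def test_missing_gene_rejected(self):
        ds = make_dataset(np.ones((1, 6)) * np.arange(6), 3, 3)
        with pytest.raises(KeyError):
            condition_means(ds, "nope")


class TestScore:
    def test_identical_conditions_score_zero(self):
        inp = RIFInput("tf", ["a", "b"], [2.0, 3.0], [2.0, 3.0], [0.5, -0.4], [0.5, -0.4])
        assert rif_score(inp) == 0.0

    def test_hand_computed_single_target(self):
        inp = RIFInput("tf", ["a"], [2.0], [1.0], [0.5], [0.5])
        # ((2*0.5)^2 - (1*0.5)^2) / 1
        assert rif_score(inp) == pytest.approx(0.75)

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        inp = _random_input(rng)
        swapped = RIFInput(inp.tf, inp.target_set, inp.e2, inp.e1, inp.r2, inp.r1)
        assert rif_score(swapped) == pytest.approx(-rif_score(inp), abs=1e-12)

    def test_quadratic_homogeneity_in_expression_scale(self):
        rng = np.random.default_rng(2)
        inp = _random_input(rng)
        c = 3.7
        scaled = RIFInput(inp.tf, inp.target_set, c * inp.e1, c * inp.e2, inp.r1, inp.r2)
        assert rif_score(scaled) == pytest.approx(c * c * rif_score(inp), rel=1e-12)

    def test_invariant_under_target_permutation(self):
        rng = np.random.default_rng(3)
        inp = _random_input(rng, n=8)
        perm = rng.permutation(8)
        shuffled = RIFInput(
            inp.tf,
            [inp.target_set[i] for i in perm],
            inp.e1[perm], inp.e2[perm], inp.r1[perm], inp.r2[perm],
        )
        assert rif_score(shuffled) == pytest.approx(rif_score(inp), rel=1e-12)

    def test_tf_in_own_target_set_rejected(self):
        with pytest.raises(ValueError):
            RIFInput("tf", ["tf"], [1.0], [1.0], [0.1], [0.1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RIFInput("tf", ["a", "b"], [1.0], [1.0, 2.0], [0.1, 0.2], [0.1, 0.2])


class TestRanking:
    def _toy_network(self, edges, dcgs):
        from coexrif import RegulatoryPairs

        return build_network(dcgs, None, RegulatoryPairs(pairs=edges))

    def test_single_tf_gets_rank_one_regardless_of_sign(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.normal(8, 2, (4, 8)), 4, 4)
        net = self._toy_network([("g1", "g2"), ("g1", "g3")], {"g2", "g3"})
        table = rank_tfs(ds, net, {"g2", "g3"})
        assert list(table["abs_rank"]) == [1]
        assert table.iloc[0]["n_de"] == 2

    def test_ranking_by_absolute_value_with_name_ties(self):
        # two TFs with identical target sets have identical |RIF|; the tie
        # breaks on TF name ascending
        rng = np.random.default_rng(5)
        values = rng.normal(8, 2, (5, 10))
        values[1] = values[0]  # tb duplicates ta, so scores tie exactly
        ds = make_dataset(values, 5, 5)
        ds.gene_ids = ["ta", "tb", "g3", "g4", "g5"]
        net = self._toy_network(
            [("ta", "g3"), ("ta", "g4"), ("tb", "g3"), ("tb", "g4")], {"g3", "g4"}
        )
        table = rank_tfs(ds, net, {"g3", "g4"})
        assert list(table["tf"]) == ["ta", "tb"]
        assert list(table["abs_rank"]) == [1, 2]

    def test_tf_without_eligible_targets_is_omitted_with_warning(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(rng.normal(8, 2, (4, 8)), 4, 4)
        net = self._toy_network([("g1", "g2"), ("g3", "g4")], {"g2", "g4"})
        # g4 is no longer a DCG at ranking time, so g3 has no eligible target
        with pytest.warns(UserWarning, match="omitted"):
            table = rank_tfs(ds, net, {"g2"})
        assert list(table["tf"]) == ["g1"]

    def test_no_rankable_tf_raises(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng.normal(8, 2, (4, 8)), 4, 4)
        net = self._toy_network([("g1", "g2")], {"g2"})
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            rank_tfs(ds, net, dcgs=set())

    def test_all_dcg_target_mode_scores_against_full_list(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng.normal(8, 2, (5, 8)), 4, 4)
        net = self._toy_network([("g1", "g2")], {"g2", "g3", "g4"})
        table = rank_tfs(ds, net, {"g2", "g3", "g4"}, targets="all-dcg")
        assert table.iloc[0]["n_de"] == 3


def test_planted_regulator_outranks_decoys_on_planted_data():
    spec = SimulationSpec(
        n_genes=60, n_samples_per_condition=20, n_modules=1, module_size=8,
        rho1=0.95, rho2=-0.85, seed=11,
    )
    ds, truth = simulate(spec)
    res = dcg_analysis(ds, n_perm=200, seed=11)
    _, pairs = build_companions(ds, truth, n_decoy_tfs=10, targets_per_decoy=3, seed=11)
    net = build_network(res.dcgs, None, pairs, corr1=res.corr1, corr2=res.corr2,
                        gene_index=ds.gene_index())
    table = rank_tfs(ds, net, res.dcgs)
    anchor = table.iloc[0]["tf"]
    assert anchor in truth.planted_tfs()
    rif_input = build_rif_input(ds, anchor, sorted(truth.dc_genes - {anchor}))
    assert rif_input.n_de == 7
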