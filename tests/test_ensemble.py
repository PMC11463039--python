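import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from nasonet import (
    EnsembleConfig,
    SimulationConfig,
    aggregate_ensemble,
    bray_curtis_association,
    build_network,
    clr_transform,
    coat_correlation,
    mutual_information_matrix,
    simulate_cohort,
    sparse_graph_partial_correlation,
    split_subnetworks,
    weighted_simes,
)
from nasonet.ensemble import (
    MethodScoreMatrix,
    SignedNetwork,
    _clr_matrix,
    _make_adapters,
    reboot_edge_pvalues,
)

from conftest import edge_labels_and_scores, make_table


class TestClrTransform:
    def test_powers_of_ten_sample(self):
        t = make_table(np.array([[1.0], [10.0], [100.0]]) / 111.0)
        clr = clr_transform(t, pseudocount=0)
        np.testing.assert_allclose(
            clr[:, 0], [-np.log(10), 0.0, np.log(10)], atol=1e-9
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=(5, 3)).astype(float)
        a = _clr_matrix(counts / counts.sum(0), 0.0)
        b = _clr_matrix(5 * counts / (5 * counts).sum(0), 0.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_uniform_sample_maps_to_zero(self):
        t = make_table(np.full((4, 2), 0.25))
        np.testing.assert_allclose(clr_transform(t, 0), 0.0, atol=1e-12)

    def test_zero_pseudocount_with_zeros_rejected(self):
        t = make_table([[1.0, 0.5], [0.0, 0.5]])
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(t, pseudocount=0)

    def test_columns_centered(self):
        rng = np.random.default_rng(3)
        rel = rng.dirichlet(np.ones(6), size=4).T
        clr = _clr_matrix(rel, 0.0)
        np.testing.assert_allclose(clr.mean(axis=0), 0.0, atol=1e-12)


class TestCoat:
    def test_huge_soft_zeroes_all_off_diagonals(self):
        rng = np.random.default_rng(1)
        clr = rng.normal(size=(6, 50))
        m = coat_correlation(clr, soft=1e6)
        off = m.raw_scores[~np.eye(6, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_independent_taxa_mostly_shrunk(self):
        rng = np.random.default_rng(2)
        clr = rng.normal(size=(10, 1000))
        m = coat_correlation(clr, soft=0.2)
        off = np.abs(m.raw_scores[~np.eye(10, dtype=bool)])
        assert off.mean() < 0.1

    def test_covarying_pair_scores_highest(self):
        rng = np.random.default_rng(5)
        basis = np.exp(rng.normal(size=(10, 400)))
        basis[1] = basis[0] * np.exp(rng.normal(0, 0.05, size=400))
        rel = basis / basis.sum(0)
        m = coat_correlation(_clr_matrix(rel, 0.0), soft=0.2)
        scores = np.abs(np.nan_to_num(m.raw_scores))
        i, j = np.unravel_index(np.argmax(scores), scores.shape)
        assert {i, j} == {0, 1}

    def test_constant_taxon_flagged(self):
        clr = np.vstack([np.zeros(20), np.random.default_rng(0).normal(size=(3, 20))])
        with pytest.warns(UserWarning, match="constant"):
            m = coat_correlation(clr, soft=0.2)
        assert np.isnan(m.raw_scores[0, 1])


class TestSparseGraph:
    def test_diagonal_truth_selects_near_empty_graph(self):
        rng = np.random.default_rng(7)
        clr = rng.normal(size=(10, 500))
        m = sparse_graph_partial_correlation(clr, nlambda=30, seed=0, n_subsamples=10)
        edges = (np.abs(np.nan_to_num(m.raw_scores)) > 1e-8).sum() // 2
        assert edges <= 2

    def test_chain_precision_edges_rank_top(self):
        p, n = 8, 600
        omega = np.eye(p) * 1.5
        for i in range(p - 1):
            omega[i, i + 1] = omega[i + 1, i] = -0.6
        cov = np.linalg.inv(omega)
        rng = np.random.default_rng(11)
        x = rng.multivariate_normal(np.zeros(p), cov, size=n).T
        m = sparse_graph_partial_correlation(x, nlambda=30, seed=0, n_subsamples=10)
        scores = np.abs(np.nan_to_num(m.raw_scores))
        iu = np.triu_indices(p, 1)
        order = np.argsort(-scores[iu])
        chain = {(i, i + 1) for i in range(p - 1)}
        top = {(iu[0][k], iu[1][k]) for k in order[: p - 1]}
        assert len(top & chain) >= p - 2  # at most one swap

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(13)
        clr = rng.normal(size=(6, 100))
        a = sparse_graph_partial_correlation(clr, nlambda=20, seed=4, n_subsamples=8)
        b = sparse_graph_partial_correlation(clr, nlambda=20, seed=4, n_subsamples=8)
        np.testing.assert_array_equal(np.nan_to_num(a.raw_scores),
                                      np.nan_to_num(b.raw_scores))


class TestMutualInformation:
    def test_identical_binary_split_gives_ln2(self):
        rel = np.array([[0.0, 0.0, 1.0, 1.0], [0.0, 0.0, 1.0, 1.0]])
        m = mutual_information_matrix(rel, bins=2)
        assert m.raw_scores[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_independent_uniform_joint_gives_zero(self):
        rel = np.array([[0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0]])
        m = mutual_information_matrix(rel, bins=2)
        assert m.raw_scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_for_all_pairs(self):
        rng = np.random.default_rng(17)
        rel = rng.dirichlet(np.ones(6), size=50).T
        m = mutual_information_matrix(rel, bins=5)
        iu = np.triu_indices(6, 1)
        assert (m.raw_scores[iu] >= -1e-12).all()

    def test_fewer_samples_than_bins_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_matrix(np.ones((3, 3)) / 3, bins=4)


class TestBrayCurtisAssociation:
    def test_identical_rows_score_one(self):
        rel = np.array([[0.5, 0.3], [0.5, 0.3], [0.0, 0.4]])
        m = bray_curtis_association(rel)
        assert m.raw_scores[0, 1] == pytest.approx(1.0)

    def test_disjoint_rows_score_zero(self):
        rel = np.array([[0.5, 0.0], [0.0, 0.5], [0.5, 0.5]])
        m = bray_curtis_association(rel)
        assert m.raw_scores[0, 1] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        rel = np.array([[2.0, 1.0], [1.0, 2.0]])
        m = bray_curtis_association(rel)
        assert m.raw_scores[0, 1] == pytest.approx(2.0 / 3.0)

    def test_all_zero_pair_undefined(self):
        rel = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        m = bray_curtis_association(rel)
        assert np.isnan(m.raw_scores[0, 1])


class TestWeightedSimes:
    def test_single_p_is_identity(self):
        assert weighted_simes([0.2]) == pytest.approx(0.2)

    def test_equal_weight_worked_example(self):
        assert weighted_simes([0.01, 0.04, 0.03]) == pytest.approx(0.03)

    def test_weighted_worked_example(self):
        assert weighted_simes([0.05, 0.01], [2.0, 1.0]) == pytest.approx(0.03)

    def test_equal_weights_match_classic_simes_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            k = rng.integers(1, 6)
            p = rng.random(k).clip(1e-6)
            classic = np.min(np.sort(p) * k / np.arange(1, k + 1))
            assert weighted_simes(p) == pytest.approx(min(classic, 1.0), abs=1e-12)

    def test_weighted_form_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            p = rng.random(k).clip(1e-6)
            w = rng.random(k) + 0.1
            order = np.argsort(p, kind="mergesort")
            brute = min(
                w.sum() * p[order][i] / w[order][: i + 1].sum() for i in range(k)
            )
            assert weighted_simes(p, w) == pytest.approx(min(brute, 1.0), abs=1e-12)

    def test_monotone_in_each_input(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            p = rng.random(4).clip(1e-6)
            w = rng.random(4) + 0.1
            base = weighted_simes(p, w)
            i = rng.integers(4)
            bumped = p.copy()
            bumped[i] = min(1.0, bumped[i] + rng.random() * (1 - bumped[i]))
            assert weighted_simes(bumped, w) >= base - 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_simes([])
        with pytest.raises(ValueError):
            weighted_simes([0.0])
        with pytest.raises(ValueError):
            weighted_simes([0.5], [0.0])


def _method_stub(name, raw, signs=None, p=None):
    raw = np.asarray(raw, dtype=float)
    return MethodScoreMatrix(name, [], raw, signs if signs is not None
                             else np.zeros_like(raw, dtype=int), p)


def _four_methods(p=3, coat_sign=1, huge_sign=1, pvals=(0.01, 0.04, 0.03, 1.0)):
    raw = np.ones((p, p)) - np.eye(p)
    pv = [np.full((p, p), v) for v in pvals]
    coat = _method_stub("coat", raw, coat_sign * (1 - np.eye(p, dtype=int)), pv[0])
    huge = _method_stub("sparse_graph", raw, huge_sign * (1 - np.eye(p, dtype=int)), pv[1])
    mi = _method_stub("mutual_information", raw, None, pv[2])
    bc = _method_stub("bray_curtis", raw, None, pv[3])
    return {m.method: m for m in (coat, huge, mi, bc)}


class TestAggregateEnsemble:
    def test_all_methods_at_max_gives_aggregate_one(self):
        mats = _four_methods()
        # add one weaker pair so min-max has spread; the strongest pair hits 1
        for m in mats.values():
            m.raw_scores[0, 1] = m.raw_scores[1, 0] = 0.2
        agg, _, _, _ = aggregate_ensemble(mats)
        assert agg[0, 2] == pytest.approx(1.0)

    def test_sign_conflict_excludes_edge(self):
        mats = _four_methods(coat_sign=1, huge_sign=-1)
        _, signs, merged, conflict = aggregate_ensemble(mats)
        assert conflict[0, 1]
        assert signs[0, 1] == 0
        assert merged[0, 1] == 1.0

    def test_sign_conflict_magnitude_policy(self):
        mats = _four_methods(coat_sign=1, huge_sign=-1)
        mats["coat"].raw_scores[:] = 0.9
        mats["sparse_graph"].raw_scores[:] = 0.1
        _, signs, _, conflict = aggregate_ensemble(mats, sign_conflict="magnitude")
        assert not conflict.any()

    def test_agreeing_or_single_sign_propagates(self):
        mats = _four_methods(coat_sign=1, huge_sign=0)
        _, signs, _, _ = aggregate_ensemble(mats)
        assert signs[0, 1] == 1

    def test_simes_merge_worked_example(self):
        mats = _four_methods(pvals=(0.01, 0.04, 0.03, 1.0))
        _, _, merged, _ = aggregate_ensemble(mats)
        assert merged[0, 1] == pytest.approx(0.04)

    def test_missing_method_rejected(self):
        mats = _four_methods()
        del mats["coat"]
        with pytest.raises(ValueError, match="coat"):
            aggregate_ensemble(mats)


class TestBuildAndSplitNetwork:
    def _net(self, pvals, threshold):
        p = len(pvals) + 1
        agg = np.ones((p, p))
        signs = np.ones((p, p), dtype=int) - np.eye(p, dtype=int)
        merged = np.ones((p, p))
        for k, v in enumerate(pvals):
            merged[0, k + 1] = merged[k + 1, 0] = v
        # only pairs (0, k) can pass; others keep p = 1
        for i in range(1, p):
            for j in range(i + 1, p):
                signs[i, j] = signs[j, i] = 0
        taxa = [f"T{i}" for i in range(p)]
        domains = {t: "bacteria" for t in taxa}
        return build_network(agg, signs, merged, threshold, domains, taxa)

    def test_zero_threshold_empty(self):
        assert self._net([1e-4, 5e-4], 0.0).n_edges == 0

    def test_threshold_one_includes_all_sign_defined(self):
        assert self._net([0.5, 0.99], 1.0).n_edges == 2

    def test_counting_at_1e3(self):
        net = self._net([1e-4, 5e-4, 2e-3, 0.05, 0.5], 1e-3)
        assert net.n_edges == 2

    def test_isolated_nodes_retained(self):
        net = self._net([0.5], 1e-3)
        assert net.n_edges == 0 and len(net.nodes) == 2

    def test_split_partition_conserves_edges(self):
        rng = np.random.default_rng(31)
        taxa = [f"B{i}" for i in range(5)] + [f"F{i}" for i in range(5)]
        domains = {t: ("bacteria" if t.startswith("B") else "fungi") for t in taxa}
        edges = {}
        for a, b in itertools.combinations(taxa, 2):
            if rng.random() < 0.4:
                edges[(a, b)] = 1 if rng.random() < 0.5 else -1
        net = SignedNetwork.from_edges(edges, domains)
        parts = split_subnetworks(net)
        assert (parts["bacteria"].n_edges + parts["fungi"].n_edges
                + parts["cross"].n_edges) == net.n_edges

    def test_cross_edge_lands_in_cross_subnetwork(self):
        net = SignedNetwork.from_edges({("B1", "F1"): 1},
                                       {"B1": "bacteria", "F1": "fungi"})
        parts = split_subnetworks(net)
        assert parts["cross"].n_edges == 1
        assert parts["bacteria"].n_edges == 0
        assert parts["fungi"].n_edges == 0

    def test_all_bacteria_network_leaves_others_empty(self):
        net = SignedNetwork.from_edges({("B1", "B2"): -1},
                                       {"B1": "bacteria", "B2": "bacteria"})
        parts = split_subnetworks(net)
        assert parts["bacteria"].n_edges == 1
        assert parts["fungi"].n_edges == 0 and parts["cross"].n_edges == 0


class TestReboot:
    def test_identical_seeds_identical_pvalues(self):
        rng = np.random.default_rng(37)
        rel = rng.dirichlet(np.ones(6), size=60).T
        cfg = EnsembleConfig(n_permutations=25, n_bootstraps=10, seed=2)
        _, p1 = reboot_edge_pvalues(rel, "bray_curtis", cfg)
        _, p2 = reboot_edge_pvalues(rel, "bray_curtis", cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_strong_pair_hits_p_floor(self):
        rng = np.random.default_rng(41)
        basis = np.exp(rng.normal(size=(8, 300)))
        basis[1] = basis[0] * np.exp(rng.normal(0, 0.05, size=300))
        rel = basis / basis.sum(0)
        cfg = EnsembleConfig(n_permutations=50, n_bootstraps=10, seed=3)
        _, pv = reboot_edge_pvalues(rel, "coat", cfg)
        assert pv[0, 1] == pytest.approx(1 / 51)

    def test_log_ratio_and_rank_methods_calibrated_under_null(self):
        """Structure-free compositions: CLR-correlation and MI p-values uniform."""
        cfg = SimulationConfig(n_samples=(200, 1), n_bacteria=10, n_fungi=10,
                               edge_density=0.0, zero_inflation_prob=0.02, seed=31)
        rel = simulate_cohort(cfg).relative["group1"].values
        ec = EnsembleConfig(seed=5)
        iu = np.triu_indices(20, 1)
        for method in ("coat", "mutual_information"):
            _, pv = reboot_edge_pvalues(rel, method, ec)
            assert stats.kstest(pv[iu], "uniform").pvalue > 0.01

    def test_too_few_permutations_warns(self):
        rng = np.random.default_rng(43)
        rel = rng.dirichlet(np.ones(4), size=30).T
        cfg = EnsembleConfig(n_permutations=10, n_bootstraps=5, seed=1)
        with pytest.warns(UserWarning, match="permutations"):
            reboot_edge_pvalues(rel, "bray_curtis", cfg)


class TestJointPermutationEquivariance:
    def test_score_matrices_permute_with_taxa(self):
        rng = np.random.default_rng(47)
        rel = rng.dirichlet(np.ones(7), size=40).T
        perm = rng.permutation(7)
        for fn in (
            lambda r: mutual_information_matrix(r, bins=4).raw_scores,
            lambda r: bray_curtis_association(r).raw_scores,
            lambda r: coat_correlation(_clr_matrix(r, 1e-6), 0.2).raw_scores,
        ):
            base = fn(rel)
            permuted = fn(rel[perm])
            np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-10)


class TestEdgeRecovery:
    def test_aggregate_score_separates_planted_edges(self, recovery_ensemble):
        cohort, result = recovery_ensemble
        y, s = edge_labels_and_scores(cohort, result)
        assert roc_auc_score(y, s) >= 0.8

    def test_signs_agree_with_planted_interactions(self, recovery_ensemble):
        cohort, result = recovery_ensemble
        taxa = result.taxon_ids
        agree = total = 0
        for (a, b), sign in cohort.planted["group1"].edge_set.items():
            i, j = taxa.index(a), taxa.index(b)
            if result.signs[i, j] != 0:
                total += 1
                agree += result.signs[i, j] == sign
        assert total > 0
        assert agree / total >= 0.8
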