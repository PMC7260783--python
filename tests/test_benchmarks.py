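import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qaffp.benchmarks import (
    BenchSet,
    ClassificationConfig,
    FingerprintScheme,
    HoppingConfig,
    RankedList,
    SimilarityConfig,
    enrichment_factor,
    ligand_overlap_fraction,
    max_fusion_scores,
    paired_difference_ci,
    pool_hopping_results,
    roc_auc,
    rogot_goldberg,
    run_classification_benchmark,
    run_scaffold_hopping,
    run_similarity_benchmark,
    similarity_matrix,
    tanimoto,
    wilcoxon_exact_paired,
)
from qaffp.chemstruct import morgan2_matrix
from qaffp.ensemble import BalancedRandomForestClassifier
from qaffp.synthetic import generate_class_set

MORGAN_SCHEME = FingerprintScheme("morgan2", lambda mols: morgan2_matrix(mols), "tanimoto")


def vec(*bits):
    return np.array(bits, dtype=np.uint8)


class TestBinarySimilarity:
    def test_rogot_goldberg_hand_values(self):
        x = vec(1, 1, 1, 0, 0, 0, 0, 0)
        y = vec(1, 1, 0, 1, 0, 0, 0, 0)
        # a=2, b=1, c=1, d=4 -> 2/6 + 4/10
        assert rogot_goldberg(x, y) == pytest.approx(2 / 6 + 4 / 10)
        mixed = vec(1, 0, 1, 0)
        assert rogot_goldberg(mixed, mixed) == 1.0
        assert rogot_goldberg(mixed, 1 - mixed) == 0.0

    def test_tanimoto_hand_values(self):
        assert tanimoto(vec(1, 1, 0, 0), vec(1, 1, 0, 0)) == 1.0
        assert tanimoto(vec(1, 0, 0), vec(0, 1, 1)) == 0.0
        # a=1, b=1, c=2
        assert tanimoto(vec(1, 1, 0, 0), vec(1, 0, 1, 1)) == pytest.approx(0.25)
        assert tanimoto(vec(0, 0), vec(0, 0)) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rogot_goldberg_properties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 64))
        x, y = rng.integers(0, 2, size=(2, n)).astype(np.uint8)
        s = rogot_goldberg(x, y)
        assert s == pytest.approx(rogot_goldberg(y, x))
        assert 0.0 <= s <= 1.0
        if np.array_equal(x, y) and 0 < x.sum() < n:
            assert s == 1.0

    def test_bulk_matrix_matches_pairwise(self):
        rng = np.random.default_rng(1)
        Q = rng.integers(0, 2, size=(5, 32)).astype(np.uint8)
        P = rng.integers(0, 2, size=(7, 32)).astype(np.uint8)
        for metric, fn in (("tanimoto", tanimoto), ("rogot_goldberg", rogot_goldberg)):
            M = similarity_matrix(Q, P, metric)
            for i, j in itertools.product(range(5), range(7)):
                assert M[i, j] == pytest.approx(fn(Q[i], P[j]))


class TestMaxFusion:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        Q = rng.integers(0, 2, size=(3, 64)).astype(np.uint8)
        P = rng.integers(0, 2, size=(5, 64)).astype(np.uint8)
        got = max_fusion_scores(Q, P, "tanimoto")
        expected = [max(tanimoto(q, p) for q in Q) for p in P]
        assert got == pytest.approx(expected)

    def test_single_query_is_plain_similarity(self):
        rng = np.random.default_rng(3)
        Q = rng.integers(0, 2, size=(1, 32)).astype(np.uint8)
        P = rng.integers(0, 2, size=(4, 32)).astype(np.uint8)
        assert max_fusion_scores(Q, P, "rogot_goldberg") == pytest.approx(
            [rogot_goldberg(Q[0], p) for p in P]
        )

    def test_empty_pool_gives_empty_vector(self):
        assert len(max_fusion_scores(np.ones((1, 8)), np.zeros((0, 8)), "tanimoto")) == 0


class TestRetrievalMetrics:
    def test_auc_perfect_inverted_and_hand_value(self):
        assert roc_auc(RankedList(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0]))) == 1.0
        assert roc_auc(RankedList(np.array([0.0, 1.0, 2.0, 3.0]), np.array([1, 1, 0, 0]))) == 0.0
        # actives {0.8, 0.5}, inactives {0.5, 0.2}: 3 wins + 1 tie of 4 pairs
        ranked = RankedList(np.array([0.8, 0.5, 0.5, 0.2]), np.array([1, 1, 0, 0]))
        assert roc_auc(ranked) == pytest.approx(0.875)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(RankedList(np.array([1.0, 2.0]), np.array([1, 1])))

    def test_ef_hand_value_and_edges(self):
        # N=1000, P=10, all actives in top 50
        scores = np.concatenate([np.linspace(10, 9, 10), np.linspace(5, 1, 990)])
        labels = np.concatenate([np.ones(10), np.zeros(990)])
        assert enrichment_factor(RankedList(scores, labels), 0.05) == pytest.approx(20.0)
        # no actives in the top fraction
        flipped = RankedList(-scores, labels)
        assert enrichment_factor(flipped, 0.05) == 0.0
        # chi=1 is always 1
        assert enrichment_factor(RankedList(scores, labels), 1.0) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_and_ef_match_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = np.round(rng.normal(size=n), 2)  # rounded -> ties occur
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        ranked = RankedList(scores, labels)
        # AUC oracle: all-pairs count with half credit for ties
        act, inact = scores[labels == 1], scores[labels == 0]
        wins = sum((a > i) + 0.5 * (a == i) for a in act for i in inact)
        assert roc_auc(ranked) == pytest.approx(wins / (len(act) * len(inact)), abs=1e-10)
        # EF oracle: explicit top-segment count under the same tie-broken order
        chi = float(rng.uniform(0.05, 0.5))
        n_top = math.ceil(chi * n)
        perm = np.random.default_rng(7).permutation(n)
        order = perm[np.argsort(-scores[perm], kind="stable")]
        p_top = labels[order[:n_top]].sum()
        expected = (p_top / n_top) / (labels.sum() / n)
        assert enrichment_factor(ranked, chi, tie_seed=7) == pytest.approx(expected, abs=1e-10)

    def test_ef_monotone_when_active_moves_up(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=40)
        labels = np.zeros(40)
        labels[[5, 20, 35]] = 1
        base = enrichment_factor(RankedList(scores, labels))
        promoted = scores.copy()
        promoted[35] = scores.max() + 1
        assert enrichment_factor(RankedList(promoted, labels)) >= base


class TestExactWilcoxon:
    def test_hand_enumerated_examples(self):
        x = np.array([2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 1.0])  # diffs {1, 2, 3}
        assert wilcoxon_exact_paired(x, y, "greater") == pytest.approx(1 / 8)
        assert wilcoxon_exact_paired(x, y, "two_sided") == pytest.approx(1 / 4)

    def test_degenerate_all_zero_differences(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_exact_paired(np.ones(5), np.ones(5))

    def test_large_n_directed_to_approximation(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="normal-approximation"):
            wilcoxon_exact_paired(x, x + 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_full_sign_enumeration(self, seed):
        """p-values equal brute-force enumeration of all 2^n sign assignments."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        diffs = np.round(rng.normal(size=n), 1)
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            diffs = np.array([0.5])
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=len(diffs))
        ]
        p_ge = np.mean([w >= w_obs - 1e-12 for w in ws])
        p_le = np.mean([w <= w_obs + 1e-12 for w in ws])
        x = np.where(diffs > 0, np.abs(diffs), 0.0)
        y = np.where(diffs > 0, 0.0, np.abs(diffs))
        assert wilcoxon_exact_paired(x, y, "greater") == pytest.approx(p_ge, abs=1e-12)
        assert wilcoxon_exact_paired(x, y, "less") == pytest.approx(p_le, abs=1e-12)
        assert wilcoxon_exact_paired(x, y, "two_sided") == pytest.approx(
            min(1.0, 2 * min(p_ge, p_le)), abs=1e-12
        )


class TestPairedDifferenceCI:
    def test_symmetric_differences_straddle_zero(self):
        diffs = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0, -0.5, 0.5])
        low, high = paired_difference_ci(diffs)
        assert low < 0 < high

    def test_constant_differences_degenerate_at_c(self):
        low, high = paired_difference_ci(np.full(8, 0.7))
        assert low == pytest.approx(0.7) and high == pytest.approx(0.7)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_difference_ci(np.array([1.0, 2.0]))

    def test_coverage_of_a_known_shift(self):
        """About 95% of CIs from shifted-normal differences contain the shift."""
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            diffs = np.random.default_rng(s).normal(0.3, 1.0, size=30)
            low, high = paired_difference_ci(diffs, level=0.95)
            hits += low <= 0.3 <= high
        assert abs(hits / n_sim - 0.95) < 0.04


class TestBalancedForest:
    def test_each_tree_bootstrap_is_class_balanced(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 8))
        y = np.array([1] * 20 + [0] * 100)
        clf = BalancedRandomForestClassifier(n_estimators=25, random_state=1).fit(X, y)
        assert all(c0 == c1 == 20 for c0, c1 in clf.tree_sample_counts_)

    def test_deterministic_probabilities(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        a = BalancedRandomForestClassifier(n_estimators=10, random_state=3).fit(X, y).predict_proba(X)
        b = BalancedRandomForestClassifier(n_estimators=10, random_state=3).fit(X, y).predict_proba(X)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def class_bench():
    bench, manifest = generate_class_set(70, 90, 3, hop_signal=0.95, seed=5)
    return bench, manifest


class TestSimilarityHarness:
    def test_planted_signal_is_retrieved(self, class_bench):
        bench, _ = class_bench
        het = BenchSet(bench.target_id, bench.actives, bench.inactives, "HET")
        res = run_similarity_benchmark(het, MORGAN_SCHEME, SimilarityConfig(n_reps=10, seed=1))
        assert res.auc_mean > 0.6  # marker substituent is learnable
        assert len(res.repetitions) == 10

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        # labels carry no structure signal: actives and inactives drawn alike
        from qaffp.synthetic import molecule_library

        mols = list(molecule_library()[0])
        idx = rng.choice(len(mols), size=120, replace=False)
        chosen = [mols[i] for i in idx]
        het = BenchSet("null", chosen[:40], chosen[40:], "HET")
        res = run_similarity_benchmark(het, MORGAN_SCHEME, SimilarityConfig(n_reps=50, seed=2))
        assert abs(res.auc_mean - 0.5) <= 3 * max(res.auc_sem, 1e-9) + 0.05

    def test_deterministic_for_fixed_seed(self, class_bench):
        bench, _ = class_bench
        het = BenchSet(bench.target_id, bench.actives, bench.inactives, "HET")
        a = run_similarity_benchmark(het, MORGAN_SCHEME, SimilarityConfig(n_reps=3, seed=9))
        b = run_similarity_benchmark(het, MORGAN_SCHEME, SimilarityConfig(n_reps=3, seed=9))
        assert a.repetitions == b.repetitions

    def test_hom_protocol_single_repetition(self, class_bench):
        bench, _ = class_bench
        hom = BenchSet(bench.target_id, bench.actives, bench.inactives, "HOM")
        res = run_similarity_benchmark(hom, MORGAN_SCHEME, SimilarityConfig(seed=1))
        assert len(res.repetitions) == 1

    def test_too_few_actives_named_error(self, class_bench):
        bench, _ = class_bench
        tiny = BenchSet(bench.target_id, bench.actives[:5], bench.inactives, "HET")
        with pytest.raises(ValueError, match="queries"):
            run_similarity_benchmark(tiny, MORGAN_SCHEME, SimilarityConfig(seed=1))


class TestClassificationHarness:
    def test_separable_features_give_high_auc(self, class_bench):
        bench, _ = class_bench
        cfg = ClassificationConfig(n_repeats=2, seed=3)
        res = run_classification_benchmark(bench, MORGAN_SCHEME, cfg)
        assert res.auc_mean >= 0.9
        assert len(res.repetitions) == 10  # 5 folds x 2 repeats

    def test_class_size_rule_is_strict(self):
        bench, _ = generate_class_set(60, 80, 2, seed=1)
        with pytest.raises(ValueError, match="more than"):
            run_classification_benchmark(bench, MORGAN_SCHEME)

    def test_label_permutation_destroys_signal(self, class_bench):
        bench, _ = class_bench
        rng = np.random.default_rng(11)
        pool = bench.actives + bench.inactives
        perm = rng.permutation(len(pool))
        shuffled = [pool[i] for i in perm]
        null = BenchSet("null", shuffled[: len(bench.actives)], shuffled[len(bench.actives):], "CLASS")
        res = run_classification_benchmark(null, MORGAN_SCHEME, ClassificationConfig(n_repeats=2, seed=4))
        assert abs(res.auc_mean - 0.5) <= 0.1


class OracleClassifier:
    """Plug-in classifier that memorizes which feature rows are 'active'."""

    def __init__(self, active_rows):
        self.active_rows = {tuple(r) for r in active_rows}
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.array([1.0 if tuple(r) in self.active_rows else 0.0 for r in np.asarray(X)])
        return np.column_stack([1 - p, p])


class TestScaffoldHopping:
    def test_toy_counts_match_planted_ground_truth(self):
        """CSK A (6 actives), B (2), C (1): RACSK = {A}; an oracle flagging one
        B compound retrieves exactly {B}."""
        bench, manifest = generate_class_set(9, 12, 3, hop_signal=1.0, seed=2, family_sizes=[6, 2, 1])
        csk_a, csk_b, _ = (manifest["family_csk"][f] for f in ("six", "five", "naph"))
        b_first = manifest["memberships"][csk_b][0]
        X = morgan2_matrix(bench.actives)
        factory = lambda seed: OracleClassifier([X[b_first]])
        res = run_scaffold_hopping(
            bench, MORGAN_SCHEME, HoppingConfig(classifier_factory=factory, seed=0)
        )
        assert res.n_acsk_total == 3
        assert res.n_racsk == 1
        assert res.retrieved_csk_ids == frozenset({csk_b})
        assert res.n_retrieved == 1

    def test_always_inactive_classifier_retrieves_nothing(self):
        bench, _ = generate_class_set(12, 10, 2, seed=3)
        factory = lambda seed: OracleClassifier([])
        res = run_scaffold_hopping(bench, MORGAN_SCHEME, HoppingConfig(classifier_factory=factory))
        assert res.n_retrieved == 0

    def test_no_racsk_skipped_with_notice(self, caplog):
        bench, _ = generate_class_set(8, 10, 4, seed=4, family_sizes=[2, 2, 2, 2])
        with caplog.at_level("INFO"):
            res = run_scaffold_hopping(bench, MORGAN_SCHEME)
        assert res.n_racsk == 0 and res.n_retrieved == 0
        assert "no RACSK" in caplog.text

    def test_pooling_is_set_union(self):
        from qaffp.benchmarks import HoppingResult

        a = HoppingResult("t", 5, 2, frozenset({"C1CCCCC1", "C1CCCC1"}))
        b = HoppingResult("t", 5, 2, frozenset({"C1CCCC1", "C1CCCCCC1"}))
        pooled = pool_hopping_results(a, b)
        assert pooled.retrieved_csk_ids == a.retrieved_csk_ids | b.retrieved_csk_ids
        assert pooled.n_retrieved >= max(a.n_retrieved, b.n_retrieved)

    def test_hop_signal_enables_cross_scaffold_retrieval(self):
        bench, manifest = generate_class_set(40, 60, 2, hop_signal=1.0, seed=6, family_sizes=[20, 20])
        res = run_scaffold_hopping(bench, MORGAN_SCHEME, HoppingConfig(seed=1))
        # both families are RACSKs; the marker lets each model find the other family
        assert res.n_racsk == 2
        assert res.n_retrieved >= 1


class TestOverlapDiagnostic:
    def test_fraction_of_shared_ligands(self, class_bench):
        bench, _ = class_bench
        panel_ligands = {m.smiles for m in bench.actives[:10]}
        frac = ligand_overlap_fraction(bench, panel_ligands)
        assert frac == pytest.approx(10 / (len(bench.actives) + len(bench.inactives)))
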