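"""External indices, NPE, residual variance, ROC — against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    roc_auc_score,
    v_measure_score,
)

from cytodeep import (
    ari,
    contingency,
    f_score,
    fmi,
    npe,
    residual_variance,
    roc_curve_area,
    score_prediction,
    v_measure,
)

from oracles import (
    ari_oracle,
    fmi_oracle,
    roc_area_oracle,
    v_measure_oracle,
)

labels_pair = st.integers(2, 6).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 3), min_size=n, max_size=n),
        st.lists(st.integers(0, 3), min_size=n, max_size=n),
    )
)


class TestContingency:
    def test_exact_crosstab(self):
        t = contingency(["A", "A", "B"], [1, 1, 2])
        assert t.total == 3
        assert t.counts[t.true_names.index("A"), t.pred_names.index("1")] == 2
        assert t.counts.sum() == t.row_sums.sum() == t.col_sums.sum()

    def test_per_class_confusion_sums_to_n(self):
        t = contingency(["A", "B", "A", "B"], [1, 1, 2, 2])
        for i in range(2):
            for j in range(2):
                assert sum(t.class_confusion(i, j)) == 4

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="length"):
            contingency(["A"], [1, 2])
        with pytest.raises(ValueError, match="empty"):
            contingency([], [])
        with pytest.raises(ValueError, match="empty"):
            contingency(["unassigned"], ["x"], exclude=("unassigned",))


class TestFScore:
    def test_perfect_agreement_is_one(self):
        t = contingency(["A", "A", "B", "B", "B"], ["A", "A", "B", "B", "B"])
        f, per_class = f_score(t)
        assert f == 1.0 and set(per_class.values()) == {1.0}

    def test_hand_computed_example(self):
        # precision_A=2/3, recall_A=1 -> F_A=0.8; precision_B=1, recall_B=1/2
        # -> F_B=2/3; weighted: 0.5*0.8 + 0.5*2/3
        t = contingency(["A", "A", "B", "B"], ["A", "A", "A", "B"])
        f, per_class = f_score(t)
        assert per_class["A"] == pytest.approx(0.8)
        assert per_class["B"] == pytest.approx(2 / 3)
        assert f == pytest.approx(0.5 * 0.8 + 0.5 * 2 / 3)

    def test_zero_overlap_class_scores_zero(self):
        t = contingency(["A", "A", "A", "B"], [1, 1, 1, 1])
        _, per_class = f_score(t)
        assert per_class["B"] == 0.0

    def test_majority_mapping_is_relabel_invariant(self):
        truth = ["A", "A", "B", "B", "C"]
        f1, _ = f_score(contingency(truth, [0, 0, 1, 1, 2]))
        f2, _ = f_score(contingency(truth, [5, 5, 9, 9, 7]))
        assert f1 == f2 == 1.0


class TestPairCountIndices:
    def test_identical_partitions_score_one(self):
        t = contingency(["A", "A", "B", "B", "C"], [2, 2, 0, 0, 1])
        assert ari(t) == pytest.approx(1.0)
        assert fmi(t) == pytest.approx(1.0)
        assert v_measure(t)[0] == pytest.approx(1.0)

    def test_fmi_hand_example_single_cluster_prediction(self):
        # pairs: TP=2, FP=4, FN=0 -> sqrt(2/6 * 2/2)
        t = contingency(["A", "A", "B", "B"], [1, 1, 1, 1])
        assert fmi(t) == pytest.approx(np.sqrt(2 / 6), abs=1e-9)

    def test_all_singletons_fmi_zero(self):
        t = contingency(["A", "A", "B", "B"], [1, 2, 3, 4])
        assert fmi(t) == 0.0

    def test_ari_degenerate_conventions(self):
        same = contingency(["A", "A"], [1, 1])
        assert ari(same) == 1.0
        singletons_vs_block = contingency(["A", "B"], [1, 1])
        assert ari(singletons_vs_block) == 0.0

    def test_v_measure_single_cluster_vs_balanced_classes(self):
        t = contingency(["A", "A", "B", "B"], [1, 1, 1, 1])
        v, hom, comp = v_measure(t)
        assert hom == pytest.approx(0.0) and v == pytest.approx(0.0)
        assert comp == 1.0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(labels_pair)
    def test_agree_with_pair_enumeration_oracles(self, pair):
        truth, pred = pair
        t = contingency(truth, pred)
        assert ari(t) == pytest.approx(ari_oracle(truth, pred), abs=1e-12)
        assert fmi(t) == pytest.approx(fmi_oracle(truth, pred), abs=1e-12)
        assert v_measure(t)[0] == pytest.approx(v_measure_oracle(truth, pred),
                                                abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(labels_pair, st.permutations(range(4)))
    def test_relabeling_prediction_leaves_indices_unchanged(self, pair, perm):
        truth, pred = pair
        renamed = [perm[p] for p in pred]
        a = contingency(truth, pred)
        b = contingency(truth, renamed)
        assert ari(a) == pytest.approx(ari(b), abs=1e-12)
        assert fmi(a) == pytest.approx(fmi(b), abs=1e-12)
        assert v_measure(a)[0] == pytest.approx(v_measure(b)[0], abs=1e-12)

    def test_agree_with_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            truth = rng.integers(0, 4, n)
            pred = rng.integers(0, 5, n)
            t = contingency(truth, pred)
            assert ari(t) == pytest.approx(adjusted_rand_score(truth, pred), abs=1e-9)
            assert fmi(t) == pytest.approx(fowlkes_mallows_score(truth, pred), abs=1e-9)
            assert v_measure(t)[0] == pytest.approx(v_measure_score(truth, pred), abs=1e-9)

    def test_corruption_degrades_indices_in_expectation(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 4, 200)
        means = []
        for flip_rate in (0.0, 0.15, 0.4):
            vals = []
            for rep in range(8):
                pred = truth.copy()
                flips = rng.random(200) < flip_rate
                pred[flips] = rng.integers(0, 4, int(flips.sum()))
                t = contingency(truth, pred)
                vals.append((ari(t), fmi(t), f_score(t)[0]))
            means.append(np.mean(vals, axis=0))
        means = np.array(means)
        assert (np.diff(means, axis=0) <= 1e-9).all()


class TestNpe:
    def test_identity_embedding_has_zero_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        labels = np.array(["a", "b"] * 30, dtype=object)
        assert npe(X, X.copy(), labels, k=5) == 0.0

    def test_tiny_swap_detected_by_enumeration(self):
        # k=1, two cells per subtype; moving one "a" next to the "b" pair
        # changes its nearest neighbor's subtype in the embedding
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        Y = np.array([[0.0], [5.05], [5.0], [5.1]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        # original: fractions a=(1,1), b=(1,1); embedded: a=(0,0), b=(0.5 case)
        # subtype a: P=(0:0, 1:1), Q=(0:1, 1:0) -> delta=1
        # subtype b: neighbors of b cells in Y are each other? b0's nn is b1
        value = npe(X, Y, labels, k=1)
        # delta_a = 1 for both a-cells; delta_b computed by enumeration:
        # in Y, b0(5.0) nn is a1(5.05) -> frac 0; b1(5.1) nn is a1 -> frac 0
        # so P_b=(1,1)->{1:1}, Q_b={0:1}, delta_b=1 -> NPE=1
        assert value == pytest.approx(1.0)

    def test_faithful_embedding_beats_shuffled_coordinates(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(8, 1, (50, 5))])
        labels = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        faithful = X[:, :2]
        shuffled = faithful[rng.permutation(100)]
        assert npe(X, faithful, labels, k=10) < npe(X, shuffled, labels, k=10)

    def test_k_too_large_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="k"):
            npe(X, X, np.array(["a", "a", "b", "b"], dtype=object), k=4)


class TestResidualVariance:
    def test_affine_distances_give_zero(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        assert residual_variance(d, 3 * d + 1) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_gives_maximum(self):
        assert residual_variance([1, 2, 3], [5, 5, 5]) == 1.0

    def test_three_point_hand_example(self):
        d_g = np.array([1.0, 2.0, 4.0])
        d_y = np.array([1.0, 3.0, 4.0])
        r = np.corrcoef(d_g, d_y)[0, 1]
        assert residual_variance(d_g, d_y) == pytest.approx(1 - r**2)

    def test_uncorrelated_distances_approach_one(self):
        rng = np.random.default_rng(0)
        assert residual_variance(rng.random(2000), rng.random(2000)) > 0.98


class TestRocArea:
    def test_perfect_and_tied_scores(self):
        assert roc_curve_area([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_curve_area([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_toy_matches_pair_counting(self):
        scores = [0.1, 0.7, 0.7, 0.4]
        truth = [0, 1, 0, 1]
        assert roc_curve_area(scores, truth) == pytest.approx(
            roc_area_oracle(scores, truth))

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=30)
            truth = rng.integers(0, 2, 30)
            if truth.min() == truth.max():
                continue
            assert roc_curve_area(scores, truth) == pytest.approx(
                roc_auc_score(truth, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve_area([0.1, 0.2], [1, 1])


def test_score_prediction_report_is_serialisable(tmp_path):
    report = score_prediction(["A", "A", "B"], ["A", "B", "B"])
    text = report.to_json(tmp_path / "m.json")
    assert (tmp_path / "m.json").read_text() == text
    table = report.format_table()
    assert "F-score" in table and "ARI" in table
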