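"""Cell matching, agreement breakdowns, confusion matrices, Cohen's kappa."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from annoqc import (
    ConfusionMatrix,
    PairResult,
    SlideContext,
    aggregate_pairs,
    cell_agreement,
    cohens_kappa,
    confusion,
    default_radius_px,
    match_points,
    region_agreement,
)
from annoqc.agreement import AgreementBreakdown, Matching, kappa_weight_matrix

from conftest import make_record


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def brute_force_match(a, b, radius):
    """Enumerate every feasible one-to-one matching; return
    (max cardinality, min total distance at that cardinality)."""
    d = cdist(a, b)
    feasible = [
        (i, j) for i in range(len(a)) for j in range(len(b))
        if d[i, j] <= radius
    ]
    best = (0, 0.0)
    for k in range(min(len(a), len(b)), 0, -1):
        dists = []
        for combo in itertools.combinations(feasible, k):
            rows = {i for i, _ in combo}
            cols = {j for _, j in combo}
            if len(rows) == k and len(cols) == k:
                dists.append(sum(d[i, j] for i, j in combo))
        if dists:
            best = (k, min(dists))
            break
    return best


def textbook_kappa(counts, weights=None):
    """Direct-summation weighted kappa, independent of the package path."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    m = counts.shape[0]
    if weights is None:
        weights = 1.0 - np.eye(m)
    num = den = 0.0
    for i in range(m):
        for j in range(m):
            num += weights[i][j] * p[i, j]
            den += weights[i][j] * row[i] * col[j]
    return 1.0 - num / den


# ---------------------------------------------------------------------

class TestDefaultRadius:
    @pytest.mark.parametrize("mpp,expected", [(0.25, 12.0), (0.5, 6.0), (1.0, 3.0)])
    def test_physical_rule_is_resolution_invariant(self, mpp, expected):
        s = SlideContext("s", mpp, 1000, 1000)
        assert default_radius_px(s) == pytest.approx(expected)


class TestMatchPoints:
    def test_single_pair_within_radius(self):
        m = match_points([(0, 0)], [(1, 0)], 12.0)
        assert m.pairs == [(0, 0, 1.0)]
        assert m.unmatched_a == [] and m.unmatched_b == []

    def test_out_of_radius_points_stay_unmatched(self):
        m = match_points([(0, 0)], [(20, 0)], 12.0)
        assert m.pairs == []
        assert m.unmatched_a == [0] and m.unmatched_b == [0]

    def test_global_optimum_beats_greedy(self):
        """Greedy would pair (0,0)-(4,0) then leave (5,0)-(9,0): total 8 is
        the optimum, and both points match."""
        m = match_points([(0, 0), (5, 0)], [(4, 0), (9, 0)], 12.0)
        assert m.n_matched == 2
        assert m.total_distance == pytest.approx(8.0)
        assert [(i, j) for i, j, _ in m.pairs] == [(0, 0), (1, 1)]

    def test_empty_inputs(self):
        m = match_points([], [(1, 1)], 5.0)
        assert m.pairs == [] and m.unmatched_b == [0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(120):
            na, nb = rng.integers(0, 7, 2)
            a = rng.uniform(0, 20, (na, 2))
            b = rng.uniform(0, 20, (nb, 2))
            m = match_points(a, b, 8.0)
            if na == 0 or nb == 0:
                assert m.n_matched == 0
                continue
            card, dist = brute_force_match(a, b, 8.0)
            assert m.n_matched == card
            assert m.total_distance == pytest.approx(dist, abs=1e-9)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = rng.uniform(0, 15, (rng.integers(1, 8), 2))
            b = rng.uniform(0, 15, (rng.integers(1, 8), 2))
            m_ab = match_points(a, b, 6.0)
            m_ba = match_points(b, a, 6.0)
            assert sorted((j, i) for i, j, _ in m_ab.pairs) == sorted(
                (i, j) for i, j, _ in m_ba.pairs
            )
            assert m_ab.unmatched_a == m_ba.unmatched_b
            assert m_ab.unmatched_b == m_ba.unmatched_a

    def test_all_pair_distances_within_radius(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0, 30, (40, 2))
        b = rng.uniform(0, 30, (35, 2))
        m = match_points(a, b, 5.0)
        assert all(d <= 5.0 for _, _, d in m.pairs)
        used_a = [i for i, _, _ in m.pairs]
        used_b = [j for _, j, _ in m.pairs]
        assert len(set(used_a)) == len(used_a)
        assert len(set(used_b)) == len(used_b)


class TestCellAgreement:
    def matched(self, n, radius=12.0):
        return Matching([(i, i, 0.0) for i in range(n)], [], [], radius)

    def test_perfect_agreement(self):
        bd = cell_agreement(self.matched(4), list("xxyy"), list("xxyy"))
        assert (bd.agreed_pct, bd.disagreed_pct, bd.missed_pct) == (100, 0, 0)

    def test_nothing_matched(self):
        m = Matching([], [0, 1], [0], 12.0)
        bd = cell_agreement(m, list("xy"), list("x"))
        assert (bd.agreed_pct, bd.disagreed_pct, bd.missed_pct) == (0, 0, 100)

    def test_mixed_breakdown_60_20_20(self):
        """6 agree + 2 disagree + 2 missed over N=10 distinct cells."""
        m = Matching([(i, i, 0.0) for i in range(8)], [8], [8], 12.0)
        labels_a = ["x"] * 6 + ["x", "x"] + ["z"]
        labels_b = ["x"] * 6 + ["y", "y"] + ["z"]
        bd = cell_agreement(m, labels_a, labels_b)
        assert bd.agreed_pct == pytest.approx(60.0)
        assert bd.disagreed_pct == pytest.approx(20.0)
        assert bd.missed_pct == pytest.approx(20.0)
        assert bd.agreed_pct + bd.disagreed_pct + bd.missed_pct == pytest.approx(100.0)

    def test_empty_both_flagged_not_applicable(self):
        bd = cell_agreement(Matching([], [], [], 12.0), [], [])
        assert not bd.applicable


class TestConfusion:
    def test_diagonal_counts(self, breast_dictionary):
        m = Matching([(i, i, 0.0) for i in range(5)], [], [], 12.0)
        cm = confusion(m, ["tumour_np1"] * 5, ["tumour_np1"] * 5,
                       breast_dictionary)
        i = cm.labels.index("tumour_np1")
        assert cm.counts[i, i] == 5
        assert cm.total == 5

    def test_off_diagonal_counts(self, breast_dictionary):
        m = Matching([(i, i, 0.0) for i in range(3)], [], [], 12.0)
        cm = confusion(m, ["tumour_np1"] * 3, ["tumour_np2"] * 3,
                       breast_dictionary)
        i = cm.labels.index("tumour_np1")
        j = cm.labels.index("tumour_np2")
        assert cm.counts[i, j] == 3
        assert cm.counts[j, i] == 0

    def test_label_order_follows_dictionary_with_np_chain_contiguous(
        self, breast_dictionary
    ):
        m = Matching([], [], [], 12.0)
        cm = confusion(m, [], [], breast_dictionary)
        i1 = cm.labels.index("tumour_np1")
        assert cm.labels[i1:i1 + 3] == ["tumour_np1", "tumour_np2", "tumour_np3"]
        assert "unknown" not in cm.labels

    def test_unknown_pairs_excluded_by_default(self, breast_dictionary):
        m = Matching([(0, 0, 0.0), (1, 1, 0.0)], [], [], 12.0)
        cm = confusion(m, ["unknown", "TILs"], ["TILs", "TILs"],
                       breast_dictionary)
        assert cm.total == 1

    def test_label_outside_dictionary_raises(self, breast_dictionary):
        m = Matching([(0, 0, 0.0)], [], [], 12.0)
        with pytest.raises(ValueError):
            confusion(m, ["mitosis"], ["TILs"], breast_dictionary)

    def test_counts_match_multinomial_expectation(self, breast_dictionary):
        """Pairs drawn from a known joint kernel: cell-wise counts within
        3 sigma of the multinomial expectation."""
        rng = np.random.default_rng(5)
        labels = ["tumour_np1", "tumour_np2"]
        joint = np.array([[0.45, 0.15], [0.05, 0.35]])
        n = 5000
        draws = rng.choice(4, size=n, p=joint.ravel())
        la = [labels[k // 2] for k in draws]
        lb = [labels[k % 2] for k in draws]
        m = Matching([(i, i, 0.0) for i in range(n)], [], [], 12.0)
        cm = confusion(m, la, lb, breast_dictionary)
        i1 = cm.labels.index("tumour_np1")
        i2 = cm.labels.index("tumour_np2")
        sub = cm.counts[np.ix_([i1, i2], [i1, i2])]
        for (r, c), p in np.ndenumerate(joint):
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(sub[r, c] - n * p) <= 3 * sigma


class TestCohensKappa:
    def test_perfect_diagonal_is_one(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.diag([5, 5, 5]))
        assert cohens_kappa(cm) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        cm = ConfusionMatrix(["a", "b"], [[10, 5], [5, 10]])
        assert cohens_kappa(cm) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, (3, 3))
        k1 = cohens_kappa(ConfusionMatrix(list("abc"), counts))
        k7 = cohens_kappa(ConfusionMatrix(list("abc"), counts * 7))
        assert k1 == pytest.approx(k7, abs=1e-12)

    def test_empty_matrix_not_applicable(self):
        cm = ConfusionMatrix(["a", "b"], np.zeros((2, 2), dtype=int))
        assert cohens_kappa(cm) is None

    def test_degenerate_chance_agreement_not_applicable(self):
        cm = ConfusionMatrix(["a", "b"], [[7, 0], [0, 0]])
        assert cohens_kappa(cm) is None

    def test_matches_sklearn_unweighted(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(30):
            counts = rng.integers(0, 25, (4, 4))
            counts[0, 0] += 1  # avoid all-zero corners making labels vanish
            ya, yb = [], []
            for (i, j), c in np.ndenumerate(counts):
                ya += [i] * int(c)
                yb += [j] * int(c)
            ours = cohens_kappa(ConfusionMatrix(list("abcd"), counts))
            ref = cohen_kappa_score(ya, yb, labels=[0, 1, 2, 3])
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_textbook_formula_weighted(self, breast_dictionary):
        rng = np.random.default_rng(9)
        labels = [
            lab.name for lab in breast_dictionary.labels_at("cell")
            if lab.name not in ("cell_box", "unknown")
        ]
        for weighting in ("none", "linear", "quadratic"):
            w = kappa_weight_matrix(labels, weighting, breast_dictionary)
            for _ in range(50):
                counts = rng.integers(0, 20, (len(labels), len(labels)))
                counts += np.eye(len(labels), dtype=int)
                cm = ConfusionMatrix(labels, counts)
                assert cohens_kappa(cm, weighting, breast_dictionary) == (
                    pytest.approx(textbook_kappa(counts, w), abs=1e-12)
                )

    def test_linear_weight_equals_unweighted_for_two_classes(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 40, (2, 2))
        cm = ConfusionMatrix(["lo", "hi"], counts)
        assert cohens_kappa(cm, "linear") == pytest.approx(
            cohens_kappa(cm, "none"), abs=1e-12
        )

    def test_np_weights_are_ordinal_within_chain(self, breast_dictionary):
        labels = ["tumour_np1", "tumour_np2", "tumour_np3", "TILs"]
        w = kappa_weight_matrix(labels, "linear", breast_dictionary)
        assert w[0][1] == pytest.approx(0.5)  # adjacent grades: half weight
        assert w[0][2] == pytest.approx(1.0)  # extreme grades: full weight
        assert w[0][3] == pytest.approx(1.0)  # across chains: full weight
        assert w[0][0] == 0.0


class TestRegionAgreement:
    def test_identical_polygons_have_jsi_one(self, small_dictionary, slide):
        ring = [(0, 0), (400, 0), (400, 400), (0, 400)]
        a = [make_record(ann_id="a1", annotator="p1", geometry=ring)]
        b = [make_record(ann_id="b1", annotator="p2", geometry=ring)]
        rows = region_agreement(a, b, small_dictionary, slide)
        (row,) = rows
        assert row.label == "tumour"
        assert row.jsi == pytest.approx(1.0)
        assert row.union_area_mm2 == pytest.approx(
            400 * 400 * (0.25 / 1000) ** 2
        )
        assert not row.one_sided

    def test_one_sided_label_flagged_with_zero_jsi(self, small_dictionary,
                                                   slide):
        a = [make_record(ann_id="a1", feature="stroma")]
        rows = region_agreement(a, [], small_dictionary, slide)
        (row,) = rows
        assert row.label == "stroma" and row.jsi == 0.0 and row.one_sided

    def test_half_overlapping_unit_squares(self, small_dictionary, slide):
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        sh = [(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)]
        a = [make_record(ann_id="a1", geometry=sq)]
        b = [make_record(ann_id="b1", annotator="p2", geometry=sh)]
        (row,) = region_agreement(a, b, small_dictionary, slide)
        assert row.jsi == pytest.approx(1.0 / 3.0)
        assert row.union_area_mm2 == pytest.approx(1.5 * (0.25 / 1000) ** 2)


class TestAggregatePairs:
    def pair(self, missed, counts=None, slide_id="s1"):
        bd = AgreementBreakdown(
            agreed_pct=100 - missed, disagreed_pct=0.0, missed_pct=missed,
            n_matched=10, n_missed_by_a=1, n_missed_by_b=1,
        )
        cm = None
        if counts is not None:
            cm = ConfusionMatrix(["a", "b"], counts)
        return PairResult(slide_id, "p1", "p2", bd, confusion=cm,
                          kappa_weighting="none")

    def test_single_pair_summary_equals_pair(self):
        s = aggregate_pairs([self.pair(30.0)])
        assert s.n_pairs == 1 and s.mean_missed_pct == pytest.approx(30.0)

    def test_mean_missed_over_two_pairs(self):
        s = aggregate_pairs([self.pair(30.0), self.pair(38.0, slide_id="s2")])
        assert s.mean_missed_pct == pytest.approx(34.0)

    def test_pooled_kappa_equals_kappa_of_sum(self):
        c1 = [[10, 5], [5, 10]]
        c2 = [[20, 1], [2, 30]]
        s = aggregate_pairs([self.pair(10.0, c1), self.pair(10.0, c2)])
        pooled = ConfusionMatrix(["a", "b"],
                                 np.array(c1) + np.array(c2))
        assert s.pooled_kappa == pytest.approx(cohens_kappa(pooled))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_pairs([])
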