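import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contcls.evaluate import (
    EvaluationError,
    IndexResult,
    MassEval,
    compute_indices,
    pearson_r,
    rank_entries,
    rank_points,
    roc_auc,
    score_indices,
    youden_point,
)


def brute_force_auc(scores, labels):
    """All-pairs concordance count: the independent AUC oracle."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    return float(
        np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg])
    )


def brute_force_youden(scores, labels):
    """Exhaustive threshold scan with the (J, sens, threshold) tie rule."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for t in list(np.unique(scores)) + [np.inf]:
        sens, spec = np.mean(pos >= t), np.mean(neg < t)
        key = (sens + spec - 1, sens, t)
        if best is None or key > best[0]:
            best = (key, (sens * 100, spec * 100))
    return best[1]


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and lo <= auc <= hi

    def test_small_example(self):
        # 4 label-pairs, 3 concordant
        assert roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])[0] == 0.75

    def test_all_ties(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
            scores = np.round(rng.random(n), 2)  # duplicates force tie handling
            assert roc_auc(scores, labels)[0] == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_delong_ci_matches_proc_reference(self):
        """95% CI frozen from R pROC ci.auc(method='delong') on this instance."""
        labels = [1] * 12 + [0] * 18
        scores = [0.3652, 0.9027, 0.4759, 0.5982, 0.6349, 0.5018, 0.3764, 0.7798,
                  0.7222, 0.2594, 1.1195, 0.8437, 0.704, 0.4314, 0.4368, 0.2284,
                  0.4772, 0.7194, 0.4622, 0.4642, 0.5367, 0.5055, 0.5561, 0.5573,
                  0.5737, 0.291, 0.51, 0.1295, 0.5034, 0.1977]
        auc, lo, hi = roc_auc(scores, labels)
        assert auc == pytest.approx(0.6944444444, abs=1e-9)
        assert lo == pytest.approx(0.4773875710, abs=1e-9)
        assert hi == pytest.approx(0.9115013179, abs=1e-9)


class TestYouden:
    def test_perfect(self):
        assert youden_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == (100.0, 100.0)

    def test_separable_with_gap(self):
        assert youden_point([0.9, 0.6, 0.55, 0.1], [1, 1, 0, 0]) == (100.0, 100.0)

    def test_tie_prefers_sensitivity(self):
        # J = 0 everywhere; the tie rule picks the all-positive operating point
        assert youden_point([0.3, 0.7], [1, 0]) == (100.0, 0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
            scores = np.round(rng.random(n), 2)
            assert youden_point(scores, labels) == pytest.approx(
                brute_force_youden(scores, labels)
            )


class TestRankPoints:
    @pytest.mark.parametrize(
        "truth,top3,expected",
        [("a", ["a", "b", "c"], 3), ("a", ["b", "a", "c"], 2),
         ("a", ["b", "c", "a"], 1), ("a", ["b", "c", "d"], 0), ("a", [], 0)],
    )
    def test_points(self, truth, top3, expected):
        assert rank_points(truth, top3) == expected

    def test_duplicates_rejected(self):
        with pytest.raises(EvaluationError, match="duplicate"):
            rank_points("a", ["b", "b", "a"])


IDC = "Invasive ductal carcinoma of the breast"
IDC_TYPE = "invasive non-specific carcinoma"
CYST = "Breast cyst"
CYST_TYPE = "cystic lesion"


class TestComputeIndices:
    def _evals(self, taxonomy):
        """4 masses whose true type lands at rank 1, 2, absent, 1."""
        return [
            MassEval("m1", IDC, 0.9, [IDC_TYPE, "x", "y"], [IDC, "a", "b"]),
            MassEval("m2", IDC, 0.8, ["x", IDC_TYPE, "y"], ["a", IDC, "b"]),
            MassEval("m3", CYST, 0.2, ["x", "y", "z"], ["a", "b", "c"]),
            MassEval("m4", CYST, 0.1, [CYST_TYPE, "y", "z"], [CYST, "b", "c"]),
        ]

    def test_rank_derived_indices(self, taxonomy):
        ix = compute_indices(self._evals(taxonomy), taxonomy)
        assert ix.dapt == pytest.approx(50.0)
        assert ix.apti == pytest.approx(100 * (3 + 2 + 0 + 3) / 12)   # 66.7
        assert ix.mdrpt == pytest.approx(25.0)
        assert ix.dapd == pytest.approx(50.0)
        assert ix.auc == 1.0 and ix.sensitivity == 100.0 and ix.specificity == 100.0

    def test_all_top1_correct(self, taxonomy):
        evals = [
            MassEval("m1", IDC, 0.9, [IDC_TYPE], [IDC]),
            MassEval("m2", CYST, 0.1, [CYST_TYPE], [CYST]),
        ]
        ix = compute_indices(evals, taxonomy)
        assert (ix.dapt, ix.apti, ix.mdrpt) == (100.0, 100.0, 0.0)
        assert (ix.dapd, ix.adpd, ix.mdrpd) == (100.0, 100.0, 0.0)

    def test_bound_invariants_on_random_inputs(self, taxonomy):
        """DAPT <= APTI, MDRPT <= 100-DAPT (and disease analogues) always hold."""
        rng = np.random.default_rng(2)
        diseases = [IDC, CYST]
        types = [IDC_TYPE, CYST_TYPE, "x", "y"]
        for _ in range(100):
            n = int(rng.integers(2, 30))
            evals = []
            for i in range(n):
                truth = diseases[int(rng.integers(2))] if i > 1 else diseases[i]
                evals.append(
                    MassEval(
                        f"m{i}", truth, float(rng.random()),
                        list(rng.choice(types, size=3, replace=False)),
                        list(rng.choice(diseases + ["a", "b"], size=3, replace=False)),
                    )
                )
            ix = compute_indices(evals, taxonomy)
            assert ix.dapt <= ix.apti + 1e-9
            assert ix.mdrpt <= 100 - ix.dapt + 1e-9
            assert ix.dapd <= ix.adpd + 1e-9
            assert ix.mdrpd <= 100 - ix.dapd + 1e-9


def _index_result(auc, *percents):
    s, sp, dapt, apti, mdrpt, dapd, adpd, mdrpd = percents
    return IndexResult(auc, 0.0, 1.0, s, sp, dapt, apti, mdrpt, dapd, adpd, mdrpd)


percent = st.floats(0, 100, allow_nan=False)


class TestScoreIndices:
    def test_known_scorecard_total(self):
        ix = _index_result(0.84, 82.6, 70.30, 48.9, 60.60, 30.0, 50.0, 77.2, 9.4)
        assert round(score_indices(ix).total, 2) == 71.82

    def test_perfect_system_scores_100(self):
        ix = _index_result(1.0, 100, 100, 100, 100, 0, 100, 100, 0)
        assert score_indices(ix).total == pytest.approx(100.0)

    @settings(max_examples=100, deadline=None)
    @given(auc=st.floats(0, 1, allow_nan=False),
           ps=st.tuples(*[percent] * 8))
    def test_total_conserved(self, auc, ps):
        card = score_indices(_index_result(auc, *ps))
        assert card.total == pytest.approx(sum(card.component_scores.values()))
        assert 0.0 <= card.total <= 100.0 + 1e-9

    def test_monotone_in_indices(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = rng.uniform(0, 100, 8)
            base = score_indices(_index_result(0.5, *ps)).total
            # improving a higher-is-better index raises the total
            ps2 = ps.copy(); ps2[0] = min(100, ps2[0] + 5)
            assert score_indices(_index_result(0.5, *ps2)).total >= base
            # worsening a missed-rate lowers it
            ps3 = ps.copy(); ps3[4] = min(100, ps3[4] + 5)
            assert score_indices(_index_result(0.5, *ps3)).total <= base

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            score_indices(_index_result(0.5, 120, 50, 50, 50, 50, 50, 50, 50))


class TestRanking:
    def test_single_entry(self):
        assert rank_entries([("only", 50.0)]).entries[0].rank == 1

    def test_tie_ordered_by_name(self):
        table = rank_entries([("B", 50.0), ("A", 50.0)])
        assert table.rank_of("A") == 1
        assert table.rank_of("B") == 2

    def test_descending_ranks(self):
        table = rank_entries([("a", 10.0), ("b", 30.0), ("c", 20.0)])
        assert [e.name for e in table.entries] == ["b", "c", "a"]
        assert [e.rank for e in table.entries] == [1, 2, 3]


class TestPearson:
    def test_identity(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_exact_anticorrelation(self):
        assert pearson_r([1, 2, 3], [6, 4, 2]) == -1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            pearson_r([1, 1, 1], [1, 2, 3])
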