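"""Split schemes, nested CV harness and the metric panel."""

import itertools

import numpy as np
import pandas as pd
import pytest

from combosyn.evaluate import (
    SCHEMES,
    classification_metrics,
    groupwise_correlation,
    make_folds,
    metrics_table,
    nested_cv,
    paired_method_test,
    regression_metrics,
    select_threshold,
    full_report,
)
from combosyn.models import MedianPolishLearner, median_polish_fit, median_polish_predict


def pair_key(df):
    return df.apply(lambda r: tuple(sorted((r.drug_a, r.drug_b))), axis=1)


@pytest.fixture(scope="module")
def quartets():
    """25-pair x 6-cell design with seeded scores."""
    rng = np.random.default_rng(99)
    drugs = [f"d{i}" for i in range(8)]
    cells = [f"c{j}" for j in range(6)]
    rows = []
    for a, b in itertools.combinations(drugs, 2):
        for c in cells:
            rows.append((a, b, c, rng.normal(4, 20)))
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "synergy"])


class TestMakeFolds:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_test_sets_partition_samples(self, quartets, scheme):
        folds = make_folds(quartets, scheme, k=4, seed=1)
        counts = np.bincount(folds.test_fold, minlength=4)
        assert counts.sum() == len(quartets)
        assert (counts > 0).all()

    def test_random_scheme_balances_folds(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "drug_a": ["a"] * 100,
                "drug_b": ["b"] * 100,
                "cell_line": [f"c{i}" for i in range(100)],
                "synergy": rng.normal(size=100),
            }
        )
        folds = make_folds(df, "random", k=5, seed=3)
        assert sorted(np.bincount(folds.test_fold)) == [20, 20, 20, 20, 20]

    def test_leave_combination_pairs_never_straddle_folds(self, quartets):
        folds = make_folds(quartets, "leave_combination", k=4, seed=2)
        df = quartets.assign(fold=folds.test_fold)
        for _, grp in df.groupby(pair_key(df)):
            assert grp["fold"].nunique() == 1

    def test_leave_drug_training_never_touches_heldout_drugs(self, quartets):
        folds = make_folds(quartets, "leave_drug", k=4, seed=2)
        for f in range(4):
            held_out = {d for d, g in folds.entity_group.items() if g == f}
            roles = folds.roles(f).to_numpy()
            pool = quartets[(roles == "train") | (roles == "validation")]
            assert not (held_out & (set(pool.drug_a) | set(pool.drug_b)))

    def test_leave_cell_line_assigns_each_cell_to_one_fold(self, quartets):
        folds = make_folds(quartets, "leave_cell_line", k=3, seed=5)
        df = quartets.assign(fold=folds.test_fold)
        for _, grp in df.groupby("cell_line"):
            assert grp["fold"].nunique() == 1

    def test_cross_fold_quartets_flagged_and_kept_out_of_both_trainings(self, quartets):
        folds = make_folds(quartets, "leave_drug", k=4, seed=7)
        assert folds.entity_group is not None
        cross_idx = np.where(folds.cross_fold)[0]
        assert cross_idx.size > 0  # the fixture design does produce them
        for i in cross_idx:
            row = folds.quartets.iloc[i]
            fa = folds.entity_group[row.drug_a]
            fb = folds.entity_group[row.drug_b]
            assert fa != fb
            # tested in the fold of the lexicographically smaller drug
            smaller_fold = fa if row.drug_a <= row.drug_b else fb
            assert folds.test_fold[i] == smaller_fold
            # never trained on in either fold that holds out one of its drugs
            for f in (fa, fb):
                assert folds.roles(f).iloc[i] in ("test", "excluded")

    def test_validation_carved_from_training_pool(self, quartets):
        for scheme in SCHEMES:
            folds = make_folds(quartets, scheme, k=3, seed=4)
            for f in range(3):
                roles = folds.roles(f)
                assert (roles == "validation").sum() > 0
                # validation and test are disjoint by construction
                assert not ((roles == "validation") & (folds.test_fold == f)).any()

    def test_identical_seed_identical_assignment(self, quartets):
        f1 = make_folds(quartets, "leave_combination", k=4, seed=9)
        f2 = make_folds(quartets, "leave_combination", k=4, seed=9)
        np.testing.assert_array_equal(f1.test_fold, f2.test_fold)
        for f in range(4):
            np.testing.assert_array_equal(f1.validation[f], f2.validation[f])

    def test_insufficient_entities_error_names_scheme(self, quartets):
        small = quartets[quartets.cell_line.isin(["c0", "c1"])]
        with pytest.raises(ValueError, match="leave_cell_line"):
            make_folds(small, "leave_cell_line", k=5, seed=0)


class TestNestedCV:
    def test_size_one_grid_equals_plain_kfold_oracle(self, quartets):
        """Median polish through the harness equals a hand-rolled loop."""
        folds = make_folds(quartets, "leave_combination", k=4, seed=3)
        result, chosen = nested_cv(
            quartets, folds, lambda: MedianPolishLearner(), [{}]
        )
        assert chosen == [{}] * 4
        for f in range(4):
            roles = folds.roles(f).to_numpy()
            train = folds.quartets[(roles == "train") | (roles == "validation")]
            test = folds.quartets[roles == "test"]
            tables = median_polish_fit(train)
            expected = median_polish_predict(tables, test)
            got = result.loc[roles == "test", "prediction"].to_numpy()
            np.testing.assert_allclose(got, expected)

    def test_every_test_sample_predicted_exactly_once(self, quartets):
        folds = make_folds(quartets, "random", k=5, seed=1)
        result, _ = nested_cv(quartets, folds, lambda: MedianPolishLearner(), [{}])
        assert result["prediction"].notna().all()

    def test_selection_driven_by_validation_not_training_error(self, quartets):
        """A memorizing learner with poor validation MSE is never chosen."""

        class Memorizer:
            def __init__(self, generalize):
                self.generalize = generalize

            def fit(self, train, validation=None):
                self.table = {
                    (r.drug_a, r.drug_b, r.cell_line): r.synergy
                    for r in train.itertuples()
                }
                self.mean = train["synergy"].mean()
                return self

            def predict(self, q):
                if self.generalize:
                    return np.full(len(q), self.mean)
                return np.array(
                    [
                        self.table.get((r.drug_a, r.drug_b, r.cell_line), 1e6)
                        for r in q.itertuples()
                    ]
                )

        folds = make_folds(quartets, "leave_combination", k=3, seed=6)
        _, chosen = nested_cv(
            quartets,
            folds,
            lambda generalize: Memorizer(generalize),
            [{"generalize": False}, {"generalize": True}],
        )
        assert all(c == {"generalize": True} for c in chosen)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m["mse"] == 0.0 and m["pearson_r"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = regression_metrics([0.0, 2.0], [1.0, 1.0])
        assert m["mse"] == 1.0 and m["rmse"] == 1.0

    def test_formula_oracle(self, rng):
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        m = regression_metrics(y, yhat)
        assert m["mse"] == pytest.approx(np.mean((y - yhat) ** 2), abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(m["mse"]), abs=1e-12)
        num = np.sum((y - y.mean()) * (yhat - yhat.mean()))
        den = np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((yhat - yhat.mean()) ** 2))
        assert m["pearson_r"] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_is_undefined_not_zero(self):
        m = regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["pearson_r"])


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        y = np.array([0.0, 10.0, 40.0, 50.0])
        yhat = np.array([1.0, 2.0, 3.0, 4.0])
        assert classification_metrics(y, yhat)["roc_auc"] == 1.0

    def test_hand_computed_confusion_panel(self):
        """TP=5, FP=5, FN=5, TN=85 at threshold 30."""
        y = np.concatenate([np.full(10, 40.0), np.full(90, 0.0)])
        yhat = np.concatenate(
            [np.full(5, 50.0), np.full(5, 10.0), np.full(5, 50.0), np.full(85, 10.0)]
        )
        m = classification_metrics(y, yhat, predicted_threshold=30.0)
        assert m["prec"] == pytest.approx(0.5, abs=1e-12)
        assert m["tpr"] == pytest.approx(0.5, abs=1e-12)
        assert m["tnr"] == pytest.approx(85 / 90, abs=1e-12)
        assert m["bacc"] == pytest.approx((0.5 + 85 / 90) / 2, abs=1e-12)
        assert m["acc"] == pytest.approx(0.9, abs=1e-12)
        # Cohen's kappa from the same table
        po, pe = 0.9, (10 * 10 + 90 * 90) / 100**2
        assert m["kappa"] == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        assert m["kappa"] == pytest.approx(0.4444444444444, abs=1e-10)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(2024)
        y = rng.choice([0.0, 40.0], size=2000)
        yhat = rng.normal(size=2000)
        m = classification_metrics(y, yhat)
        assert m["roc_auc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_truth(self):
        m = classification_metrics([0.0, 1.0], [5.0, 50.0])
        assert np.isnan(m["roc_auc"]) and np.isnan(m["pr_auc"])
        assert m["tnr"] == 0.5  # thresholded metrics still computed

    def test_report_invariants(self, rng):
        y = rng.normal(4, 22, size=200)
        yhat = y + rng.normal(0, 10, size=200)
        rep = full_report(y, yhat)
        assert rep.rmse == pytest.approx(np.sqrt(rep.mse))
        assert rep.bacc == pytest.approx((rep.tpr + rep.tnr) / 2)


class TestSelectThreshold:
    def test_separated_scores_cut_in_gap(self):
        y = np.array([0.0, 0.0, 40.0, 50.0])
        yhat = np.array([-5.0, -4.0, 20.0, 30.0])
        t = select_threshold(y, yhat)
        assert -4.0 < t < 20.0

    def test_constant_predictions_return_lowest_candidate(self):
        y = np.array([0.0, 40.0])
        yhat = np.array([3.0, 3.0])
        assert select_threshold(y, yhat) == pytest.approx(2.0)

    def test_exhaustive_search_oracle(self, rng):
        y = rng.normal(10, 25, size=20)
        yhat = y + rng.normal(0, 15, size=20)
        if not ((y > 30).any() and (y <= 30).any()):
            pytest.skip("fixture lost a class")
        t = select_threshold(y, yhat)
        pos = y > 30
        uniq = np.sort(np.unique(yhat))
        candidates = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2])

        def bacc(cut):
            pred = yhat > cut
            return 0.5 * (
                np.sum(pred & pos) / pos.sum() + np.sum(~pred & ~pos) / (~pos).sum()
            )

        best = max(candidates, key=bacc)
        assert bacc(t) == pytest.approx(bacc(best))

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.0, 1.0], [1.0, 2.0])


class TestPairedMethodTest:
    def test_identical_errors_undefined(self):
        stat, p = paired_method_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(stat) and np.isnan(p)

    def test_uniformly_larger_errors_significant(self):
        e1 = np.linspace(1, 5, 30)
        stat, p = paired_method_test(e1, e1 + 1.0)
        assert p < 0.001
        assert stat == 0.0  # all differences share one sign

    def test_rank_enumeration_oracle(self):
        e1 = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        e2 = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        stat, _ = paired_method_test(e1, e2)
        d = e1 - e2
        # midranks of |d|, computed by direct enumeration
        abs_d = np.abs(d)
        ranks = np.array(
            [
                np.sum(abs_d < v) + (np.sum(abs_d == v) + 1) / 2.0
                for v in abs_d
            ]
        )
        w_pos = ranks[d > 0].sum()
        w_neg = ranks[d < 0].sum()
        assert stat == pytest.approx(min(w_pos, w_neg))


class TestGroupwiseCorrelation:
    def test_perfect_predictions(self, quartets):
        out = groupwise_correlation(quartets, quartets["synergy"], group_by="drug")
        ok = out[out["flag"] == "ok"]
        assert np.allclose(ok["r"], 1.0)

    def test_constant_group_flagged(self):
        q = pd.DataFrame(
            {
                "drug_a": ["a"] * 3 + ["b"] * 3,
                "drug_b": ["x"] * 6,
                "cell_line": ["c1", "c2", "c3"] * 2,
                "synergy": [5.0, 5.0, 5.0, 1.0, 2.0, 3.0],
            }
        )
        out = groupwise_correlation(q, np.arange(6.0), group_by="drug")
        assert out.loc["a", "flag"] == "zero_variance"
        assert np.isnan(out.loc["a", "r"])
        assert out.loc["b", "flag"] == "ok"

    def test_group_by_oracle(self, quartets, rng):
        pred = quartets["synergy"].to_numpy() + rng.normal(0, 5, len(quartets))
        out = groupwise_correlation(quartets, pred, group_by="drug")
        drug = "d3"
        mask = (quartets.drug_a == drug) | (quartets.drug_b == drug)
        expected = np.corrcoef(quartets.loc[mask, "synergy"], pred[mask.to_numpy()])[0, 1]
        assert out.loc[drug, "r"] == pytest.approx(expected, abs=1e-12)


class TestMetricsTable:
    def test_summary_rows_and_internal_consistency(self, rng):
        reports = []
        for _ in range(3):
            y = rng.normal(4, 22, size=100)
            reports.append(full_report(y, y + rng.normal(0, 12, size=100)))
        table = metrics_table(reports)
        assert list(table.index[-2:]) == ["mean", "sd"]
        fold_rows = table.iloc[:3]
        np.testing.assert_allclose(fold_rows["rmse"], np.sqrt(fold_rows["mse"]))
        assert table.loc["mean", "mse"] == pytest.approx(fold_rows["mse"].mean())
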