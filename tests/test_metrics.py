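"""Tile/ROI/patient voting, confusion-matrix metrics, AUC, kappa, CIs."""

import numpy as np
import pandas as pd
import pytest

from histotile import (ConfusionMatrix, accuracy, aggregate_predictions,
                       classify_tile, confusion, exact_binomial_ci, f1,
                       fleiss_kappa, load_predictions, patient_vote, precision,
                       recall, roc_auc, roi_vote, specificity)


class TestClassifyTile:
    def test_boundary_is_immature(self):
        assert classify_tile(0.50) == "immature"
        assert classify_tile(0.49) == "mature"

    def test_extremes(self):
        assert classify_tile(1.0) == "immature"
        assert classify_tile(0.0) == "mature"

    def test_custom_cutoff(self):
        assert classify_tile(0.3, cutoff=0.3) == "immature"
        assert classify_tile(0.29, cutoff=0.3) == "mature"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_tile(1.2)
        with pytest.raises(ValueError):
            classify_tile(0.5, cutoff=-0.1)


class TestVoting:
    def test_roi_majority(self):
        assert roi_vote(["immature", "immature", "mature"]) == "immature"
        assert roi_vote(["mature"]) == "mature"

    def test_roi_tie_defaults_to_mature(self):
        assert roi_vote(["mature", "immature"]) == "mature"
        assert roi_vote(["mature", "immature"], tie="immature") == "immature"

    def test_patient_tie_is_mature(self):
        assert patient_vote(["immature", "immature", "mature", "mature"]) \
            == "mature"
        assert patient_vote(["immature", "immature", "immature", "mature"]) \
            == "immature"
        assert patient_vote(["immature"]) == "immature"

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            roi_vote([])
        with pytest.raises(ValueError):
            patient_vote([])

    def test_voting_monotone_toward_immature(self, rng):
        """Flipping one tile mature→immature never moves an ROI vote back
        toward mature."""
        order = {"mature": 0, "immature": 1}
        for _ in range(50):
            labels = list(rng.choice(["mature", "immature"],
                                     size=rng.integers(1, 9)))
            before = roi_vote(labels)
            flips = [i for i, x in enumerate(labels) if x == "mature"]
            if not flips:
                continue
            labels[flips[0]] = "immature"
            assert order[roi_vote(labels)] >= order[before]


class TestConfusion:
    def test_perfect_predictions(self):
        t = ["mature"] * 5 + ["immature"] * 5
        cm = confusion(t, t)
        assert (cm.tn, cm.fp, cm.tp, cm.fn) == (5, 0, 5, 0)

    def test_all_predicted_immature(self):
        t = ["mature"] * 5 + ["immature"] * 5
        cm = confusion(t, ["immature"] * 10)
        assert (cm.tn, cm.fp, cm.tp, cm.fn) == (0, 5, 5, 0)

    def test_random_vectors_match_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix as sk_cm
        t = list(rng.choice(["mature", "immature"], size=200))
        p = list(rng.choice(["mature", "immature"], size=200))
        cm = confusion(t, p)
        sk = sk_cm(t, p, labels=["mature", "immature"])
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == \
            (sk[0, 0], sk[0, 1], sk[1, 0], sk[1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["mature"], ["mature", "immature"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tn=-1, fp=0, tp=0, fn=0)


class TestScalarMetrics:
    def test_metric_identities(self, rng):
        for _ in range(20):
            tn, fp, tp, fn = rng.integers(1, 100, size=4)
            cm = ConfusionMatrix(int(tn), int(fp), int(tp), int(fn))
            p, r = precision(cm), recall(cm)
            assert f1(cm) == pytest.approx(2 * p * r / (p + r))
            assert accuracy(cm) == pytest.approx((tp + tn) / (tn + fp + tp + fn))
            for val in (p, r, f1(cm), accuracy(cm), specificity(cm)):
                assert 0.0 <= val <= 1.0

    def test_undefined_marker_not_zero(self):
        cm = ConfusionMatrix(tn=5, fp=0, tp=0, fn=0)
        assert precision(cm) is None
        assert recall(cm) is None
        assert f1(cm) is None
        assert specificity(cm) == 1.0
        assert specificity(ConfusionMatrix(0, 0, 5, 5)) is None

    def test_specificity_extremes(self):
        assert specificity(ConfusionMatrix(tn=13, fp=2, tp=11, fn=2)) \
            == pytest.approx(13 / 15)
        assert specificity(ConfusionMatrix(tn=7, fp=0, tp=1, fn=1)) == 1.0
        assert specificity(ConfusionMatrix(tn=0, fp=7, tp=1, fn=1)) == 0.0


class TestExactBinomialCI:
    def test_boundary_bounds(self):
        assert exact_binomial_ci(15, 15)[1] == 1.0
        assert exact_binomial_ci(0, 15)[0] == 0.0

    def test_matches_beta_quantile_oracle(self):
        from scipy import stats
        low, high = exact_binomial_ci(12, 15, 0.95)
        assert low == pytest.approx(stats.beta.ppf(0.025, 12, 4))
        assert high == pytest.approx(stats.beta.ppf(0.975, 13, 3))

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for s, n in [(12, 15), (1, 30), (29, 30)]:
            low, high = exact_binomial_ci(s, n)
            sm_low, sm_high = proportion_confint(s, n, 0.05, method="beta")
            assert low == pytest.approx(sm_low)
            assert high == pytest.approx(sm_high)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(-1, 4)


def pairwise_auc(labels, probs):
    """O(n^2) oracle: share of (immature, mature) pairs ranked correctly,
    ties counting one half."""
    pos = [p for l, p in zip(labels, probs) if l == "immature"]
    neg = [p for l, p in zip(labels, probs) if l == "mature"]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = ["mature"] * 4 + ["immature"] * 4
        probs = [0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9]
        assert roc_auc(labels, probs) == 1.0

    def test_all_equal_probabilities(self):
        labels = ["mature", "immature"] * 3
        assert roc_auc(labels, [0.5] * 6) == 0.5

    def test_toy_set_matches_pairwise_oracle(self):
        labels = ["mature", "immature", "mature", "immature", "immature",
                  "mature"]
        probs = [0.2, 0.8, 0.5, 0.5, 0.3, 0.7]
        assert roc_auc(labels, probs) == pytest.approx(
            pairwise_auc(labels, probs), abs=1e-12)

    def test_random_sets_match_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(20):
            n = int(rng.integers(4, 30))
            labels = ["immature" if x else "mature"
                      for x in rng.integers(0, 2, size=n)]
            if len(set(labels)) < 2:
                continue
            probs = np.round(rng.random(n), 1)  # coarse grid forces ties
            ours = roc_auc(labels, probs)
            assert ours == pytest.approx(pairwise_auc(labels, probs), abs=1e-12)
            y = [1 if l == "immature" else 0 for l in labels]
            assert ours == pytest.approx(roc_auc_score(y, probs), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = ["immature" if x else "mature"
                  for x in rng.integers(0, 2, size=20)]
        labels[0], labels[1] = "immature", "mature"
        probs = rng.random(20)
        assert roc_auc(labels, probs) == pytest.approx(
            roc_auc(labels, probs ** 3), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(["mature", "mature"], [0.1, 0.2])


class TestFleissKappa:
    def test_full_agreement_two_categories(self):
        ratings = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_independent_uniform_ratings_near_zero(self):
        rng = np.random.default_rng(42)
        ratings = rng.integers(0, 2, size=(2000, 4))
        assert abs(fleiss_kappa(ratings)) < 0.05

    def test_hand_worked_toy_table(self):
        # 4 items x 3 raters; category counts per item:
        # [3,0], [2,1], [1,2], [0,3]
        ratings = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]])
        # P_i = (sum n_ij^2 - n) / (n(n-1)) -> 1, 1/3, 1/3, 1
        # P_bar = 2/3; p_j = (0.5, 0.5); P_e = 0.5; kappa = (2/3-1/2)/(1/2)
        assert fleiss_kappa(ratings) == pytest.approx(1 / 3)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import (aggregate_raters,
                                                   fleiss_kappa as sm_kappa)
        ratings = rng.integers(0, 3, size=(30, 5))
        table, _ = aggregate_raters(ratings)
        assert fleiss_kappa(ratings) == pytest.approx(sm_kappa(table))

    def test_single_category_undefined(self):
        ratings = np.zeros((4, 3), dtype=int)
        assert fleiss_kappa(ratings) is None

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            fleiss_kappa(np.zeros(5))


def prediction_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "roi_id", "tile_id",
                                       "true_label", "prob_immature"])


class TestAggregatePredictions:
    def test_patient_tie_resolves_mature(self):
        rows = []
        for roi, (label, prob) in enumerate(
                [("immature", 0.9), ("mature", 0.1)]):
            for t in range(3):
                rows.append(("p1", f"roi{roi}", f"t{t}", label, prob))
        res = aggregate_predictions(prediction_frame(rows))
        assert res.patients.loc[0, "pred_label"] == "mature"
        assert res.patients.loc[0, "true_label"] == "mature"

    def test_unanimous_high_probability_perfect_at_all_levels(self):
        rows = [("p1", "r1", f"t{i}", "immature", 0.9) for i in range(4)]
        rows += [("p2", "r1", f"t{i}", "mature", 0.1) for i in range(4)]
        res = aggregate_predictions(prediction_frame(rows))
        for cm in (res.tile_cm, res.roi_cm, res.patient_cm):
            assert cm.fp == 0 and cm.fn == 0
        assert accuracy(res.patient_cm) == 1.0

    def test_heterogeneous_roi_truth_is_voted_not_rejected(self):
        rows = [("p1", "r1", "t1", "immature", 0.9),
                ("p1", "r1", "t2", "immature", 0.9),
                ("p1", "r1", "t3", "mature", 0.9)]
        res = aggregate_predictions(prediction_frame(rows))
        assert res.rois.loc[0, "true_label"] == "immature"

    def test_five_patient_table_matches_enumeration_oracle(self, rng):
        rows = []
        for p in range(5):
            for r in range(int(rng.integers(1, 4))):
                truth = "immature" if rng.random() < 0.5 else "mature"
                for t in range(int(rng.integers(1, 5))):
                    rows.append((f"p{p}", f"r{r}", f"t{t}", truth,
                                 float(np.round(rng.random(), 2))))
        table = prediction_frame(rows)
        res = aggregate_predictions(table)

        # independent enumeration oracle over plain dicts
        def vote(labels):
            ni = labels.count("immature")
            nm = len(labels) - ni
            return "immature" if ni > nm else "mature"

        tiles = {}
        for pid, rid, tid, truth, prob in rows:
            tiles.setdefault((pid, rid), []).append(
                (truth, "immature" if prob >= 0.5 else "mature"))
        roi_truth, roi_pred = {}, {}
        for key, pairs in tiles.items():
            roi_truth[key] = vote([a for a, _ in pairs])
            roi_pred[key] = vote([b for _, b in pairs])
        pat = {}
        for (pid, rid) in tiles:
            pat.setdefault(pid, []).append((roi_truth[(pid, rid)],
                                            roi_pred[(pid, rid)]))
        exp_pat = {p: (vote([a for a, _ in v]), vote([b for _, b in v]))
                   for p, v in pat.items()}
        got = {row.patient_id: (row.true_label, row.pred_label)
               for row in res.patients.itertuples()}
        assert got == exp_pat

    def test_duplicate_tile_rows_rejected(self):
        rows = [("p1", "r1", "t1", "mature", 0.2),
                ("p1", "r1", "t1", "mature", 0.3)]
        with pytest.raises(ValueError):
            aggregate_predictions(prediction_frame(rows))

    def test_csv_round_trip(self, tmp_path):
        rows = [("p1", "r1", "t1", "mature", 0.2),
                ("p1", "r1", "t2", "immature", 0.8)]
        f = tmp_path / "preds.csv"
        prediction_frame(rows).to_csv(f, index=False)
        table = load_predictions(f)
        res = aggregate_predictions(table)
        assert res.tile_cm.tp == 1 and res.tile_cm.tn == 1
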