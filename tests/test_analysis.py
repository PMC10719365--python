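"""Balanced sampling, correlation pruning, LOPO-CV classification,
permutation baselines, ablations and the biomarker screens."""

import numpy as np
import pandas as pd
import pytest

from chromascope.analysis import (
    RFConfig,
    ablation_cells,
    ablation_patients,
    balance_sample,
    balanced_accuracy,
    compare_to_control,
    gini_ranking,
    lopo_cv_rfc,
    patient_majority_vote,
    permutation_baseline,
    prune_correlated,
    qc_embedding,
    significance_stars,
    welch_screen_bh,
)
from chromascope.synthetic import simulate_feature_cohort

FAST_RF = RFConfig(n_estimators=60)

TUMOR_EFFECTS = {"tumor": {"volume": 1.4, "hc_fraction": 1.25, "foci_rate": 1.8}}


@pytest.fixture(scope="module")
def planted_cohort():
    """Two-condition cohort with planted volume/HC/foci effects."""
    return simulate_feature_cohort(
        n_patients_per_condition=4, cells_per_patient=60,
        condition_effects=TUMOR_EFFECTS, n_noise_features=10, seed=11,
    )


@pytest.fixture(scope="module")
def null_cohort():
    """Zero-effect cohort: no condition signal beyond patient noise."""
    return simulate_feature_cohort(
        n_patients_per_condition=3, cells_per_patient=50, n_noise_features=10, seed=12
    )


def cells_table(n_patients, cells_per_patient, conditions=("a",), timepoints=("T0",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, cond in enumerate(conditions):
        for p in range(n_patients):
            pid = f"{cond}-P{p}"
            for tp in timepoints:
                for i in range(cells_per_patient):
                    rows.append({"patient_id": pid, "condition": cond, "timepoint": tp,
                                 "sample_id": f"{pid}-{tp}", "f": rng.normal()})
    return pd.DataFrame(rows)


class TestBalanceSample:
    def test_per_patient_tumor_total(self):
        table = cells_table(10, 300, conditions=("tumor",))
        out = balance_sample(table, 185, by="patient_id", seed=0)
        assert len(out) == 1850
        assert (out.groupby("patient_id").size() == 185).all()

    def test_per_group_total(self):
        table = cells_table(4, 250, conditions=("meningioma", "glioma", "hn"), timepoints=("T0", "T1", "T2"))
        out = balance_sample(table, 772, by="condition", within=("timepoint",), seed=0)
        assert len(out) == 2316
        assert (out.groupby("condition").size() == 772).all()

    def test_deterministic_under_seed(self):
        table = cells_table(5, 100)
        a = balance_sample(table, 40, seed=7)
        b = balance_sample(table, 40, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = balance_sample(table, 40, seed=8)
        assert not a["f"].equals(c["f"])

    def test_insufficient_level_excluded(self):
        table = pd.concat([cells_table(1, 100, conditions=("rich",)),
                           cells_table(1, 10, conditions=("poor",))])
        out = balance_sample(table, 50, by="condition", seed=0)
        assert set(out["condition"]) == {"rich"}

    def test_no_level_meets_floor_raises(self):
        with pytest.raises(ValueError, match="floor"):
            balance_sample(cells_table(2, 10), 50, seed=0)


class TestPruneCorrelated:
    def _table(self, rng, n=200):
        f1 = rng.normal(size=n)
        return pd.DataFrame({"patient_id": "p", "condition": "c",
                             "f1": f1, "f2": 2 * f1, "f3": rng.normal(size=n)})

    def test_duplicate_feature_removed_keeping_earlier(self, rng):
        out, removed = prune_correlated(self._table(rng))
        assert removed == ["f2"]
        assert list(out.columns[-2:]) == ["f1", "f3"]

    def test_exact_threshold_pair_kept(self):
        u = np.tile([1.0, -1.0], 8)
        v = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        table = pd.DataFrame({"patient_id": "p", "a": u, "b": 4 * u + 3 * v})
        r = abs(table[["a", "b"]].corr().iloc[0, 1])
        assert r <= 0.8  # correlation is 4/5 exactly (to fp rounding)
        _, removed = prune_correlated(table, features=["a", "b"])
        assert removed == []

    def test_independent_features_survive(self, rng):
        table = pd.DataFrame({f"f{i}": rng.normal(size=1000) for i in range(8)})
        table["patient_id"] = "p"
        out, removed = prune_correlated(table)
        assert removed == []
        corr = out[[f"f{i}" for i in range(8)]].corr().abs().to_numpy()
        assert (corr[~np.eye(8, dtype=bool)] <= 0.8).all()

    def test_constant_column_removed_with_warning(self, rng):
        table = self._table(rng)
        table["konst"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            _, removed = prune_correlated(table)
        assert "konst" in removed


class TestBalancedAccuracy:
    def test_hand_computed_confusion(self):
        # confusion [[8,2],[4,6]] -> (0.8 + 0.6)/2 = 0.7
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 8 + [1] * 2 + [0] * 4 + [1] * 6
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.7)

    def test_perfect_and_constant(self):
        assert balanced_accuracy([0, 1, 1], [0, 1, 1]) == 1.0
        assert balanced_accuracy([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])


class TestLopoCV:
    def test_fold_structure(self, null_cohort):
        cv = lopo_cv_rfc(null_cohort, rf=RFConfig(n_estimators=10), seed=0)
        assert len(cv.fold_patients) == null_cohort["patient_id"].nunique()
        # each fold's test patient never contributes training rows: every
        # prediction row for patient p comes from a model that saw no p-cells;
        # structurally, predictions cover every cell exactly once
        assert len(cv.predictions) == len(null_cohort)
        counts = cv.predictions.groupby("patient_id").size()
        expected = null_cohort.groupby("patient_id").size()
        assert (counts == expected).all()

    def test_planted_effect_gives_high_accuracy(self, planted_cohort):
        cv = lopo_cv_rfc(planted_cohort, rf=FAST_RF, seed=0)
        assert cv.mean_score > 0.9

    def test_confusion_rows_sum_to_one(self, planted_cohort):
        cv = lopo_cv_rfc(planted_cohort, rf=FAST_RF, seed=0)
        np.testing.assert_allclose(cv.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_label_leakage_guard(self, null_cohort):
        bad = null_cohort.copy()
        bad.loc[bad.index[:10], "condition"] = "other"
        with pytest.raises(ValueError, match="leakage"):
            lopo_cv_rfc(bad, rf=FAST_RF, seed=0)


class TestMajorityVote:
    def _cv(self, preds):
        return type("CV", (), {"predictions": preds})()

    def test_majority_and_tie(self):
        preds = pd.DataFrame({
            "patient_id": ["p1"] * 100 + ["p2"] * 4,
            "y_true": ["tumor"] * 100 + ["control"] * 4,
            "y_pred": ["tumor"] * 60 + ["control"] * 40 + ["tumor", "tumor", "control", "control"],
        })
        out = patient_majority_vote(self._cv(preds))
        p1 = out[out["patient_id"] == "p1"].iloc[0]
        assert p1["correct"] and not p1["ambiguous"]
        p2 = out[out["patient_id"] == "p2"].iloc[0]
        assert p2["ambiguous"] and p2["call"] == "control" and p2["correct"]

    def test_all_correct_gives_one(self, planted_cohort):
        cv = lopo_cv_rfc(planted_cohort, rf=FAST_RF, seed=0)
        vote = patient_majority_vote(cv)
        expected = (
            cv.predictions.groupby("patient_id")
            .apply(lambda s: s["y_pred"].mode().iloc[0] == s["y_true"].iloc[0], include_groups=False)
            .mean()
        )
        assert vote["correct"].mean() == pytest.approx(expected)


class TestPermutationBaseline:
    def test_returns_n_perm_null_values(self, null_cohort):
        base = permutation_baseline(null_cohort, n_perm=3, rf=RFConfig(n_estimators=10), seed=0)
        assert base.null_means.shape == (3,)
        assert base.null_fold_scores.shape == (3, null_cohort["patient_id"].nunique())

    def test_two_class_null_near_half(self, null_cohort):
        base = permutation_baseline(null_cohort, n_perm=5, rf=RFConfig(n_estimators=30), seed=1)
        assert base.null_mean == pytest.approx(0.5, abs=0.05)

    def test_three_class_null_near_third(self):
        table = simulate_feature_cohort(
            n_patients_per_condition=3, cells_per_patient=40,
            conditions=("a", "b", "c"), n_noise_features=6, seed=5,
        )
        base = permutation_baseline(table, n_perm=5, rf=RFConfig(n_estimators=30), seed=2)
        assert base.null_mean == pytest.approx(1 / 3, abs=0.06)

    def test_planted_effect_beats_null(self, planted_cohort):
        base = permutation_baseline(planted_cohort, n_perm=5, rf=FAST_RF, seed=3)
        assert np.mean(base.real_fold_scores) > base.null_mean
        assert base.p_value < 0.05


class TestAblation:
    def test_full_k_matches_standard_lopo(self, planted_cohort):
        # k = all patients per class: every fold trains on the full
        # training set, so the ablation reduces to plain LOPO
        cv = lopo_cv_rfc(planted_cohort, rf=FAST_RF, seed=42)
        ab = ablation_patients(planted_cohort, k_grid=[4], reps=1, rf=FAST_RF, seed=42)
        assert ab.scores[0, 0] == pytest.approx(cv.mean_score)

    def test_full_p_matches_standard_lopo(self, planted_cohort):
        cv = lopo_cv_rfc(planted_cohort, rf=FAST_RF, seed=42)
        ab = ablation_cells(planted_cohort, p_grid=[1.0], reps=1, rf=FAST_RF, seed=42)
        assert ab.scores[0, 0] == pytest.approx(cv.mean_score)

    def test_learning_curve_non_decreasing(self, planted_cohort):
        ab = ablation_patients(planted_cohort, k_grid=[1, 3], reps=3, rf=FAST_RF, seed=0)
        means = ab.scores.mean(axis=1)
        assert means[1] >= means[0] - 0.05  # up to noise

    def test_reps_dimension(self, planted_cohort):
        ab = ablation_cells(planted_cohort, p_grid=[0.3], reps=10,
                            rf=RFConfig(n_estimators=10), seed=0)
        assert ab.scores.shape == (1, 10)

    def test_k_exceeding_patients_raises(self, planted_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            ablation_patients(planted_cohort, k_grid=[99], reps=1, rf=FAST_RF, seed=0)


class TestGiniRanking:
    def test_planted_feature_ranks_first(self, rng):
        n = 400
        table = pd.DataFrame({f"noise_{i}": rng.normal(size=n) for i in range(6)})
        table["signal"] = rng.normal(size=n)
        table["patient_id"] = np.repeat([f"P{i}" for i in range(8)], n // 8)
        table["condition"] = np.where(table["patient_id"].isin([f"P{i}" for i in range(4)]), "a", "b")
        table.loc[table["condition"] == "b", "signal"] += 3.0
        cv = lopo_cv_rfc(table, rf=FAST_RF, seed=0)
        ranked = gini_ranking(cv, top_n=3)
        assert ranked.iloc[0]["feature"] == "signal"
        # per-fold normalized importances sum to 1
        np.testing.assert_allclose(cv.importances.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_noise_near_uniform(self, null_cohort):
        feats = [c for c in null_cohort.columns if c.startswith("noise_")]
        cv = lopo_cv_rfc(null_cohort, features=feats, rf=FAST_RF, seed=0)
        imp = cv.importances.mean(axis=0)
        assert imp.max() < 3.0 / len(feats)


class TestWelchScreen:
    def test_identical_groups_nothing_significant(self, rng):
        base = rng.normal(size=50)
        table = pd.DataFrame({"condition": ["a"] * 50 + ["b"] * 50,
                              "f1": np.tile(base, 2), "f2": np.tile(base[::-1], 2)})
        screen = welch_screen_bh(table)
        assert screen.significant_features == []

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_welch_statistic_matches_direct_formula(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        table = pd.DataFrame({"condition": ["a"] * 40 + ["b"] * 60, "f": np.concatenate([a, b])})
        screen = welch_screen_bh(table)
        t_direct = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 40 + b.var(ddof=1) / 60)
        assert screen.table.iloc[0]["statistic"] == pytest.approx(t_direct)

    def test_adjusted_p_monotone_and_bounded(self, planted_cohort):
        screen = welch_screen_bh(planted_cohort)
        t = screen.table.dropna(subset=["p_raw"]).sort_values("p_raw")
        assert (t["p_adj"].to_numpy() >= t["p_raw"].to_numpy() - 1e-15).all()
        assert (np.diff(t["p_adj"].to_numpy()) >= -1e-15).all()

    def test_zero_variance_pair_flagged(self):
        table = pd.DataFrame({"condition": ["a"] * 5 + ["b"] * 5, "f": [1.0] * 10})
        screen = welch_screen_bh(table)
        assert np.isnan(screen.table.iloc[0]["p_raw"])

    def test_pairwise_for_three_groups(self, rng):
        table = pd.DataFrame({"condition": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
                              "f": rng.normal(size=90)})
        screen = welch_screen_bh(table)
        assert len(screen.table) == 3  # (a,b), (a,c), (b,c)


class TestCompareToControl:
    def test_control_normalized_mean_is_one(self, rng):
        table = pd.DataFrame({"condition": ["control"] * 40 + ["tumor"] * 40,
                              "v": np.concatenate([rng.normal(5, 1, 40), rng.normal(8, 1, 40)])})
        out = compare_to_control(table, "v")
        ctrl = out[out["condition"] == "control"].iloc[0]
        assert ctrl["normalized_mean"] == pytest.approx(1.0)
        tum = out[out["condition"] == "tumor"].iloc[0]
        assert tum["normalized_mean"] == pytest.approx(8 / 5, rel=0.1)
        assert tum["stars"] == "****"

    def test_star_codes(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-5) == "****"

    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            compare_to_control(pd.DataFrame({"condition": ["a"], "v": [1.0]}), "v")


class TestQcEmbedding:
    def test_tsne_shape_and_determinism(self, null_cohort):
        emb1 = qc_embedding(null_cohort, seed=0, perplexity=10)
        emb2 = qc_embedding(null_cohort, seed=0, perplexity=10)
        assert len(emb1) == len(null_cohort)
        np.testing.assert_allclose(emb1[["dim1", "dim2"]], emb2[["dim1", "dim2"]])

    def test_lda_duplicates_coincide(self, null_cohort):
        dup = pd.concat([null_cohort, null_cohort.iloc[[0]]], ignore_index=True)
        emb = qc_embedding(dup, method="lda", seed=0)
        np.testing.assert_allclose(emb.iloc[0][["dim1", "dim2"]].astype(float),
                                   emb.iloc[-1][["dim1", "dim2"]].astype(float))

    def test_unknown_method_raises(self, null_cohort):
        with pytest.raises(ValueError, match="unknown"):
            qc_embedding(null_cohort, method="pca", seed=0)
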