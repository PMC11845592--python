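"""Outcome rules, filtering, imputation, matching, and balance metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kneetwin.cohort import (
    MatchConfig,
    balance_report,
    cohens_d,
    cramers_v,
    derive_outcomes,
    embed_and_match,
    filter_dataset,
    impute,
    ks_sensitivity,
    match_in_embedding,
    standardize_covariates,
)


class TestDeriveOutcomes:
    klg = pd.DataFrame(
        [[1, 1, 1, 1],      # stays healthy
         [1, 1, 2, 3],      # develops radiographic OA
         [3, 3, 3, 4],      # OA at baseline
         [np.nan, 1, 1, 1]],  # missing baseline
        columns=["v0", "v1", "v2", "v3"],
    )
    surgery = pd.Series([0, 0, 1, 0])

    def test_oa_incidence_rules(self):
        labels = derive_outcomes(self.klg, self.surgery, "oa_incidence")
        assert labels.tolist() == ["control", "case", "excluded", "excluded"]

    def test_knee_replacement_rules(self):
        labels = derive_outcomes(self.klg, self.surgery, "knee_replacement")
        # baseline-OA knee is excluded from the OA analysis but is a KR case
        assert labels.tolist()[:3] == ["control", "control", "case"]


class TestFilterDataset:
    def _table(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({
            "PC1": rng.normal(size=10), "PC2": rng.normal(size=10),
            "age": rng.normal(60, 9, 10), "bmi": rng.normal(28, 5, 10),
            "side": ["right"] * 10,
        })
        return t

    def test_subjects_missing_a_pc_mode_dropped(self):
        t = self._table()
        t.loc[[2, 5], "PC1"] = np.nan
        out = filter_dataset(t, ["PC1", "PC2"], ["age", "bmi"])
        assert len(out) == 8

    def test_five_percent_missingness_rule(self):
        rng = np.random.default_rng(1)
        n = 100
        t = pd.DataFrame({
            "PC1": rng.normal(size=n),
            "age": rng.normal(size=n), "bmi": rng.normal(size=n),
        })
        t.loc[:5, "age"] = np.nan   # 6% missing -> dropped
        t.loc[:3, "bmi"] = np.nan   # 4% missing -> kept
        out = filter_dataset(t, ["PC1"], ["age", "bmi"])
        assert "age" not in out.columns
        assert "bmi" in out.columns

    def test_clean_table_unchanged(self):
        t = self._table()
        out = filter_dataset(t, ["PC1", "PC2"], ["age", "bmi"])
        pd.testing.assert_frame_equal(out, t)

    def test_left_knees_removed(self):
        t = self._table()
        t.loc[[0, 1], "side"] = "left"
        out = filter_dataset(t, ["PC1", "PC2"], ["age", "bmi"])
        assert len(out) == 8


class TestImpute:
    def test_observed_values_bitwise_preserved(self, rng):
        n = 120
        t = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        t["target"] = 2 * t["a"] - t["b"] + rng.normal(0, 0.1, n)
        holes = rng.uniform(size=n) < 0.05
        t_miss = t.copy()
        t_miss.loc[holes, "target"] = np.nan
        out = impute(t_miss, seed=0, columns=["a", "b", "c", "target"])
        obs = ~holes
        assert np.array_equal(out.loc[obs, "target"], t.loc[obs, "target"])
        assert out["target"].notna().all()

    def test_beats_median_fill_on_predictable_column(self, rng):
        n = 300
        t = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t["target"] = np.sin(t["a"]) + 0.5 * t["b"] + rng.normal(0, 0.05, n)
        holes = rng.uniform(size=n) < 0.03
        t_miss = t.copy()
        t_miss.loc[holes, "target"] = np.nan
        out = impute(t_miss, seed=0, columns=["a", "b", "target"])
        rmse = np.sqrt(np.mean((out.loc[holes, "target"] - t.loc[holes, "target"]) ** 2))
        rmse_median = np.sqrt(
            np.mean((t_miss["target"].median() - t.loc[holes, "target"]) ** 2)
        )
        assert rmse < rmse_median

    def test_deterministic_given_seed(self, rng):
        n = 100
        t = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t.loc[:4, "b"] = np.nan
        out1 = impute(t, seed=7, columns=["a", "b"])
        out2 = impute(t, seed=7, columns=["a", "b"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_fully_missing_column_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute(t, seed=0, columns=["a", "b"])


class TestKSSensitivity:
    def test_identical_columns_statistic_zero(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=50)})
        out = ks_sensitivity(t, t)
        assert out.loc["a", "statistic"] == 0.0

    def test_large_shift_detected(self, rng):
        a = pd.DataFrame({"a": rng.normal(size=200)})
        b = pd.DataFrame({"a": a["a"] + 5.0})
        assert ks_sensitivity(a, b).loc["a", "p"] < 1e-10

    def test_matches_brute_force_cdf_sup_difference(self, rng):
        a = rng.normal(size=150)
        b = a.copy()
        idx = rng.choice(150, 5, replace=False)
        b[idx] += rng.normal(0, 0.5, 5)
        out = ks_sensitivity(pd.DataFrame({"x": a}), pd.DataFrame({"x": b}))
        # brute force: sup |F_a - F_b| over all sample points
        pts = np.concatenate([a, b])
        fa = np.searchsorted(np.sort(a), pts, side="right") / a.size
        fb = np.searchsorted(np.sort(b), pts, side="right") / b.size
        assert np.isclose(out.loc["x", "statistic"], np.max(np.abs(fa - fb)))


class TestMatching:
    def test_coincident_control_matched_at_zero_distance(self):
        emb = pd.DataFrame(
            {"e0": [1.0, 5.0, 1.0, 9.0], "e1": 0.0, "e2": 0.0},
            index=["case0", "case1", "ctrl0", "ctrl1"],
        )
        res = match_in_embedding(emb, ["case0", "case1"], ["ctrl0", "ctrl1"])
        row = res.pairs.set_index("case_id")
        assert row.loc["case0", "control_id"] == "ctrl0"
        assert row.loc["case0", "distance"] == 0.0

    def test_matches_equal_brute_force_distance_matrix(self, rng):
        ids = [f"s{i}" for i in range(50)]
        emb = pd.DataFrame(rng.normal(size=(50, 3)), columns=["e0", "e1", "e2"],
                           index=ids)
        cases, controls = ids[:20], ids[20:]
        res = match_in_embedding(emb, cases, controls)
        D = np.linalg.norm(
            emb.loc[cases, ["e0", "e1", "e2"]].to_numpy()[:, None]
            - emb.loc[controls, ["e0", "e1", "e2"]].to_numpy()[None], axis=2
        )
        brute = [controls[j] for j in D.argmin(axis=1)]
        assert res.pairs["control_id"].tolist() == brute

    def test_each_match_minimizes_distance(self, rng):
        ids = [f"s{i}" for i in range(40)]
        emb = pd.DataFrame(rng.normal(size=(40, 3)), columns=["e0", "e1", "e2"],
                           index=ids)
        res = match_in_embedding(emb, ids[:15], ids[15:])
        E = emb[["e0", "e1", "e2"]]
        for _, row in res.pairs.iterrows():
            d_all = np.linalg.norm(
                E.loc[ids[15:]].to_numpy() - E.loc[row["case_id"]].to_numpy(), axis=1
            )
            assert row["distance"] <= d_all.min() + 1e-12

    def test_zero_controls_rejected(self, rng):
        cov = pd.DataFrame(rng.normal(size=(10, 3)), index=range(10))
        with pytest.raises(ValueError, match="no controls"):
            embed_and_match(cov, list(range(10)), [], MatchConfig(seed=0))

    def test_planted_clusters_match_within_cluster(self, rng):
        # cases all in cluster A; controls half in A, half in cluster B
        n_case, n_ctrl = 30, 60
        A = rng.normal(0, 1, (n_case + n_ctrl // 2, 4))
        B = rng.normal(8, 1, (n_ctrl // 2, 4))
        X = np.vstack([A[:n_case], A[n_case:], B])
        ids = [f"s{i}" for i in range(len(X))]
        cov = pd.DataFrame(X, index=ids)
        cases = ids[:n_case]
        controls = ids[n_case:]
        in_cluster_a = set(ids[n_case:n_case + n_ctrl // 2])
        res = embed_and_match(cov, cases, controls, MatchConfig(seed=3))
        frac = np.mean([c in in_cluster_a for c in res.pairs["control_id"]])
        assert frac >= 0.9


class TestBalance:
    def test_identical_pairs_all_zero(self):
        ids = [f"s{i}" for i in range(8)]
        t = pd.DataFrame({
            "age": [60, 61, 62, 63] * 2, "sex": [0, 1, 0, 1] * 2,
            "outcome": [1, 1, 1, 1, 0, 0, 0, 0],
        }, index=ids)
        emb = pd.DataFrame(
            np.vstack([np.arange(4)[:, None].repeat(3, 1)] * 2),
            columns=["e0", "e1", "e2"], index=ids,
        )
        res = match_in_embedding(emb, ids[:4], ids[4:])
        rep = balance_report(t, res, ["age"], ["sex"])
        assert rep.continuous.loc["age", "post_cohens_d"] == 0.0
        assert rep.categorical.loc["sex", "post_cramers_v"] == 0.0

    def test_point_biserial_equals_pearson_with_binary_coding(self, rng):
        x = rng.normal(size=200)
        g = rng.integers(0, 2, 200)
        r_pb = stats.pointbiserialr(g, x)
        r_p = stats.pearsonr(g.astype(float), x)
        assert abs(r_pb.correlation - r_p.statistic) < 1e-12

    def test_swapping_groups_negates_d(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 60)
        assert np.isclose(cohens_d(a, b), -cohens_d(b, a))
        assert cohens_d(a, a) == 0.0

    def test_cramers_v_bounds(self, rng):
        g = rng.integers(0, 2, 300)
        v, _chi, _p = cramers_v(g, g)  # perfect association
        assert 0.99 < v <= 1.0
        v2, _chi2, _p2 = cramers_v(g, rng.integers(0, 3, 300))
        assert 0.0 <= v2 <= 1.0

    def test_matching_on_confounded_embedding_reduces_smd(self, rng):
        # plant a 0.8 SD BMI shift; embed on BMI alone so matching can fix it
        n_case, n_ctrl = 40, 80
        bmi = np.concatenate([rng.normal(28.8, 4.0, n_case) + 0.8 * 4.0,
                              rng.normal(28.8, 4.0, n_ctrl)])
        ids = [f"s{i}" for i in range(n_case + n_ctrl)]
        t = pd.DataFrame({"bmi": bmi,
                          "outcome": [1] * n_case + [0] * n_ctrl}, index=ids)
        std = standardize_covariates(t, ["bmi"], [])
        res = embed_and_match(std, ids[:n_case], ids[n_case:], MatchConfig(seed=5))
        rep = balance_report(t, res, ["bmi"], [])
        pre = abs(rep.continuous.loc["bmi", "pre_cohens_d"])
        post = abs(rep.continuous.loc["bmi", "post_cohens_d"])
        assert post < pre
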