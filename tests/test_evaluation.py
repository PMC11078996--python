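import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oomorph.evaluation import (
    ablation_eval,
    delong_paired,
    delong_variance,
    pca_reduce,
    roc_auc,
    sens_spec,
    subgroup_eval,
    welch_t,
)
from oomorph.features import FeatureTable


def auc_brute_force(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_separable_example(self):
        scores = [0.9, 0.8, 0.7, 0.3]
        labels = [1, 1, 0, 0]
        assert auc_brute_force(scores, labels) == 1.0
        assert roc_auc(scores, labels) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.uniform(size=200), 2)  # ties guaranteed
        labels = rng.integers(0, 2, size=200)
        assert abs(roc_auc(scores, labels)
                   - auc_brute_force(scores, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base, abs=1e-12)


class TestSensSpec:
    def test_perfect(self):
        assert sens_spec([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_all_negative_prediction(self):
        assert sens_spec([0, 0, 0, 0], [1, 0, 1, 0]) == (0.0, 1.0)

    def test_hand_built_table(self):
        # TP=3 FN=2 TN=6 FP=1
        truth = [1] * 5 + [0] * 7
        pred = [1, 1, 1, 0, 0] + [0] * 6 + [1]
        sens, spec = sens_spec(pred, truth)
        assert sens == pytest.approx(0.6)
        assert spec == pytest.approx(6 / 7, abs=5e-4)

    def test_undefined_side_is_none(self):
        sens, spec = sens_spec([0, 1], [0, 0])
        assert sens is None and spec == 0.5


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        res = delong_paired(s, s, y)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_z_sign_matches_auc_difference(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        good = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        bad = rng.normal(size=100)
        res = delong_paired(good, bad, y)
        assert res.auc_a > res.auc_b
        assert res.z > 0

    def test_variance_matches_bootstrap(self):
        """Small fixture: DeLong variance of the paired AUC difference
        agrees with a seeded bootstrap estimate within 15%."""
        scores_a = np.array([0.82, 0.34, 0.91, 0.75, 0.56, 0.41,
                             0.66, 0.28, 0.88, 0.49, 0.61, 0.15])
        scores_b = np.array([0.71, 0.42, 0.80, 0.68, 0.62, 0.30,
                             0.55, 0.39, 0.77, 0.58, 0.44, 0.22])
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0])
        res = delong_paired(scores_a, scores_b, labels)
        rng = np.random.default_rng(0)
        diffs = []
        n = len(labels)
        while len(diffs) < 10_000:
            idx = rng.integers(0, n, size=n)
            y = labels[idx]
            if y.sum() in (0, n):
                continue
            diffs.append(roc_auc(scores_a[idx], y) - roc_auc(scores_b[idx], y))
        assert res.var_diff == pytest.approx(np.var(diffs), rel=0.15)

    def test_independent_scores_variance_decomposes(self):
        """With independent score vectors the paired variance approaches the
        sum of the single-curve DeLong variances (covariance ~ 0)."""
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(300, int), np.zeros(300, int)]
        a, b = rng.normal(size=600), rng.normal(size=600)
        res = delong_paired(a, b, y)
        _, va = delong_variance(a, y)
        _, vb = delong_variance(b, y)
        assert res.var_diff == pytest.approx(va + vb, rel=0.25)

    def test_degenerate_variance_raises(self):
        # both models separate perfectly (constant placement values, zero
        # estimated variance) yet their AUCs differ: 1.0 vs 0.0
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([1, 1, 0, 0])
        with pytest.raises(FloatingPointError):
            delong_paired(a, b, y)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0.3, 2, 45)
        t, df, p = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_equal_variance_limit_agrees_with_pooled(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        t, _, _ = welch_t(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(pooled.statistic, abs=1e-9)

    def test_zero_variance_both_groups(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])
        t, _, p = welch_t([1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_flags_generator_driven_features(self, recovery_study):
        """Outcome-driving features separate blastocyst-positive from
        -negative groups; a cohort-average PVS-vs-ZP ratio (independent of
        every driver) does not."""
        df = recovery_study["table"].data
        pos = df[df["outcome"] == 1]
        neg = df[df["outcome"] == 0]
        _, _, p_age = welch_t(pos["oocyte_age"], neg["oocyte_age"])
        assert p_age < 1e-6
        _, _, p_inert = welch_t(pos["cohort_avg_pvs_vs_zp_area_ratio"],
                                neg["cohort_avg_pvs_vs_zp_area_ratio"])
        assert p_inert > 0.01

    def test_narrower_range_in_positive_group(self, recovery_study):
        """Optimum-deviation outcome: blastocyst-positive oocytes occupy a
        narrower driver-feature range than negative ones."""
        df = recovery_study["table"].data
        pos = df[df["outcome"] == 1]["ooplasm_roundness"]
        neg = df[df["outcome"] == 0]["ooplasm_roundness"]
        assert pos.std() < neg.std()


class TestPCA:
    def _low_rank_table(self, n=400, factors=3, per=5, noise=1e-3):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(n, factors))
        load = rng.normal(size=(factors, factors * per))
        x = f @ load + noise * rng.normal(size=(n, factors * per))
        return pd.DataFrame(x, columns=[f"v{i}" for i in range(factors * per)])

    def test_recovers_factor_count(self):
        reduced, k = pca_reduce(self._low_rank_table(), 0.95)
        assert k == 3
        assert list(reduced.columns) == ["PC1", "PC2", "PC3"]

    def test_threshold_one_gives_rank(self):
        df = self._low_rank_table(noise=0.0)
        _, k = pca_reduce(df, 1.0)
        assert k == 3  # rank of the noiseless low-rank table

    def test_duplicated_columns_do_not_increase_components(self):
        df = self._low_rank_table()
        doubled = pd.concat([df, df.add_suffix("_dup")], axis=1)
        _, k1 = pca_reduce(df, 0.95)
        _, k2 = pca_reduce(doubled, 0.95)
        assert k2 == k1

    def test_constant_columns_dropped_with_warning(self):
        df = self._low_rank_table()
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="const"):
            _, k = pca_reduce(df, 0.95)
        assert k == 3

    def test_reconstruction_error_monotone(self):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler
        z = StandardScaler().fit_transform(self._low_rank_table(noise=0.3))
        errs = []
        for k in (1, 2, 3, 4):
            p = PCA(n_components=k).fit(z)
            rec = p.inverse_transform(p.transform(z))
            errs.append(((z - rec) ** 2).mean())
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestAblation:
    def test_driver_group_hurts_null_group_does_not(self, recovery_study):
        abl = recovery_study["ablations"]
        assert abl["ooplasm"]["delong"].p_value < 0.05
        assert abl["ooplasm"]["auc"] < recovery_study["test_auc"]
        assert abl["zp"]["delong"].p_value > 0.05

    def test_empty_group_list_rejected(self, recovery_study):
        with pytest.raises(ValueError):
            ablation_eval(recovery_study["table"], recovery_study["split"], [])


class TestSubgroups:
    def test_age_binning_with_exclusion(self):
        ages = [25, 30, 34, 35, 38, 40, 44]
        rows = pd.DataFrame({
            "oocyte_age": ages,
            "outcome": [0, 1, 0, 1, 0, 1, 0],
            "clinic": ["c"] * 7,
        })
        rng = np.random.default_rng(0)
        out = subgroup_eval(rng.uniform(size=7), rows, by="age",
                            exclude_age_over=43)
        counts = {s["subgroup"]: s["report"].n for s in out}
        assert counts == {"<30": 1, "30-34": 2, "35-37": 1, "38-39": 1,
                          ">=40": 1}

    def test_clinic_partition_sums_to_total(self, recovery_study):
        rows = recovery_study["test_rows"]
        out = subgroup_eval(recovery_study["prob"], rows, by="clinic")
        assert sum(s["report"].n for s in out) == len(rows)

    def test_single_class_subgroup_auc_none(self):
        rows = pd.DataFrame({
            "oocyte_age": [25, 26, 35, 36, 35],
            "outcome": [1, 1, 0, 1, 1],
            "clinic": ["c"] * 5,
        })
        out = subgroup_eval([0.6, 0.7, 0.2, 0.8, 0.9], rows, by="age")
        by_name = {s["subgroup"]: s for s in out}
        assert by_name["<30"]["report"].auc is None
        assert by_name["<30"]["delong_vs_overall"] is None
        assert by_name["<30"]["report"].specificity is None
        assert by_name["35-37"]["report"].auc is not None

    def test_uniform_generator_no_excess_subgroup_significance(self, recovery_study):
        """Performance is homogeneous across clinics by construction, so
        clinic subgroup AUCs should rarely differ from overall."""
        rows = recovery_study["test_rows"]
        out = subgroup_eval(recovery_study["prob"], rows, by="clinic")
        n_sig = sum(s["delong_vs_overall"].p_value < 0.05 for s in out
                    if s["delong_vs_overall"] is not None)
        assert n_sig <= 1  # at most one of five sites by chance
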