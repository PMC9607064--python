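import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sustdiet.stats import (
    bh_fdr,
    chi_square,
    compute_bmi,
    cooks_distance_filter,
    gg_epsilon,
    harmonise_mood,
    hierarchical_regression,
    log_transform_if_skewed,
    mauchly_test,
    paired_t,
    rm_anova,
    score_cognition_logs,
)


class TestHarmoniseMood:
    def test_quartile_cut_on_eight_scores(self):
        out = harmonise_mood(range(1, 9), ["PANAS"] * 8, q=4)
        assert [h.quantile_group for h in out] == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_all_equal_scores_warn_but_stay_balanced(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = harmonise_mood([5] * 8, ["PANAS"] * 8, q=4)
        sizes = np.bincount([h.quantile_group for h in out])[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_two_scales_cut_independently_and_balanced(self, rng):
        raw = np.concatenate([rng.integers(0, 37, 40), rng.integers(10, 51, 40)])
        scales = ["POMS"] * 40 + ["PANAS"] * 40
        out = harmonise_mood(raw, scales, q=4)
        frame = pd.DataFrame({"scale": scales, "g": [h.quantile_group for h in out]})
        for _, sub in frame.groupby("scale"):
            sizes = sub["g"].value_counts()
            assert sizes.max() - sizes.min() <= 1
        # brute-force rank-cut oracle within one scale
        poms = frame[frame["scale"] == "POMS"]["g"].to_numpy()
        vals = -raw[:40]  # POMS reversed towards negative affect
        order = np.argsort(vals, kind="stable")
        oracle = np.empty(40, dtype=int)
        oracle[order] = np.arange(40) * 4 // 40 + 1
        assert (poms == oracle).all()

    def test_poms_orientation_reversed(self):
        # high POMS (elated) = best mood = group 1
        out = harmonise_mood([36, 0, 20, 10], ["POMS"] * 4, q=4)
        assert out[0].quantile_group == 1
        assert out[1].quantile_group == 4

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="fewer than q"):
            harmonise_mood([1, 2], ["POMS", "POMS"], q=4)


class TestLogTransform:
    def test_symmetric_sample_untouched(self, rng):
        x = rng.normal(10, 1, 500)
        out, flag, _ = log_transform_if_skewed(x)
        assert not flag
        assert np.array_equal(out, x)

    def test_lognormal_sample_transformed_and_less_skewed(self, rng):
        for seed in range(5):
            x = np.exp(np.random.default_rng(seed).normal(0, 1, 400))
            out, flag, _ = log_transform_if_skewed(x)
            assert flag
            assert abs(sps.skew(out)) < abs(sps.skew(x))

    def test_constant_vector_untouched(self):
        out, flag, _ = log_transform_if_skewed(np.full(10, 3.0))
        assert not flag

    def test_zeros_offset_by_half_smallest_positive(self):
        x = np.array([0.0, 0.0, 0.1, 0.2, 0.1, 0.3, 50.0, 80.0, 100.0, 200.0])
        out, flag, offset = log_transform_if_skewed(x, skew_threshold=0.5)
        assert flag
        assert offset == pytest.approx(0.05)
        assert np.isfinite(out).all()


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["degenerate"]

    def test_hand_computed_statistic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, np.zeros(4))
        assert res["t"] == pytest.approx(2.5 / (np.std(x, ddof=1) / 2), rel=1e-6)
        assert res["t"] == pytest.approx(3.873, abs=1e-3)
        assert res["df"] == 3

    def test_sign_flip_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t(np.arange(5.0) + 2.0, np.arange(5.0))
        assert res["degenerate"] and np.isinf(res["t"]) and res["p"] == 0.0


class TestChiSquare:
    def test_balanced_table_zero(self):
        assert chi_square([[10, 10], [10, 10]])["x2"] == 0.0

    def test_proportional_rows_zero(self):
        assert chi_square([[10, 30], [5, 15]])["x2"] == pytest.approx(0.0)

    def test_permutation_invariance(self):
        t = np.array([[12, 41], [45, 13]])
        base = chi_square(t)["x2"]
        assert chi_square(t[::-1])["x2"] == pytest.approx(base)
        assert chi_square(t[:, ::-1])["x2"] == pytest.approx(base)
        assert chi_square(t.T)["x2"] == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 10]])

    def test_matches_hand_formula(self):
        t = np.array([[20, 30], [40, 10]])
        n = t.sum()
        expected = np.outer(t.sum(1), t.sum(0)) / n
        hand = ((t - expected) ** 2 / expected).sum()
        assert chi_square(t)["x2"] == pytest.approx(hand)


class TestBhFdr:
    def test_step_up_accepts_borderline_set(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05).all()

    def test_all_ones_rejected_nothing(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    def test_single_pvalue_reduces_to_raw_threshold(self):
        assert bh_fdr([0.049], q=0.05)[0]
        assert not bh_fdr([0.051], q=0.05)[0]

    def test_matches_brute_force_maximisation(self, rng):
        """Step-up output equals maximising over all rejection cutoffs."""
        for _ in range(20):
            m = int(rng.integers(1, 13))
            p = rng.random(m)
            got = bh_fdr(p, q=0.05)
            best = np.zeros(m, dtype=bool)
            for cut in sorted(p):
                mask = p <= cut
                if cut <= mask.sum() * 0.05 / m and mask.sum() > best.sum():
                    best = mask
            assert np.array_equal(got, best)


class TestCooks:
    @staticmethod
    def _loo_oracle(X, y):
        """Leave-one-out refit influence, the textbook definition."""
        import statsmodels.api as sm

        Xc = sm.add_constant(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        full = sm.OLS(y, Xc).fit()
        p = Xc.shape[1]
        s2 = full.mse_resid
        out = np.empty(len(y))
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            sub = sm.OLS(y[keep], Xc[keep]).fit()
            delta = Xc @ full.params - Xc @ sub.params
            out[i] = (delta @ delta) / (p * s2)
        return out

    def test_closed_form_equals_loo_refit(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, -2.0] + rng.normal(size=30)
        _, d = cooks_distance_filter(X, y)
        assert np.allclose(d, self._loo_oracle(X, y), rtol=1e-8)

    def test_gross_outlier_excluded(self, rng):
        X = rng.normal(size=(40, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.5, 40)
        y[7] += 25.0
        retained, d = cooks_distance_filter(X, y)
        assert not retained[7]

    def test_clean_balanced_design_fully_retained(self):
        # duplicated two-level balanced design has equal leverage 2/n at
        # every point, so bounded noise keeps every D_i under 4/n
        X = np.tile([-1.0, 1.0], 40)[:, None]
        noise = np.random.default_rng(5).uniform(-0.1, 0.1, 80)
        y = 3 * X[:, 0] + noise
        retained, d = cooks_distance_filter(X, y)
        assert retained.all()
        assert (d < 4.0 / 80).all()
        assert np.allclose(d, self._loo_oracle(X, y), rtol=1e-8)

    def test_exact_line_has_zero_distances(self):
        X = np.linspace(0, 1, 12)[:, None]
        y = 2 + 3 * X[:, 0]
        _, d = cooks_distance_filter(X, y)
        assert np.allclose(d, 0.0, atol=1e-12)


class TestHierarchicalRegression:
    @staticmethod
    def _frame(rng, n=200, beta_diet=0.0):
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=["female", "bmi", "kcal",
                                                            "alcohol", "exercise"])
        df["diet"] = rng.normal(size=n)
        df["y"] = 0.2 * df["bmi"] + beta_diet * df["diet"] + rng.normal(size=n)
        return df

    def test_orthogonal_step2_gives_zero_r2_change(self, rng):
        df = self._frame(rng)
        # orthogonalise diet against outcome and covariates in-sample
        import statsmodels.api as sm

        X = sm.add_constant(df[["female", "bmi", "kcal", "alcohol", "exercise", "y"]])
        df["diet"] = sm.OLS(df["diet"], X).fit().resid
        steps = hierarchical_regression(
            df, "y", ["female", "bmi", "kcal", "alcohol", "exercise"], ["diet"],
            cooks_exclude=False,
        )
        assert steps[1].r2_change == pytest.approx(0.0, abs=1e-12)
        assert steps[1].f_change == pytest.approx(0.0, abs=1e-9)

    def test_single_predictor_beta_equals_pearson_r(self, rng):
        df = self._frame(rng, beta_diet=0.4)
        steps = hierarchical_regression(df, "y", ["diet"], ["bmi"], cooks_exclude=False)
        r = np.corrcoef(df["diet"], df["y"])[0, 1]
        assert steps[0].beta_std["diet"] == pytest.approx(r, rel=1e-9)

    def test_r2_and_beta_invariant_to_affine_rescaling(self, rng):
        df = self._frame(rng, beta_diet=0.3)
        scaled = df.copy()
        scaled["kcal"] = scaled["kcal"] * 1000 + 2000
        scaled["diet"] = scaled["diet"] / 13.0
        covs = ["female", "bmi", "kcal", "alcohol", "exercise"]
        a = hierarchical_regression(df, "y", covs, ["diet"], cooks_exclude=False)
        b = hierarchical_regression(scaled, "y", covs, ["diet"], cooks_exclude=False)
        assert a[1].r2 == pytest.approx(b[1].r2)
        assert a[1].beta_std["diet"] == pytest.approx(b[1].beta_std["diet"])

    def test_f_change_formula(self, rng):
        df = self._frame(rng, beta_diet=0.5)
        covs = ["female", "bmi", "kcal", "alcohol", "exercise"]
        s1, s2 = hierarchical_regression(df, "y", covs, ["diet"], cooks_exclude=False)
        n = s2.n
        expected = ((s2.r2 - s1.r2) / 1) / ((1 - s2.r2) / (n - 6 - 1))
        assert s2.f_change == pytest.approx(expected)
        assert s2.df == (1, n - 7)

    def test_rank_deficiency_rejected(self, rng):
        df = self._frame(rng)
        df["dup"] = df["bmi"]
        with pytest.raises(ValueError, match="rank deficient"):
            hierarchical_regression(df, "y", ["bmi", "dup"], ["diet"])

    def test_cooks_exclusion_applied_once(self, rng):
        df = self._frame(rng, beta_diet=0.3)
        df.loc[3, "y"] += 30.0
        steps = hierarchical_regression(
            df, "y", ["female", "bmi", "kcal", "alcohol", "exercise"], ["diet"]
        )
        assert 3 in steps[1].excluded_ids
        assert steps[0].excluded_ids == steps[1].excluded_ids
        assert steps[0].n == len(df) - len(steps[0].excluded_ids)


class TestSphericity:
    def test_two_levels_always_one(self, rng):
        S = np.cov(rng.normal(size=(50, 2)), rowvar=False)
        assert gg_epsilon(S) == 1.0

    def test_compound_symmetry_gives_one(self):
        for k in (3, 4, 6):
            S = np.full((k, k), 0.6) + np.eye(k) * 0.8
            assert gg_epsilon(S) == pytest.approx(1.0)

    def test_rank_one_hits_lower_bound(self):
        v = np.array([1.0, -2.0, 1.0])
        S = np.outer(v, v)
        assert gg_epsilon(S) == pytest.approx(0.5)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gg_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_matches_pingouin_epsilon(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(size=(40, 4))
        data[:, 1] += 0.8 * data[:, 0]
        S = np.cov(data, rowvar=False)
        wide = pd.DataFrame(data, columns=list("abcd"))
        assert gg_epsilon(S) == pytest.approx(float(pg.epsilon(wide, correction="gg")),
                                              rel=1e-6)


class TestRmAnova:
    @staticmethod
    def _wide(rng, n=40, k=3, effect=0.0, rho=0.4):
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        data = rng.multivariate_normal(np.zeros(k), cov, size=n)
        data[:, -1] += effect
        return pd.DataFrame(data, columns=[f"c{j}" for j in range(k)])

    def test_one_way_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        wide = self._wide(rng, effect=0.5)
        res = rm_anova(wide, within={"condition": ["c0", "c1", "c2"]})
        long = wide.reset_index().melt(id_vars="index", var_name="condition",
                                       value_name="y")
        oracle = pg.rm_anova(data=long, dv="y", within="condition", subject="index",
                             correction=True)
        row = res.effects.loc["condition"]
        assert row["F"] == pytest.approx(float(oracle["F"][0]), rel=1e-6)
        assert res.epsilon_gg["condition"] == pytest.approx(float(oracle["eps"][0]),
                                                            rel=1e-6)

    def test_mauchly_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        wide = self._wide(rng, n=35)
        res = rm_anova(wide, within={"condition": ["c0", "c1", "c2"]})
        spher = pg.sphericity(wide)
        assert res.mauchly["condition"]["w"] == pytest.approx(float(spher.W), rel=1e-6)
        assert res.mauchly["condition"]["p"] == pytest.approx(float(spher.pval), rel=1e-4)

    def test_two_level_factor_never_corrected(self, rng):
        wide = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = rm_anova(wide, within={"delay": ["a", "b"]})
        assert res.epsilon_gg["delay"] == 1.0
        assert not res.effects.loc["delay", "gg_applied"]

    def test_within_by_covariate_interaction_detected(self, rng):
        n = 120
        diet = rng.normal(size=n)
        base = rng.normal(size=(n, 1)) + rng.normal(size=(n, 4), scale=0.7)
        wide = pd.DataFrame(base, columns=["ic", "ia", "dc", "da"])
        wide[["dc", "da"]] = wide[["dc", "da"]].to_numpy() + 0.8 * diet[:, None]
        res = rm_anova(
            wide,
            within={"delay": ["immediate", "delayed"], "wordtype": ["concrete", "abstract"]},
            covariates=pd.DataFrame({"diet": diet}),
        )
        assert res.effects.loc["delay x diet", "p"] < 0.001
        assert res.effects.loc["delay x wordtype", "p"] > 0.001  # no planted interaction

    def test_missing_cells_rejected(self, rng):
        wide = pd.DataFrame(rng.normal(size=(20, 4)))
        wide.iloc[3, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(wide, within={"a": [0, 1], "b": [0, 1]})


class TestCognitionScoring:
    def test_perfect_serial_sevens(self):
        logs = {"serial_sevens": [{"correct": True, "rt_ms": 900.0}] * 28}
        out = score_cognition_logs(logs)
        assert out["serial7_pct_correct"] == 100.0
        assert out["serial7_mean_rt_ms"] == 900.0

    def test_flanker_condition_accuracy(self):
        trials = []
        for cond in ("congruent", "incongruent", "neutral"):
            for i in range(24):
                correct = not (cond == "incongruent" and i < 4)
                trials.append({"condition": cond, "correct": correct, "rt_ms": 500.0})
        out = score_cognition_logs({"flanker": trials})
        assert out["flanker_incongruent_pct_correct"] == pytest.approx(83.33, abs=0.01)
        assert out["flanker_congruent_pct_correct"] == 100.0

    def test_recall_counts_by_type_and_phase(self):
        words = {"abstract": [f"a{i}" for i in range(15)],
                 "concrete": [f"c{i}" for i in range(15)]}
        logs = {"recall": {"words": words,
                           "immediate": [f"c{i}" for i in range(9)] + ["a0"],
                           "delayed": ["c0", "c1", "a0", "nonword"]}}
        out = score_cognition_logs(logs)
        assert out["recall_immediate_concrete"] == 9
        assert out["recall_immediate_abstract"] == 1
        assert out["recall_delayed_concrete"] == 2
        assert out["recall_delayed_abstract"] == 1

    def test_malformed_trial_reports_index(self):
        logs = {"serial_sevens": [{"correct": True, "rt_ms": 1.0}, {"correct": True}]}
        with pytest.raises(ValueError, match="trial 1"):
            score_cognition_logs(logs)


class TestBmi:
    def test_formula(self):
        assert compute_bmi(70.0, 1.70) == pytest.approx(24.22, abs=0.01)

    def test_linearity_in_weight(self):
        assert compute_bmi(140.0, 1.70) == pytest.approx(2 * compute_bmi(70.0, 1.70))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0.0, 1.7)
        with pytest.raises(ValueError):
            compute_bmi(70.0, -1.0)
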