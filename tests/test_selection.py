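import numpy as np
import pandas as pd
import pytest

from nephroradiomics.errors import DegenerateInputError
from nephroradiomics.selection import (
    SelectionConfig,
    combined_voting,
    correlation_filter,
    cv_feature_voting,
    lasso_select,
    multivariate_logistic_filter,
    run_cascade,
    univariate_logistic_filter,
    znormalize,
)


def _null_table(rng, n, p, prefix="f"):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"{prefix}{i:03d}" for i in range(p)])


@pytest.fixture
def labels100():
    return np.r_[np.zeros(50), np.ones(50)].astype(int)


class TestZNormalize:
    def test_uses_sample_sd(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _ = znormalize(df)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        df = _null_table(rng, 30, 4)
        z1, _ = znormalize(df)
        z2, _ = znormalize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_constant_column_dropped(self, rng):
        df = _null_table(rng, 20, 3)
        df["const"] = 7.0
        z, dropped = znormalize(df)
        assert dropped == ["const"]
        assert "const" not in z.columns

    def test_train_statistics_apply_to_test_split(self, rng):
        df = _null_table(rng, 40, 3)
        train, test = df.iloc[:30], df.iloc[30:]
        z, _ = znormalize(test, stats_from=train)
        expected = (test - train.mean()) / train.std(ddof=1)
        np.testing.assert_allclose(z.to_numpy(), expected.to_numpy())


class TestCorrelationFilter:
    def test_label_identical_feature_retained(self, rng, labels100):
        df = _null_table(rng, 100, 5)
        df["copy"] = labels100.astype(float)
        assert "copy" in correlation_filter(df, labels100, 0.05)

    def test_null_type_one_rate_near_nominal(self, labels100):
        rng = np.random.default_rng(1234)
        df = _null_table(rng, 100, 1000)
        kept = correlation_filter(df, labels100, 0.05)
        assert abs(len(kept) / 1000 - 0.05) < 0.02

    def test_tiny_sample_rarely_significant(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1, 1])
        hits = 0
        for _ in range(50):
            df = pd.DataFrame({"x": rng.standard_normal(3)})
            hits += len(correlation_filter(df, y, 0.05))
        assert hits <= 3  # only near-perfect |r| can pass at n=3

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            correlation_filter(_null_table(rng, 10, 2), np.zeros(10), 0.05)


class TestLogisticStages:
    def test_label_identical_feature_survives_both(self, rng, labels100):
        df = _null_table(rng, 100, 4)
        df["sig"] = labels100 + 0.1 * rng.standard_normal(100)
        z, _ = znormalize(df)
        uni = univariate_logistic_filter(z, labels100, 0.10)
        assert "sig" in uni
        multi = multivariate_logistic_filter(z[uni], labels100, 0.05)
        assert "sig" in multi

    def test_duplicated_feature_survives_at_most_once(self, rng, labels100):
        df = pd.DataFrame({
            "a": labels100 + 0.5 * rng.standard_normal(100),
        })
        df["b"] = df["a"]
        df["c"] = rng.standard_normal(100)
        z, _ = znormalize(df)
        multi = multivariate_logistic_filter(z, labels100, 0.05)
        assert len({"a", "b"} & set(multi)) <= 1

    def test_perfect_separation_is_handled(self, labels100):
        df = pd.DataFrame({"sep": labels100.astype(float)})
        z, _ = znormalize(df)
        assert univariate_logistic_filter(z, labels100, 0.10) == ["sep"]


class TestLasso:
    def test_huge_alpha_shrinks_everything(self, rng, labels100):
        df = _null_table(rng, 100, 5)
        df["sig"] = labels100 + 0.3 * rng.standard_normal(100)
        z, _ = znormalize(df)
        assert lasso_select(z, labels100, alpha=50.0) == []

    def test_small_alpha_approaches_unpenalized_support(self, rng, labels100):
        df = _null_table(rng, 100, 3)
        df["sig"] = labels100 + 0.5 * rng.standard_normal(100)
        z, _ = znormalize(df)
        kept = lasso_select(z, labels100, alpha=1e-6)
        assert "sig" in kept and len(kept) >= 3  # near-full support retained

    def test_strong_feature_recovered_across_seeds(self):
        """Effect of 2 SD at n=200 with many nulls is selected in >= 95%
        of runs."""
        hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(100), np.ones(100)].astype(int)
            df = _null_table(rng, 200, 30)
            df["sig"] = 2.0 * y + rng.standard_normal(200)
            z, _ = znormalize(df)
            hits += "sig" in lasso_select(z, y, alpha=0.05)
        assert hits / runs >= 0.95


class TestVoting:
    def test_deterministic_under_fixed_fold_seed(self, rng, labels100):
        df = _null_table(rng, 100, 10)
        df["sig"] = labels100 + 0.4 * rng.standard_normal(100)
        cfg = SelectionConfig(fold_seed=3)
        r1 = cv_feature_voting(df, labels100, cfg)
        r2 = cv_feature_voting(df, labels100, cfg)
        assert r1.voting_count == r2.voting_count
        assert r1.final_set == r2.final_set

    def test_label_identical_feature_gets_five_votes(self, rng, labels100):
        df = _null_table(rng, 100, 8)
        df["copy"] = labels100 + 0.05 * rng.standard_normal(100)
        rep = cv_feature_voting(df, labels100, SelectionConfig(fold_seed=0))
        assert rep.voting_count.get("copy", 0) == 5
        assert "copy" in rep.final_set

    def test_stage_survivor_sets_are_nested(self, rng, labels100):
        df = _null_table(rng, 100, 20)
        df["sig"] = labels100 + 0.5 * rng.standard_normal(100)
        stages = run_cascade(df, labels100, SelectionConfig())
        assert set(stages["univariate"]) <= set(stages["correlation"])
        assert set(stages["multivariate"]) <= set(stages["univariate"])
        assert set(stages["lasso"]) <= set(stages["multivariate"])

    def test_votes_bounded_by_fold_count(self, rng, labels100):
        df = _null_table(rng, 100, 15)
        rep = cv_feature_voting(df, labels100, SelectionConfig(fold_seed=1))
        assert all(0 <= v <= 5 for v in rep.voting_count.values())
        assert all(rep.voting_count.get(f, 0) >= 4 for f in rep.final_set)

    def test_planted_effects_reach_vote_threshold(self):
        """Three informative features at 1.5 SD separation among 200 nulls
        (n=150) all reach >= 4 votes in most replicates."""
        ok = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            y = np.r_[np.zeros(75), np.ones(75)].astype(int)
            df = _null_table(rng, 150, 200, prefix="n")
            for k in range(3):
                df[f"sig{k}"] = 1.5 * y + rng.standard_normal(150)
            rep = cv_feature_voting(df, y, SelectionConfig(fold_seed=seed))
            ok += all(rep.voting_count.get(f"sig{k}", 0) >= 4 for k in range(3))
        assert ok / reps >= 0.8

    def test_too_few_subjects_per_class_rejected(self, rng):
        y = np.r_[np.zeros(3), np.ones(7)].astype(int)
        with pytest.raises(DegenerateInputError):
            cv_feature_voting(_null_table(rng, 10, 3), y)

    def test_combined_set_is_union_of_single_model_sets(self, rng, labels100):
        t2 = _null_table(rng, 100, 6, prefix="t")
        adc = _null_table(rng, 100, 6, prefix="a")
        t2["sigT"] = labels100 + 0.3 * rng.standard_normal(100)
        adc["sigA"] = labels100 + 0.3 * rng.standard_normal(100)
        cfg = SelectionConfig(fold_seed=2)
        rt = cv_feature_voting(t2, labels100, cfg)
        ra = cv_feature_voting(adc, labels100, cfg)
        rc = combined_voting(t2, adc, labels100, rt, ra, cfg)
        expected = {f"t2w__{c}" for c in rt.final_set} | {f"adc__{c}" for c in ra.final_set}
        assert set(rc.final_set) == expected
        assert all(0 <= v <= 5 for v in rc.voting_count.values())
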