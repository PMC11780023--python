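import numpy as np
import pandas as pd
import pytest

from dlradiomics.selection import (
    _lambda_max,
    _path_fit,
    fuse_and_prune,
    icc_21,
    icc_filter,
    lasso_select,
    zscore,
)


def make_tables(rng, n=30, p=20, noise=0.0, repeat_noise=0.0):
    base = rng.normal(size=(n, p))
    cols = [f"f{i:02d}" for i in range(p)]
    r1 = pd.DataFrame(base, columns=cols)
    r2 = pd.DataFrame(base + noise * rng.normal(size=(n, p)), columns=cols)
    rr = pd.DataFrame(base + repeat_noise * rng.normal(size=(n, p)), columns=cols)
    return r1, r2, rr


class TestICC:
    def test_identical_readers_give_one(self, rng):
        r1, r2, rr = make_tables(rng)
        res = icc_filter(r1, r2, rr)
        assert np.allclose(res.inter_reader_icc, 1.0)
        assert np.allclose(res.intra_reader_icc, 1.0)
        assert res.retained.all()

    def test_independent_reader_near_zero(self, rng):
        n, p = 30, 100
        base = rng.normal(size=(n, p))
        indep = rng.normal(size=(n, p))
        cols = [f"f{i}" for i in range(p)]
        res = icc_filter(
            pd.DataFrame(base, columns=cols),
            pd.DataFrame(indep, columns=cols),
            pd.DataFrame(base, columns=cols),
        )
        assert abs(res.inter_reader_icc.mean()) < 0.15
        assert not res.retained.any() or res.retained.mean() < 0.1

    def test_both_thresholds_required(self, rng):
        # inter high but intra low -> rejected
        r1, r2, rr = make_tables(rng, noise=0.01, repeat_noise=5.0)
        res = icc_filter(r1, r2, rr)
        assert (res.inter_reader_icc > 0.8).all()
        assert not res.retained.any()

    def test_zero_variance_dropped_with_warning(self, rng):
        r1, r2, rr = make_tables(rng, n=12, p=3)
        for t in (r1, r2, rr):
            t["f00"] = 1.0
        with pytest.warns(UserWarning, match="undefined ICC"):
            res = icc_filter(r1, r2, rr)
        assert not res.retained["f00"]

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        ours = icc_21(data)[0]
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([0, 1], 12),
                "scores": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        )
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert np.isclose(ours, icc2, atol=1e-6)

    def test_too_few_cases(self, rng):
        r1, r2, rr = make_tables(rng, n=5)
        with pytest.raises(ValueError, match="at least 10"):
            icc_filter(r1, r2, rr)


class TestZscore:
    def test_sample_sd_convention(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _ = zscore(train)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_apply_uses_train_stats(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"a": [4.0]})
        _, tz = zscore(train, test)
        assert np.isclose(tz["a"].iloc[0], 2.0)

    def test_test_mean_need_not_be_zero(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=20)})
        test = pd.DataFrame({"a": rng.normal(loc=3.0, size=20)})
        _, tz = zscore(train, test)
        assert abs(tz["a"].mean()) > 0.5

    def test_no_leakage_from_test_rows(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=10)})
        t1 = pd.DataFrame({"a": rng.normal(size=5)})
        t2 = t1 * 100.0
        z1, a1 = zscore(train, t1)
        z2, _ = zscore(train, t2)
        assert np.allclose(z1["a"], z2["a"])

    def test_zero_variance_dropped(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=5), "b": np.ones(5)})
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = zscore(train)
        assert list(z.columns) == ["a"]


def planted_design(seed=0, n=200, p_noise=50):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    X = rng.standard_normal((n, p_noise + 3))
    for c in range(3):
        X[y == c, c] += 2.0
    cols = [f"f{i:02d}" for i in range(p_noise + 3)]
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return pd.DataFrame(X, columns=cols), y


class TestLasso:
    def test_zero_selection_at_lambda_max(self):
        X, y = planted_design()
        lam_max = _lambda_max(X.to_numpy(), y, 3)
        (W, _), = _path_fit(X.to_numpy(), y, 3, np.array([lam_max]))
        assert int((np.abs(W) > 1e-8).any(axis=1).sum()) == 0

    def test_planted_recovery(self):
        X, y = planted_design(seed=0)
        sel = lasso_select(X, y, seed=0)
        assert {"f00", "f01", "f02"} <= set(sel.selected_names)

    def test_one_se_is_sparser_than_min(self):
        X, y = planted_design(seed=1)
        sel = lasso_select(X, y, seed=1)
        assert sel.lambda_1se >= sel.lambda_min

    def test_deterministic(self):
        X, y = planted_design(seed=2)
        a = lasso_select(X, y, seed=3)
        b = lasso_select(X, y, seed=3)
        assert a.lambda_1se == b.lambda_1se
        assert a.selected_names == b.selected_names

    def test_matches_sklearn_at_fixed_lambda(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X, y = planted_design(seed=4, n=80, p_noise=10)
        lam = 0.05
        (W, b), = _path_fit(X.to_numpy(), y, 3, np.array([lam]))
        ref = sklearn_lm.LogisticRegression(
            solver="saga", l1_ratio=1.0, C=1.0 / (len(y) * lam),
            max_iter=20000, tol=1e-8,
        ).fit(X.to_numpy(), y)
        assert np.abs(W.T - ref.coef_).max() < 1e-3

    def test_class_starvation_rejected(self):
        X, y = planted_design(seed=5, n=20)
        y = np.array([0] * 16 + [1] * 2 + [2] * 2)
        with pytest.raises(ValueError, match="per class"):
            lasso_select(X, y)


class TestFusion:
    def test_duplicate_dropped(self, rng):
        a = rng.normal(size=100)
        table = pd.DataFrame({"rad_A": a, "deep_B": a, "deep_C": rng.normal(size=100)})
        fs = fuse_and_prune(["rad_A"], ["deep_B", "deep_C"], table)
        assert fs.members == ["rad_A", "deep_C"]
        assert fs.dropped_pairs[0][:2] == ("rad_A", "deep_B")

    def test_independent_columns_survive(self, rng):
        n = 500
        table = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"c{i}" for i in range(8)])
        fs = fuse_and_prune(["c0", "c1", "c2", "c3"], ["c4", "c5", "c6", "c7"], table)
        assert len(fs.members) == 8

    def test_correlation_chain_keeps_endpoints(self, rng):
        n = 2000
        a = rng.normal(size=n)
        c = 0.5 * a + np.sqrt(0.75) * rng.normal(size=n)
        b = a + c + 0.1 * rng.normal(size=n)  # rho(A,B), rho(B,C) high; rho(A,C) ~ 0.5
        table = pd.DataFrame({"A": a, "B": b, "C": c})
        fs = fuse_and_prune(["A", "B"], ["C"], table, rho_max=0.8)
        assert fs.members == ["A", "C"]

    def test_invariant_max_rho(self, rng):
        n = 120
        base = rng.normal(size=(n, 6))
        table = pd.DataFrame(
            np.column_stack([base, base[:, 0] * 0.98 + 0.02 * rng.normal(size=n)]),
            columns=["r0", "r1", "r2", "d0", "d1", "d2", "d3"],
        )
        fs = fuse_and_prune(["r0", "r1", "r2"], ["d0", "d1", "d2", "d3"], table)
        from scipy import stats

        rho = stats.spearmanr(table[fs.members]).statistic
        off = np.abs(np.asarray(rho) - np.eye(len(fs.members)))
        assert off.max() <= 0.9

    def test_overlapping_namespaces_rejected(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        with pytest.raises(ValueError, match="overlap"):
            fuse_and_prune(["x"], ["x"], table)
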