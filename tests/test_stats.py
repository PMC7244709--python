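"""Inferential core: subsetting, OLS/AICc, hierarchical partitioning,
multimodel inference and the spatial statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from macrogen import stats
from macrogen.stats import (CollinearityError, DegenerateInputError,
                            NoValidModelsError, SpatialWeights,
                            TooManyVariablesError, aicc_from_llf,
                            build_weights, data_rich_subset,
                            hierarchical_partitioning, hp_significance,
                            iterative_hp, modified_ttest, morans_i,
                            multimodel_inference, ols_fit, sqrt_transform)


def random_design(rng, n=50, p=4, signal=None):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    y = rng.normal(size=n)
    if signal:
        for c, b in signal.items():
            y = y + b * X[c].to_numpy()
    return y, X


class TestDataRichSubset:
    def setup_method(self):
        self.cells = pd.DataFrame(
            {
                "unit_id": list("abcd"),
                "coverage": [0.08, 0.01, 0.01, 0.07],
                "n_sequences": [3, 500, 3, 3],
                "gd": [0.1] * 4,
            }
        )

    def test_union_of_coverage_and_count_rules(self):
        out = data_rich_subset(self.cells, min_coverage=0.07,
                               count_threshold=100.0)
        assert set(out["unit_id"]) == {"a", "b", "d"}

    def test_default_threshold_is_sd_of_counts(self):
        sd = self.cells["n_sequences"].std(ddof=1)
        out = data_rich_subset(self.cells, min_coverage=0.07)
        expect = data_rich_subset(self.cells, min_coverage=0.07,
                                  count_threshold=float(sd))
        assert list(out["unit_id"]) == list(expect["unit_id"])


class TestSqrtTransform:
    def test_values(self):
        assert sqrt_transform([0.0, 0.04]) == pytest.approx([0.0, 0.2])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform([-0.1])


class TestOlsFit:
    def test_exact_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"].to_numpy() - 1.0 * X["b"].to_numpy()
        fit = ols_fit(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.resid, 0.0, atol=1e-10)
        assert np.isfinite(fit.aicc)

    def test_aicc_matches_closed_form(self, rng):
        # n=10, one slope -> K=3; compare against direct formula from RSS
        n = 10
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = 0.5 * X["a"].to_numpy() + rng.normal(size=n)
        fit = ols_fit(y, X)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), X["a"]]), y, rcond=None)
        rss = float(((y - np.column_stack([np.ones(n), X["a"]]) @ beta) ** 2).sum())
        k = 3
        llf = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1)
        want = -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(want, abs=1e-10)

    def test_singular_design_raises(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(CollinearityError):
            ols_fit(rng.normal(size=20), X)

    def test_null_slope_confidence_coverage(self, rng):
        # with a pure-noise predictor the slope CI covers 0 at ~nominal rate
        import statsmodels.api as sm

        miss = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            res = sm.OLS(y, sm.add_constant(x)).fit()
            lo, hi = res.conf_int()[1]
            miss += not (lo <= 0.0 <= hi)
        assert miss / reps < 0.07

    def test_aicc_guard_small_n(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            ols_fit(rng.normal(size=5), X)


class TestHierarchicalPartitioning:
    def test_single_predictor_identity(self, rng):
        y, X = random_design(rng, p=1, signal={"x0": 1.0})
        hp = hierarchical_partitioning(y, X)
        fit = ols_fit(y, X)
        assert hp.table["ic_raw"].iloc[0] == pytest.approx(fit.r2)
        assert hp.table["joint_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_predictors_have_zero_joint(self):
        n = 32
        t = np.arange(n)
        X = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
        })
        y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy()
        hp = hierarchical_partitioning(y, X)
        r2a = ols_fit(y, X, ["a"]).r2
        r2b = ols_fit(y, X, ["b"]).r2
        assert hp.table.loc["a", "ic_raw"] == pytest.approx(r2a, abs=1e-10)
        assert hp.table.loc["b", "ic_raw"] == pytest.approx(r2b, abs=1e-10)
        assert np.allclose(hp.table["joint_raw"], 0.0, atol=1e-10)

    def test_ic_sums_to_full_model_r2(self, rng):
        for _ in range(30):
            p = int(rng.integers(2, 9))
            y, X = random_design(rng, n=40, p=p,
                                 signal={"x0": 1.0, f"x{p-1}": 0.5})
            hp = hierarchical_partitioning(y, X)
            assert hp.table["ic_raw"].sum() == pytest.approx(
                hp.r2_full, abs=1e-10)

    def test_matches_all_orderings_brute_force(self, rng):
        def brute(y, X):
            cols = list(X.columns)

            def r2(sub):
                return ols_fit(y, X, sub).r2 if sub else 0.0

            ics = dict.fromkeys(cols, 0.0)
            perms = list(itertools.permutations(cols))
            for perm in perms:
                sofar = []
                for c in perm:
                    ics[c] += r2(sofar + [c]) - r2(sofar)
                    sofar.append(c)
            return {c: v / len(perms) for c, v in ics.items()}

        for p in (2, 3, 4, 5):
            y, X = random_design(rng, n=30, p=p, signal={"x0": 0.8})
            hp = hierarchical_partitioning(y, X)
            want = brute(y, X)
            for c in X.columns:
                assert hp.table.loc[c, "ic_raw"] == pytest.approx(
                    want[c], abs=1e-10)

    def test_too_many_variables(self, rng):
        y, X = random_design(rng, n=40, p=13)
        with pytest.raises(TooManyVariablesError):
            hierarchical_partitioning(y, X)

    def test_ic_percentages_sum_to_100(self, rng):
        y, X = random_design(rng, p=5, signal={"x1": 1.0})
        hp = hierarchical_partitioning(y, X)
        assert hp.table["ic_pct"].sum() == pytest.approx(100.0)


class TestHpSignificance:
    def test_signal_flagged_noise_not_usually(self, rng):
        hits_signal = 0
        hits_noise = 0
        reps = 30
        for i in range(reps):
            y, X = random_design(rng, n=60, p=2, signal={"x0": 1.5})
            sig = hp_significance(y, X, n_rand=200, seed=int(rng.integers(2**31)))
            hits_signal += bool(sig.loc["x0", "significant"])
            hits_noise += bool(sig.loc["x1", "significant"])
        assert hits_signal == reps
        assert hits_noise <= reps * 0.25

    def test_deterministic_given_seed(self, rng):
        y, X = random_design(rng, n=40, p=3, signal={"x0": 1.0})
        a = hp_significance(y, X, n_rand=100, seed=11)
        b = hp_significance(y, X, n_rand=100, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestIterativeHp:
    def test_all_significant_is_identity(self, rng):
        y, X = random_design(rng, n=80, p=2,
                             signal={"x0": 2.0, "x1": 2.0})
        retained, hp, history = iterative_hp(y, X, n_rand=200, seed=0)
        assert retained == ["x0", "x1"]
        assert len(history) == 1

    def test_recovers_single_true_variable(self, rng):
        ok = 0
        for i in range(10):
            y, X = random_design(rng, n=100, p=2, signal={"x0": 2.0})
            retained, *_ = iterative_hp(y, X, n_rand=200, seed=i)
            ok += retained == ["x0"]
        assert ok >= 8

    def test_deterministic_given_seed(self, rng):
        y, X = random_design(rng, n=60, p=4, signal={"x0": 1.0})
        r1, _, _ = iterative_hp(y, X, n_rand=100, seed=3)
        r2, _, _ = iterative_hp(y, X, n_rand=100, seed=3)
        assert r1 == r2


class TestMultimodelInference:
    def test_single_candidate_gets_weight_one(self, rng):
        y, X = random_design(rng, n=50, p=1, signal={"x0": 1.0})
        ms = multimodel_inference(y, X, ["x0"])
        assert ms.table["weight"].iloc[0] == pytest.approx(1.0)
        assert ms.saw["x0"] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, rng):
        y, X = random_design(rng, n=60, p=3, signal={"x0": 1.0, "x1": 0.3})
        ms = multimodel_inference(y, X)
        assert ms.table["weight"].sum() == pytest.approx(1.0)
        assert ms.table["delta_aicc"].iloc[0] == 0.0

    def test_equal_aicc_symmetry(self, rng):
        # duplicate-strength predictors by symmetry: y built from x0+x1 with
        # exchangeable noise gives near-equal AICc; construct exact symmetry
        n = 40
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": -x + 0.0})
        # models {a} and {b} are identical fits -> equal AICc -> 0.5/0.5
        y = x + rng.normal(size=n) * 0.5
        ms = multimodel_inference(y, X, ["a", "b"], r_max=0.99)
        singles = ms.table[ms.table["variables"].map(len) == 1]
        assert singles["weight"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_collinear_pairs_excluded(self, rng):
        n = 60
        a = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": a + 0.1 * rng.normal(size=n),
                          "c": rng.normal(size=n)})
        y = a + rng.normal(size=n)
        ms = multimodel_inference(y, X)
        for vars_ in ms.table["variables"]:
            assert not {"a", "b"} <= set(vars_)

    def test_variable_in_every_model_has_saw_one(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 2.0 * X["a"].to_numpy() + 0.1 * rng.normal(size=n)
        ms = multimodel_inference(y, X)
        assert all("a" in v for v in ms.table["variables"])
        assert ms.saw["a"] == pytest.approx(1.0)

    def test_delta_aicc_threshold_strict(self, rng):
        y, X = random_design(rng, n=60, p=4, signal={"x0": 2.0})
        ms = multimodel_inference(y, X, delta_max=5.0)
        assert (ms.table["delta_aicc"] <= 5.0).all()

    def test_empty_candidates_raise(self, rng):
        y, X = random_design(rng, n=30, p=1)
        with pytest.raises(NoValidModelsError):
            multimodel_inference(y, X, [])


class TestBuildWeights:
    def test_knn_collinear_points(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        w = build_weights(coords=pts, scheme="knn", k=4)
        for i in range(5):
            assert set(w.neighbors[i]) == set(range(5)) - {i}
        assert np.allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)

    def test_knn_requires_enough_units(self):
        with pytest.raises(ValueError):
            build_weights(coords=np.zeros((3, 2)), scheme="knn", k=4)

    def test_contiguity_shared_edge_and_island(self):
        from shapely.geometry import box

        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(5, 5, 6, 6)]
        w = build_weights(polygons=polys, scheme="contiguity")
        assert list(w.neighbors[0]) == [1]
        assert list(w.neighbors[1]) == [0]
        assert w.islands == [2]
        assert w.W[2].nnz == 0

    def test_no_self_neighbours(self):
        pts = np.random.default_rng(0).normal(size=(12, 2))
        w = build_weights(coords=pts, scheme="knn", k=4)
        for i, nb in enumerate(w.neighbors):
            assert i not in set(nb)
            assert len(nb) == 4


def rook_grid_weights(nside):
    idx = {(i, j): k for k, (i, j) in enumerate(
        (i, j) for i in range(nside) for j in range(nside))}
    rows, cols, vals, neigh = [], [], [], []
    for (i, j), k in idx.items():
        nb = [idx[t] for t in [(i+1, j), (i-1, j), (i, j+1), (i, j-1)]
              if t in idx]
        neigh.append(np.array(nb))
        rows += [k] * len(nb)
        cols += nb
        vals += [1.0 / len(nb)] * len(nb)
    n = nside * nside
    return SpatialWeights(n=n, neighbors=neigh,
                          W=sp.csr_matrix((vals, (rows, cols)), shape=(n, n)))


class TestMoransI:
    def test_null_expectation(self, rng):
        w = rook_grid_weights(5)
        out = morans_i(rng.normal(size=25), w, n_sims=99, seed=0)
        assert out["EI"] == pytest.approx(-1.0 / 24)

    def test_checkerboard_is_minus_one(self):
        w = rook_grid_weights(6)
        vals = np.array([(i + j) % 2 for i in range(6) for j in range(6)],
                        dtype=float) * 2 - 1
        out = morans_i(vals, w, n_sims=99, seed=1)
        assert out["I"] == pytest.approx(-1.0, abs=1e-12)
        assert out["p"] <= 0.05

    def test_constant_values_degenerate(self):
        w = rook_grid_weights(4)
        with pytest.raises(DegenerateInputError):
            morans_i(np.ones(16), w, n_sims=9, seed=0)

    def test_smooth_gradient_detected_positive(self, rng):
        w = rook_grid_weights(6)
        vals = np.array([i for i in range(6) for j in range(6)], dtype=float)
        out = morans_i(vals + 0.1 * rng.normal(size=36), w,
                       n_sims=999, seed=2)
        assert out["I"] > 0.5
        assert out["p"] < 0.01

    def test_deterministic_given_seed(self, rng):
        w = rook_grid_weights(5)
        v = rng.normal(size=25)
        assert morans_i(v, w, 99, seed=5) == morans_i(v, w, 99, seed=5)


class TestModifiedTtest:
    def test_perfect_association(self, rng):
        pts = rng.uniform(0, 10, size=(20, 2))
        x = rng.normal(size=20)
        out = modified_ttest(x, 2.0 * x + 1.0, pts)
        assert out["r"] == pytest.approx(1.0)
        assert out["p"] < 1e-10

    def test_effective_sample_size_near_n_without_autocorrelation(self, rng):
        ess = []
        for _ in range(50):
            pts = rng.uniform(0, 100, size=(40, 2))
            ess.append(modified_ttest(rng.normal(size=40),
                                      rng.normal(size=40), pts)["ess"])
        med = np.median(ess)
        assert 25 <= med <= 55     # close to n = 40

    def test_ess_deflated_under_shared_gradient(self, rng):
        deflated = 0
        reps = 40
        for _ in range(reps):
            pts = rng.uniform(0, 10, size=(40, 2))
            g = pts[:, 0]
            x = g + 0.3 * rng.normal(size=40)
            y = g + 0.3 * rng.normal(size=40)
            out = modified_ttest(x, y, pts)
            deflated += out["ess"] < 40
        assert deflated >= 0.9 * reps

    def test_zero_variance_rejected(self, rng):
        pts = rng.uniform(0, 1, size=(15, 2))
        with pytest.raises(DegenerateInputError):
            modified_ttest(np.ones(15), rng.normal(size=15), pts)


def test_aicc_formula_direct():
    # K=3, n=10: penalty 2K + 2K(K+1)/(n-K-1) = 6 + 4
    assert aicc_from_llf(0.0, 10, 3) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        aicc_from_llf(0.0, 4, 3)
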