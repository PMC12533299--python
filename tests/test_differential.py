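"""PLS-DA, VIP, permutation testing, Mann-Whitney, fold change, volcano."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctcmet import (fit_plsda, fold_changes, mann_whitney_u, permutation_test,
                    vip_scores, volcano_screen)
from ctcmet.differential import DifferentialError


def _toy_xy(n=40, J=10, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2))
    X = rng.normal(0, 1, (n, J))
    X[y == "b", :3] += effect
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return X, y


class TestPLSDA:
    def test_perfect_predictor_gives_r2y_one(self):
        """y duplicated as a feature (other features orthogonal to it):
        one component explains all of y."""
        rng = np.random.default_rng(1)
        n = 40
        y = np.array(["a", "b"] * (n // 2))
        yc = (y == "b").astype(float)
        yc = yc - yc.mean()
        noise = rng.normal(0, 1, (n, 3))
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)  # orthogonalize vs y
        X = np.column_stack([yc, noise])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        model = fit_plsda(X, y, n_components=1)
        assert model.r2y == pytest.approx(1.0, abs=1e-10)

    def test_single_feature_closed_form(self):
        """With one predictor the weight vector is +-1 and the scores are
        the centered feature itself."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = np.where(x + rng.normal(0, 0.5, 30) > 0, "hi", "lo")
        X = ((x - x.mean()) / x.std(ddof=1)).reshape(-1, 1)
        model = fit_plsda(X, y, n_components=1, cv_folds=5)
        assert abs(model.weights[0, 0]) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            model.scores[:, 0], model.weights[0, 0] * (X[:, 0] - X[:, 0].mean()),
            atol=1e-10)

    def test_scores_orthogonal_and_r2y_monotone(self):
        X, y = _toy_xy(n=60, J=20, seed=3, effect=1.0)
        m1 = fit_plsda(X, y, n_components=1)
        m3 = fit_plsda(X, y, n_components=3)
        G = m3.scores.T @ m3.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        assert m3.r2y >= m1.r2y - 1e-12

    def test_zero_variance_feature_named(self):
        X, y = _toy_xy()
        X[:, 4] = 2.0
        with pytest.raises(DifferentialError, match="x4"):
            fit_plsda(X, y)

    def test_class_size_vs_folds_checked(self):
        X, y = _toy_xy(n=10)
        with pytest.raises(DifferentialError, match="cv_folds"):
            fit_plsda(X, y, cv_folds=7)

    def test_agrees_with_reference_pls_weights(self):
        """First-component weights match an independent PLS implementation
        (sklearn NIPALS) up to sign."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = _toy_xy(n=50, J=8, seed=4, effect=0.8)
        model = fit_plsda(X, y, n_components=2, cv_folds=5)
        ref = PLSRegression(n_components=2, scale=False).fit(
            X, (y == "b").astype(float))
        for a in range(2):
            w, wr = model.weights[:, a], ref.x_weights_[:, a]
            sign = np.sign(w @ wr)
            np.testing.assert_allclose(w, sign * wr, atol=1e-8)


class TestVIP:
    def test_formula_collapses_for_unit_weight(self):
        X, y = _toy_xy(n=20, J=2, seed=5)
        X[:, 0] = (y == "b").astype(float)
        X[:, 1] = np.random.default_rng(1).normal(0, 1, 20)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        # after one component driven entirely by feature 0, VIPs -> (sqrt2, 0)
        model = fit_plsda(X, y, n_components=1, cv_folds=5)
        vip = vip_scores(model)
        assert vip.iloc[0] == pytest.approx(np.sqrt(2), abs=0.05)

    def test_mean_squared_vip_is_one(self, two_group_screen):
        *_, table, model = two_group_screen
        vip = vip_scores(model)
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_formula(self):
        """VIP equals an independently coded evaluation of
        sqrt(J * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)."""
        for seed in range(5):
            X, y = _toy_xy(n=30, J=7, seed=seed, effect=0.6)
            model = fit_plsda(X, y, n_components=3, cv_folds=5)
            vip = vip_scores(model).to_numpy()
            J, A = model.weights.shape
            ssy = model.ssy_per_component
            brute = np.empty(J)
            for j in range(J):
                acc = 0.0
                for a in range(A):
                    wa = model.weights[:, a]
                    acc += ssy[a] * (wa[j] / np.linalg.norm(wa)) ** 2
                brute[j] = np.sqrt(J * acc / ssy.sum())
            np.testing.assert_allclose(vip, brute, atol=1e-10)


class TestPermutation:
    def test_extreme_observed_gives_minimal_p(self):
        X, y = _toy_xy(n=30, J=6, seed=6, effect=3.0)
        rep = permutation_test(X, y, n_permutations=50, cv_folds=5, seed=0)
        assert rep.p_q2 == pytest.approx(1 / 51)
        assert rep.p_r2y >= 1 / 51

    def test_fixed_seed_reproducible(self):
        X, y = _toy_xy(n=24, J=5, seed=7, effect=1.0)
        r1 = permutation_test(X, y, n_permutations=30, cv_folds=4, seed=9)
        r2 = permutation_test(X, y, n_permutations=30, cv_folds=4, seed=9)
        np.testing.assert_array_equal(r1.permuted_q2, r2.permuted_q2)
        assert r1.p_q2 == r2.p_q2

    def test_few_permutations_warn(self):
        X, y = _toy_xy(n=24, J=4, seed=8)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(X, y, n_permutations=10, cv_folds=4, seed=0)


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_matches_full_enumeration(self):
        """Exact two-sided p equals direct enumeration of all C(n+m, n)
        rank arrangements of the pooled sample."""
        rng = np.random.default_rng(10)
        for _ in range(6):
            nx, ny = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.normal(0, 1, nx)
            y = rng.normal(0, 1, ny)
            u_obs, p = mann_whitney_u(x, y)
            pooled = np.concatenate([x, y])
            n = pooled.size
            u_all = []
            for pos in itertools.combinations(range(n), nx):
                ranks = np.argsort(np.argsort(pooled)) + 1
                rx = ranks[list(pos)].sum()
                u_all.append(rx - nx * (nx + 1) / 2)
            u_all = np.asarray(u_all)
            mu = nx * ny / 2
            p_exact = np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12)
            assert p == pytest.approx(p_exact, abs=1e-12)

    def test_exact_vs_normal_approx_close_at_n8(self):
        rng = np.random.default_rng(11)
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 8)
            _, p_exact = mann_whitney_u(x, y)
            p_norm = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.02


class TestFoldChangeAndVolcano:
    def test_fold_change_example(self):
        data = pd.DataFrame({"m": [3.0, 3.0, 1.0, 1.0]}, index=list("abcd"))
        fc = fold_changes(data, ["A", "A", "B", "B"], "A", "B")
        assert fc.loc["m", "fc"] == pytest.approx(3.0)
        assert fc.loc["m", "log2fc"] == pytest.approx(np.log2(3), abs=1e-9)
        assert fc.loc["m", "direction"] == "up"

    def test_equal_means_fail_criterion(self):
        data = pd.DataFrame({"m": [2.0, 2.0, 2.0, 2.0]}, index=list("abcd"))
        fc = fold_changes(data, ["A", "A", "B", "B"], "A", "B")
        table = volcano_screen(
            pd.Series([1.5], index=["m"]), fc, pd.Series([0.01], index=["m"]))
        assert not table["passes_volcano"].iloc[0]

    def test_volcano_rules_hand_checked(self):
        idx = ["m1", "m2", "m3"]
        vip = pd.Series([1.2, 0.8, 1.5], index=idx)
        fc = pd.DataFrame({"fc": [2.0, 3.0, 1.2],
                           "log2fc": np.log2([2.0, 3.0, 1.2]),
                           "direction": ["up"] * 3}, index=idx)
        p = pd.Series([0.01, 0.001, 0.01], index=idx)
        table = volcano_screen(vip, fc, p)
        assert table["passes_volcano"].tolist() == [True, False, False]
        assert table["passes_vip"].tolist() == [True, False, True]

    def test_down_regulation_passes_fc_criterion(self):
        idx = ["m"]
        table = volcano_screen(
            pd.Series([1.1], index=idx),
            pd.DataFrame({"fc": [0.5], "log2fc": [-1.0],
                          "direction": ["down"]}, index=idx),
            pd.Series([0.01], index=idx))
        assert table["passes_volcano"].iloc[0]

    def test_permissive_thresholds_pass_everything(self, two_group_screen):
        *_, table, model = two_group_screen
        vip = table["vip"]
        fc = table[["fc", "log2fc", "direction"]]
        out = volcano_screen(vip, fc, table["p_value"], vip_threshold=0.0,
                             fc_threshold=1.0, p_threshold=1.0)
        assert out["passes_volcano"].all()

    def test_survivors_invariant_to_ordering(self, two_group_screen):
        *_, table, model = two_group_screen
        perm = table.sample(frac=1, random_state=0)
        out = volcano_screen(perm["vip"], perm[["fc", "log2fc", "direction"]],
                             perm["p_value"])
        survivors = set(out.index[out["passes_volcano"]])
        assert survivors == set(table.index[table["passes_volcano"]])

    def test_volcano_implies_vip(self, two_group_screen):
        *_, table, model = two_group_screen
        assert (table["passes_vip"] | ~table["passes_volcano"]).all()

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(DifferentialError, match="differ"):
            volcano_screen(
                pd.Series([1.0], index=["a"]),
                pd.DataFrame({"fc": [2.0], "log2fc": [1.0],
                              "direction": ["up"]}, index=["b"]),
                pd.Series([0.01], index=["a"]))


def test_screen_recovers_signatures(two_group_screen):
    """Default two-population conditions: the cascade keeps most true
    signature metabolites and few null ones."""
    cfg, matrix, truth, table, model = two_group_screen
    true_set = set(truth.differential.index[truth.differential.any(axis=1)])
    survivors = set(table.index[table["passes_volcano"]])
    tp = len(survivors & true_set)
    sens = tp / len(true_set)
    spec = 1 - (len(survivors) - tp) / (len(table) - len(true_set))
    assert sens >= 0.7
    assert spec >= 0.95
    assert model.r2y > 0.5 and model.q2 > 0.3
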