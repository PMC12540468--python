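"""OPLS-DA fitting, VIP scores, permutation diagnostics, differential calls."""

import numpy as np
import pytest

from spotmatch.chemstats import (
    GroupDesign,
    differential_metabolites,
    fit_oplsda,
    permutation_test,
    vip_scores,
)
from spotmatch.synthetic import SyntheticScenario, generate_group_study


def design(n_case, n_ctrl):
    return GroupDesign(
        np.array(["case"] * n_case + ["ctrl"] * n_ctrl, dtype=object), "case", "ctrl"
    )


def signal_data(seed=1):
    sc = SyntheticScenario(seed=seed)
    case, ctrl, truth = generate_group_study(sc)
    x = np.vstack([case.intensity, ctrl.intensity])
    return x, design(len(case), len(ctrl)), truth, case.mz_values


def null_data(seed, n=30, p=50):
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(2.0, 0.3, (2 * n, p))), design(n, n)


class TestFitOplsda:
    def test_separated_groups_have_high_q2(self):
        x, d, _, _ = signal_data()
        m = fit_oplsda(x, d, seed=1)
        assert m.Q2_cum > 0.5
        assert 0 <= m.R2X_cum <= 1 and 0 <= m.R2Y_cum <= 1

    def test_null_labels_have_low_q2(self):
        x, d = null_data(2)
        m = fit_oplsda(x, d, seed=2)
        assert m.Q2_cum <= 0.1

    def test_single_informative_metabolite_zero_noise(self):
        y = np.array([1.0] * 10 + [-1.0] * 10)
        x = np.column_stack([y * 2.0 + 5.0])
        m = fit_oplsda(x, design(10, 10), n_orth=1, seed=0)
        assert m.R2Y_cum == pytest.approx(1.0, abs=1e-6)

    def test_scores_orthogonal(self):
        x, d, _, _ = signal_data()
        m = fit_oplsda(x, d, n_orth=2, seed=3)
        for k in range(m.n_orth):
            inner = m.t_pred @ m.t_orth[:, k]
            assert abs(inner) / (np.linalg.norm(m.t_pred) *
                                 np.linalg.norm(m.t_orth[:, k])) < 1e-8

    def test_constant_columns_dropped_with_warning(self):
        x, d = null_data(3)
        x[:, 5] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_oplsda(x, d, seed=0)
        assert 5 not in m.kept_columns

    def test_fewer_observations_than_folds(self):
        x = np.random.default_rng(0).uniform(1, 2, (6, 4))
        with pytest.raises(ValueError, match="folds"):
            fit_oplsda(x, design(3, 3), cv_folds=7)

    def test_deterministic_given_seed(self):
        x, d, _, _ = signal_data()
        m1 = fit_oplsda(x, d, seed=9)
        m2 = fit_oplsda(x, d, seed=9)
        assert m1.Q2_cum == m2.Q2_cum and m1.R2X_cum == m2.R2X_cum

    def test_matches_pls_when_no_orthogonal_components(self):
        # with zero orthogonal components the predictive scores coincide
        # with the first component of an ordinary PLS fit
        from sklearn.cross_decomposition import PLSRegression

        x, d, _, _ = signal_data()
        m = fit_oplsda(x, d, n_orth=0, seed=0)
        xc = (x - x.mean(0)) / x.std(0, ddof=1)
        pls = PLSRegression(n_components=1, scale=False).fit(xc, d.y - d.y.mean())
        t_ref = pls.x_scores_[:, 0]
        corr = np.corrcoef(m.t_pred, t_ref)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)


class TestVip:
    def test_single_metabolite_vip_is_one(self):
        y = np.array([1.0] * 5 + [-1.0] * 5)
        x = np.column_stack([y + np.random.default_rng(0).normal(0, 0.1, 10)])
        m = fit_oplsda(x, design(5, 5), cv_folds=5, seed=0)
        assert vip_scores(m)[0] == pytest.approx(1.0, abs=1e-9)

    def test_mean_squared_vip_is_one(self):
        for seed in (1, 2, 3):
            x, d, _, _ = signal_data(seed)
            m = fit_oplsda(x, d, seed=seed)
            vip = vip_scores(m)
            assert (vip**2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_exchangeable_metabolites_all_vip_one(self):
        # identical duplicated columns contribute symmetrically
        y = np.array([1.0] * 8 + [-1.0] * 8)
        rng = np.random.default_rng(4)
        col = y + rng.normal(0, 0.2, 16)
        x = np.column_stack([col, col, col])
        m = fit_oplsda(x, design(8, 8), cv_folds=4, seed=0)
        np.testing.assert_allclose(vip_scores(m), 1.0, atol=1e-9)

    def test_informative_metabolites_rank_top(self):
        hits = 0
        for seed in range(100):
            x, d, truth, _ = signal_data(seed)
            m = fit_oplsda(x, d, seed=seed)
            vip = vip_scores(m, n_variables=x.shape[1])
            top5 = set(np.argsort(vip)[-5:].tolist())
            if top5 == set(truth["informative_indices"].tolist()):
                hits += 1
        assert hits >= 95


class TestPermutation:
    def test_signal_data_beats_all_permutations(self):
        x, d, _, _ = signal_data(5)
        q2, perm, p = permutation_test(x, d, n_perm=50, seed=5)
        assert np.median(perm) < 0
        assert (perm >= q2).sum() == 0
        assert p == pytest.approx(1 / 51)

    def test_null_data_not_significant(self):
        ok = 0
        for seed in range(10):
            x, d = null_data(seed + 100, n=15, p=20)
            _, _, p = permutation_test(x, d, n_perm=39, seed=seed)
            if p > 0.05:
                ok += 1
        assert ok >= 9

    def test_zero_permutations_rejected(self):
        x, d = null_data(6)
        with pytest.raises(ValueError):
            permutation_test(x, d, n_perm=0)

    def test_small_n_perm_warns(self):
        x, d = null_data(7, n=10, p=5)
        with pytest.warns(UserWarning, match="small"):
            permutation_test(x, d, n_perm=5, seed=0)


class TestDifferential:
    def test_identical_groups_yield_no_calls(self):
        rng = np.random.default_rng(8)
        block = rng.uniform(1, 2, (30, 20))
        x = np.vstack([block, block])
        table = differential_metabolites(x, design(30, 30), seed=0)
        assert table["significant"].sum() == 0

    def test_planted_metabolites_recovered(self):
        x, d, truth, mz = signal_data(1)
        table = differential_metabolites(x, d, mz_values=mz, seed=1)
        called = set(table.loc[table["significant"], "mz"])
        assert set(truth["informative_mz"]) <= called
        assert len(called) - len(truth["informative_mz"]) <= 3

    def test_results_sorted_by_vip(self):
        x, d, _, mz = signal_data(2)
        table = differential_metabolites(x, d, mz_values=mz, seed=2)
        assert (np.diff(table["VIP"]) <= 1e-12).all()

    def test_vip_boundary_is_strict(self):
        x, d, _, mz = signal_data(3)
        table = differential_metabolites(x, d, mz_values=mz, seed=3)
        at_or_below = table["VIP"] <= 1.0
        assert not (table.loc[at_or_below, "significant"]).any()

    def test_zero_variance_metabolite_noted_not_called(self):
        x, d = null_data(9)
        x[:, 0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            table = differential_metabolites(x, d, seed=0)
        row = table[table["mz"] == 0.0].iloc[0]
        assert row["note"] == "zero_variance" and not row["significant"]

    def test_wilcoxon_option(self):
        x, d, truth, mz = signal_data(4)
        table = differential_metabolites(x, d, mz_values=mz, test="wilcoxon", seed=4)
        called = set(table.loc[table["significant"], "mz"])
        assert set(truth["informative_mz"]) <= called

    def test_null_false_call_rate_controlled(self):
        # zero-effect generator run: the level check of the VIP & p conjunction
        rates = []
        for seed in range(100):
            sc = SyntheticScenario(seed=seed + 500, effect_sd_units=0.0)
            case, ctrl, _ = generate_group_study(sc)
            x = np.vstack([case.intensity, ctrl.intensity])
            table = differential_metabolites(x, design(len(case), len(ctrl)),
                                             seed=seed)
            rates.append(table["significant"].mean())
        assert np.mean(rates) <= 0.05
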