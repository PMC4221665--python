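import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphovar.catalog import TraitTable, build_catalog
from morphovar.zscore import (
    fit_strain_effect,
    normalize_cv,
    reference_replicate_zscores,
    zscore_matrix,
)


def _cv_table(mean, cv, extra=None):
    n = len(mean)
    data = {
        "strain_id": [f"s{i}" for i in range(n)],
        "group": ["wildtype"] * n,
        "replicate_index": list(range(1, n + 1)),
        "C101_A": np.asarray(mean, float),
        "C102_A": np.ones(n),
        "CCV101_A": np.asarray(cv, float),
    }
    if extra:
        data.update(extra)
    return TraitTable(pd.DataFrame(data))


CATALOG_CV = build_catalog(n_gamma=2, n_beta=0, n_binomial=0, n_cv=1)


def _tricube_local_linear(y, x, frac):
    """Brute-force locally weighted linear regression (no robustness pass)."""
    n = len(x)
    k = max(2, int(np.ceil(frac * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d)[:k]
        h = d[idx].max()
        w = (1 - np.clip(d[idx] / h, 0, 1) ** 3) ** 3
        X = np.column_stack([np.ones(k), x[idx] - x[i]])
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, X.T @ (w * y[idx]))
        out[i] = beta[0]
    return out


class TestNormalizeCV:
    def test_constant_cv_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        t = _cv_table(rng.uniform(1, 10, 40), np.full(40, 0.3))
        out = normalize_cv(t, CATALOG_CV)
        assert np.abs(out.values["CCV101_A"]).max() < 1e-6

    def test_exact_smooth_trend_fully_removed(self):
        """Noiseless CV that is a smooth monotone function of the mean."""
        rng = np.random.default_rng(1)
        m = rng.uniform(1, 10, 60)
        t = _cv_table(m, 0.5 - 0.02 * m)
        out = normalize_cv(t, CATALOG_CV)
        assert np.abs(out.values["CCV101_A"]).max() < 1e-3

    def test_matches_local_linear_oracle(self):
        """Residuals agree with a brute-force tricube local-linear fit."""
        rng = np.random.default_rng(2)
        m = rng.uniform(1, 10, 50)
        cv = 0.5 / np.sqrt(m) + 0.01 * rng.standard_normal(50)
        t = _cv_table(m, cv)
        out = normalize_cv(t, CATALOG_CV, iterations=0)
        oracle = cv - _tricube_local_linear(cv, m, 0.4)
        assert np.abs(out.values["CCV101_A"].to_numpy() - oracle).max() < 1e-8

    def test_default_span_is_0_4(self):
        assert inspect.signature(normalize_cv).parameters["span"].default == 0.4

    def test_missing_partner_column_names_both_ids(self):
        t = _cv_table(np.ones(5), np.ones(5))
        t.values = t.values.drop(columns=["C101_A"])
        with pytest.raises(KeyError, match="CCV101_A.*C101_A"):
            normalize_cv(t, CATALOG_CV)


class TestFitStrainEffect:
    def test_no_effect_when_groups_identical(self):
        # identical constants plus symmetric machine-scale jitter, so the
        # group means coincide exactly and the fit is identifiable
        jit = 1e-9
        ref = np.array([5.0 - jit, 5.0 + jit] * 3 + [5.0])
        stn = np.array([5.0 - jit, 5.0 + jit])
        fit = fit_strain_effect(ref, stn, "gaussian_cv")
        assert abs(fit.beta1) < 1e-6 and abs(fit.z) < 0.1

    def test_quasibinomial_matches_irls_oracle(self):
        """Wald z equals an independently written IRLS quasi-binomial fit."""
        y = np.array([50.0, 52, 48, 100])
        n = np.array([200.0, 200, 200, 200])
        x = np.array([0.0, 0, 0, 1])
        X = np.column_stack([np.ones(4), x])
        beta = np.zeros(2)
        for _ in range(200):
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            W = n * mu * (1 - mu)
            work = eta + (y - n * mu) / W
            new = np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (W * work))
            if np.max(np.abs(new - beta)) < 1e-13:
                beta = new
                break
            beta = new
        mu = 1 / (1 + np.exp(-(X @ beta)))
        phi = ((y - n * mu) ** 2 / (n * mu * (1 - mu))).sum() / (len(y) - 2)
        cov = phi * np.linalg.inv(X.T @ (X * (n * mu * (1 - mu))[:, None]))
        z_oracle = beta[1] / np.sqrt(cov[1, 1])

        fit = fit_strain_effect([50, 52, 48], [100], "binomial_od", [200] * 3, [200])
        assert fit.converged
        assert abs(fit.z - z_oracle) < 1e-4

    def test_gaussian_equals_pooled_t_statistic(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.4, 1, 8)
        fit = fit_strain_effect(a, b, "gaussian_cv")
        t, _ = stats.ttest_ind(b, a)
        assert abs(fit.z - t) < 1e-6

    def test_gamma_z_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        ref, stn = rng.gamma(20, 0.05, 12), rng.gamma(20, 0.07, 4)
        z1 = fit_strain_effect(ref, stn, "gamma").z
        z2 = fit_strain_effect(10 * ref, 10 * stn, "gamma").z
        assert abs(z1 - z2) < 1e-6

    def test_beta_fit_recovers_direction(self):
        rng = np.random.default_rng(6)
        ref = rng.beta(40, 60, 20)
        stn = rng.beta(60, 40, 5)
        fit = fit_strain_effect(ref, stn, "beta")
        assert fit.converged and fit.z > 2
        assert 0.45 < fit.fitted_mean < 0.75

    def test_zero_variance_flagged_not_converged(self):
        fit = fit_strain_effect([0.3, 0.3, 0.3], [0.3], "beta")
        assert not fit.converged and np.isnan(fit.z)

    def test_support_violations_raise(self):
        with pytest.raises(ValueError, match="positive"):
            fit_strain_effect([1.0, -2.0], [1.0], "gamma")
        with pytest.raises(ValueError, match="0, 1"):
            fit_strain_effect([0.5, 1.5], [0.5], "beta")

    def test_reference_needs_two_cultures(self):
        with pytest.raises(ValueError, match="two reference"):
            fit_strain_effect([1.0], [2.0], "gamma")


class TestZScoreMatrix:
    def test_single_strain_gives_one_row(self):
        catalog = build_catalog(2, 0, 0, 0)
        rng = np.random.default_rng(7)
        rows = []
        for i in range(6):
            rows.append(("BY", "wildtype", i + 1, rng.gamma(20, 0.05), rng.gamma(20, 0.05)))
        rows.append(("MUT", "deletion", 1, rng.gamma(20, 0.08), rng.gamma(20, 0.05)))
        values = pd.DataFrame(
            rows, columns=["strain_id", "group", "replicate_index", "C101_A", "C102_A"]
        )
        z = zscore_matrix(TraitTable(values), catalog)
        assert z.z.shape == (1, 2)
        assert list(z.z.index) == ["MUT"]

    def test_missing_reference_group_raises(self, small_screen, small_catalog):
        _, table, _ = small_screen
        nonref = table.subset(table.values["group"] != "wildtype")
        with pytest.raises(ValueError, match="wildtype"):
            zscore_matrix(nonref, small_catalog)

    def test_all_missing_parameter_dropped(self, small_catalog):
        from morphovar.simulate import SimulationConfig, simulate

        table, _ = simulate(
            SimulationConfig(seed=8, n_wildtype_reps=6, n_natural=2, n_deletion=2),
            small_catalog,
        )
        # one deletion strain loses one gamma parameter entirely
        table.values.loc[
            table.values["strain_id"] == "DEL001", "C101_A"
        ] = np.nan
        z = zscore_matrix(table, small_catalog)
        assert "C101_A" in z.dropped_params
        assert "C101_A" not in z.z.columns

    def test_row_permutation_leaves_z_unchanged(self, small_catalog):
        from morphovar.simulate import SimulationConfig, simulate

        table, _ = simulate(
            SimulationConfig(seed=12, n_wildtype_reps=6, n_natural=2, n_deletion=3),
            small_catalog,
        )
        z1 = zscore_matrix(table, small_catalog)
        perm = np.random.default_rng(0).permutation(len(table.values))
        shuffled = TraitTable(
            table.values.iloc[perm].reset_index(drop=True),
            table.trials.iloc[perm].reset_index(drop=True),
        )
        z2 = zscore_matrix(shuffled, small_catalog)
        pd.testing.assert_frame_equal(
            z1.z.sort_index(), z2.z.sort_index(), atol=1e-9, rtol=0
        )

    def test_null_simulation_zscores_approximately_standard_normal(self):
        """Under the global null the Z matrix is close to standard normal."""
        catalog = build_catalog(6, 2, 4, 4)
        from morphovar.simulate import SimulationConfig, simulate

        table, _ = simulate(
            SimulationConfig(
                seed=11, n_wildtype_reps=20, n_natural=0, n_deletion=40,
                natural_effect_sd=0.0, deletion_effect_sd=0.0,
            ),
            catalog,
        )
        z = zscore_matrix(table, catalog)
        flat = z.z.to_numpy().ravel()
        assert abs(flat.mean()) < 0.1
        assert 0.85 < flat.std() < 1.15
        col_sd = z.z.std(ddof=1)
        assert ((col_sd > 0.6) & (col_sd < 1.4)).all()

    def test_reference_replicate_zscores_shape(self, small_screen, small_z):
        config, _, _ = small_screen
        _, wt_z = small_z
        assert wt_z.z.shape[0] == config.n_wildtype_reps
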