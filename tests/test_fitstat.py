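import numpy as np
import pandas as pd
import pytest

from trapdiv.fitstat import (
    ModelSpec,
    deviance_explained,
    fit_additive,
    morans_i,
    select_k,
)


def make_table(n=120, seed=0, family="gaussian", b_forest=1.0, b_group=0.5,
               b_inter=-1.5, sigma=0.5, group=True):
    rng = np.random.default_rng(seed)
    forest = rng.uniform(0, 1, n)
    x, y = rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)
    if group:
        g = np.where(np.arange(n) % 2 == 0, "aquatic", "terrestrial")
        eta = 0.3 + b_forest * forest + b_group * (g == "terrestrial") \
            + b_inter * forest * (g == "terrestrial")
    else:
        g = None
        eta = 0.3 + b_forest * forest
    if family == "gaussian":
        resp = eta + rng.normal(0, sigma, n)
    else:
        resp = rng.poisson(np.exp(eta))
    table = pd.DataFrame({"y": resp, "forest_cover": forest, "x": x, "yc": y})
    if group:
        table["lifecycle"] = g
    return table


def spec(**kw):
    base = dict(response="y", coords=("x", "yc"))
    base.update(kw)
    return ModelSpec(**base)


class TestGaussianFits:
    def test_k1_equals_ols(self):
        """With k = 1 the smooth vanishes and the fit is exactly OLS."""
        table = make_table(n=80, seed=1)
        fit = fit_additive(table, spec(group="lifecycle", k=1))
        x = np.column_stack([
            np.ones(len(table)),
            table["forest_cover"],
            (table["lifecycle"] == "terrestrial").astype(float),
            table["forest_cover"] * (table["lifecycle"] == "terrestrial"),
        ])
        beta_ols = np.linalg.lstsq(x, table["y"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params.to_numpy()[:4], beta_ols, atol=1e-6)
        assert fit.k_used == 1

    def test_k1_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        table = make_table(n=100, seed=2)
        fit = fit_additive(table, spec(group="lifecycle", k=1))
        x = np.column_stack([
            np.ones(len(table)),
            table["forest_cover"],
            (table["lifecycle"] == "terrestrial").astype(float),
            table["forest_cover"] * (table["lifecycle"] == "terrestrial"),
        ])
        ref = sm.OLS(table["y"].to_numpy(), x).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-4)

    def test_constant_response_zero_deviance_explained(self):
        table = make_table(n=50, seed=3)
        table["y"] = 7.0
        fit = fit_additive(table, spec(k=1))
        with pytest.raises(ValueError, match="null deviance"):
            deviance_explained(fit)

    def test_deviance_explained_matches_population_r2(self):
        """Signal/noise chosen for R^2 = 0.5; n large enough to pin it."""
        rng = np.random.default_rng(9)
        n = 10000
        forest = rng.uniform(0, 1, n)
        signal = forest - forest.mean()
        sigma = signal.std()  # equal signal and noise variance -> R^2 = 0.5
        y = signal + rng.normal(0, sigma, n)
        table = pd.DataFrame({
            "y": y, "forest_cover": forest,
            "x": rng.uniform(0, 10, n), "yc": rng.uniform(0, 10, n),
        })
        fit = fit_additive(table, spec(k=1))
        assert deviance_explained(fit) == pytest.approx(50.0, abs=2.0)

    def test_smooth_absorbs_spatial_trend(self):
        rng = np.random.default_rng(4)
        n = 200
        x, y = rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)
        forest = rng.uniform(0, 1, n)
        resp = 2.0 * forest + np.sin(x / 200) + np.cos(y / 200) + rng.normal(0, 0.2, n)
        table = pd.DataFrame({"y": resp, "forest_cover": forest, "x": x, "yc": y})
        flat = fit_additive(table, spec(k=1))
        smooth = fit_additive(table, spec(k=15))
        assert smooth.deviance < flat.deviance
        assert abs(smooth.params["forest_cover"] - 2.0) < 0.15


class TestCountFits:
    def test_poisson_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        table = make_table(n=150, seed=5, family="poisson")
        fit = fit_additive(table, spec(group="lifecycle", k=1, family="poisson"))
        x = np.column_stack([
            np.ones(len(table)),
            table["forest_cover"],
            (table["lifecycle"] == "terrestrial").astype(float),
            table["forest_cover"] * (table["lifecycle"] == "terrestrial"),
        ])
        ref = sm.GLM(table["y"].to_numpy(), x, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-5)
        assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-4)
        assert fit.deviance == pytest.approx(ref.deviance, rel=1e-6)

    def test_non_integer_counts_rejected(self):
        table = make_table(n=40, seed=6, family="poisson")
        table["y"] = table["y"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            fit_additive(table, spec(k=1, family="poisson"))

    def test_quasipoisson_scales_se_by_dispersion(self):
        rng = np.random.default_rng(7)
        n = 300
        forest = rng.uniform(0, 1, n)
        mu = np.exp(1.0 + 1.2 * forest)
        y = rng.poisson(rng.gamma(shape=2.0, scale=mu / 2.0))  # overdispersed
        table = pd.DataFrame({
            "y": y.astype(float), "forest_cover": forest,
            "x": rng.uniform(0, 100, n), "yc": rng.uniform(0, 100, n),
        })
        qp = fit_additive(table, spec(k=1, family="quasipoisson"))
        po_table = table.copy()
        po = fit_additive(po_table, spec(k=1, family="poisson"))
        assert qp.dispersion > 1.2
        ratio = qp.se / po.se
        assert np.allclose(ratio, np.sqrt(qp.dispersion), rtol=1e-6)
        assert np.allclose(qp.params, po.params, atol=1e-8)

    def test_rank_deficiency_named(self):
        table = make_table(n=60, seed=8)
        table["forest_cover"] = 1.0  # collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_additive(table, spec(k=1))


class TestSelectK:
    def test_singleton_grid_returned(self):
        table = make_table(n=60, seed=10)
        fit = select_k(table, spec(k=1), k_grid=[4])
        assert fit.spec.k == 4

    def test_unstructured_residuals_prefer_small_k(self):
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            table = make_table(n=150, seed=seed)  # no spatial signal
            fit = select_k(table, spec(group="lifecycle"), k_grid=[1, 3, 5, 8, 12, 16, 20])
            if fit.spec.k <= 5:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_spatial_signal_prefers_larger_k(self):
        rng = np.random.default_rng(0)
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 200
            x, y = rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)
            forest = rng.uniform(0, 1, n)
            flat_y = forest + rng.normal(0, 0.3, n)
            bumpy_y = forest + 1.5 * np.sin(x / 120) * np.cos(y / 120) \
                + rng.normal(0, 0.3, n)
            grid = [1, 3, 5, 8, 12, 16, 20]
            base = dict(forest_cover=forest, x=x, yc=y)
            k_flat = select_k(pd.DataFrame({"y": flat_y, **base}), spec(), grid).spec.k
            k_bumpy = select_k(pd.DataFrame({"y": bumpy_y, **base}), spec(), grid).spec.k
            if k_bumpy > k_flat:
                wins += 1
        assert wins >= 6

    def test_infeasible_k_degrades(self):
        table = make_table(n=30, seed=11)
        fit = fit_additive(table.iloc[:8], spec(k=20))
        assert fit.k_used <= 8

    def test_aic_favours_true_terms(self):
        """Adding the real predictor lowers AIC on average."""
        diffs = []
        for seed in range(20):
            table = make_table(n=120, seed=seed, group=False)
            with_term = fit_additive(table, spec(k=1))
            null = table.copy()
            null["forest_cover"] = 0.0
            # intercept-only comparison via a constant forest column is rank
            # deficient; shuffle the predictor instead
            rng = np.random.default_rng(seed)
            null["forest_cover"] = rng.permutation(table["forest_cover"].to_numpy())
            without = fit_additive(null, spec(k=1))
            diffs.append(without.aic - with_term.aic)
        assert np.mean(diffs) > 0


class TestParameterRecovery:
    def test_lifecycle_slope_signs_recovered(self):
        """Fits on synthetic archipelago data recover both slope signs."""
        from trapdiv import landcov, synthio

        effects = synthio.default_effects()
        traps = synthio.generate_design(synthio.study_config())
        raster = synthio.raster_for_design(traps, seed=0)
        f = landcov.batch_cover(raster, traps).set_index("trap_id")["forest_cover"]
        xy = traps.set_index("trap_id")[["x", "y"]]
        terr_taxa = [t for t, lc in effects.taxa if lc == "terrestrial"]
        aq_taxa = [t for t, lc in effects.taxa if lc == "aquatic"]
        ok = 0
        n_rep = 20
        for seed in range(n_rep):
            counts = synthio.generate_counts(traps, f, effects, seed=seed)
            rows = []
            for lc, cols in (("terrestrial", terr_taxa), ("aquatic", aq_taxa)):
                for trap_id, total in counts[cols].sum(axis=1).items():
                    rows.append((trap_id, lc, int(total)))
            table = pd.DataFrame(rows, columns=["trap_id", "lifecycle", "abund"])
            table = table.merge(f.rename("forest_cover"), left_on="trap_id",
                                right_index=True)
            table = table.merge(xy, left_on="trap_id", right_index=True)
            fit = fit_additive(
                table,
                ModelSpec(response="abund", group="lifecycle", k=8, family="poisson",
                          coords=("x", "y")),
            )
            b_aq = fit.params["forest_cover"]
            b_terr = b_aq + fit.params["forest_cover:lifecycle[terrestrial]"]
            if b_aq < 0 and b_terr > 0:
                ok += 1
        assert ok >= int(0.95 * n_rep)


class TestMoransI:
    def test_minimum_observations(self):
        with pytest.raises(ValueError):
            morans_i(np.array([1.0, -1.0]), np.array([[0, 0], [1, 1]]))

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(10), np.random.default_rng(0).uniform(0, 1, (10, 2)))

    def test_smooth_gradient_positive(self, rng):
        n = 100
        xy = rng.uniform(0, 100, (n, 2))
        resid = xy[:, 0] / 100 + rng.normal(0, 0.05, n)
        res = morans_i(resid, xy)
        assert res.i > 0 and res.p < 0.01

    def test_iid_residuals_near_null_expectation(self):
        n = 80
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            xy = rng.uniform(0, 100, (n, 2))
            res = morans_i(rng.normal(size=n), xy)
            if abs(res.i - res.expected) < 3 * np.sqrt(res.variance):
                hits += 1
        assert hits >= 36  # >= ~95% within 3 null SD

    def test_permutation_mean_matches_expectation(self, rng):
        n = 60
        xy = rng.uniform(0, 100, (n, 2))
        resid = rng.normal(size=n)
        vals = [morans_i(rng.permutation(resid), xy).i for _ in range(300)]
        e = -1.0 / (n - 1)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - e) < 3 * se

    def test_zero_distance_pairs_flagged(self):
        xy = np.array([[0, 0], [0, 0], [1, 1], [2, 2]], dtype=float)
        res = morans_i(np.array([1.0, -1.0, 0.5, -0.5]), xy)
        assert res.n_zero_distance_pairs == 1
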