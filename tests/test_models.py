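"""Gibbs sampler correctness: conjugate oracles, determinism, DIC, summaries."""

import numpy as np
import pandas as pd
import pytest

from thermnorm.models import (
    FittedModel,
    McmcSettings,
    ModelError,
    ModelSpec,
    TEST_MCMC,
    compare_random_structures,
    compute_dic,
    fit_binary_mixed,
    fit_gaussian_mixed,
    fit_mixed,
    pmcmc,
    summarize_fixed_effects,
    support_category,
)

SHORT_MCMC = McmcSettings(iterations=8_000, burnin=1_000, thin=5)


def _make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id",
            "aquarium_id",
            "unit_id",
            "trait",
            "temperature_c",
            "centred_temperature",
            "body_mass_g",
            "scaled_mass",
            "value",
        ],
    )


def _gaussian_table(
    seed=0,
    n_fish=40,
    v_int=1.0,
    v_slope=0.04,
    cov=0.16,
    v_res=0.5,
    beta=(2.0, 0.3, 0.5),
    with_groups=False,
):
    rng = np.random.default_rng(seed)
    temps = np.array([-6.0, -3.0, 0.0, 3.0, 6.0])
    g = np.array([[v_int, cov], [cov, v_slope]])
    us = rng.multivariate_normal([0.0, 0.0], g, size=n_fish)
    mass = rng.normal(0, 1, n_fish)
    rows = []
    for i in range(n_fish):
        for t in temps:
            mu = beta[0] + beta[1] * t + beta[2] * mass[i] + us[i, 0] + us[i, 1] * t
            rows.append(
                {
                    "fish_id": f"F{i}",
                    "aquarium_id": f"A{i % 4}" if with_groups else pd.NA,
                    "unit_id": f"C{i % 8}" if with_groups else pd.NA,
                    "trait": "y",
                    "temperature_c": t + 8,
                    "centred_temperature": t,
                    "body_mass_g": np.nan,
                    "scaled_mass": mass[i],
                    "value": mu + rng.normal(0, np.sqrt(v_res)),
                }
            )
    return _make_table(rows), us


class TestGaussianSampler:
    def test_seed_determinism(self):
        table, _ = _gaussian_table(seed=1)
        a = fit_gaussian_mixed(table, "y", "slopes", SHORT_MCMC, seed=9)
        b = fit_gaussian_mixed(table, "y", "slopes", SHORT_MCMC, seed=9)
        assert a.samples.equals(b.samples)
        assert a.dic == b.dic

    def test_variance_recovery_within_credible_intervals(self):
        """Posterior intervals cover the generating G at a single seed."""
        from thermnorm.models import hpd_interval

        table, _ = _gaussian_table(seed=2, n_fish=200)
        fit = fit_gaussian_mixed(table, "y", "slopes", TEST_MCMC, seed=5)
        for comp, truth in [
            (fit.variance_draws("intercept"), 1.0),
            (fit.variance_draws("slope"), 0.04),
            (fit.covariance_draws("intercept", "slope"), 0.16),
            (fit.residual_draws(), 0.5),
        ]:
            lo, hi = hpd_interval(comp)
            assert lo <= truth <= hi

    def test_posterior_individual_effects_match_analytic_shrinkage(self):
        """With variances nearly known (huge data), u means approach BLUPs."""
        table, us = _gaussian_table(seed=3, n_fish=60, v_slope=0.0, cov=0.0)
        table = table[table["trait"] == "y"]
        fit = fit_gaussian_mixed(table, "y", "intercepts", SHORT_MCMC, seed=2)
        # analytic shrinkage with the true variances: u_j = k * mean residual
        resid = []
        sub = table.copy()
        sub["mu"] = (
            fit.samples["beta_intercept"].mean()
            + fit.samples["beta_ct"].mean() * sub["centred_temperature"]
            + fit.samples["beta_mass"].mean() * sub["scaled_mass"]
        )
        sub["r"] = sub["value"] - sub["mu"]
        k = 1.0 / (1.0 + 0.5 / (5 * 1.0))  # V_res=0.5, n=5 obs, V_int=1
        blup = sub.groupby("fish_id", sort=False)["r"].mean() * k
        est = fit.u_mean[:, 0]
        assert np.corrcoef(blup.to_numpy(), est)[0, 1] > 0.99
        assert np.abs(blup.to_numpy() - est).mean() < 0.1

    def test_null_variance_concentrates_near_zero(self):
        """Data with no individual effects: V_int posterior hugs zero."""
        from thermnorm.models import hpd_interval

        table, _ = _gaussian_table(seed=4, n_fish=60, v_int=0.0, v_slope=0.0, cov=0.0)
        fit = fit_gaussian_mixed(table, "y", "intercepts", TEST_MCMC, seed=3)
        lo, _ = hpd_interval(fit.variance_draws("intercept"))
        v_res = float(fit.residual_draws().mean())
        assert lo < 0.01 * v_res

    def test_every_g_draw_is_positive_semidefinite(self, smr_slopes_fit):
        eig = np.linalg.eigvalsh(smr_slopes_fit.g_draws)
        assert eig.min() > -1e-10

    def test_singular_design_rejected(self):
        table, _ = _gaussian_table(seed=5, n_fish=10)
        table["scaled_mass"] = 0.0  # constant covariate, collinear with intercept
        with pytest.raises(ModelError, match="singular"):
            fit_gaussian_mixed(table, "y", "intercepts", SHORT_MCMC)

    def test_slopes_need_repeated_measures(self):
        table, _ = _gaussian_table(seed=6, n_fish=10)
        # one fish retains a single observation; temperatures still vary
        thinned = table[~((table["fish_id"] == "F0") & (table["centred_temperature"] != 0.0))]
        with pytest.raises(ModelError, match="2 observations"):
            fit_gaussian_mixed(thinned, "y", "slopes", SHORT_MCMC)


class TestBinarySampler:
    def _binary_table(self, seed=0, n_fish=80, v_int=1.0, b_ct=0.5):
        rng = np.random.default_rng(seed)
        temps = np.array([-6.0, -3.0, 0.0, 3.0, 6.0])
        u = rng.normal(0, np.sqrt(v_int), n_fish)
        rows = []
        for i in range(n_fish):
            for t in temps:
                latent = b_ct * t + u[i] + rng.normal()
                rows.append(
                    {
                        "fish_id": f"F{i}",
                        "aquarium_id": pd.NA,
                        "unit_id": pd.NA,
                        "trait": "b",
                        "temperature_c": t + 8,
                        "centred_temperature": t,
                        "body_mass_g": np.nan,
                        "scaled_mass": rng.normal(),
                        "value": float(latent > 0),
                    }
                )
        return _make_table(rows)

    def test_latent_variance_recovery(self):
        from thermnorm.models import hpd_interval

        table = self._binary_table(seed=1)
        fit = fit_binary_mixed(table, "b", "intercepts", TEST_MCMC, seed=4)
        lo, hi = hpd_interval(fit.variance_draws("intercept"))
        assert lo <= 1.0 <= hi

    def test_strong_temperature_effect_sign(self):
        """The probit slope's sign matches the generative sign decisively."""
        table = self._binary_table(seed=2, b_ct=0.6)
        fit = fit_binary_mixed(table, "b", "intercepts", SHORT_MCMC, seed=1)
        draws = fit.samples["beta_ct"]
        assert (draws > 0).mean() > 0.999

    def test_single_class_response_rejected(self):
        table = self._binary_table(seed=3)
        table["value"] = 1.0
        with pytest.raises(ModelError, match="single class"):
            fit_binary_mixed(table, "b", "intercepts", SHORT_MCMC)

    def test_residual_variance_fixed_at_one(self):
        table = self._binary_table(seed=4)
        fit = fit_binary_mixed(table, "b", "intercepts", SHORT_MCMC, seed=2)
        assert "V_residual" not in fit.samples.columns
        assert np.all(fit.residual_draws() == 1.0)


class TestBivariate:
    def test_trait_paired_with_itself_gives_unit_correlation(self):
        table, _ = _gaussian_table(seed=7, n_fish=30)
        clone = table.copy()
        clone["trait"] = "y2"
        clone["value"] = table["value"]  # identical trait
        both = pd.concat([table, clone], ignore_index=True)
        spec = ModelSpec(
            traits=("y", "y2"),
            families=("gaussian", "gaussian"),
            random_structure="intercepts",
            mcmc=SHORT_MCMC,
            seed=3,
        )
        fit = fit_mixed(both, spec)
        cor = fit.correlation_draws("y_intercept", "y2_intercept")
        assert cor.mean() > 0.9

    def test_independent_traits_straddle_zero(self):
        from thermnorm.models import hpd_interval

        table, _ = _gaussian_table(seed=8, n_fish=50)
        rng = np.random.default_rng(99)
        other = table.copy()
        other["trait"] = "z"
        other["value"] = rng.normal(size=len(other))
        both = pd.concat([table, other], ignore_index=True)
        spec = ModelSpec(
            traits=("y", "z"),
            families=("gaussian", "gaussian"),
            random_structure="intercepts",
            mcmc=SHORT_MCMC,
            seed=4,
        )
        fit = fit_mixed(both, spec)
        lo, hi = hpd_interval(fit.correlation_draws("y_intercept", "z_intercept"))
        assert lo <= 0.0 <= hi

    def test_too_few_shared_individuals_rejected(self):
        table, _ = _gaussian_table(seed=9, n_fish=6)
        other, _ = _gaussian_table(seed=10, n_fish=6)
        other = other.copy()
        other["trait"] = "z"
        other["fish_id"] = "Q" + other["fish_id"]
        both = pd.concat([table, other], ignore_index=True)
        spec = ModelSpec(
            traits=("y", "z"),
            families=("gaussian", "gaussian"),
            random_structure="intercepts",
            mcmc=SHORT_MCMC,
        )
        with pytest.raises(ModelError, match="at least 2 individuals"):
            fit_mixed(both, spec)


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        dev = np.full(100, 123.456)
        dic, p_d = compute_dic(dev, 123.456)
        assert p_d == pytest.approx(0.0, abs=1e-6)
        assert dic == pytest.approx(123.456, abs=1e-6)

    def test_non_finite_deviance_rejected(self):
        with pytest.raises(ModelError):
            compute_dic(np.array([1.0, np.inf]), 1.0)

    def test_deviance_at_mean_matches_independent_recomputation(self):
        """Recompute D(theta-bar) from posterior means with the normal density."""
        table, _ = _gaussian_table(seed=11, n_fish=30, v_slope=0.0, cov=0.0)
        fit = fit_gaussian_mixed(table, "y", "intercepts", SHORT_MCMC, seed=7)
        sub = table.reset_index(drop=True)
        beta = [
            fit.samples["beta_intercept"].mean(),
            fit.samples["beta_ct"].mean(),
            fit.samples["beta_mass"].mean(),
        ]
        u = dict(zip(fit.fish_ids, fit.u_mean[:, 0]))
        eta = (
            beta[0]
            + beta[1] * sub["centred_temperature"]
            + beta[2] * sub["scaled_mass"]
            + sub["fish_id"].map(u)
        ).to_numpy()
        s2 = float(fit.residual_draws().mean())
        r = sub["value"].to_numpy() - eta
        oracle = len(sub) * np.log(2 * np.pi * s2) + float(r @ r) / s2
        # eta-bar in the fit averages correlated draws; means-of-means agree
        # to within a small fraction of a deviance unit per observation
        assert abs(oracle - fit.deviance_at_mean) < 0.02 * len(sub)

    def test_pure_noise_slopes_do_not_win_strongly(self):
        """Null slope variance: the slopes model gains no strong support."""
        strong = 0
        for seed in range(3):
            table, _ = _gaussian_table(
                seed=100 + seed, n_fish=40, v_slope=0.0, cov=0.0
            )
            fi = fit_gaussian_mixed(table, "y", "intercepts", SHORT_MCMC, seed=seed)
            fs = fit_gaussian_mixed(table, "y", "slopes", SHORT_MCMC, seed=seed)
            if compare_random_structures(fi, fs).support == "strong":
                strong += 1
        assert strong == 0


class TestComparison:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (92.0, "strong"),  # printed dDIC for SMR
            (30.0, "strong"),
            (7.0, "substantial"),
            (4.2, "none"),  # day-time activity
            (-0.12, "none"),  # night-time activity
        ],
    )
    def test_support_categories(self, delta, expected):
        assert support_category(delta) == expected

    def test_mismatched_fits_rejected(self, smr_intercepts_fit, smr_slopes_fit):
        with pytest.raises(ModelError):
            compare_random_structures(smr_slopes_fit, smr_intercepts_fit)
        comp = compare_random_structures(smr_intercepts_fit, smr_slopes_fit)
        assert comp.delta_dic == smr_intercepts_fit.dic - smr_slopes_fit.dic


class TestSummaries:
    def _fake_fit(self, draws_dict):
        samples = pd.DataFrame(draws_dict)
        spec = ModelSpec(
            traits=("y",), families=("gaussian",), random_structure="intercepts"
        )
        return FittedModel(
            spec=spec,
            samples=samples,
            g_draws=np.ones((len(samples), 1, 1)),
            component_names=["intercept"],
            fish_ids=[],
            u_mean=np.zeros((0, 1)),
            dic=0.0,
            p_d=0.0,
            deviance_at_mean=0.0,
            ess={},
            low_ess=False,
        )

    def test_symmetric_posterior_pmcmc_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, 10_000)
        assert pmcmc(draws) > 0.9

    def test_one_sided_posterior_floored(self):
        draws = np.abs(np.random.default_rng(0).normal(0, 1, 2000)) + 0.01
        assert pmcmc(draws) == pytest.approx(1 / 2000)

    def test_significance_and_interaction_directive(self):
        rng = np.random.default_rng(1)
        fit = self._fake_fit(
            {
                "beta_intercept": rng.normal(5, 0.1, 4000),
                "beta_ct": rng.normal(0.5, 0.05, 4000),
                "beta_mass": rng.normal(0.2, 0.05, 4000),
                "beta_ct_mass": rng.normal(0.0, 0.1, 4000),
            }
        )
        summary = summarize_fixed_effects(fit)
        by_effect = summary.set_index("effect")
        assert by_effect.loc["ct", "significant"]
        assert not by_effect.loc["ct_mass", "significant"]
        assert summary.attrs["drop_interaction"]
        assert by_effect.loc["ct", "pmcmc"] == pytest.approx(1 / 4000)
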