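"""Synthetic-study generator: reaction norms, masses, traces, behaviour."""

import numpy as np
import pytest

from thermnorm import respirometry as resp
from thermnorm.simulate import (
    SimulationConfig,
    SimulationError,
    TrialSchedule,
    cooling_rate_c_per_day,
    draw_individuals,
    simulate_mass_trajectories,
    simulate_o2_trace,
    simulate_study,
)


class TestDrawIndividuals:
    def test_degenerate_g_gives_exactly_zero_slopes(self):
        cfg = SimulationConfig(seed=0)
        cfg.traits["smr"].v_slope = 0.0
        cfg.traits["smr"].cov_int_slope = 0.0
        ind = draw_individuals(cfg)
        assert (ind["smr_slope"] == 0.0).all()

    def test_sample_correlation_converges_to_configured(self):
        """Law of large numbers: empirical (intercept, slope) correlation."""
        ind = draw_individuals(SimulationConfig(n_fish=2000, seed=3))
        c = np.corrcoef(ind["smr_intercept"], ind["smr_slope"])[0, 1]
        assert abs(c - 0.8) < 0.05

    def test_same_seed_identical_ensembles(self):
        a = draw_individuals(SimulationConfig(seed=12))
        b = draw_individuals(SimulationConfig(seed=12))
        assert a.equals(b)

    def test_non_psd_g_rejected_naming_trait(self):
        cfg = SimulationConfig(seed=0)
        cfg.traits["mmr"].cov_int_slope = 1.0  # |cov| > sqrt(Vint*Vslope)
        with pytest.raises(SimulationError, match="mmr"):
            draw_individuals(cfg)

    def test_empirical_g_converges_in_frobenius_norm(self):
        cfg = SimulationConfig(n_fish=5000, seed=7)
        ind = draw_individuals(cfg)
        emp = np.cov(
            np.stack([ind["smr_intercept"], ind["smr_slope"]]), ddof=1
        )
        true_g = cfg.traits["smr"].g_matrix
        rel = np.linalg.norm(emp - true_g) / np.linalg.norm(true_g)
        assert rel < 0.05

    def test_round_robin_aquaria(self):
        ind = draw_individuals(SimulationConfig(n_fish=10, n_aquaria=5, seed=0))
        assert ind["aquarium_id"].tolist() == [f"A{i % 5}" for i in range(10)]


class TestMassTrajectories:
    def _flat_growth_config(self):
        cfg = SimulationConfig(seed=0, n_fish=5)
        tp = cfg.traits["sgr"]
        tp.intercept = 0.0
        tp.temp_slope = 0.0
        tp.mass_coef = 0.0
        tp.v_intercept = 0.0
        tp.v_slope = 0.0
        tp.cov_int_slope = 0.0
        tp.v_residual = 0.0
        tp.v_aquarium = 0.0
        return cfg

    def test_zero_sgr_keeps_mass_constant(self):
        cfg = self._flat_growth_config()
        ind = draw_individuals(cfg)
        masses = simulate_mass_trajectories(ind, cfg)
        wide = masses.pivot(index="fish_id", columns="temperature_c", values="mass_g")
        assert np.allclose(wide.std(axis=1), 0.0)

    def test_positive_growth_hand_value(self):
        # 0.38124 %/day for 25 days from 7.0 g is 7.7 g
        cfg = self._flat_growth_config()
        cfg.traits["sgr"].intercept = 0.38123963775993294
        ind = draw_individuals(cfg)
        ind["baseline_mass_g"] = 7.0
        masses = simulate_mass_trajectories(ind, cfg)
        m11 = masses[masses["temperature_c"] == 11.0]["mass_g"]
        assert np.allclose(m11, 7.7, atol=1e-6)

    def test_weight_loss_hand_value(self):
        cfg = self._flat_growth_config()
        cfg.traits["sgr"].intercept = -0.4214420928713749
        ind = draw_individuals(cfg)
        ind["baseline_mass_g"] = 7.0
        masses = simulate_mass_trajectories(ind, cfg)
        m11 = masses[masses["temperature_c"] == 11.0]["mass_g"]
        assert np.allclose(m11, 6.3, atol=1e-6)

    def test_non_positive_baseline_rejected(self):
        cfg = self._flat_growth_config()
        ind = draw_individuals(cfg)
        ind.loc[0, "baseline_mass_g"] = 0.0
        with pytest.raises(SimulationError):
            simulate_mass_trajectories(ind, cfg)


class TestO2Traces:
    def test_constant_mo2_gives_exact_slopes(self):
        """1 mg/h in 0.1 L effective volume is a -10 mg/L/h decline."""
        cfg = SimulationConfig(
            seed=0, o2_noise_sd_mg_l=0.0, background_rate_mg_h_per_h=0.0
        )
        cfg.schedule.chamber_volume_ml = 100.0
        trace = simulate_o2_trace("t", "C00", 8.0, None, 1.0, 1.0, cfg)
        for idx in trace.closed_segments():
            cs = resp.fit_cycle_slope(trace.time_s[idx], trace.o2_mg_per_l[idx])
            assert cs.slope_mg_per_l_h == pytest.approx(-10.0, abs=1e-9)

    def test_blank_without_background_is_flat(self):
        cfg = SimulationConfig(
            seed=0, o2_noise_sd_mg_l=0.0, background_rate_mg_h_per_h=0.0
        )
        trace = simulate_o2_trace("b", "C15", 8.0, None, 0.0, 0.0, cfg)
        for idx in trace.closed_segments():
            cs = resp.fit_cycle_slope(trace.time_s[idx], trace.o2_mg_per_l[idx])
            assert cs.slope_mg_per_l_h == pytest.approx(0.0, abs=1e-12)

    def test_noisy_trace_reproducible(self):
        cfg = SimulationConfig(seed=4)
        a = simulate_o2_trace("t", "C00", 8.0, 7.0, 0.8, 4.0, cfg, trial_index=3)
        b = simulate_o2_trace("t", "C00", 8.0, 7.0, 0.8, 4.0, cfg, trial_index=3)
        assert np.array_equal(a.o2_mg_per_l, b.o2_mg_per_l)

    def test_fish_exceeding_chamber_rejected(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(SimulationError):
            simulate_o2_trace("t", "C00", 8.0, 200.0, 0.8, 4.0, cfg)

    def test_schedule_validation(self):
        with pytest.raises(SimulationError):
            TrialSchedule(flush_minutes=0.0).validate()


class TestActivity:
    def test_saturated_latent_gives_all_zero_movement(self):
        cfg = SimulationConfig(seed=0, n_fish=30)
        for t in ("activity_day", "activity_night"):
            cfg.traits[t].intercept = -10.0
            cfg.traits[t].v_intercept = 0.0
            cfg.traits[t].v_aquarium = 0.0
            cfg.traits[t].v_unit = 0.0
        study = simulate_study(cfg)
        assert (study.activity["distance_mm"] == 0).all()

    def test_zero_inflation_matches_probit_target(self):
        cfg = SimulationConfig(seed=8, n_fish=500)
        # isolate the marginal rate: no temperature trend, and no group
        # effects (with only 5 aquaria / 15 arenas their realized means
        # would dominate the comparison)
        cfg.traits["activity_day"].temp_slope = 0.0
        cfg.traits["activity_day"].v_aquarium = 0.0
        cfg.traits["activity_day"].v_unit = 0.0
        study = simulate_study(cfg)
        day = study.activity[study.activity["period"] == "day"]
        p_zero = (day["distance_mm"] == 0).mean()
        n = len(day)
        # binomial error around the configured target
        assert abs(p_zero - cfg.zero_inflation_target) < 3 * np.sqrt(0.25 / n) + 0.02

    def test_invalid_zero_inflation_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(zero_inflation_target=1.5).validate()


class TestStudyBundle:
    def test_shapes_and_schema(self, paper_scale_study):
        study = paper_scale_study
        n, t = study.config.n_fish, len(study.config.temperatures)
        assert len(study.manifest) == n * t
        assert len(study.masses) == n * t
        assert len(study.feeding) == n * t
        assert len(study.activity) == 2 * n * t
        # one blank per batch of 15 fish per temperature
        assert len(study.blank_trial_ids()) == t * int(np.ceil(n / 15))

    def test_truth_mean_smr_at_centre_matches_intercept(self):
        cfg = SimulationConfig(seed=21, n_fish=400)
        # remove the body-mass covariate: fish grow during cooling, so the
        # mean mass at the centre temperature sits above the baseline mean
        cfg.traits["smr"].mass_coef = 0.0
        study = simulate_study(cfg)
        at_centre = study.metabolic[study.metabolic["temperature_c"] == 8.0]
        v_tot = (
            cfg.traits["smr"].v_intercept
            + cfg.traits["smr"].v_aquarium
            + cfg.traits["smr"].v_unit
        )
        se = np.sqrt(v_tot / len(at_centre))
        assert abs(at_centre["smr_norm"].mean() - 0.90) < 4 * se + 0.01

    def test_different_seeds_same_schema_different_values(self):
        a = simulate_study(SimulationConfig(seed=1, n_fish=4))
        b = simulate_study(SimulationConfig(seed=2, n_fish=4))
        assert list(a.masses.columns) == list(b.masses.columns)
        assert not np.allclose(a.masses["mass_g"], b.masses["mass_g"])

    def test_trace_generation_deterministic_per_trial(self):
        study = simulate_study(SimulationConfig(seed=3, n_fish=2))
        tid = study.manifest["trial_id"].iloc[0]
        assert np.array_equal(
            study.trace_for(tid).o2_mg_per_l, study.trace_for(tid).o2_mg_per_l
        )

    def test_write_round_trip(self, tmp_path):
        study = simulate_study(SimulationConfig(seed=3, n_fish=2))
        study.write(tmp_path)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "manifest.csv").exists()


def test_cooling_rate_arithmetic():
    assert cooling_rate_c_per_day(14.0, 2.0, 100.0) == pytest.approx(0.12)
    with pytest.raises(SimulationError):
        cooling_rate_c_per_day(14.0, 2.0, 0.0)
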