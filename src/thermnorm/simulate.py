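"""Synthetic thermal-plasticity studies with known ground truth.

Generates complete studies mirroring the slow-cooling design: ~73 juvenile
fish held in 5 aquaria, measured for metabolic rate (intermittent-closed
respirometry), growth, movement activity and food intake at 14, 11, 8, 5 and
2 degC while being cooled at 0.12 degC/day.

Each individual carries a linear thermal reaction norm per trait: a random
(intercept, slope) pair drawn from a trait-specific 2x2 covariance matrix G,
around population-level fixed effects of centred temperature and scaled body
mass.  Metabolic traits default to a strong positive intercept-slope
correlation (0.8) so among-individual variance grows with temperature;
behavioural traits default to zero slope variance (no plasticity variation)
and heavy zero-inflation on a latent probit scale.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams, so each component (individuals,
masses, traces, behaviour) is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .respirometry import PHASE_CLOSED, PHASE_FLUSH, RespirometryTrace

GAUSSIAN_TRAITS = ("smr", "mmr", "sgr")
BINARY_TRAITS = ("activity_day", "activity_night", "feeding")

# Named sub-stream tags for seed splitting (stable across runs).
_STREAMS = {
    "individuals": 1,
    "masses": 2,
    "metabolic": 3,
    "activity": 4,
    "feeding": 5,
    "trace": 6,
    "background": 7,
}


class SimulationError(ValueError):
    pass


@dataclass
class TrialSchedule:
    """Timing and chamber constants for respirometry trials.

    Closed phases lengthen at cold temperatures (slower respiration needs a
    longer window for a resolvable O2 decline): 5 min at 14 degC to 21 min at
    2 degC, linearly interpolated at intermediate temperatures.  The first,
    manually started closed phase after the exhaustive chase is shorter
    (3-11 min, same interpolation).  Flushes are 4 min at all temperatures,
    trials run ~17.5 h, and O2 is sampled every 2 s.
    """

    closed_minutes_by_temperature: dict[float, float] = field(
        default_factory=lambda: {14.0: 5.0, 11.0: 9.0, 8.0: 13.0, 5.0: 17.0, 2.0: 21.0}
    )
    mmr_first_closed_minutes_by_temperature: dict[float, float] = field(
        default_factory=lambda: {14.0: 3.0, 11.0: 5.0, 8.0: 7.0, 5.0: 9.0, 2.0: 11.0}
    )
    flush_minutes: float = 4.0
    trial_hours: float = 17.5
    sampling_period_s: float = 2.0
    chamber_volume_ml: float = 126.5

    def validate(self) -> None:
        durations = (
            list(self.closed_minutes_by_temperature.values())
            + list(self.mmr_first_closed_minutes_by_temperature.values())
            + [self.flush_minutes, self.trial_hours, self.sampling_period_s]
        )
        if any(d <= 0 for d in durations):
            raise SimulationError("all schedule durations must be positive")


@dataclass
class TraitParams:
    """Generative parameters for one trait's reaction norms.

    ``intercept=None`` (binary traits) derives the latent intercept from the
    configured zero-inflation target.  Variances are on the trait scale for
    Gaussian traits and the latent probit (liability) scale for binary ones,
    where the residual is fixed at 1.
    """

    intercept: Optional[float]
    temp_slope: float
    mass_coef: float
    v_intercept: float
    v_slope: float
    cov_int_slope: float
    v_residual: float
    v_aquarium: float
    v_unit: float

    @property
    def g_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.v_intercept, self.cov_int_slope],
                [self.cov_int_slope, self.v_slope],
            ]
        )


def _default_traits() -> dict[str, TraitParams]:
    # Metabolic and growth traits: intercept-slope correlation 0.8, slope sd
    # = 20% of intercept sd, so among-individual variance rises with
    # temperature.  Behavioural traits: latent probit with no slope variance.
    return {
        "smr": TraitParams(0.90, 0.07, 0.15, 0.04, 0.0016, 0.0064, 0.04, 0.002, 0.002),
        "mmr": TraitParams(4.0, 0.22, 0.60, 0.36, 0.0144, 0.0576, 0.36, 0.01, 0.01),
        "sgr": TraitParams(0.30, 0.08, -0.05, 0.02, 0.0008, 0.0032, 0.02, 0.001, 0.0),
        "activity_day": TraitParams(None, 0.15, 0.0, 1.0, 0.0, 0.0, 1.0, 0.05, 0.05),
        "activity_night": TraitParams(None, 0.12, 0.0, 1.0, 0.0, 0.0, 1.0, 0.05, 0.05),
        "feeding": TraitParams(None, 0.25, 0.0, 1.0, 0.0, 0.0, 1.0, 0.05, 0.05),
    }


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic study."""

    n_fish: int = 73
    n_aquaria: int = 5
    temperatures: tuple[float, ...] = (14.0, 11.0, 8.0, 5.0, 2.0)
    centre_temperature: float = 8.0
    traits: dict[str, TraitParams] = field(default_factory=_default_traits)
    mass_mean_g: float = 7.27
    mass_sd_g: float = 1.75
    allometric_exponent: float = 1.0
    #: marginal proportion of behavioural trials with zero movement
    zero_inflation_target: float = 0.55
    #: marginal proportions of feeding observations at 0 and at full ration
    feeding_zero_proportion: float = 0.49
    feeding_full_proportion: float = 0.34
    feeding_ration: int = 10
    #: days between consecutive measurement temperatures (3 degC at 0.12 degC/day)
    interval_days: float = 25.0
    behaviour_trial_s: float = 3600.0
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    o2_noise_sd_mg_l: float = 0.005
    o2_saturation_mg_l: float = 9.0
    mmr_recovery_tau_h: float = 1.0
    #: blank-chamber background: zero until onset, then linear growth (mg/h per h)
    background_onset_h: float = 8.0
    background_rate_mg_h_per_h: float = 0.01
    #: measurement noise on the three post-trial background recordings
    post_fish_noise_sd_mg_h: float = 0.001
    #: cross-trait correlations between individual intercepts, keyed
    #: "trait_a:trait_b" (e.g. more active individuals also eat more);
    #: trait_b must have no intercept-slope covariance of its own
    intercept_correlation_pairs: dict[str, float] = field(
        default_factory=lambda: {"activity_day:feeding": 0.42}
    )
    batch_size: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish <= 0 or self.n_aquaria <= 0:
            raise SimulationError("n_fish and n_aquaria must be positive")
        if list(self.temperatures) != sorted(self.temperatures, reverse=True) or len(
            set(self.temperatures)
        ) != len(self.temperatures):
            raise SimulationError("temperatures must be strictly decreasing")
        if not 0.0 <= self.zero_inflation_target <= 1.0:
            raise SimulationError("zero_inflation_target must be in [0, 1]")
        if self.mass_mean_g <= 0 or self.mass_sd_g < 0:
            raise SimulationError("mass parameters invalid")
        for name, tp in self.traits.items():
            if tp.v_residual < 0 or tp.v_aquarium < 0 or tp.v_unit < 0:
                raise SimulationError(f"trait {name}: variances must be >= 0")
            eig = np.linalg.eigvalsh(tp.g_matrix)
            if eig.min() < -1e-10:
                raise SimulationError(
                    f"trait {name}: G matrix is not positive semi-definite"
                )
        self.schedule.validate()

    def centred(self, temperature: float) -> float:
        return temperature - self.centre_temperature

    def rng(self, stream: str, *extra: int) -> np.random.Generator:
        """Deterministic per-component generator derived from the study seed."""
        key = (int(self.seed), _STREAMS[stream]) + tuple(int(e) for e in extra)
        return np.random.default_rng(np.random.SeedSequence(key))

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return conv(self)


def cooling_rate_c_per_day(
    t_start_c: float, t_end_c: float, duration_days: float
) -> float:
    """Average cooling rate over an experiment, degC/day (positive when cooling)."""
    if duration_days <= 0:
        raise SimulationError("duration must be positive")
    return (t_start_c - t_end_c) / duration_days


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------

def draw_individuals(config: SimulationConfig) -> pd.DataFrame:
    """Draw each fish's per-trait (intercept, slope) pair and baseline mass.

    Reaction-norm effects come from the configured bivariate normal G per
    trait; aquarium assignment is round-robin.  Columns: fish_id,
    aquarium_id, baseline_mass_g, and ``<trait>_intercept`` /
    ``<trait>_slope`` deviations (zero-mean, around the fixed effects).
    """
    config.validate()
    rng = config.rng("individuals")
    n = config.n_fish
    out = pd.DataFrame(
        {
            "fish_id": [f"F{i:03d}" for i in range(n)],
            "aquarium_id": [f"A{i % config.n_aquaria}" for i in range(n)],
        }
    )
    mass = rng.normal(config.mass_mean_g, config.mass_sd_g, size=n)
    out["baseline_mass_g"] = np.clip(mass, 0.3 * config.mass_mean_g, None)
    for name, tp in config.traits.items():
        g = tp.g_matrix
        if tp.v_slope == 0.0 and tp.cov_int_slope == 0.0:
            u0 = rng.normal(0.0, np.sqrt(tp.v_intercept), size=n)
            u1 = np.zeros(n)
        else:
            draws = rng.multivariate_normal(np.zeros(2), g, size=n, method="cholesky")
            u0, u1 = draws[:, 0], draws[:, 1]
        out[f"{name}_intercept"] = u0
        out[f"{name}_slope"] = u1
    # induce configured cross-trait intercept correlations (shared-component
    # construction; preserves each trait's marginal intercept variance)
    for key, rho in config.intercept_correlation_pairs.items():
        a, b = key.split(":")
        if a not in config.traits or b not in config.traits:
            raise SimulationError(f"unknown trait in correlation pair {key!r}")
        if not -1.0 <= rho <= 1.0:
            raise SimulationError(f"correlation {key!r} outside [-1, 1]")
        if config.traits[b].cov_int_slope != 0.0:
            raise SimulationError(
                f"cross-trait correlation target {b!r} must not have its own "
                "intercept-slope covariance"
            )
        sd_a = np.sqrt(config.traits[a].v_intercept)
        sd_b = np.sqrt(config.traits[b].v_intercept)
        if sd_a == 0 or sd_b == 0:
            continue
        out[f"{b}_intercept"] = (
            rho * (sd_b / sd_a) * out[f"{a}_intercept"]
            + np.sqrt(1.0 - rho**2) * out[f"{b}_intercept"]
        )
    return out


def _aquarium_effects(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        name: rng.normal(0.0, np.sqrt(tp.v_aquarium), size=config.n_aquaria)
        for name, tp in config.traits.items()
    }


def _latent_intercept(config: SimulationConfig, trait: str, p_zero: float) -> float:
    """Latent probit intercept hitting a marginal zero proportion.

    The marginal P(positive) under intercept variance V_id, unit variance
    V_unit and residual 1 is Phi(mu / sqrt(1 + V_id + V_unit)).
    """
    tp = config.traits[trait]
    scale = np.sqrt(1.0 + tp.v_intercept + tp.v_unit + tp.v_aquarium)
    return float(ndtri(1.0 - p_zero) * scale)


def trait_intercept(config: SimulationConfig, trait: str) -> float:
    """Fixed-effect intercept; derived from zero-inflation targets for binary traits."""
    tp = config.traits[trait]
    if tp.intercept is not None:
        return tp.intercept
    if trait == "feeding":
        return _latent_intercept(config, trait, config.feeding_zero_proportion)
    return _latent_intercept(config, trait, config.zero_inflation_target)


# ---------------------------------------------------------------------------
# Masses and growth
# ---------------------------------------------------------------------------

def simulate_mass_trajectories(
    individuals: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Body mass of every fish at each measurement temperature.

    The generative rule inverts the specific-growth-rate definition: mass at
    the next temperature is ``mass * exp(SGR/100 * days)``, with the true SGR
    for an interval evaluated at the interval's midpoint temperature from the
    fish's growth reaction norm plus interval-level residual noise.  Weight
    loss (negative SGR) is allowed.
    """
    if (individuals["baseline_mass_g"] <= 0).any():
        raise SimulationError("baseline masses must be positive")
    rng = config.rng("masses")
    tp = config.traits["sgr"]
    aq = _aquarium_effects(config, config.rng("masses", 1))["sgr"]
    aq_idx = individuals["aquarium_id"].str.lstrip("A").astype(int).to_numpy()
    temps = list(config.temperatures)
    n = len(individuals)
    mass = individuals["baseline_mass_g"].to_numpy(float).copy()
    scaled_mass0 = (mass - config.mass_mean_g) / config.mass_sd_g
    rows = [
        pd.DataFrame(
            {
                "fish_id": individuals["fish_id"],
                "temperature_c": temps[0],
                "mass_g": mass.copy(),
            }
        )
    ]
    u0 = individuals["sgr_intercept"].to_numpy(float)
    u1 = individuals["sgr_slope"].to_numpy(float)
    intercept = trait_intercept(config, "sgr")
    for t_hi, t_lo in zip(temps, temps[1:]):
        mid_ct = config.centred((t_hi + t_lo) / 2.0)
        sgr = (
            intercept
            + tp.temp_slope * mid_ct
            + tp.mass_coef * scaled_mass0
            + u0
            + u1 * mid_ct
            + aq[aq_idx]
            + rng.normal(0.0, np.sqrt(tp.v_residual), size=n)
        )
        mass = mass * np.exp(sgr / 100.0 * config.interval_days)
        rows.append(
            pd.DataFrame(
                {"fish_id": individuals["fish_id"], "temperature_c": t_lo, "mass_g": mass.copy()}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Metabolic truth and O2 traces
# ---------------------------------------------------------------------------

def simulate_metabolic_truth(
    individuals: pd.DataFrame, masses: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-trial true SMR and MMR (mg/h), including trial-level residuals.

    Columns: fish_id, temperature_c, chamber_id, batch_id, mass_g,
    smr_norm / mmr_norm (reaction-norm value, no residual) and
    smr_true / mmr_true (the trial-level plateau / post-chase rate the trace
    simulator realises).
    """
    rng = config.rng("metabolic")
    aq_rng = config.rng("metabolic", 1)
    aq_eff = _aquarium_effects(config, aq_rng)
    n_chambers = config.batch_size  # chambers 0..14 hold fish; 15 is the blank
    chamber_eff = {
        name: aq_rng.normal(0.0, np.sqrt(tp.v_unit), size=n_chambers)
        for name, tp in config.traits.items()
    }
    aq_idx = individuals["aquarium_id"].str.lstrip("A").astype(int).to_numpy()
    mass_wide = masses.pivot(index="fish_id", columns="temperature_c", values="mass_g")
    mass_wide = mass_wide.loc[individuals["fish_id"]]
    rows = []
    for temp in config.temperatures:
        ct = config.centred(temp)
        m = mass_wide[temp].to_numpy(float)
        scaled_m = (m - config.mass_mean_g) / config.mass_sd_g
        allo = (m / config.mass_mean_g) ** (config.allometric_exponent - 1.0)
        rec = {"temperature_c": temp}
        for name in ("smr", "mmr"):
            tp = config.traits[name]
            u0 = individuals[f"{name}_intercept"].to_numpy(float)
            u1 = individuals[f"{name}_slope"].to_numpy(float)
            chamber = np.arange(len(individuals)) % config.batch_size
            norm = (
                trait_intercept(config, name)
                + tp.temp_slope * ct
                + tp.mass_coef * scaled_m
                + u0
                + u1 * ct
                + aq_eff[name][aq_idx]
                + chamber_eff[name][chamber]
            ) * allo
            obs = norm + rng.normal(0.0, np.sqrt(tp.v_residual), size=len(norm))
            rec[f"{name}_norm"] = norm
            rec[f"{name}_true"] = np.clip(obs, 0.01, None)
        chamber = np.arange(len(individuals)) % config.batch_size
        batch = np.arange(len(individuals)) // config.batch_size
        rows.append(
            pd.DataFrame(
                {
                    "fish_id": individuals["fish_id"],
                    "temperature_c": temp,
                    "chamber_id": [f"C{c:02d}" for c in chamber],
                    "batch_id": [f"T{temp:g}_B{b}" for b in batch],
                    "mass_g": m,
                    "smr_norm": rec["smr_norm"],
                    "smr_true": rec["smr_true"],
                    "mmr_norm": rec["mmr_norm"],
                    "mmr_true": rec["mmr_true"],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    # enforce MMR > SMR at the trial level (an exhausted fish respires above
    # its eventual plateau)
    low = out["mmr_true"] <= out["smr_true"]
    out.loc[low, "mmr_true"] = out.loc[low, "smr_true"] * 1.5
    return out


def _cycle_starts(
    temp: float, schedule: TrialSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-phase (start_s, duration_s) arrays for one trial, cycle 0 first."""
    first = schedule.mmr_first_closed_minutes_by_temperature[temp] * 60.0
    closed = schedule.closed_minutes_by_temperature[temp] * 60.0
    flush = schedule.flush_minutes * 60.0
    total = schedule.trial_hours * 3600.0
    starts, durs = [0.0], [first]
    t = first + flush
    while t + closed <= total:
        starts.append(t)
        durs.append(closed)
        t += closed + flush
    return np.asarray(starts), np.asarray(durs)


def background_mg_h(config: SimulationConfig, t_s: np.ndarray | float) -> np.ndarray:
    """Blank-chamber background MO2 (mg/h) as a function of trial time."""
    t_h = np.asarray(t_s, dtype=float) / 3600.0
    return config.background_rate_mg_h_per_h * np.clip(
        t_h - config.background_onset_h, 0.0, None
    )


def simulate_o2_trace(
    trial_id: str,
    chamber_id: str,
    temperature_c: float,
    fish_mass_g: Optional[float],
    smr_mg_h: float,
    mmr_mg_h: float,
    config: SimulationConfig,
    background_scale: float = 1.0,
    trial_index: int = 0,
) -> RespirometryTrace:
    """Synthesise one intermittent-closed trace.

    During closed phases O2 declines linearly at rate
    ``(MO2_fish(t) + background(t)) / (chamber volume - fish volume)``
    with Gaussian measurement noise; flush phases ramp O2 back toward
    saturation.  The fish's MO2 decays exponentially from MMR toward the SMR
    plateau with time constant ``mmr_recovery_tau_h``.  Blank traces pass
    ``fish_mass_g=None`` and ``smr_mg_h=mmr_mg_h=0``.
    """
    schedule = config.schedule
    vol_l = schedule.chamber_volume_ml / 1000.0
    fish_vol = 0.0 if fish_mass_g is None else fish_mass_g / 1000.0
    if fish_vol >= vol_l:
        raise SimulationError(
            f"trial {trial_id}: fish volume exceeds chamber volume"
        )
    eff_vol = vol_l - fish_vol
    rng = config.rng("trace", trial_index)
    starts, durs = _cycle_starts(temperature_c, schedule)
    dt = schedule.sampling_period_s
    tau_s = config.mmr_recovery_tau_h * 3600.0
    sat = config.o2_saturation_mg_l

    times, o2, phases = [], [], []
    level = sat
    total = schedule.trial_hours * 3600.0
    # the fish holds its post-chase maximum through the first (MMR) closed
    # phase; exponential recovery toward the SMR plateau starts once that
    # phase ends
    recovery_t0 = durs[0]
    for i, (s, d) in enumerate(zip(starts, durs)):
        t = np.arange(s, s + d + 0.5 * dt, dt)
        mid = s + d / 2.0
        mo2 = smr_mg_h + (mmr_mg_h - smr_mg_h) * np.exp(
            -max(0.0, mid - recovery_t0) / tau_s
        )
        bg = float(background_mg_h(config, mid)) * background_scale
        slope = -(mo2 + bg) / eff_vol / 3600.0  # mg/L/s
        seg = level + slope * (t - s)
        times.append(t)
        o2.append(seg)
        phases.append(np.full(len(t), PHASE_CLOSED, dtype=object))
        level = seg[-1]
        # flush back toward saturation
        f_end = starts[i + 1] if i + 1 < len(starts) else min(s + d + schedule.flush_minutes * 60.0, total)
        tf = np.arange(t[-1] + dt, f_end, dt)
        if len(tf):
            frac = (tf - tf[0]) / max(f_end - tf[0], dt)
            seg_f = level + (sat - level) * np.clip(frac * 1.25, 0.0, 1.0)
            times.append(tf)
            o2.append(seg_f)
            phases.append(np.full(len(tf), PHASE_FLUSH, dtype=object))
            level = seg_f[-1]
        else:
            level = sat
    time_s = np.concatenate(times)
    o2_arr = np.concatenate(o2)
    if config.o2_noise_sd_mg_l > 0:
        o2_arr = o2_arr + rng.normal(0.0, config.o2_noise_sd_mg_l, size=len(o2_arr))
    return RespirometryTrace(
        trial_id=trial_id,
        chamber_id=chamber_id,
        chamber_volume_l=vol_l,
        fish_mass_g=fish_mass_g,
        time_s=time_s,
        o2_mg_per_l=o2_arr,
        phase=np.concatenate(phases),
    )


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def simulate_activity(
    individuals: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Movement activity (day and night) and feeding records.

    Movement follows a latent-threshold (probit) model: latent = fixed
    effects + individual intercept (+ slope x centred temperature if
    configured) + arena effect + standard-normal residual; the fish moves iff
    the latent value is positive.  Conditional on moving, swimming speed is
    log-normal with a temperature-increasing median; distance = speed x
    trial duration.  Pellets eaten mix a point mass at the full ration with a
    uniform partial ration, conditional on eating at all.
    """
    config.validate()
    act_rng = config.rng("activity")
    feed_rng = config.rng("feeding")
    n = len(individuals)
    arena = np.arange(n) % config.batch_size
    aq_idx = individuals["aquarium_id"].str.lstrip("A").astype(int).to_numpy()
    scaled_m = (
        individuals["baseline_mass_g"].to_numpy(float) - config.mass_mean_g
    ) / config.mass_sd_g

    activity_rows = []
    for trait, period in (("activity_day", "day"), ("activity_night", "night")):
        tp = config.traits[trait]
        mu0 = trait_intercept(config, trait)
        u0 = individuals[f"{trait}_intercept"].to_numpy(float)
        u1 = individuals[f"{trait}_slope"].to_numpy(float)
        aq_eff = act_rng.normal(0.0, np.sqrt(tp.v_aquarium), size=config.n_aquaria)
        arena_eff = act_rng.normal(0.0, np.sqrt(tp.v_unit), size=config.batch_size)
        for temp in config.temperatures:
            ct = config.centred(temp)
            latent = (
                mu0
                + tp.temp_slope * ct
                + tp.mass_coef * scaled_m
                + u0
                + u1 * ct
                + aq_eff[aq_idx]
                + arena_eff[arena]
                + act_rng.normal(0.0, 1.0, size=n)
            )
            moved = latent > 0
            log_speed = act_rng.normal(-1.0 + 0.08 * ct, 0.6, size=n)
            speed = np.where(moved, np.exp(log_speed), 0.0)  # mm/s
            activity_rows.append(
                pd.DataFrame(
                    {
                        "fish_id": individuals["fish_id"],
                        "aquarium_id": individuals["aquarium_id"],
                        "arena_id": [f"R{a:02d}" for a in arena],
                        "temperature_c": temp,
                        "period": period,
                        "distance_mm": speed * config.behaviour_trial_s,
                        "duration_s": config.behaviour_trial_s,
                    }
                )
            )
    activity = pd.concat(activity_rows, ignore_index=True)

    tp = config.traits["feeding"]
    mu0 = trait_intercept(config, "feeding")
    u0 = individuals["feeding_intercept"].to_numpy(float)
    u1 = individuals["feeding_slope"].to_numpy(float)
    aq_eff = feed_rng.normal(0.0, np.sqrt(tp.v_aquarium), size=config.n_aquaria)
    arena_eff = feed_rng.normal(0.0, np.sqrt(tp.v_unit), size=config.batch_size)
    p_full = config.feeding_full_proportion / max(
        1e-12, 1.0 - config.feeding_zero_proportion
    )
    feeding_rows = []
    for temp in config.temperatures:
        ct = config.centred(temp)
        latent = (
            mu0
            + tp.temp_slope * ct
            + tp.mass_coef * scaled_m
            + u0
            + u1 * ct
            + aq_eff[aq_idx]
            + arena_eff[arena]
            + feed_rng.normal(0.0, 1.0, size=n)
        )
        ate = latent > 0
        full = feed_rng.random(n) < p_full
        partial = feed_rng.integers(1, config.feeding_ration, size=n)
        pellets = np.where(ate, np.where(full, config.feeding_ration, partial), 0)
        feeding_rows.append(
            pd.DataFrame(
                {
                    "fish_id": individuals["fish_id"],
                    "aquarium_id": individuals["aquarium_id"],
                    "arena_id": [f"R{a:02d}" for a in arena],
                    "temperature_c": temp,
                    "pellets": pellets,
                }
            )
        )
    return activity, pd.concat(feeding_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete simulated study bundle with its generative truth."""

    config: SimulationConfig
    individuals: pd.DataFrame
    masses: pd.DataFrame
    metabolic: pd.DataFrame  # per-trial truth incl. chamber/batch assignment
    activity: pd.DataFrame
    feeding: pd.DataFrame
    manifest: pd.DataFrame
    background_scales: dict[str, float]

    @property
    def truth(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "individuals": self.individuals.to_dict(orient="list"),
        }

    def blank_trial_ids(self) -> list[str]:
        return sorted(self.manifest["blank_trial_id"].unique())

    def trace_for(self, trial_id: str) -> RespirometryTrace:
        """Generate (deterministically) the O2 trace for one trial id."""
        if trial_id.startswith("blank_"):
            batch = trial_id[len("blank_"):]
            temp = float(batch.split("_")[0][1:])
            idx = self._trial_index(trial_id)
            return simulate_o2_trace(
                trial_id, "C15", temp, None, 0.0, 0.0, self.config,
                background_scale=self.background_scales.get("C15", 1.0),
                trial_index=idx,
            )
        rec = self.manifest.loc[self.manifest["trial_id"] == trial_id]
        if rec.empty:
            raise SimulationError(f"unknown trial id {trial_id}")
        r = rec.iloc[0]
        truth = self.metabolic[
            (self.metabolic["fish_id"] == r["fish_id"])
            & (self.metabolic["temperature_c"] == r["temperature_c"])
        ].iloc[0]
        return simulate_o2_trace(
            trial_id,
            r["chamber_id"],
            float(r["temperature_c"]),
            float(r["fish_mass_g"]),
            float(truth["smr_true"]),
            float(truth["mmr_true"]),
            self.config,
            background_scale=self.background_scales.get(r["chamber_id"], 1.0),
            trial_index=self._trial_index(trial_id),
        )

    def _trial_index(self, trial_id: str) -> int:
        all_ids = list(self.manifest["trial_id"]) + self.blank_trial_ids()
        return all_ids.index(trial_id)

    def iter_traces(self) -> Iterator[RespirometryTrace]:
        for tid in list(self.manifest["trial_id"]) + self.blank_trial_ids():
            yield self.trace_for(tid)

    def write(self, outdir: str | Path, include_traces: bool = False) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "individuals.csv", index=False)
        self.masses.to_csv(out / "masses.csv", index=False)
        self.activity.to_csv(out / "activity.csv", index=False)
        self.feeding.to_csv(out / "feeding.csv", index=False)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=float)
        if include_traces:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            for trace in self.iter_traces():
                trace.to_frame().to_csv(tdir / f"{trace.trial_id}.csv", index=False)


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study from one config (and its seed).

    Traces are synthesised lazily (``study.trace_for`` / ``iter_traces``)
    from the stored per-trial truth, so the bundle itself stays small; the
    same trial id always yields a byte-identical trace.
    """
    config = config or SimulationConfig()
    config.validate()
    individuals = draw_individuals(config)
    masses = simulate_mass_trajectories(individuals, config)
    metabolic = simulate_metabolic_truth(individuals, masses, config)
    activity, feeding = simulate_activity(individuals, config)

    bg_rng = config.rng("background")
    chambers = [f"C{c:02d}" for c in range(config.batch_size)] + ["C15"]
    # chamber-to-chamber variation in how much microbial load develops
    background_scales = {
        c: float(np.exp(bg_rng.normal(0.0, 0.1))) for c in chambers
    }

    # post-trial background recordings are taken immediately after the last
    # cycle, so their level matches the blank curve at its final midpoint
    last_mid_s = {}
    for temp in config.temperatures:
        starts, durs = _cycle_starts(temp, config.schedule)
        last_mid_s[temp] = starts[-1] + durs[-1] / 2.0
    manifest = metabolic[
        ["fish_id", "temperature_c", "chamber_id", "batch_id", "mass_g"]
    ].copy()
    manifest = manifest.rename(columns={"mass_g": "fish_mass_g"})
    manifest.insert(
        0,
        "trial_id",
        [
            f"{r.fish_id}_T{r.temperature_c:g}"
            for r in manifest.itertuples(index=False)
        ],
    )
    manifest["post_fish_background_mean_mg_h"] = [
        float(background_mg_h(config, last_mid_s[t])) * background_scales[c]
        + bg_rng.normal(0.0, config.post_fish_noise_sd_mg_h)
        for c, t in zip(manifest["chamber_id"], manifest["temperature_c"])
    ]
    manifest["post_fish_background_mean_mg_h"] = manifest[
        "post_fish_background_mean_mg_h"
    ].clip(lower=0.0)
    manifest["blank_trial_id"] = "blank_" + manifest["batch_id"]
    return SyntheticStudy(
        config=config,
        individuals=individuals,
        masses=masses,
        metabolic=metabolic,
        activity=activity,
        feeding=feeding,
        manifest=manifest,
        background_scales=background_scales,
    )
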