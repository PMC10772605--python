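"""End-to-end pipeline: simulate -> respirometry -> traits -> models -> report.

One :func:`run_pipeline` call executes every stage on a synthetic study (or
user-supplied tables), producing a :class:`RunReport` with per-trait DIC
comparisons, temperature-specific repeatability, reaction-norm correlations
and retention bookkeeping.  The run is idempotent under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as tio
from . import respirometry as resp
from .models import (
    McmcSettings,
    fit_mixed,
    ModelSpec,
    PriorConfig,
    compare_random_structures,
    summarize_fixed_effects,
)
from .repeatability import (
    reaction_norm_correlation,
    repeatability_curve,
)
from .simulate import SimulationConfig, SyntheticStudy, simulate_study
from .traits import Exclusions, assemble_trait_table, growth_records

log = logging.getLogger("thermnorm")

#: analysis family per trait
TRAIT_FAMILIES = {
    "smr": "gaussian",
    "mmr": "gaussian",
    "as": "gaussian",
    "sgr": "gaussian",
    "activity_day": "binary",
    "activity_night": "binary",
    "feeding": "binary",
}
DEFAULT_ANALYSIS_TRAITS = ("smr", "mmr", "as", "sgr", "activity_day", "activity_night")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    outdir: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    priors: PriorConfig = field(default_factory=PriorConfig)
    analysis_traits: tuple[str, ...] = DEFAULT_ANALYSIS_TRAITS
    #: process raw simulated O2 traces (full fidelity) vs use trial-level truth
    trace_level: bool = True
    exclusions: Exclusions = field(default_factory=Exclusions)
    #: (trait_a, trait_b, kind) bivariate correlations to estimate
    correlation_pairs: tuple[tuple[str, str, str], ...] = (
        ("smr", "as", "slope-slope"),
        ("activity_day", "sgr", "intercept-intercept"),
    )
    include_feeding: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if "traits" in sim:
                from .simulate import TraitParams

                sim["traits"] = {
                    name: tp if not isinstance(tp, dict) else TraitParams(**tp)
                    for name, tp in sim["traits"].items()
                }
            if "schedule" in sim and isinstance(sim["schedule"], dict):
                from .simulate import TrialSchedule

                sim["schedule"] = TrialSchedule(**sim["schedule"])
            if "temperatures" in sim:
                sim["temperatures"] = tuple(sim["temperatures"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "mcmc" in kwargs:
            kwargs["mcmc"] = McmcSettings(**kwargs["mcmc"])
        if "priors" in kwargs:
            kwargs["priors"] = PriorConfig(**kwargs["priors"])
        if "exclusions" in kwargs:
            ex = kwargs["exclusions"]
            kwargs["exclusions"] = Exclusions(
                fish=list(ex.get("fish", [])),
                observations=[tuple(o) for o in ex.get("observations", [])],
            )
        for key in ("analysis_traits",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "correlation_pairs" in kwargs:
            kwargs["correlation_pairs"] = tuple(
                tuple(p) for p in kwargs["correlation_pairs"]
            )
        return cls(**kwargs)

    def fingerprint(self) -> str:
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

        return tio.config_fingerprint(conv(self))


@dataclass
class RunReport:
    """Headline outputs of one pipeline run, traceable to its output files."""

    seed: int
    config_fingerprint: str
    comparisons: pd.DataFrame  # trait, dic_intercepts, dic_slopes, delta_dic, support
    fixed_effects: pd.DataFrame
    repeatability: pd.DataFrame  # trait, temperature_c, rc_mean, rc_lo, rc_hi
    correlations: pd.DataFrame
    retention: pd.DataFrame
    extreme_rc: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_fingerprint": self.config_fingerprint,
            "comparisons": self.comparisons.to_dict(orient="records"),
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
            "repeatability": self.repeatability.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "retention": self.retention.to_dict(orient="records"),
            "extreme_rc": self.extreme_rc.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=float)


def metabolic_estimates_from_study(
    study: SyntheticStudy, trace_level: bool = True
) -> pd.DataFrame:
    """Metabolic SMR/MMR/AS per trial, via the respirometry pipeline.

    With ``trace_level=True`` every simulated O2 trace is synthesised and
    processed exactly as real data would be (cycle slopes, background
    correction, lowest-10% SMR rule).  With ``trace_level=False`` the
    simulator's trial-level truth is used directly, which is faster and
    isolates the statistical stages from trace-processing error.
    """
    if not trace_level:
        est = study.metabolic.rename(
            columns={"smr_true": "smr_mg_h", "mmr_true": "mmr_mg_h", "mass_g": "fish_mass_g"}
        ).copy()
        est["as_mg_h"] = est["mmr_mg_h"] - est["smr_mg_h"]
        est["mass_g"] = est["fish_mass_g"]
        return est[
            ["fish_id", "temperature_c", "chamber_id", "smr_mg_h", "mmr_mg_h", "as_mg_h", "mass_g"]
        ]

    blank_series: dict[str, np.ndarray] = {}
    for blank_id in study.blank_trial_ids():
        trace = study.trace_for(blank_id)
        series = resp.trace_mo2_series(trace)
        blank_series[blank_id] = series["mo2_mg_h"].to_numpy(float)

    rows = []
    for rec in study.manifest.itertuples(index=False):
        trace = study.trace_for(rec.trial_id)
        est = resp.process_trial(
            trace,
            blank_series[rec.blank_trial_id],
            float(rec.post_fish_background_mean_mg_h),
            fish_id=str(rec.fish_id),
            temperature_c=float(rec.temperature_c),
        )
        rows.append(
            {
                "fish_id": est.fish_id,
                "temperature_c": est.temperature_c,
                "chamber_id": rec.chamber_id,
                "smr_mg_h": est.smr_mg_h,
                "mmr_mg_h": est.mmr_mg_h,
                "as_mg_h": est.as_mg_h,
                "mass_g": rec.fish_mass_g,
                "n_cycles": est.n_cycles,
                "n_lowest_used": est.n_lowest_used,
                "n_outliers_removed": est.n_outliers_removed,
                "background_onset_cycle": est.background_onset_cycle,
            }
        )
    return pd.DataFrame(rows)


def build_trait_table(
    study: SyntheticStudy,
    estimates: pd.DataFrame,
    exclusions: Optional[Exclusions] = None,
    include_feeding: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    growth = growth_records(
        study.masses,
        ladder=study.config.temperatures,
        interval_days=study.config.interval_days,
    )
    fish_info = study.individuals[["fish_id", "aquarium_id"]]
    return assemble_trait_table(
        metabolic_estimates=estimates,
        growth=growth,
        activity=study.activity,
        feeding=study.feeding if include_feeding else None,
        fish_info=fish_info,
        masses=study.masses,
        exclusions=exclusions,
        centre_temperature=study.config.centre_temperature,
        feeding_ration=study.config.feeding_ration,
    )


def _trait_seed(base_seed: int, trait: str, structure: str) -> int:
    # stable across processes (unlike hash())
    import zlib

    h = zlib.crc32(f"{trait}:{structure}".encode()) % 10_000
    return (int(base_seed) * 10_007 + h) % (2**31 - 1)


def analyse_trait_table(
    table: pd.DataFrame, config: RunConfig
) -> RunReport:
    """Fit both random structures per trait, compare, and summarise."""
    comparisons, fixed_rows, rc_rows, corr_rows, extreme_rows = [], [], [], [], []
    fits = {}
    slope_support: dict[str, bool] = {}
    for trait in config.analysis_traits:
        family = TRAIT_FAMILIES[trait]
        pair = {}
        for structure in ("intercepts", "slopes"):
            spec = ModelSpec(
                traits=(trait,),
                families=(family,),
                random_structure=structure,
                priors=config.priors,
                mcmc=config.mcmc,
                seed=_trait_seed(config.seed, trait, structure),
            )
            pair[structure] = fit_mixed(table, spec)
        fits[trait] = pair
        comp = compare_random_structures(pair["intercepts"], pair["slopes"])
        slope_support[trait] = comp.support == "strong"
        comparisons.append(
            {
                "trait": trait,
                "dic_intercepts": comp.dic_intercepts,
                "dic_slopes": comp.dic_slopes,
                "delta_dic": comp.delta_dic,
                "support": comp.support,
            }
        )
        log.info(
            "trait %-14s dDIC=%8.2f support=%s", trait, comp.delta_dic, comp.support
        )

        best = pair["slopes"] if slope_support[trait] else pair["intercepts"]
        fe = summarize_fixed_effects(best)
        fe.insert(0, "trait", trait)
        fe.insert(1, "structure", best.spec.random_structure)
        fixed_rows.append(fe)

        grid_step = 0.1 if trait == "sgr" else 1.0
        temps = sorted(table.loc[table["trait"] == trait, "temperature_c"].unique())
        curve = repeatability_curve(
            best,
            grid_step=grid_step,
            t_range=(min(temps), max(temps)),
            centre_temperature=config.simulation.centre_temperature,
        )
        df = curve.to_frame()
        df.insert(0, "trait", trait)
        df.insert(1, "structure", best.spec.random_structure)
        rc_rows.append(df)
        from .repeatability import find_extreme_repeatability

        for mode in ("min", "max"):
            t_ext, flat = find_extreme_repeatability(curve, mode)
            extreme_rows.append(
                {"trait": trait, "mode": mode, "temperature_c": t_ext, "flat": flat}
            )

        if slope_support[trait]:
            est = reaction_norm_correlation(pair["slopes"], "intercept-slope")
            corr_rows.append(
                {
                    "trait_a": trait,
                    "trait_b": trait,
                    "kind": est.kind,
                    "mean": est.mean,
                    "hpd_lo": est.hpd_lo,
                    "hpd_hi": est.hpd_hi,
                    "significant": est.significant,
                }
            )

    for trait_a, trait_b, kind in config.correlation_pairs:
        if trait_a not in config.analysis_traits or trait_b not in config.analysis_traits:
            continue
        if kind == "slope-slope" and not (
            slope_support.get(trait_a) and slope_support.get(trait_b)
        ):
            log.info(
                "skipping slope-slope correlation %s-%s: no random-slope support",
                trait_a,
                trait_b,
            )
            continue
        structure = "slopes" if kind == "slope-slope" else "intercepts"
        spec = ModelSpec(
            traits=(trait_a, trait_b),
            families=(TRAIT_FAMILIES[trait_a], TRAIT_FAMILIES[trait_b]),
            random_structure=structure,
            priors=config.priors,
            mcmc=config.mcmc,
            seed=_trait_seed(config.seed, f"{trait_a}+{trait_b}", structure),
        )
        bi_fit = fit_mixed(table, spec)
        est = reaction_norm_correlation(
            bi_fit, kind, traits=(trait_a, trait_b), slope_support=slope_support
        )
        corr_rows.append(
            {
                "trait_a": trait_a,
                "trait_b": trait_b,
                "kind": est.kind,
                "mean": est.mean,
                "hpd_lo": est.hpd_lo,
                "hpd_hi": est.hpd_hi,
                "significant": est.significant,
            }
        )

    retention = (
        table.groupby(["trait", "temperature_c"]).size().rename("n_observations").reset_index()
    )
    return RunReport(
        seed=config.seed,
        config_fingerprint=config.fingerprint(),
        comparisons=pd.DataFrame(comparisons),
        fixed_effects=pd.concat(fixed_rows, ignore_index=True)
        if fixed_rows
        else pd.DataFrame(),
        repeatability=pd.concat(rc_rows, ignore_index=True) if rc_rows else pd.DataFrame(),
        correlations=pd.DataFrame(
            corr_rows,
            columns=["trait_a", "trait_b", "kind", "mean", "hpd_lo", "hpd_hi", "significant"],
        ),
        retention=retention,
        extreme_rc=pd.DataFrame(extreme_rows),
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full study pipeline from one configuration."""
    logging.basicConfig(level=config.log_level)
    stage = "simulate"
    try:
        study = simulate_study(config.simulation)
        log.info("simulated %d fish x %d temperatures", config.simulation.n_fish,
                 len(config.simulation.temperatures))
        stage = "respirometry"
        estimates = metabolic_estimates_from_study(study, config.trace_level)
        log.info("processed %d metabolic trials", len(estimates))
        stage = "traits"
        table, retention = build_trait_table(
            study, estimates, config.exclusions, config.include_feeding
        )
        log.info("trait table: %d rows, %d traits", len(table), table["trait"].nunique())
        stage = "models"
        report = analyse_trait_table(table, config)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fp = config.fingerprint()
        tio.write_table(estimates, out / "metabolic_estimates.csv", config.seed, fp)
        tio.write_trait_table(table, out / "trait_table.csv", config.seed, fp)
        tio.write_table(report.comparisons, out / "comparison.csv", config.seed, fp)
        tio.write_table(report.fixed_effects, out / "fixed_effects.csv", config.seed, fp)
        tio.write_table(report.correlations, out / "correlations.csv", config.seed, fp)
        tio.write_table(report.retention, out / "retention.csv", config.seed, fp)
        for trait, grp in report.repeatability.groupby("trait"):
            tio.write_table(
                grp.drop(columns=["trait"]),
                out / f"repeatability_{trait}.csv",
                config.seed,
                fp,
            )
        with open(out / "report.json", "w") as fh:
            fh.write(report.to_json())
    return report
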