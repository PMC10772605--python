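"""Conditional (temperature-specific) repeatability and reaction-norm correlations.

Repeatability at temperature T partitions variance from the random-slopes
model: the among-individual variance at centred temperature t is

    V_id(t) = V_int + 2 t Cov(int, slope) + t^2 V_slope

and the conditional repeatability is R_C(t) = V_id(t) / (V_id(t) + V_res).
For binary traits the residual is the latent probit variance (1), so R_C is
on the liability scale.  Aquarium and chamber/arena variances are excluded
from the denominator by default (the ratio of among-individual to
among-individual-plus-residual variance); a switch adds them for sensitivity
analysis.

R_C is summarised per grid point from per-draw ratios (mean of ratios), so
the posterior interval propagates variance-component uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import FittedModel, ModelError, hpd_interval


class RepeatabilityError(ValueError):
    pass


def conditional_repeatability(
    v_int: np.ndarray | float,
    v_slope: np.ndarray | float,
    cov: np.ndarray | float,
    v_res: np.ndarray | float,
    centred_t: float,
    extra_variance: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, int]:
    """Per-draw R_C at one centred temperature; returns (draws, n_clipped).

    Draws where the quadratic form goes (numerically) negative are clipped
    to zero and counted.
    """
    v_id = (
        np.asarray(v_int, dtype=float)
        + 2.0 * centred_t * np.asarray(cov, dtype=float)
        + centred_t**2 * np.asarray(v_slope, dtype=float)
    )
    v_id = np.atleast_1d(v_id)
    n_clip = int((v_id < 0).sum())
    v_id = np.clip(v_id, 0.0, None)
    denom = v_id + np.asarray(v_res, dtype=float) + np.asarray(extra_variance, dtype=float)
    return v_id / denom, n_clip


@dataclass
class RepeatabilityCurve:
    """R_C(T) posterior mean and 95% interval over a raw-temperature grid."""

    trait: str
    temperature_c: np.ndarray
    rc_mean: np.ndarray
    rc_lo: np.ndarray
    rc_hi: np.ndarray
    grid_step: float
    n_clipped: int
    flat: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_c": self.temperature_c,
                "rc_mean": self.rc_mean,
                "rc_lo": self.rc_lo,
                "rc_hi": self.rc_hi,
            }
        )

    def at(self, temperature_c: float) -> float:
        i = int(np.argmin(np.abs(self.temperature_c - temperature_c)))
        return float(self.rc_mean[i])


def repeatability_curve(
    fit: FittedModel,
    grid: Optional[Sequence[float]] = None,
    grid_step: float = 1.0,
    t_range: tuple[float, float] = (2.0, 14.0),
    centre_temperature: float = 8.0,
    include_group_variances: bool = False,
    trait: Optional[str] = None,
) -> RepeatabilityCurve:
    """Conditional repeatability curve from a fitted univariate model.

    An intercepts-only fit yields a flat curve (the marginal repeatability).
    The grid is on the raw temperature scale and mapped through the centring
    constant; by default it spans the measured range at ``grid_step``.
    """
    if trait is None:
        trait = fit.spec.traits[0]
    prefix = f"{trait}_" if fit.spec.is_bivariate else ""
    comp_int = prefix + "intercept"
    v_int = fit.variance_draws(comp_int)
    has_slopes = fit.spec.random_structure == "slopes"
    if has_slopes:
        v_slope = fit.variance_draws(prefix + "slope")
        cov = fit.covariance_draws(comp_int, prefix + "slope")
    else:
        v_slope = np.zeros_like(v_int)
        cov = np.zeros_like(v_int)
    v_res = fit.residual_draws(trait)
    extra = 0.0
    if include_group_variances:
        extra = np.zeros_like(v_int)
        for col in fit.samples.columns:
            if col.startswith("V_aquarium") or col.startswith("V_unit"):
                extra = extra + fit.samples[col].to_numpy()

    if grid is None:
        lo, hi = t_range
        grid = np.round(np.arange(lo, hi + grid_step / 2, grid_step), 10)
    grid = np.asarray(grid, dtype=float)

    means, los, his = [], [], []
    n_clip = 0
    for t_raw in grid:
        ct = t_raw - centre_temperature
        draws, clipped = conditional_repeatability(
            v_int, v_slope, cov, v_res, ct, extra
        )
        n_clip += clipped
        means.append(float(draws.mean()))
        lo_i, hi_i = hpd_interval(draws)
        los.append(lo_i)
        his.append(hi_i)

    means_arr = np.asarray(means)
    flat = bool(len(means_arr) == 0 or np.ptp(means_arr) < 1e-12)
    return RepeatabilityCurve(
        trait=trait,
        temperature_c=grid,
        rc_mean=means_arr,
        rc_lo=np.asarray(los),
        rc_hi=np.asarray(his),
        grid_step=float(grid_step),
        n_clipped=n_clip,
        flat=flat,
    )


def find_extreme_repeatability(
    curve: RepeatabilityCurve, mode: str = "min"
) -> tuple[float, bool]:
    """Grid temperature where the posterior-mean R_C is lowest (or highest).

    Ties are broken toward the warmer temperature.  Returns
    ``(temperature, flat)``; ``flat`` flags a constant curve, for which the
    warmest grid point is returned by convention.
    """
    if len(curve.temperature_c) == 0:
        raise RepeatabilityError("empty curve")
    if mode not in ("min", "max"):
        raise RepeatabilityError(f"unknown mode {mode!r}")
    vals = curve.rc_mean if mode == "min" else -curve.rc_mean
    best = vals.min()
    # warmer-temperature tie-break: among ties, take the largest temperature
    ties = curve.temperature_c[np.isclose(vals, best, rtol=0, atol=1e-12)]
    return float(ties.max()), curve.flat


@dataclass
class CorrelationEstimate:
    """Posterior summary of one reaction-norm correlation."""

    trait_a: str
    trait_b: str
    kind: str  # "intercept-intercept" | "intercept-slope" | "slope-slope"
    mean: float
    hpd_lo: float
    hpd_hi: float
    significant: bool


def reaction_norm_correlation(
    fit: FittedModel,
    kind: str = "intercept-slope",
    traits: Optional[tuple[str, str]] = None,
    slope_support: Optional[dict[str, bool]] = None,
) -> CorrelationEstimate:
    """Correlation between reaction-norm components from a fitted G matrix.

    * ``intercept-slope`` on a univariate slopes fit: within-trait
      correlation between individual intercepts and slopes.
    * ``intercept-intercept`` / ``slope-slope`` on a bivariate fit: the
      cross-trait correlation.  Slope-slope correlations are refused unless
      ``slope_support`` marks both traits as having random-slope support
      (correlating plasticities of traits without plasticity variation is
      meaningless).
    """
    if kind == "intercept-slope":
        if fit.spec.random_structure != "slopes":
            raise ModelError(
                "intercept-slope correlation needs a random-slopes fit"
            )
        trait = (traits or (fit.spec.traits[0],))[0]
        prefix = f"{trait}_" if fit.spec.is_bivariate else ""
        draws = fit.correlation_draws(prefix + "intercept", prefix + "slope")
        trait_a = trait_b = trait
    elif kind in ("intercept-intercept", "slope-slope"):
        if not fit.spec.is_bivariate:
            raise ModelError(f"{kind} correlation needs a bivariate fit")
        trait_a, trait_b = traits or fit.spec.traits
        comp = "slope" if kind == "slope-slope" else "intercept"
        if kind == "slope-slope":
            if fit.spec.random_structure != "slopes":
                raise ModelError("slope-slope correlation needs a slopes fit")
            support = slope_support or {}
            unsupported = [
                t for t in (trait_a, trait_b) if not support.get(t, False)
            ]
            if slope_support is not None and unsupported:
                raise ModelError(
                    "slope-slope correlation refused: no random-slope support "
                    f"for trait(s) {unsupported} (no among-individual "
                    "plasticity variation to correlate)"
                )
        draws = fit.correlation_draws(f"{trait_a}_{comp}", f"{trait_b}_{comp}")
    else:
        raise ModelError(f"unknown correlation kind {kind!r}")

    lo, hi = hpd_interval(draws)
    return CorrelationEstimate(
        trait_a=trait_a,
        trait_b=trait_b,
        kind=kind,
        mean=float(draws.mean()),
        hpd_lo=lo,
        hpd_hi=hi,
        significant=not (lo <= 0.0 <= hi),
    )


def plot_repeatability(curve: RepeatabilityCurve, ax=None):
    """Basic diagnostic plot of an R_C(T) curve with its 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(
        curve.temperature_c, curve.rc_lo, curve.rc_hi, alpha=0.25, lw=0
    )
    ax.plot(curve.temperature_c, curve.rc_mean, marker="o", ms=3)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("conditional repeatability $R_C$")
    ax.set_ylim(0, 1)
    ax.set_title(curve.trait)
    return ax


def correlation_from_g_block(g_block: np.ndarray) -> float:
    """Correlation implied by one 2x2 covariance block (single draw)."""
    g = np.asarray(g_block, dtype=float)
    denom = np.sqrt(g[0, 0] * g[1, 1])
    if denom == 0:
        return 0.0
    return float(np.clip(g[0, 1] / denom, -1.0, 1.0))
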