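"""Bayesian mixed models for thermal reaction norms.

Random-intercept and random-slope linear mixed models fitted by Gibbs
sampling, for Gaussian traits and for binary traits via probit latent-value
(Albert-Chib) data augmentation, plus bivariate models with a joint
individual-level covariance matrix across traits.  Models are compared with
the deviance information criterion (DIC, conditional-deviance convention).

Model
-----
For observation *i* of individual *j*::

    y_i = x_i' beta + z_i' u_j + a_aq(i) + c_unit(i) + e_i

with fixed effects ``x_i = (1, centred temperature, scaled mass[, their
interaction])``, individual effects ``u_j ~ N(0, G)`` where ``z_i = (1)``
(random intercepts) or ``(1, centred temperature)`` (random slopes),
holding-aquarium and measurement-unit (chamber/arena) intercepts, and
residual ``e_i ~ N(0, sigma2)``.  Binary traits model a latent Gaussian
liability with residual variance fixed at 1; the observation is 1 iff the
liability is positive.

Priors are weakly informative and parameter-expanded: variance components
get hierarchical inverse-Wishart / inverse-gamma priors equivalent to
half-t(nu) distributions on standard deviations (Huang-Wand construction);
fixed effects get a diffuse normal prior.  All full conditionals are
conjugate, so the sampler is a pure Gibbs scheme and deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = [
    "McmcSettings",
    "PriorConfig",
    "ModelSpec",
    "FittedModel",
    "ModelComparison",
    "fit_gaussian_mixed",
    "fit_binary_mixed",
    "fit_bivariate_mixed",
    "compute_dic",
    "compare_random_structures",
    "summarize_fixed_effects",
    "TEST_MCMC",
]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class McmcSettings:
    """Chain length settings (defaults mirror the long production profile)."""

    iterations: int = 650_000
    burnin: int = 50_000
    thin: int = 40

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burnin) // self.thin

    def validate(self) -> None:
        if self.burnin >= self.iterations or self.thin < 1:
            raise ModelError("invalid MCMC settings")


#: Short profile for tests and quick exploration (3000 posterior draws).
TEST_MCMC = McmcSettings(iterations=26_000, burnin=2_000, thin=8)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the parameter-expanded variance priors.

    ``nu`` and ``sd_scale`` give half-t(nu, scale) marginals on random-effect
    standard deviations; ``beta_variance`` is the diffuse normal prior
    variance on fixed effects; ``resid_nu``/``resid_scale`` parameterise the
    (near-flat) inverse-gamma prior on Gaussian residual variances.
    """

    nu: float = 1.0
    sd_scale: float = 5.0
    beta_variance: float = 1e8
    resid_nu: float = 0.002
    resid_scale: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: trait(s), family per trait, and the random structure."""

    traits: tuple[str, ...]
    families: tuple[str, ...]  # per trait: "gaussian" | "binary"
    random_structure: str = "slopes"  # "intercepts" | "slopes"
    include_interaction: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0
    ess_floor: float = 200.0

    def __post_init__(self) -> None:
        if self.random_structure not in ("intercepts", "slopes"):
            raise ModelError(f"unknown random structure {self.random_structure!r}")
        if len(self.traits) != len(self.families):
            raise ModelError("one family per trait required")
        for fam in self.families:
            if fam not in ("gaussian", "binary"):
                raise ModelError(f"unknown family {fam!r}")

    @property
    def is_bivariate(self) -> bool:
        return len(self.traits) == 2


# ---------------------------------------------------------------------------
# Random-variate helpers
# ---------------------------------------------------------------------------

def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _inv_wishart(
    rng: np.random.Generator, df: float, scale: np.ndarray
) -> np.ndarray:
    """Draw from IW(df, scale) via a Bartlett decomposition."""
    q = scale.shape[0]
    l_inv = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((q, q))
    for i in range(q):
        a[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    w = l_inv @ a
    w = w @ w.T
    return np.linalg.inv(w)


def _small_inv(m: np.ndarray) -> np.ndarray:
    """Inverse of a small SPD matrix (hand-rolled 1x1/2x2 fast paths)."""
    q = m.shape[0]
    if q == 1:
        return np.array([[1.0 / m[0, 0]]])
    if q == 2:
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    return np.linalg.inv(m)


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, positive: np.ndarray
) -> np.ndarray:
    """Unit-variance normals truncated to (0, inf) or (-inf, 0) per element."""
    lo = ndtr(-mean)  # P(z <= 0)
    u = rng.random(len(mean))
    arg = np.where(positive, lo + u * (1.0 - lo), u * lo)
    z = mean + ndtri(np.clip(arg, 1e-16, 1.0 - 1e-16))
    # guard the astronomically deep tail where the inverse-cdf saturates
    return np.where(positive, np.maximum(z, 1e-10), np.minimum(z, -1e-10))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass
class _Factor:
    name: str
    idx: np.ndarray  # level per row; -1 where the factor does not apply
    n_levels: int


@dataclass
class _Design:
    y: np.ndarray
    binary_rows: np.ndarray  # bool mask
    x: np.ndarray
    x_names: list[str]
    zid: np.ndarray  # (n, q)
    comp_names: list[str]
    fish_idx: np.ndarray
    fish_ids: list[str]
    trait_idx: np.ndarray  # residual-variance bin per row
    factors: list[_Factor]


def _factor_from(values: pd.Series, name: str) -> Optional[_Factor]:
    mask = values.notna()
    if mask.sum() == 0:
        return None
    codes = np.full(len(values), -1, dtype=int)
    lab, _ = pd.factorize(values[mask])
    codes[mask.to_numpy()] = lab
    n_lev = codes.max() + 1
    if n_lev < 2:
        return None  # a single level is indistinguishable from the intercept
    return _Factor(name, codes, n_lev)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> _Design:
    """Assemble response, fixed-effect and random-effect structures.

    For bivariate specs the rows of both traits are stacked; each trait gets
    its own block of fixed effects, its own residual-variance bin, its own
    aquarium/unit factors, and its own block of the individual-level random
    effect vector (so G spans both traits).
    """
    frames = []
    for t_i, trait in enumerate(spec.traits):
        sub = table[table["trait"] == trait].copy()
        sub = sub[sub["value"].notna()]
        if sub.empty:
            raise ModelError(f"no observations for trait {trait!r}")
        sub["_trait_idx"] = t_i
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)

    y = data["value"].to_numpy(float)
    trait_idx = data["_trait_idx"].to_numpy(int)
    binary_rows = np.zeros(len(data), dtype=bool)
    for t_i, fam in enumerate(spec.families):
        rows = trait_idx == t_i
        if fam == "binary":
            vals = set(np.unique(y[rows]))
            if not vals <= {0.0, 1.0}:
                raise ModelError(
                    f"trait {spec.traits[t_i]!r}: binary family needs 0/1 values"
                )
            if len(vals) < 2:
                raise ModelError(
                    f"trait {spec.traits[t_i]!r}: response has a single class"
                )
            binary_rows[rows] = True

    ct = data["centred_temperature"].to_numpy(float)
    sm = np.nan_to_num(data["scaled_mass"].to_numpy(float))

    # fixed effects, block-diagonal per trait
    cols = ["intercept", "ct", "mass"] + (["ct_mass"] if spec.include_interaction else [])
    p_per = len(cols)
    x = np.zeros((len(data), p_per * len(spec.traits)))
    x_names = []
    for t_i, trait in enumerate(spec.traits):
        rows = trait_idx == t_i
        base = t_i * p_per
        x[rows, base + 0] = 1.0
        x[rows, base + 1] = ct[rows]
        x[rows, base + 2] = sm[rows]
        if spec.include_interaction:
            x[rows, base + 3] = ct[rows] * sm[rows]
        prefix = f"{trait}." if spec.is_bivariate else ""
        x_names += [prefix + c for c in cols]
    for t_i, trait in enumerate(spec.traits):
        rows = trait_idx == t_i
        sub_x = x[np.ix_(rows, range(t_i * p_per, (t_i + 1) * p_per))]
        if np.linalg.matrix_rank(sub_x) < p_per:
            raise ModelError(
                f"trait {trait!r}: singular fixed-effect design "
                "(constant or collinear covariate)"
            )

    # individual random-effect design
    q_per = 2 if spec.random_structure == "slopes" else 1
    q = q_per * len(spec.traits)
    zid = np.zeros((len(data), q))
    comp_names = []
    for t_i, trait in enumerate(spec.traits):
        rows = trait_idx == t_i
        base = t_i * q_per
        zid[rows, base] = 1.0
        prefix = f"{trait}_" if spec.is_bivariate else ""
        comp_names.append(prefix + "intercept")
        if q_per == 2:
            zid[rows, base + 1] = ct[rows]
            comp_names.append(prefix + "slope")

    fish_cat, fish_ids = pd.factorize(data["fish_id"])
    if spec.random_structure == "slopes":
        counts = np.bincount(fish_cat)
        if counts.min() < 2:
            raise ModelError(
                "random slopes need at least 2 observations per individual"
            )
    if spec.is_bivariate:
        shared = set(data.loc[trait_idx == 0, "fish_id"]) & set(
            data.loc[trait_idx == 1, "fish_id"]
        )
        if len(shared) < 2:
            raise ModelError(
                "bivariate model needs at least 2 individuals observed on both traits"
            )

    factors: list[_Factor] = []
    for col, fname in (("aquarium_id", "aquarium"), ("unit_id", "unit")):
        if col not in data.columns:
            continue
        for t_i, trait in enumerate(spec.traits):
            rows = trait_idx == t_i
            vals = data[col].where(pd.Series(rows, index=data.index), other=pd.NA)
            suffix = f".{trait}" if spec.is_bivariate else ""
            fac = _factor_from(vals, fname + suffix)
            if fac is not None:
                factors.append(fac)

    return _Design(
        y=y,
        binary_rows=binary_rows,
        x=x,
        x_names=x_names,
        zid=zid,
        comp_names=comp_names,
        fish_idx=np.asarray(fish_cat, dtype=int),
        fish_ids=[str(f) for f in fish_ids],
        trait_idx=trait_idx,
        factors=factors,
    )


# ---------------------------------------------------------------------------
# The Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Posterior samples plus DIC and diagnostics for one fitted model."""

    spec: ModelSpec
    samples: pd.DataFrame
    g_draws: np.ndarray  # (n_draws, q, q)
    component_names: list[str]
    fish_ids: list[str]
    u_mean: np.ndarray  # posterior-mean individual effects (n_fish, q)
    dic: float
    p_d: float
    deviance_at_mean: float
    ess: dict[str, float]
    low_ess: bool

    def variance_draws(self, component: str) -> np.ndarray:
        i = self.component_names.index(component)
        return self.g_draws[:, i, i]

    def covariance_draws(self, comp_a: str, comp_b: str) -> np.ndarray:
        i = self.component_names.index(comp_a)
        j = self.component_names.index(comp_b)
        return self.g_draws[:, i, j]

    def correlation_draws(self, comp_a: str, comp_b: str) -> np.ndarray:
        cov = self.covariance_draws(comp_a, comp_b)
        va = self.variance_draws(comp_a)
        vb = self.variance_draws(comp_b)
        denom = np.sqrt(np.clip(va * vb, 1e-300, None))
        return np.clip(cov / denom, -1.0, 1.0)

    def residual_draws(self, trait: Optional[str] = None) -> np.ndarray:
        if trait is None:
            trait = self.spec.traits[0]
        t_i = self.spec.traits.index(trait)
        if self.spec.families[t_i] == "binary":
            return np.ones(len(self.samples))
        col = f"V_residual.{trait}" if self.spec.is_bivariate else "V_residual"
        return self.samples[col].to_numpy()


def fit_mixed(table: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit any supported model (the family-specific wrappers call this)."""
    spec.mcmc.validate()
    design = build_design(table, spec)
    return _run_gibbs(design, spec)


def _run_gibbs(d: _Design, spec: ModelSpec) -> FittedModel:
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 101)))
    pr = spec.priors
    mc = spec.mcmc
    n, p = d.x.shape
    q = d.zid.shape[1]
    n_fish = len(d.fish_ids)
    n_traits = len(spec.traits)
    nu, a_sq = pr.nu, pr.sd_scale**2

    # --- precomputations -------------------------------------------------
    # per-trait X'X and per-fish Z'Z blocks (weights are constant per trait
    # within an iteration, so these are reweighted scalar-wise each sweep)
    xtx = np.zeros((n_traits, p, p))
    ztz = np.zeros((n_traits, n_fish, q, q))
    for t_i in range(n_traits):
        rows = d.trait_idx == t_i
        xs = d.x[rows]
        xtx[t_i] = xs.T @ xs
        zs = d.zid[rows]
        fi = d.fish_idx[rows]
        for j in range(q):
            for k in range(j, q):
                v = np.bincount(fi, weights=zs[:, j] * zs[:, k], minlength=n_fish)
                ztz[t_i, :, j, k] = v
                if k != j:
                    ztz[t_i, :, k, j] = v
    factor_counts = [
        [
            np.bincount(
                f.idx[(f.idx >= 0) & (d.trait_idx == t_i)], minlength=f.n_levels
            )
            for t_i in range(n_traits)
        ]
        for f in d.factors
    ]

    # --- state -----------------------------------------------------------
    beta = np.zeros(p)
    u = np.zeros((n_fish, q))
    g = np.eye(q)
    g_aux = np.full(q, 1.0)
    fac_eff = [np.zeros(f.n_levels) for f in d.factors]
    fac_v = [1.0 for _ in d.factors]
    fac_aux = [1.0 for _ in d.factors]
    sig2 = np.ones(n_traits)
    resid_fixed = np.array([fam == "binary" for fam in spec.families])
    ystar = d.y.astype(float).copy()
    y_sign = d.y[d.binary_rows] > 0.5

    def factor_contrib() -> np.ndarray:
        out = np.zeros(n)
        for f, eff in zip(d.factors, fac_eff):
            m = f.idx >= 0
            out[m] += eff[f.idx[m]]
        return out

    n_draws = mc.n_draws
    store_beta = np.empty((n_draws, p))
    store_g = np.empty((n_draws, q, q))
    store_fv = np.empty((n_draws, len(d.factors)))
    store_sig2 = np.empty((n_draws, n_traits))
    store_dev = np.empty(n_draws)
    eta_sum = np.zeros(n)
    u_sum = np.zeros((n_fish, q))
    keep = 0

    i_beta_prior = np.eye(p) / pr.beta_variance
    n_per_trait = np.array([(d.trait_idx == t).sum() for t in range(n_traits)])

    univariate = n_traits == 1
    has_binary = bool(d.binary_rows.any())
    x_t = np.ascontiguousarray(d.x.T)
    zid_cols = [np.ascontiguousarray(d.zid[:, k]) for k in range(q)]
    any_binary_rows = d.binary_rows
    f_contrib = factor_contrib()
    masks = [f.idx >= 0 for f in d.factors]
    fidx_safe = [np.clip(f.idx, 0, None) for f in d.factors]
    trait_rows = [d.trait_idx == t_i for t_i in range(n_traits)]

    for it in range(mc.iterations):
        w = 1.0 / sig2  # per-trait precision
        w_row = w[d.trait_idx] if not univariate else None
        u_contrib = np.einsum("nq,nq->n", d.zid, u[d.fish_idx])

        # -- latent liabilities for binary rows
        if has_binary:
            eta_b = (
                d.x[any_binary_rows] @ beta
                + u_contrib[any_binary_rows]
                + f_contrib[any_binary_rows]
            )
            ystar[any_binary_rows] = _truncated_normal(rng, eta_b, y_sign)

        # -- fixed effects (one-solve draw: beta = P^-1 (b + L eps))
        r = ystar - u_contrib - f_contrib
        if univariate:
            prec = w[0] * xtx[0] + i_beta_prior
            rhs = x_t @ r * w[0]
        else:
            prec = np.tensordot(w, xtx, axes=1) + i_beta_prior
            rhs = x_t @ (w_row * r)
        chol = np.linalg.cholesky(prec)
        beta = np.linalg.solve(prec, rhs + chol @ rng.standard_normal(p))

        # -- individual effects
        r = ystar - d.x @ beta - f_contrib
        g_inv = _small_inv(g)
        if univariate:
            prec_u = w[0] * ztz[0] + g_inv
            wr = r * w[0]
        else:
            prec_u = np.tensordot(w, ztz, axes=1) + g_inv  # (n_fish, q, q)
            wr = w_row * r
        rhs_u = np.column_stack(
            [
                np.bincount(d.fish_idx, weights=zid_cols[k] * wr, minlength=n_fish)
                for k in range(q)
            ]
        )
        chol_u = np.linalg.cholesky(prec_u)
        eps = rng.standard_normal((n_fish, q, 1))
        u = np.linalg.solve(prec_u, rhs_u[..., None] + chol_u @ eps)[..., 0]

        # -- G (parameter-expanded inverse-Wishart)
        s_mat = u.T @ u
        scale = 2.0 * nu * np.diag(1.0 / g_aux) + s_mat
        g = _inv_wishart(rng, nu + q - 1 + n_fish, scale)
        g_inv_new = _small_inv(g)
        for k in range(q):
            g_aux[k] = _inv_gamma(
                rng, 0.5 * (nu + q), nu * g_inv_new[k, k] + 1.0 / a_sq
            )

        # -- aquarium / unit factors (f_contrib maintained incrementally)
        u_contrib = np.einsum("nq,nq->n", d.zid, u[d.fish_idx])
        base = ystar - d.x @ beta - u_contrib
        for fi_, f in enumerate(d.factors):
            m = masks[fi_]
            old = np.where(m, fac_eff[fi_][fidx_safe[fi_]], 0.0)
            f_contrib -= old
            resid = (base - f_contrib)[m]
            if univariate:
                prec_f = w[0] * factor_counts[fi_][0] + 1.0 / fac_v[fi_]
                wresid = resid * w[0]
            else:
                prec_f = 1.0 / fac_v[fi_] + sum(
                    w[t_i] * factor_counts[fi_][t_i] for t_i in range(n_traits)
                )
                wresid = w_row[m] * resid
            rhs_f = np.bincount(f.idx[m], weights=wresid, minlength=f.n_levels)
            fac_eff[fi_] = (
                rhs_f + np.sqrt(prec_f) * rng.standard_normal(f.n_levels)
            ) / prec_f
            f_contrib += np.where(m, fac_eff[fi_][fidx_safe[fi_]], 0.0)
            ss = float(fac_eff[fi_] @ fac_eff[fi_])
            fac_v[fi_] = _inv_gamma(
                rng, 0.5 * (nu + f.n_levels), nu / fac_aux[fi_] + 0.5 * ss
            )
            fac_aux[fi_] = _inv_gamma(
                rng, 0.5 * (nu + 1.0), nu / fac_v[fi_] + 1.0 / a_sq
            )

        # -- residual variances (Gaussian traits only)
        eta = d.x @ beta + u_contrib + f_contrib
        resid_all = ystar - eta
        for t_i in range(n_traits):
            if resid_fixed[t_i]:
                continue
            rr = resid_all if univariate else resid_all[trait_rows[t_i]]
            sig2[t_i] = _inv_gamma(
                rng,
                0.5 * (pr.resid_nu + n_per_trait[t_i]),
                0.5 * (pr.resid_nu * pr.resid_scale + float(rr @ rr)),
            )

        # -- store
        if it >= mc.burnin and (it - mc.burnin) % mc.thin == 0 and keep < n_draws:
            store_beta[keep] = beta
            store_g[keep] = g
            store_fv[keep] = fac_v
            store_sig2[keep] = sig2
            store_dev[keep] = _deviance(d, eta, sig2, spec)
            eta_sum += eta
            u_sum += u
            keep += 1

    if keep != n_draws:  # pragma: no cover - arithmetic guard
        raise ModelError("draw bookkeeping failed")

    eta_bar = eta_sum / n_draws
    sig2_bar = store_sig2.mean(axis=0)
    dev_at_mean = _deviance(d, eta_bar, sig2_bar, spec)
    dic, p_d = compute_dic(store_dev, dev_at_mean)

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(d.x_names):
        cols[f"beta_{name}"] = store_beta[:, j]
    for i in range(q):
        for j in range(i, q):
            cols[f"G[{d.comp_names[i]};{d.comp_names[j]}]"] = store_g[:, i, j]
    for fi_, f in enumerate(d.factors):
        cols[f"V_{f.name}"] = store_fv[:, fi_]
    for t_i, trait in enumerate(spec.traits):
        if spec.families[t_i] == "gaussian":
            name = f"V_residual.{trait}" if spec.is_bivariate else "V_residual"
            cols[name] = store_sig2[:, t_i]
    cols["deviance"] = store_dev
    samples = pd.DataFrame(cols)

    ess = {}
    watch = [c for c in samples.columns if c.startswith(("G[", "V_"))]
    watch += [c for c in samples.columns if c.startswith("beta_")][:2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in watch:
            arr = samples[c].to_numpy()
            if np.allclose(arr.std(), 0.0):
                ess[c] = float(len(arr))
            else:
                ess[c] = float(az.ess(arr[None, :]))
    low_ess = any(v < spec.ess_floor for v in ess.values())
    if low_ess:
        warnings.warn(
            "low effective sample size for some variance components; "
            "interpret posterior summaries with caution",
            RuntimeWarning,
            stacklevel=2,
        )

    return FittedModel(
        spec=spec,
        samples=samples,
        g_draws=store_g,
        component_names=list(d.comp_names),
        fish_ids=list(d.fish_ids),
        u_mean=u_sum / n_draws,
        dic=dic,
        p_d=p_d,
        deviance_at_mean=dev_at_mean,
        ess=ess,
        low_ess=low_ess,
    )


def _deviance(
    d: _Design, eta: np.ndarray, sig2: np.ndarray, spec: ModelSpec
) -> float:
    """Conditional deviance -2 log p(y | beta, u, factors, sigma2)."""
    dev = 0.0
    for t_i in range(len(spec.traits)):
        rows = d.trait_idx == t_i
        if spec.families[t_i] == "binary":
            e = eta[rows]
            yy = d.y[rows] > 0.5
            dev += -2.0 * float(
                np.sum(np.where(yy, log_ndtr(e), log_ndtr(-e)))
            )
        else:
            r = d.y[rows] - eta[rows]
            s2 = sig2[t_i]
            dev += float(
                rows.sum() * np.log(2.0 * np.pi * s2) + (r @ r) / s2
            )
    return dev


# ---------------------------------------------------------------------------
# Family-specific wrappers
# ---------------------------------------------------------------------------

def fit_gaussian_mixed(
    table: pd.DataFrame,
    trait: str,
    random_structure: str = "slopes",
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    include_interaction: bool = False,
    priors: PriorConfig | None = None,
) -> FittedModel:
    """Fit a univariate Gaussian mixed model for one trait."""
    spec = ModelSpec(
        traits=(trait,),
        families=("gaussian",),
        random_structure=random_structure,
        include_interaction=include_interaction,
        priors=priors or PriorConfig(),
        mcmc=mcmc or McmcSettings(),
        seed=seed,
    )
    return fit_mixed(table, spec)


def fit_binary_mixed(
    table: pd.DataFrame,
    trait: str,
    random_structure: str = "slopes",
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    include_interaction: bool = False,
    priors: PriorConfig | None = None,
) -> FittedModel:
    """Fit a univariate probit mixed model (latent residual variance 1)."""
    spec = ModelSpec(
        traits=(trait,),
        families=("binary",),
        random_structure=random_structure,
        include_interaction=include_interaction,
        priors=priors or PriorConfig(),
        mcmc=mcmc or McmcSettings(),
        seed=seed,
    )
    return fit_mixed(table, spec)


def fit_bivariate_mixed(
    table: pd.DataFrame,
    traits: tuple[str, str],
    families: tuple[str, str],
    random_structure: str = "intercepts",
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    priors: PriorConfig | None = None,
) -> FittedModel:
    """Fit a bivariate model with a joint cross-trait G matrix.

    With ``random_structure="slopes"`` both traits get correlated random
    intercepts and slopes (G is 4x4); with intercepts only, G is 2x2
    (intercept-intercept covariance across traits).
    """
    spec = ModelSpec(
        traits=tuple(traits),
        families=tuple(families),
        random_structure=random_structure,
        priors=priors or PriorConfig(),
        mcmc=mcmc or McmcSettings(),
        seed=seed,
    )
    return fit_mixed(table, spec)


# ---------------------------------------------------------------------------
# DIC, comparison, fixed-effect summaries
# ---------------------------------------------------------------------------

def compute_dic(
    deviance_draws: np.ndarray, deviance_at_mean: float
) -> tuple[float, float]:
    """DIC = 2 mean(D) - D(posterior-mean parameters); returns (DIC, pD).

    Conditional-deviance convention: the deviance is evaluated with the
    random effects in focus, so pD counts their effective parameters.
    """
    dev = np.asarray(deviance_draws, dtype=float)
    if not np.isfinite(dev).all() or not np.isfinite(deviance_at_mean):
        raise ModelError("non-finite deviance")
    d_bar = float(dev.mean())
    p_d = d_bar - deviance_at_mean
    return 2.0 * d_bar - deviance_at_mean, p_d


@dataclass
class ModelComparison:
    """DIC comparison of random-intercepts vs random-slopes fits."""

    trait: str
    dic_intercepts: float
    dic_slopes: float
    delta_dic: float
    support: str  # "none" | "substantial" | "strong"


def support_category(delta_dic: float) -> str:
    """Support for the random-slopes model: strong if dDIC >= 10, substantial in [5, 10)."""
    if delta_dic >= 10.0:
        return "strong"
    if delta_dic >= 5.0:
        return "substantial"
    return "none"


def compare_random_structures(
    fit_intercepts: FittedModel, fit_slopes: FittedModel
) -> ModelComparison:
    """ΔDIC = DIC(intercepts) - DIC(slopes); positive favours slopes."""
    if fit_intercepts.spec.traits != fit_slopes.spec.traits:
        raise ModelError("comparison requires fits of the same trait(s)")
    if fit_intercepts.spec.families != fit_slopes.spec.families:
        raise ModelError("comparison requires the same family")
    if fit_intercepts.spec.random_structure != "intercepts":
        raise ModelError("first argument must be the random-intercepts fit")
    if fit_slopes.spec.random_structure != "slopes":
        raise ModelError("second argument must be the random-slopes fit")
    delta = fit_intercepts.dic - fit_slopes.dic
    return ModelComparison(
        trait="+".join(fit_intercepts.spec.traits),
        dic_intercepts=fit_intercepts.dic,
        dic_slopes=fit_slopes.dic,
        delta_dic=delta,
        support=support_category(delta),
    )


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a 1-d sample."""
    lo, hi = az.hdi(np.asarray(draws, dtype=float), hdi_prob=prob)
    return float(lo), float(hi)


def pmcmc(draws: np.ndarray) -> float:
    """Twice the smaller tail proportion around zero, floored at 1/n."""
    draws = np.asarray(draws)
    n = len(draws)
    p_pos = float((draws > 0).mean())
    p_neg = float((draws < 0).mean())
    return float(min(1.0, max(2.0 * min(p_pos, p_neg), 1.0 / n)))


def summarize_fixed_effects(fit: FittedModel, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, HPD interval, pMCMC and significance per fixed effect.

    The returned frame carries a ``drop_interaction`` attribute (in
    ``DataFrame.attrs``): True when an interaction term is present but not
    significant, directing an explicit second fit without it.
    """
    rows = []
    drop_interaction = False
    for col in fit.samples.columns:
        if not col.startswith("beta_"):
            continue
        draws = fit.samples[col].to_numpy()
        lo, hi = hpd_interval(draws, prob)
        sig = not (lo <= 0.0 <= hi)
        rows.append(
            {
                "effect": col[len("beta_"):],
                "mean": float(draws.mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
                "pmcmc": pmcmc(draws),
                "significant": sig,
            }
        )
        if col.endswith("ct_mass") and not sig:
            drop_interaction = True
    out = pd.DataFrame(rows)
    out.attrs["drop_interaction"] = drop_interaction
    return out
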