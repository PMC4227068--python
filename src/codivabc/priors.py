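"""Priors on demographic and divergence-time parameters, and time scaling.

Divergence times tau are in coalescent units of a constant *reference*
population whose mutation-scaled size theta_C equals the expectation of the
prior on descendant-population size (theta = 4*N*mu per site).  One time
unit is theta_C / mu generations, written 4N_C generations.

Per population pair the demographic parameters are: mutation-scaled sizes
theta_A (ancestral), theta_D1 and theta_D2 (descendants); bottleneck
severities zeta_D1, zeta_D2 in (0, 1] (the fraction of the descendant
population persisting through the post-divergence bottleneck); tau_B in
[0, 1], the fraction of the time back to divergence at which the bottleneck
ends; and a symmetric migration rate m between the descendants.  Mutation
rate variation among loci is modelled by multipliers upsilon_j that are iid
Gamma(alpha, 1/alpha) (mean one), with alpha ~ U(1, 20) drawn afresh for
every prior sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .partitions import DivergenceModel, ModelPriorSpec

__all__ = [
    "Distribution",
    "PriorConfig",
    "DemographicParams",
    "ParameterDraw",
    "draw_parameters",
    "theta_C",
    "tau_to_generations",
    "scale_divergence_time",
    "divergence_summaries",
    "exponential_matching_uniform",
    "uniform_matching_exponential",
]


class ConfigError(ValueError):
    """Raised for inconsistent or unsupported prior configuration."""


@dataclass(frozen=True)
class Distribution:
    """A one-dimensional prior distribution.

    kind is one of ``gamma`` (shape-scale, mean = a*b), ``exponential``
    (parameterized by its mean, i.e. gamma with shape 1), ``uniform``
    (low, high) or ``beta`` (a, b).
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        k, p = self.kind, self.params
        if k == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ConfigError("gamma needs positive (shape, scale)")
        elif k == "exponential":
            if len(p) != 1 or p[0] <= 0:
                raise ConfigError("exponential needs a positive mean")
        elif k == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise ConfigError("uniform needs ordered (low, high)")
        elif k == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ConfigError("beta needs positive (a, b)")
        else:
            raise ConfigError(f"unknown distribution kind {k!r}")

    @property
    def mean(self) -> float:
        k, p = self.kind, self.params
        if k == "gamma":
            return p[0] * p[1]
        if k == "exponential":
            return p[0]
        if k == "uniform":
            return 0.5 * (p[0] + p[1])
        return p[0] / (p[0] + p[1])

    @property
    def variance(self) -> float:
        k, p = self.kind, self.params
        if k == "gamma":
            return p[0] * p[1] ** 2
        if k == "exponential":
            return p[0] ** 2
        if k == "uniform":
            return (p[1] - p[0]) ** 2 / 12.0
        a, b = p
        return a * b / ((a + b) ** 2 * (a + b + 1))

    def sample(self, rng: np.random.Generator, size=None):
        k, p = self.kind, self.params
        if k == "gamma":
            return rng.gamma(p[0], p[1], size=size)
        if k == "exponential":
            return rng.exponential(p[0], size=size)
        if k == "uniform":
            return rng.uniform(p[0], p[1], size=size)
        return rng.beta(p[0], p[1], size=size)


def exponential_matching_uniform(upper: float) -> Distribution:
    """Exponential prior with the same variance as U(0, upper):
    mean = upper / sqrt(12)."""
    if upper <= 0:
        raise ConfigError("upper bound must be positive")
    return Distribution("exponential", (upper / math.sqrt(12.0),))


def uniform_matching_exponential(mean: float) -> Distribution:
    """U(0, b) with the same variance as an exponential of the given mean:
    b = mean * sqrt(12)."""
    if mean <= 0:
        raise ConfigError("mean must be positive")
    return Distribution("uniform", (0.0, mean * math.sqrt(12.0)))


_OFF = None


@dataclass(frozen=True)
class PriorConfig:
    """Full prior configuration for one analysis model.

    The default configuration mirrors a diffuse analysis with a DPP over
    divergence models, exponential priors on times and sizes, free
    uniform bottleneck severities, and no migration.
    """

    Y: int
    tau_prior: Distribution = Distribution("exponential", (2.887,))
    thetaD_prior: Distribution = Distribution("exponential", (0.025,))
    thetaA_prior: Distribution | None = None  # defaults to thetaD_prior
    zeta_prior: Distribution | None = Distribution("beta", (1.0, 1.0))
    tauB_prior: Distribution | None = Distribution("uniform", (0.0, 1.0))
    migration_prior: Distribution | None = None
    alpha_prior: Distribution = Distribution("uniform", (1.0, 20.0))
    model_prior: ModelPriorSpec = ModelPriorSpec("dpp", (2.0, 2.0))
    theta_constraint: str = "three_free"  # or "shared_single"
    zeta_constraint: str = "free"  # or "equal", "off"
    msbayes_joint_thetaD: bool = False
    mu: float = 1e-8

    def __post_init__(self) -> None:
        if self.Y < 1:
            raise ConfigError("Y must be >= 1")
        if self.mu <= 0:
            raise ConfigError("mutation rate mu must be positive")
        if self.theta_constraint not in ("three_free", "shared_single"):
            raise ConfigError(
                f"unknown theta constraint {self.theta_constraint!r}")
        if self.zeta_constraint not in ("free", "equal", "off"):
            raise ConfigError(
                f"unknown zeta constraint {self.zeta_constraint!r}")
        if self.zeta_constraint == "off":
            if self.zeta_prior is not None:
                raise ConfigError("zeta_prior given but zeta_constraint is "
                                  "'off'")
            if self.tauB_prior is not None:
                raise ConfigError("tauB has no effect without a bottleneck; "
                                  "set tauB_prior to None when zeta is off")
        else:
            if self.zeta_prior is None:
                raise ConfigError("zeta_constraint requires a zeta_prior")
            if self.tauB_prior is None:
                raise ConfigError("bottlenecks need a tauB_prior")
        if self.msbayes_joint_thetaD:
            if self.thetaD_prior.kind != "uniform":
                raise ConfigError("the joint descendant-size mode places a "
                                  "uniform prior on the mean size")
            if self.theta_constraint != "three_free":
                raise ConfigError("joint descendant-size mode needs free "
                                  "theta parameters")

    @property
    def effective_thetaA_prior(self) -> Distribution:
        return self.thetaA_prior if self.thetaA_prior is not None \
            else self.thetaD_prior


@dataclass(frozen=True)
class DemographicParams:
    thetaA: float
    thetaD1: float
    thetaD2: float
    zetaD1: float = 1.0
    zetaD2: float = 1.0
    tauB: float = 1.0
    m: float = 0.0

    def __post_init__(self) -> None:
        if min(self.thetaA, self.thetaD1, self.thetaD2) <= 0:
            raise ValueError("theta parameters must be positive")
        if not (0 < self.zetaD1 <= 1 and 0 < self.zetaD2 <= 1):
            raise ValueError("zeta must be in (0, 1]")
        if not 0 <= self.tauB <= 1:
            raise ValueError("tauB must be in [0, 1]")
        if self.m < 0:
            raise ValueError("migration rate must be >= 0")


@dataclass(frozen=True)
class ParameterDraw:
    """One draw of all model parameters from the joint prior."""

    model: DivergenceModel
    demographics: tuple[DemographicParams, ...]
    alpha: float
    upsilon: tuple[float, ...]
    chi: float | None = None

    @property
    def T(self) -> np.ndarray:
        """Per-pair divergence times in 4N_C units."""
        return self.model.times

    @property
    def ntau(self) -> int:
        return self.model.ntau

    def summaries(self) -> tuple[float, float, float]:
        """(T_bar, s2_T, D_T) of the per-pair divergence times."""
        return divergence_summaries(self.T)


def divergence_summaries(T) -> tuple[float, float, float]:
    """Mean, population variance, and dispersion index of divergence times.

    D_T = s2_T / T_bar is the conventional statistic for temporal clustering
    of divergences; D_T < 0.01 is the usual one-event criterion.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 1 or T.size < 1:
        raise ValueError("T must be a non-empty vector")
    t_bar = float(T.mean())
    s2 = float(T.var())  # population (divide-by-Y) variance
    if t_bar == 0:
        raise ValueError("mean divergence time is zero; D_T undefined")
    return t_bar, s2, s2 / t_bar


def theta_C(config: PriorConfig) -> float:
    """Mutation-scaled size of the reference population: the expectation of
    the descendant-size prior (for U(0, b) priors this is b/2, the
    half-the-upper-limit convention)."""
    return config.thetaD_prior.mean


def tau_to_generations(tau: float, config: PriorConfig) -> float:
    """Convert a divergence time from 4N_C units to generations:
    tau * theta_C / mu."""
    return tau * theta_C(config) / config.mu


def scale_divergence_time(T_i: float, thetaD1: float, thetaD2: float,
                          rho: float, config: PriorConfig) -> float:
    """Locus-scaled divergence time T_{i,j} = T_i * theta_C /
    (mean(thetaD1, thetaD2) * rho): time in units proportional to the
    expected number of mutations for this pair and locus."""
    if min(T_i, thetaD1, thetaD2, rho) <= 0:
        raise ValueError("all inputs must be positive")
    theta_bar = 0.5 * (thetaD1 + thetaD2)
    return T_i * theta_C(config) / (theta_bar * rho)


def _draw_demographics(config: PriorConfig,
                       rng: np.random.Generator) -> DemographicParams:
    if config.theta_constraint == "shared_single":
        th = float(config.thetaD_prior.sample(rng))
        thetaA = thetaD1 = thetaD2 = th
    elif config.msbayes_joint_thetaD:
        # The mean of the two descendant sizes is uniform; a Beta(1,1)
        # fraction splits it, making the two sizes negatively correlated.
        mean_size = float(config.thetaD_prior.sample(rng))
        x = float(rng.beta(1.0, 1.0))
        thetaD1 = 2.0 * x * mean_size
        thetaD2 = 2.0 * (1.0 - x) * mean_size
        thetaA = float(config.effective_thetaA_prior.sample(rng))
    else:
        thetaD1 = float(config.thetaD_prior.sample(rng))
        thetaD2 = float(config.thetaD_prior.sample(rng))
        thetaA = float(config.effective_thetaA_prior.sample(rng))

    if config.zeta_constraint == "off":
        zeta1 = zeta2 = 1.0
        tauB = 1.0
    else:
        zeta1 = float(config.zeta_prior.sample(rng))
        zeta2 = zeta1 if config.zeta_constraint == "equal" \
            else float(config.zeta_prior.sample(rng))
        tauB = float(config.tauB_prior.sample(rng))

    m = 0.0 if config.migration_prior is None \
        else float(config.migration_prior.sample(rng))
    # zero draws from continuous priors have measure zero but guard anyway
    eps = np.finfo(float).tiny
    return DemographicParams(max(thetaA, eps), max(thetaD1, eps),
                             max(thetaD2, eps), max(zeta1, eps),
                             max(zeta2, eps), tauB, m)


def draw_parameters(config: PriorConfig, n_loci: int,
                    rng: np.random.Generator) -> ParameterDraw:
    """Draw one full parameter vector from the joint prior.

    ``n_loci`` is the number of unique loci K across the dataset; one
    mutation-rate multiplier upsilon is drawn per locus.
    """
    chi = config.model_prior.draw_chi(rng)
    t = config.model_prior.sample(config.Y, rng, chi=chi)
    ntau = max(t)
    tau = tuple(float(x) for x in config.tau_prior.sample(rng, size=ntau))
    # continuous priors put zero mass at 0, but guard against underflow
    tau = tuple(max(x, np.finfo(float).tiny) for x in tau)
    model = DivergenceModel(t, tau)
    demos = tuple(_draw_demographics(config, rng) for _ in range(config.Y))
    alpha = float(config.alpha_prior.sample(rng))
    upsilon = tuple(float(x)
                    for x in rng.gamma(alpha, 1.0 / alpha, size=n_loci))
    return ParameterDraw(model, demos, alpha, upsilon, chi=chi)
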