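"""Domain types and the deterministic mathematical core.

This module houses the dose-toxicity link, the prior densities and the
joint log-density of the full hierarchy.  Everything here is pure
``numpy``/``scipy``: the MCMC machinery in :mod:`bridgetox.inference`
targets the same density through a compiled kernel, and the functions
here double as the reference implementation for brute-force oracles.

Model sketch
------------
Each animal study ``i`` (species ``A_i``) and each human subgroup ``l``
has a two-parameter logistic dose-toxicity curve on a common human
dosing scale,

    logit(p) = intercept + exp(log_slope) * log(scale * dose / d_ref),

where ``scale`` is the species translation factor ``delta`` for animal
data and the subgroup bridging factor ``eps`` for human data.  Study
parameters are exchangeable within species; species means are
exchangeable under a supra-species distribution.  Each human parameter
vector ``gamma_l`` follows a prespecified-weight mixture over (a)
exchangeability with each animal species, (b) exchangeability with the
other human subgroups, and (c) a robust, non-exchangeable bivariate
normal of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln

__all__ = [
    "AnimalStudyData",
    "HumanTrialData",
    "TranslationPrior",
    "BridgingPrior",
    "HierarchyPriors",
    "ExchangeabilityWeights",
    "NonExchangeablePrior",
    "ModelConfig",
    "ParameterPoint",
    "dlt_probability",
    "joint_log_density",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"{name} must contain integers")
    return arr.astype(int)


def _check_dose_table(doses: np.ndarray, n: np.ndarray, r: np.ndarray, what: str) -> None:
    if len(doses) == 0:
        raise ValueError(f"{what}: empty dose table")
    if not (len(doses) == len(n) == len(r)):
        raise ValueError(f"{what}: doses, n, r must have equal length")
    if np.any(doses <= 0):
        raise ValueError(f"{what}: doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise ValueError(f"{what}: doses must be strictly increasing")
    if np.any(n < 1):
        raise ValueError(f"{what}: each dose group needs at least one subject (n >= 1)")
    if np.any(r < 0) or np.any(r > n):
        raise ValueError(f"{what}: DLT counts must satisfy 0 <= r <= n")


@dataclass(frozen=True)
class AnimalStudyData:
    """Aggregated dose/n/DLT table from one animal study."""

    study_id: str
    species: str
    doses: np.ndarray
    n: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "doses", _as_float_array(self.doses, "doses"))
        object.__setattr__(self, "n", _as_int_array(self.n, "n"))
        object.__setattr__(self, "r", _as_int_array(self.r, "r"))
        _check_dose_table(self.doses, self.n, self.r, f"animal study {self.study_id}")

    @property
    def n_doses(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class HumanTrialData:
    """Accumulated dose/n/DLT table for one human subgroup (1-based index)."""

    subgroup: int
    doses: np.ndarray
    n: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        if self.subgroup < 1:
            raise ValueError("subgroup index is 1-based")
        object.__setattr__(self, "doses", _as_float_array(self.doses, "doses"))
        object.__setattr__(self, "n", _as_int_array(self.n, "n"))
        object.__setattr__(self, "r", _as_int_array(self.r, "r"))
        _check_dose_table(self.doses, self.n, self.r, f"human subgroup {self.subgroup}")


@dataclass(frozen=True)
class TranslationPrior:
    """Log-normal prior on one species' dose translation factor."""

    meanlog: float
    sdlog: float

    def __post_init__(self):
        if self.sdlog <= 0:
            raise ValueError("sdlog must be positive")


@dataclass(frozen=True)
class BridgingPrior:
    """Truncated-normal prior on a subgroup's bridging scale, mode 1."""

    nu: float = 0.255
    lower: float = 0.0
    upper: float = 2.0

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if not (self.lower < 1.0 < self.upper):
            raise ValueError("truncation bounds must bracket the mode 1")


@dataclass(frozen=True)
class HierarchyPriors:
    """Hyperpriors of the random-effects hierarchy.

    ``b1, s1`` parameterize the normal priors on the supra-species
    intercept mean and the human-population intercept mean; ``b2, s2``
    the corresponding log-slope means.  ``z1..z4`` are half-normal
    scales for the between-study / between-subgroup heterogeneity sds
    ``tau1..tau4``; ``c1, c2`` for the between-species sds.  All
    correlations get uniform(-1, 1) priors.
    """

    b1: float = -1.099
    s1: float = 1.98
    b2: float = 0.0
    s2: float = 0.99
    z1: float = 0.5
    z2: float = 0.25
    z3: float = 0.25
    z4: float = 0.125
    c1: float = 1.0
    c2: float = 0.5
    d_ref: float = 5.0

    def __post_init__(self):
        for name in ("s1", "s2", "z1", "z2", "z3", "z4", "c1", "c2", "d_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ExchangeabilityWeights:
    """Prespecified mixture weights for one subgroup.

    ``species`` maps each species label to its exchangeability weight;
    ``human`` is the human-only exchangeability weight and ``robust``
    the non-exchangeability weight.  Entries must sum to 1.
    """

    species: Mapping[str, float]
    human: float = 0.0
    robust: float = 0.0

    def __post_init__(self):
        vals = list(self.species.values()) + [self.human, self.robust]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("weights must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def vector(self, species_order: Sequence[str]) -> np.ndarray:
        """Weights as (w_S1, ..., w_SK, w_H, w_R) in the given species order."""
        return np.array(
            [self.species.get(s, 0.0) for s in species_order] + [self.human, self.robust]
        )


@dataclass(frozen=True)
class NonExchangeablePrior:
    """Independent bivariate-normal prior for a non-exchangeable subgroup."""

    mean: np.ndarray = field(default_factory=lambda: np.array([-1.099, 0.0]))
    cov: np.ndarray = field(
        default_factory=lambda: np.array([[4.0, 0.0], [0.0, 1.0]])
    )

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).reshape(2)
        cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def sd_corr(self) -> tuple:
        """(sd1, sd2, corr) coordinates of the covariance."""
        s1 = float(np.sqrt(self.cov[0, 0]))
        s2 = float(np.sqrt(self.cov[1, 1]))
        corr = float(self.cov[0, 1] / (s1 * s2))
        return s1, s2, corr


_PRESETS = ("A", "B", "C", "D", "E", "custom")


@dataclass(frozen=True)
class ModelConfig:
    """Full prior/weight specification of one analysis model.

    The number of human subgroups ``L`` is the length of ``weights``;
    all per-subgroup lists must match it.
    """

    species: Sequence[str]
    translation: Mapping[str, TranslationPrior]
    weights: Sequence[ExchangeabilityWeights]
    bridging: Sequence[BridgingPrior] = None
    nonex: Sequence[NonExchangeablePrior] = None
    hierarchy: HierarchyPriors = field(default_factory=HierarchyPriors)
    preset: str = "custom"
    fixed_eps: Sequence[bool] = None

    def __post_init__(self):
        species = tuple(self.species)
        object.__setattr__(self, "species", species)
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for s in species:
            if s not in self.translation:
                raise ValueError(f"missing translation prior for species {s!r}")
        L = len(self.weights)
        if L < 1:
            raise ValueError("need at least one subgroup")
        for w in self.weights:
            for s in w.species:
                if s not in species:
                    raise ValueError(f"weight refers to unknown species {s!r}")
        if self.bridging is None:
            object.__setattr__(self, "bridging", tuple(BridgingPrior() for _ in range(L)))
        else:
            object.__setattr__(self, "bridging", tuple(self.bridging))
        if self.nonex is None:
            object.__setattr__(self, "nonex", tuple(NonExchangeablePrior() for _ in range(L)))
        else:
            object.__setattr__(self, "nonex", tuple(self.nonex))
        if self.fixed_eps is None:
            object.__setattr__(self, "fixed_eps", tuple(False for _ in range(L)))
        else:
            object.__setattr__(self, "fixed_eps", tuple(bool(f) for f in self.fixed_eps))
        if not (len(self.bridging) == len(self.nonex) == len(self.fixed_eps) == L):
            raise ValueError("per-subgroup specifications must have equal length")

    @property
    def n_subgroups(self) -> int:
        return len(self.weights)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def weight_matrix(self) -> np.ndarray:
        """(L, K+2) array of mixture weights in species order + (H, R)."""
        return np.stack([w.vector(self.species) for w in self.weights])

    def with_weights(self, weights: Sequence[ExchangeabilityWeights]) -> "ModelConfig":
        if len(weights) == len(self.weights):
            return replace(self, weights=tuple(weights))
        L = len(weights)
        return replace(
            self,
            weights=tuple(weights),
            bridging=tuple(self.bridging[0] for _ in range(L)),
            nonex=tuple(self.nonex[0] for _ in range(L)),
            fixed_eps=tuple(False for _ in range(L)),
        )


#: Default species translation priors on the human-equivalent dose scale.
DEFAULT_TRANSLATION = {
    "rat": TranslationPrior(meanlog=-1.820, sdlog=0.323),
    "monkey": TranslationPrior(meanlog=-1.127, sdlog=0.273),
}


def default_config(
    weights: Sequence[ExchangeabilityWeights],
    species: Sequence[str] = ("rat", "monkey"),
    preset: str = "custom",
    **kwargs,
) -> ModelConfig:
    """ModelConfig with the default priors for the rat/monkey setting."""
    translation = {s: DEFAULT_TRANSLATION[s] for s in species}
    return ModelConfig(
        species=species,
        translation=translation,
        weights=tuple(weights),
        preset=preset,
        **kwargs,
    )


@dataclass
class ParameterPoint:
    """One point of the full parameter space.

    Component indicators ``z`` are 0-based: values ``0..K-1`` select the
    corresponding species' exchangeability distribution, ``K`` the
    human-only distribution, and ``K+1`` the non-exchangeable prior.
    """

    theta: np.ndarray        # (M, 2) per-study (intercept, log_slope)
    mu_species: np.ndarray   # (K, 2)
    m: np.ndarray            # (2,)
    gamma: np.ndarray        # (L, 2)
    mu_h: np.ndarray         # (2,)
    delta: np.ndarray        # (K,) species translation factors
    eps: np.ndarray          # (L,) subgroup bridging factors
    tau: np.ndarray          # (4,) heterogeneity sds
    sigma: np.ndarray        # (2,) between-species sds
    rho: float
    kappa: float
    eta: float
    z: np.ndarray            # (L,) int component indicators

    def validate(self, n_species: int) -> None:
        if np.any(self.tau <= 0) or np.any(self.sigma <= 0):
            raise ValueError("tau and sigma must be positive")
        for c in (self.rho, self.kappa, self.eta):
            if not -1.0 <= c <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
        if np.any(self.delta <= 0):
            raise ValueError("delta must be positive")
        if np.any((self.eps <= 0) | (self.eps >= 2)):
            raise ValueError("eps must lie in (0, 2)")
        if np.any((self.z < 0) | (self.z > n_species + 1)):
            raise ValueError("component indicator out of range")


def dlt_probability(intercept, log_slope, scale, dose, d_ref):
    """DLT probability of the two-parameter logistic dose-toxicity curve.

    ``logit(p) = intercept + exp(log_slope) * log(scale * dose / d_ref)``.
    Broadcasts over array arguments; strictly increasing in ``dose``.
    """
    dose = np.asarray(dose, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive")
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    if np.any(np.asarray(d_ref) <= 0):
        raise ValueError("d_ref must be positive")
    lin = intercept + np.exp(log_slope) * np.log(scale * dose / d_ref)
    return expit(lin)


def _binom_loglik(r, n, p) -> float:
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    const = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return float(np.sum(const + r * np.log(p) + (n - r) * np.log1p(-p)))


def _bvn_logpdf(x, mean, sd1, sd2, corr) -> float:
    if not (-1.0 < corr < 1.0):
        return -np.inf
    z1 = (x[0] - mean[0]) / sd1
    z2 = (x[1] - mean[1]) / sd2
    q = (z1 * z1 - 2.0 * corr * z1 * z2 + z2 * z2) / (1.0 - corr * corr)
    return float(
        -np.log(2 * np.pi) - np.log(sd1 * sd2) - 0.5 * np.log(1 - corr * corr) - 0.5 * q
    )


def _halfnormal_logpdf(x, scale) -> float:
    if x <= 0:
        return -np.inf
    return float(stats.halfnorm.logpdf(x, scale=scale))


def joint_log_density(
    config: ModelConfig,
    animal: List[AnimalStudyData],
    human: List[HumanTrialData],
    point: ParameterPoint,
) -> float:
    """Log of the joint (unnormalized posterior) density at ``point``.

    Sums the binomial likelihood terms, the random-effects densities,
    the per-subgroup mixture component selected by ``point.z`` (density
    times prior weight), and every hyper/translation/bridging prior.
    Returns ``-inf`` at the boundary of the support (e.g. a correlation
    of +/-1); raises for indicators outside ``0..K+1``.
    """
    K = config.n_species
    L = config.n_subgroups
    hp = config.hierarchy
    point.validate(K)
    if len(point.gamma) != L or len(point.eps) != L or len(point.z) != L:
        raise ValueError("point dimensions do not match config subgroups")
    if not (-1.0 < point.rho < 1.0 and -1.0 < point.kappa < 1.0 and -1.0 < point.eta < 1.0):
        return -np.inf

    species_index = {s: k for k, s in enumerate(config.species)}
    tau1, tau2, tau3, tau4 = point.tau
    sig1, sig2 = point.sigma
    logp = 0.0

    # Animal likelihood and study-level random effects.
    for i, study in enumerate(animal):
        k = species_index[study.species]
        p = dlt_probability(
            point.theta[i, 0], point.theta[i, 1], point.delta[k], study.doses, hp.d_ref
        )
        logp += _binom_loglik(study.r, study.n, p)
        logp += _bvn_logpdf(point.theta[i], point.mu_species[k], tau1, tau2, point.rho)

    # Species means under the supra-species distribution.
    for k in range(K):
        logp += _bvn_logpdf(point.mu_species[k], point.m, sig1, sig2, point.kappa)

    # Human likelihood.
    for trial in human:
        l = trial.subgroup - 1
        if not 0 <= l < L:
            raise ValueError(f"subgroup {trial.subgroup} not covered by config")
        p = dlt_probability(
            point.gamma[l, 0], point.gamma[l, 1], point.eps[l], trial.doses, hp.d_ref
        )
        logp += _binom_loglik(trial.r, trial.n, p)

    # Mixture component density x prior weight per subgroup.
    W = config.weight_matrix()
    for l in range(L):
        c = int(point.z[l])
        w = W[l, c]
        if w <= 0:
            return -np.inf
        if c < K:
            dens = _bvn_logpdf(point.gamma[l], point.mu_species[c], tau1, tau2, point.rho)
        elif c == K:
            dens = _bvn_logpdf(point.gamma[l], point.mu_h, tau3, tau4, point.eta)
        else:
            s1, s2, corr = config.nonex[l].sd_corr
            dens = _bvn_logpdf(point.gamma[l], config.nonex[l].mean, s1, s2, corr)
        logp += np.log(w) + dens

    # Hyperpriors.
    logp += float(stats.norm.logpdf(point.m[0], hp.b1, hp.s1))
    logp += float(stats.norm.logpdf(point.m[1], hp.b2, hp.s2))
    logp += float(stats.norm.logpdf(point.mu_h[0], hp.b1, hp.s1))
    logp += float(stats.norm.logpdf(point.mu_h[1], hp.b2, hp.s2))
    for x, scale in zip(point.tau, (hp.z1, hp.z2, hp.z3, hp.z4)):
        logp += _halfnormal_logpdf(x, scale)
    logp += _halfnormal_logpdf(sig1, hp.c1)
    logp += _halfnormal_logpdf(sig2, hp.c2)
    logp += 3 * np.log(0.5)  # uniform(-1,1) priors on rho, kappa, eta

    # Translation and bridging priors.
    for k, s in enumerate(config.species):
        tp = config.translation[s]
        logp += float(stats.lognorm.logpdf(point.delta[k], tp.sdlog, scale=np.exp(tp.meanlog)))
    for l in range(L):
        if config.fixed_eps[l]:
            continue
        bp = config.bridging[l]
        a = (bp.lower - 1.0) / bp.nu
        b = (bp.upper - 1.0) / bp.nu
        logp += float(stats.truncnorm.logpdf(point.eps[l], a, b, loc=1.0, scale=bp.nu))

    return float(logp)
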