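"""Posterior computation, predictive risks and summaries.

``fit`` runs the compiled Metropolis-within-Gibbs kernel over the full
hierarchy and returns :class:`PosteriorDraws`.  Subgroups listed in the
config but absent from the data are sampled from their meta-analytic
predictive construction (fresh mixture-component draws given the
hyperparameter state), so the same object serves for posterior
inference and for MAP predictive priors of not-yet-observed subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _gibbs
from .model_core import (
    AnimalStudyData,
    BridgingPrior,
    ExchangeabilityWeights,
    HumanTrialData,
    ModelConfig,
    NonExchangeablePrior,
)

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "RiskSamples",
    "fit",
    "component_probabilities",
    "predictive_dlt_risk",
    "map_prior_risk",
    "interval_probabilities",
    "summarize",
    "split_rhat",
    "effective_draws",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 2
    iterations: int = 15000
    burnin: int = 5000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burn-in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin

    def doubled(self) -> "McmcSettings":
        """Retry settings after a convergence flag: twice the iterations
        and at least two chains (cross-chain split-R-hat is far less
        noisy than single-chain halves)."""
        return McmcSettings(
            chains=max(2, self.chains),
            iterations=2 * self.iterations,
            burnin=2 * self.burnin,
            seed=self.seed + 77,
            thin=self.thin,
        )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus indicator draws and diagnostics."""

    params: Dict[str, np.ndarray]     # name -> (chains, draws)
    z: np.ndarray                     # (chains, draws, L) int
    config: ModelConfig
    settings: McmcSettings
    rhat: Dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return self.z.shape[0]

    @property
    def n_draws(self) -> int:
        return self.z.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled into one flat vector."""
        return self.params[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iter, parameter, value) table."""
        rows = []
        for name, arr in self.params.items():
            for c in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class RiskSamples:
    """Per-dose sampled DLT probabilities (columns follow ``doses``)."""

    doses: np.ndarray
    samples: np.ndarray   # (n_samples, n_doses)

    def __post_init__(self):
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.doses):
            raise ValueError("samples must be (n_samples, n_doses)")
        if self.samples.size == 0:
            raise ValueError("empty risk samples")
        if np.any((self.samples < 0) | (self.samples > 1)):
            raise ValueError("risk samples must lie in [0, 1]")


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of an array of draws shaped (chains, n)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def effective_draws(x: np.ndarray) -> float:
    """Autocorrelation-based effective sample size (Geyer pairing).

    ``x`` is (chains, n); chains contribute additively.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    total = 0.0
    for row in x:
        n = len(row)
        row = row - row.mean()
        var = np.dot(row, row) / n
        if var == 0:
            total += n
            continue
        nf = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(row, nf)
        acf = np.fft.irfft(f * np.conjugate(f))[:n].real / (var * n)
        s = 0.0
        t = 1
        while t + 1 < n:
            pair = acf[t] + acf[t + 1]
            if pair < 0:
                break
            s += pair
            t += 2
        total += n / (1.0 + 2.0 * s)
    return float(total)


def _pack_animal(config: ModelConfig, animal: Sequence[AnimalStudyData]):
    species_index = {s: k for k, s in enumerate(config.species)}
    M = len(animal)
    sp_idx = np.zeros(M, dtype=np.int64)
    off = np.zeros(M + 1, dtype=np.int64)
    dose, n, r = [], [], []
    for i, st in enumerate(animal):
        if st.species not in species_index:
            raise ValueError(f"study {st.study_id}: unknown species {st.species!r}")
        sp_idx[i] = species_index[st.species]
        dose.extend(st.doses)
        n.extend(st.n)
        r.extend(st.r)
        off[i + 1] = off[i] + st.n_doses
    return (
        sp_idx,
        off,
        np.asarray(dose, dtype=float),
        np.asarray(n, dtype=float),
        np.asarray(r, dtype=float),
    )


def _pack_human(config: ModelConfig, human: Sequence[HumanTrialData]):
    L = config.n_subgroups
    by_subgroup: Dict[int, HumanTrialData] = {}
    for tr in human:
        if tr.subgroup in by_subgroup:
            raise ValueError(f"duplicate data for subgroup {tr.subgroup}")
        if tr.subgroup > L:
            raise ValueError(f"subgroup {tr.subgroup} not covered by config (L={L})")
        by_subgroup[tr.subgroup] = tr
    off = np.zeros(L + 1, dtype=np.int64)
    dose, n, r = [], [], []
    for l in range(L):
        tr = by_subgroup.get(l + 1)
        if tr is not None:
            dose.extend(tr.doses)
            n.extend(tr.n)
            r.extend(tr.r)
            off[l + 1] = off[l] + len(tr.doses)
        else:
            off[l + 1] = off[l]
    return (
        off,
        np.asarray(dose, dtype=float),
        np.asarray(n, dtype=float),
        np.asarray(r, dtype=float),
    )


def _param_names(config: ModelConfig, animal: Sequence[AnimalStudyData]) -> List[str]:
    names: List[str] = []
    for st in animal:
        names += [f"theta1[{st.study_id}]", f"theta2[{st.study_id}]"]
    for s in config.species:
        names += [f"mu1[{s}]", f"mu2[{s}]"]
    names += ["m1", "m2"]
    for l in range(1, config.n_subgroups + 1):
        names += [f"gamma1[{l}]", f"gamma2[{l}]"]
    names += ["muH1", "muH2"]
    names += [f"delta[{s}]" for s in config.species]
    names += [f"eps[{l}]" for l in range(1, config.n_subgroups + 1)]
    names += ["tau1", "tau2", "tau3", "tau4", "sigma1", "sigma2", "rho", "kappa", "eta"]
    return names


def fit(
    config: ModelConfig,
    animal: Sequence[AnimalStudyData],
    human: Sequence[HumanTrialData],
    settings: McmcSettings = McmcSettings(),
    fixed: Optional[dict] = None,
    diagnostics: bool = True,
) -> PosteriorDraws:
    """Draw from the joint posterior (the prior when both lists are empty).

    ``fixed`` optionally freezes parts of the hierarchy, e.g.
    ``{"mu_species": (K,2) array, "psi": (tau1, tau2, rho), "delta":
    (K,) array}``; frozen parameters keep their given values throughout,
    which yields the reduced models used by the quadrature oracles.
    """
    fixed = fixed or {}
    unknown = set(fixed) - {"mu_species", "psi", "delta"}
    if unknown:
        raise ValueError(f"unknown fixed-parameter keys: {sorted(unknown)}")
    K, L = config.n_species, config.n_subgroups
    hp = config.hierarchy

    sp_idx, a_off, a_dose, a_n, a_r = _pack_animal(config, animal)
    h_off, h_dose, h_n, h_r = _pack_human(config, human)

    W = config.weight_matrix()
    m0 = np.stack([p.mean for p in config.nonex]) if L else np.zeros((0, 2))
    r0 = np.stack([np.asarray(p.sd_corr) for p in config.nonex]) if L else np.zeros((0, 3))
    zc = np.array([hp.z1, hp.z2, hp.z3, hp.z4])
    dmeanlog = np.array([config.translation[s].meanlog for s in config.species])
    dsdlog = np.array([config.translation[s].sdlog for s in config.species])
    nu = np.array([bp.nu for bp in config.bridging])
    fix_eps = np.array(config.fixed_eps, dtype=np.bool_)

    init_mu_s = np.asarray(
        fixed.get("mu_species", np.tile([hp.b1, hp.b2], (K, 1))), dtype=float
    ).reshape(K, 2)
    init_psi = np.asarray(
        fixed.get("psi", [0.674 * hp.z1, 0.674 * hp.z2, 0.0]), dtype=float
    ).reshape(3)
    init_delta = np.asarray(fixed.get("delta", np.exp(dmeanlog)), dtype=float).reshape(K)

    names = _param_names(config, animal)
    P = len(names)
    n_keep = settings.draws_per_chain
    all_out = np.empty((settings.chains, n_keep, P))
    all_z = np.empty((settings.chains, n_keep, L), dtype=np.int64)

    for c in range(settings.chains):
        out = np.empty((n_keep, P))
        zout = np.empty((n_keep, L), dtype=np.int64)
        kept = _gibbs.run_chain(
            settings.seed + 1000003 * c,
            settings.iterations,
            settings.burnin,
            settings.thin,
            sp_idx, a_off, a_dose, a_n, a_r,
            h_off, h_dose, h_n, h_r,
            W, m0, r0,
            hp.b1, hp.s1, hp.b2, hp.s2,
            zc, hp.c1, hp.c2, hp.d_ref,
            dmeanlog, dsdlog, nu,
            "mu_species" in fixed, "psi" in fixed, "delta" in fixed,
            fix_eps,
            init_mu_s, init_psi, init_delta,
            out, zout,
        )
        if kept != n_keep:  # pragma: no cover - defensive
            raise RuntimeError("kernel kept an unexpected number of draws")
        all_out[c] = out
        all_z[c] = zout

    params = {name: all_out[:, :, j].copy() for j, name in enumerate(names)}
    draws = PosteriorDraws(params=params, z=all_z, config=config, settings=settings)

    if diagnostics:
        monitored = [
            n
            for n in names
            if n.startswith(("gamma1[", "gamma2[", "eps[", "muH", "m1", "m2"))
        ]
        rhat = {n: split_rhat(params[n]) for n in monitored}
        draws.rhat = rhat
        finite = [v for v in rhat.values() if np.isfinite(v)]
        draws.converged = all(v <= RHAT_THRESHOLD for v in finite)
        if not draws.converged:
            warnings.warn(
                "possible non-convergence: split-R-hat above "
                f"{RHAT_THRESHOLD} for {[k for k, v in rhat.items() if np.isfinite(v) and v > RHAT_THRESHOLD]}",
                stacklevel=2,
            )
    return draws


def component_probabilities(draws: PosteriorDraws, subgroup: int) -> np.ndarray:
    """Posterior probability of each mixture component for a subgroup.

    Returns a length ``K+2`` vector ordered (species..., human-only,
    non-exchangeable); entries are fractions of indicator draws.
    """
    L = draws.config.n_subgroups
    if not 1 <= subgroup <= L:
        raise ValueError(f"subgroup {subgroup} was not included in the fit")
    K = draws.config.n_species
    zz = draws.z[:, :, subgroup - 1].reshape(-1)
    counts = np.bincount(zz, minlength=K + 2)
    return counts / counts.sum()


def _risk_matrix(g1, g2, eps, panel, d_ref):
    log_ratio = np.log(eps[:, None] * panel[None, :] / d_ref)
    return expit(g1[:, None] + np.exp(g2)[:, None] * log_ratio)


def predictive_dlt_risk(
    draws: PosteriorDraws, subgroup: int, dose_panel: Sequence[float]
) -> RiskSamples:
    """Sampled DLT risks over a dose panel for a fitted subgroup.

    For subgroups without observed data the fit already sampled their
    curve parameters from the mixture given the hyperparameter draws,
    so the result is the meta-analytic predictive (MAP) prior.
    """
    panel = np.asarray(dose_panel, dtype=float)
    if panel.size == 0:
        raise ValueError("empty dose panel")
    if np.any(panel <= 0) or np.any(np.diff(panel) <= 0):
        raise ValueError("dose panel must be positive and sorted increasing")
    L = draws.config.n_subgroups
    if not 1 <= subgroup <= L:
        raise ValueError(f"subgroup {subgroup} was not included in the fit")
    g1 = draws.stacked(f"gamma1[{subgroup}]")
    g2 = draws.stacked(f"gamma2[{subgroup}]")
    eps = draws.stacked(f"eps[{subgroup}]")
    p = _risk_matrix(g1, g2, eps, panel, draws.config.hierarchy.d_ref)
    return RiskSamples(doses=panel, samples=p)


def map_prior_risk(
    draws: PosteriorDraws,
    weights: ExchangeabilityWeights,
    dose_panel: Sequence[float],
    bridging: BridgingPrior = BridgingPrior(),
    nonex: NonExchangeablePrior = NonExchangeablePrior(),
    seed: int = 0,
) -> RiskSamples:
    """MAP predictive prior for a subgroup that was *not* in the fit.

    Per retained draw a fresh component is selected from ``weights``, a
    fresh curve parameter vector is generated from that component given
    the drawn hyperparameters, and a fresh bridging factor is drawn from
    its truncated-normal prior.
    """
    panel = np.asarray(dose_panel, dtype=float)
    if panel.size == 0:
        raise ValueError("empty dose panel")
    cfg = draws.config
    K = cfg.n_species
    rng = np.random.default_rng(seed)
    w = weights.vector(cfg.species)
    n = draws.n_chains * draws.n_draws

    comp = rng.choice(K + 2, size=n, p=w)
    mean = np.zeros((n, 2))
    sd1 = np.zeros(n)
    sd2 = np.zeros(n)
    corr = np.zeros(n)
    for k, s in enumerate(cfg.species):
        sel = comp == k
        mean[sel, 0] = draws.stacked(f"mu1[{s}]")[sel]
        mean[sel, 1] = draws.stacked(f"mu2[{s}]")[sel]
        sd1[sel] = draws.stacked("tau1")[sel]
        sd2[sel] = draws.stacked("tau2")[sel]
        corr[sel] = draws.stacked("rho")[sel]
    sel = comp == K
    mean[sel, 0] = draws.stacked("muH1")[sel]
    mean[sel, 1] = draws.stacked("muH2")[sel]
    sd1[sel] = draws.stacked("tau3")[sel]
    sd2[sel] = draws.stacked("tau4")[sel]
    corr[sel] = draws.stacked("eta")[sel]
    sel = comp == K + 1
    r1, r2, rc = nonex.sd_corr
    mean[sel] = nonex.mean
    sd1[sel] = r1
    sd2[sel] = r2
    corr[sel] = rc

    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    g1 = mean[:, 0] + sd1 * u1
    g2 = mean[:, 1] + sd2 * (corr * u1 + np.sqrt(1.0 - corr**2) * u2)

    eps = 1.0 + bridging.nu * rng.standard_normal(n)
    bad = (eps <= bridging.lower) | (eps >= bridging.upper)
    while np.any(bad):
        eps[bad] = 1.0 + bridging.nu * rng.standard_normal(bad.sum())
        bad = (eps <= bridging.lower) | (eps >= bridging.upper)

    p = _risk_matrix(g1, g2, eps, panel, cfg.hierarchy.d_ref)
    return RiskSamples(doses=panel, samples=p)


def interval_probabilities(
    risks: RiskSamples, under_cut: float = 0.16, over_cut: float = 0.33
) -> np.ndarray:
    """(P_under, P_target, P_over) per dose; rows sum to 1.

    Under-dosing is ``p < under_cut``, the target interval is
    ``[under_cut, over_cut)`` and over-dosing is ``p >= over_cut``.
    """
    if not 0.0 < under_cut < over_cut < 1.0:
        raise ValueError("need 0 < under_cut < over_cut < 1")
    s = risks.samples
    p_under = (s < under_cut).mean(axis=0)
    p_over = (s >= over_cut).mean(axis=0)
    return np.column_stack([p_under, 1.0 - p_under - p_over, p_over])


def summarize(risks: RiskSamples) -> pd.DataFrame:
    """Per-dose mean, sd, median and 95% interval over pooled samples."""
    s = risks.samples
    return pd.DataFrame(
        {
            "dose": risks.doses,
            "mean": s.mean(axis=0),
            "sd": s.std(axis=0, ddof=1),
            "median": np.median(s, axis=0),
            "q2.5": np.quantile(s, 0.025, axis=0),
            "q97.5": np.quantile(s, 0.975, axis=0),
        }
    )
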