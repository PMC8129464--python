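"""Paired sequential trial simulation and operating characteristics.

Simulates a first-in-human trial T1 (region R1) followed by a bridging
trial T2 (region R2) on the shared panel {0.1, 0.5, 1, 5, 10, 20}
mg/kg under one of six truth scenarios, analysed with one of five
preset models:

* ``A`` -- full robust model: animal co-data for both trials, plus
  human-subgroup borrowing into T2 (T2 weights give positive mass to
  the human-only exchangeability component).
* ``B`` -- no animal data; human parameter vectors fully exchangeable.
* ``C`` -- each trial analysed alone (non-exchangeable, no animal).
* ``D`` -- animal co-data for each trial, no borrowing across human
  subgroups (T2 analysed without the T1 human data).
* ``E`` -- T1 alone; T2 pools the T1 data into a single subgroup with
  the bridging factor fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .escalation import EscalationConfig, TrialState, declare_mtd, recommend_next_dose, starting_dose
from .inference import (
    McmcSettings,
    PosteriorDraws,
    RiskSamples,
    fit,
    interval_probabilities,
    predictive_dlt_risk,
)
from .model_core import (
    AnimalStudyData,
    ExchangeabilityWeights,
    HumanTrialData,
    ModelConfig,
    default_config,
)

__all__ = [
    "DOSE_PANEL",
    "SCENARIOS",
    "ScenarioSpec",
    "TrialResult",
    "OperatingCharacteristics",
    "DEFAULT_INTERIM_MCMC",
    "simulate_cohort_outcome",
    "preset_weights",
    "run_trial_pair",
    "run_simulation",
    "operating_characteristics",
]

DOSE_PANEL = np.array([0.1, 0.5, 1.0, 5.0, 10.0, 20.0])

#: Reduced per-interim MCMC settings used inside large simulations; the
#: full two-chain 15000/5000 settings remain available via ``mcmc=``.
DEFAULT_INTERIM_MCMC = McmcSettings(chains=1, iterations=8000, burnin=3000)


@dataclass(frozen=True)
class ScenarioSpec:
    """True human DLT probabilities over the panel, per region."""

    scenario: int
    truth_r1: np.ndarray
    truth_r2: np.ndarray
    mtd_r1: Optional[int]
    mtd_r2: Optional[int]

    def __post_init__(self):
        for name in ("truth_r1", "truth_r2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != DOSE_PANEL.shape:
                raise ValueError("truth vector must match the 6-dose panel")
            if np.any((arr <= 0) | (arr >= 1)) or np.any(np.diff(arr) < 0):
                raise ValueError("truths must be in (0,1) and non-decreasing")
            object.__setattr__(self, name, arr)

    def truth(self, region: int) -> np.ndarray:
        return self.truth_r1 if region == 1 else self.truth_r2

    def true_mtd(self, region: int) -> Optional[int]:
        return self.mtd_r1 if region == 1 else self.mtd_r2


SCENARIOS: Dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, (0.01, 0.03, 0.10, 0.25, 0.34, 0.47), (0.01, 0.03, 0.10, 0.25, 0.34, 0.47), 3, 3),
    2: ScenarioSpec(2, (0.01, 0.03, 0.10, 0.25, 0.34, 0.47), (0.05, 0.12, 0.25, 0.37, 0.50, 0.60), 3, 2),
    3: ScenarioSpec(3, (0.01, 0.03, 0.10, 0.25, 0.34, 0.47), (0.01, 0.03, 0.07, 0.15, 0.25, 0.37), 3, 4),
    4: ScenarioSpec(4, (0.01, 0.03, 0.05, 0.08, 0.15, 0.25), (0.02, 0.05, 0.07, 0.12, 0.25, 0.36), 5, 4),
    # In region R2 of scenario 5 every dose is overly toxic; no dose is
    # regarded as the true MTD there.
    5: ScenarioSpec(5, (0.25, 0.34, 0.47, 0.55, 0.65, 0.75), (0.40, 0.50, 0.60, 0.70, 0.80, 0.90), 0, None),
    6: ScenarioSpec(6, (0.01, 0.03, 0.05, 0.08, 0.15, 0.25), (0.10, 0.25, 0.36, 0.50, 0.60, 0.68), 5, 1),
}


@dataclass
class TrialResult:
    region: int
    doses: np.ndarray
    n: np.ndarray
    r: np.ndarray
    stopped_early: bool
    stop_reason: str
    declared_mtd: Optional[int]
    aborted: bool = False
    trace: List[dict] = field(default_factory=list)

    @property
    def total_patients(self) -> int:
        return int(self.n.sum())

    @property
    def total_dlts(self) -> int:
        return int(self.r.sum())


@dataclass
class OperatingCharacteristics:
    region: int
    n_trials: int
    pcs: float                      # % declaring the true MTD (NaN if none exists)
    pct_stopped_early: float
    pct_aborted: float
    pct_no_mtd: float               # completed but no eligible dose to declare
    pct_declared: np.ndarray        # per dose, %
    mean_patients: np.ndarray       # per dose
    mean_dlts: float


def simulate_cohort_outcome(true_prob: float, cohort_size: int, rng_seed) -> int:
    """Binomial DLT count for one cohort; ``rng_seed`` is an int seed or
    a ``numpy.random.Generator``."""
    if not 0.0 <= true_prob <= 1.0:
        raise ValueError("true_prob must lie in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return int(rng.binomial(cohort_size, true_prob))


def preset_weights(preset: str, trial: int) -> ExchangeabilityWeights:
    """Prespecified mixture weights of an analysis model for trial 1 or 2."""
    if preset == "A":
        if trial == 1:
            return ExchangeabilityWeights({"rat": 0.2, "monkey": 0.6}, human=0.0, robust=0.2)
        return ExchangeabilityWeights({"rat": 0.1, "monkey": 0.5}, human=0.2, robust=0.2)
    if preset == "B":
        return ExchangeabilityWeights({}, human=1.0, robust=0.0)
    if preset == "C":
        return ExchangeabilityWeights({}, human=0.0, robust=1.0)
    if preset == "D":
        return ExchangeabilityWeights({"rat": 0.2, "monkey": 0.6}, human=0.0, robust=0.2)
    if preset == "E":
        return ExchangeabilityWeights({}, human=0.0, robust=1.0)
    raise ValueError(f"unknown preset {preset!r}")


def _uses_animal(preset: str) -> bool:
    return preset in ("A", "D")


def _human_config(weights, **kwargs) -> ModelConfig:
    return ModelConfig(species=(), translation={}, weights=tuple(weights), **kwargs)


def _state_to_data(state: TrialState, subgroup: int) -> Optional[HumanTrialData]:
    used = state.n > 0
    if not used.any():
        return None
    return HumanTrialData(
        subgroup=subgroup, doses=state.doses[used], n=state.n[used], r=state.r[used]
    )


class _Fitter:
    """Runs one interim fit with the convergence-doubling retry."""

    def __init__(self, config, animal, mcmc, fixed=None):
        self.config = config
        self.animal = animal
        self.mcmc = mcmc
        self.fixed = fixed
        self.n_fits = 0

    def __call__(self, human: List[HumanTrialData], seed: int) -> Tuple[Optional[PosteriorDraws], bool]:
        import warnings as _w

        settings = McmcSettings(
            chains=self.mcmc.chains,
            iterations=self.mcmc.iterations,
            burnin=self.mcmc.burnin,
            seed=seed,
            thin=self.mcmc.thin,
        )
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            draws = fit(self.config, self.animal, human, settings, fixed=self.fixed)
            self.n_fits += 1
            if not draws.converged:
                draws = fit(self.config, self.animal, human, settings.doubled(), fixed=self.fixed)
                self.n_fits += 1
        return draws, draws.converged


def _run_single_trial(
    truths: np.ndarray,
    start_index: int,
    analyse: Callable[[TrialState], Tuple[Optional[RiskSamples], bool]],
    esc: EscalationConfig,
    rng: np.random.Generator,
    region: int,
) -> TrialResult:
    state = TrialState(doses=DOSE_PANEL.copy())
    trace: List[dict] = []
    dose = start_index
    declared = None
    aborted = False
    while True:
        dlts = simulate_cohort_outcome(truths[dose], esc.cohort_size, rng)
        state.record_cohort(dose, esc.cohort_size, dlts)
        risks, ok = analyse(state)
        if not ok:
            aborted = True
            state.stopped = True
            state.stop_reason = "aborted (unconverged after retry)"
            break
        iv = interval_probabilities(risks, esc.start_under_cut, esc.overdose_cut)
        over = iv[:, 2]
        if state.total_patients >= esc.max_patients:
            med = np.median(risks.samples, axis=0)
            declared = declare_mtd(med, over, state, esc)
            trace.append({"cohort": state.cohort, "dose_index": dose, "dlts": dlts,
                          "over_probs": over.copy(), "decision": f"declare {declared}"})
            break
        nxt = recommend_next_dose(over, state, esc)
        trace.append({"cohort": state.cohort, "dose_index": dose, "dlts": dlts,
                      "over_probs": over.copy(), "decision": "stop" if nxt is None else f"next {nxt}"})
        if nxt is None:
            state.stopped = True
            state.stop_reason = "safety"
            break
        dose = nxt
    return TrialResult(
        region=region,
        doses=state.doses,
        n=state.n.copy(),
        r=state.r.copy(),
        stopped_early=state.stopped and not aborted,
        stop_reason=state.stop_reason,
        declared_mtd=declared,
        aborted=aborted,
        trace=trace,
    )


def _not_started(region: int) -> TrialResult:
    return TrialResult(
        region=region,
        doses=DOSE_PANEL.copy(),
        n=np.zeros(len(DOSE_PANEL), dtype=int),
        r=np.zeros(len(DOSE_PANEL), dtype=int),
        stopped_early=True,
        stop_reason="no safe starting dose",
        declared_mtd=None,
        trace=[],
    )


def run_trial_pair(
    scenario: ScenarioSpec,
    preset: str,
    animal: Sequence[AnimalStudyData],
    esc: EscalationConfig = EscalationConfig(),
    mcmc: McmcSettings = DEFAULT_INTERIM_MCMC,
    seed: int = 0,
) -> Tuple[TrialResult, TrialResult]:
    """Simulate T1 then T2 under one scenario and analysis preset.

    The weights used for the T1 subgroup stay fixed during T2; T2 data
    never feed back into a re-analysis of T1.  If the T2 starting-dose
    rule admits no dose, T2 is recorded as stopped for safety at cohort
    zero.
    """
    if preset not in ("A", "B", "C", "D", "E"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    animal = list(animal) if _uses_animal(preset) else []
    w1 = preset_weights(preset, 1)
    w2 = preset_weights(preset, 2)

    def fit_seed() -> int:
        return int(rng.integers(2**31 - 1))

    # ---- trial T1 -------------------------------------------------------
    if _uses_animal(preset):
        cfg_t1 = default_config([w1])
    else:
        cfg_t1 = _human_config([w1])
    fitter_t1 = _Fitter(cfg_t1, animal, mcmc)

    def analyse_t1(state: TrialState):
        human = [d for d in [_state_to_data(state, 1)] if d is not None]
        draws, ok = fitter_t1(human, fit_seed())
        if not ok:
            return None, False
        return predictive_dlt_risk(draws, 1, DOSE_PANEL), True

    t1 = _run_single_trial(scenario.truth_r1, 0, analyse_t1, esc, rng, region=1)
    t1_data = None
    used = t1.n > 0
    if used.any():
        t1_data = HumanTrialData(subgroup=1, doses=t1.doses[used], n=t1.n[used], r=t1.r[used])

    # ---- trial T2 analysis plumbing ------------------------------------
    if preset in ("A", "B"):
        # joint fit over both subgroups; subgroup 2 carries the accrued T2 data
        if preset == "A":
            cfg_t2 = default_config([w1, w2])
        else:
            cfg_t2 = _human_config([w1, w2])
        fitter_t2 = _Fitter(cfg_t2, animal, mcmc)

        def analyse_t2(state: TrialState):
            human = [d for d in (t1_data, _state_to_data(state, 2)) if d is not None]
            draws, ok = fitter_t2(human, fit_seed())
            if not ok:
                return None, False
            return predictive_dlt_risk(draws, 2, DOSE_PANEL), True

    elif preset in ("C", "D"):
        # T2 analysed without the T1 human data
        if preset == "D":
            cfg_t2 = default_config([w2])
        else:
            cfg_t2 = _human_config([w2])
        fitter_t2 = _Fitter(cfg_t2, animal, mcmc)

        def analyse_t2(state: TrialState):
            human = [d for d in [_state_to_data(state, 1)] if d is not None]
            draws, ok = fitter_t2(human, fit_seed())
            if not ok:
                return None, False
            return predictive_dlt_risk(draws, 1, DOSE_PANEL), True

    else:  # preset E: pool T1 data into the single analysed subgroup
        cfg_t2 = _human_config([w2], fixed_eps=(True,))
        fitter_t2 = _Fitter(cfg_t2, [], mcmc)

        def analyse_t2(state: TrialState):
            n = state.n + (t1.n if t1_data is not None else 0)
            r = state.r + (t1.r if t1_data is not None else 0)
            pooled = TrialState(doses=state.doses, n=n, r=r,
                                highest_administered=int(np.nonzero(n > 0)[0][-1]) if n.any() else -1)
            human = [d for d in [_state_to_data(pooled, 1)] if d is not None]
            draws, ok = fitter_t2(human, fit_seed())
            if not ok:
                return None, False
            return predictive_dlt_risk(draws, 1, DOSE_PANEL), True

    # ---- T2 starting dose ----------------------------------------------
    if preset in ("A", "B", "E"):
        empty = TrialState(doses=DOSE_PANEL.copy())
        risks, ok = analyse_t2(empty)
        if not ok:
            t2 = _not_started(2)
            t2.aborted = True
            t2.stop_reason = "aborted (unconverged after retry)"
            return t1, t2
        under = interval_probabilities(risks, esc.start_under_cut, esc.overdose_cut)[:, 0]
        start = starting_dose(under, esc)
        if start is None:
            return t1, _not_started(2)
    else:
        start = 0

    t2 = _run_single_trial(scenario.truth_r2, start, analyse_t2, esc, rng, region=2)
    return t1, t2


def operating_characteristics(
    results: Sequence[TrialResult], scenario: ScenarioSpec, region: Optional[int] = None
) -> OperatingCharacteristics:
    """Aggregate one region's replicate results.

    Percentages of per-dose declarations, early safety stops, aborted
    fits and completed-without-declaration trials add to 100.
    """
    results = list(results)
    if not results:
        raise ValueError("no trial results supplied")
    if region is None:
        region = results[0].region
    if any(t.region != region for t in results):
        raise ValueError("results mix regions")
    n = len(results)
    n_doses = len(DOSE_PANEL)
    declared = np.zeros(n_doses)
    stopped = aborted = none_declared = 0
    patients = np.zeros(n_doses)
    dlts = 0.0
    for t in results:
        patients += t.n
        dlts += t.total_dlts
        if t.aborted:
            aborted += 1
        elif t.stopped_early:
            stopped += 1
        elif t.declared_mtd is None:
            none_declared += 1
        else:
            declared[t.declared_mtd] += 1
    true_mtd = scenario.true_mtd(region)
    pcs = 100.0 * declared[true_mtd] / n if true_mtd is not None else float("nan")
    return OperatingCharacteristics(
        region=region,
        n_trials=n,
        pcs=pcs,
        pct_stopped_early=100.0 * stopped / n,
        pct_aborted=100.0 * aborted / n,
        pct_no_mtd=100.0 * none_declared / n,
        pct_declared=100.0 * declared / n,
        mean_patients=patients / n,
        mean_dlts=dlts / n,
    )


def run_simulation(
    scenario_id: int,
    preset: str,
    reps: int,
    seed: int,
    animal: Optional[Sequence[AnimalStudyData]] = None,
    esc: EscalationConfig = EscalationConfig(),
    mcmc: McmcSettings = DEFAULT_INTERIM_MCMC,
) -> Tuple[List[Tuple[TrialResult, TrialResult]], OperatingCharacteristics, OperatingCharacteristics]:
    """Replicate trial pairs and aggregate per-region characteristics."""
    from .synthetic_data import default_fixture

    scenario = SCENARIOS[scenario_id]
    if animal is None:
        animal = default_fixture()
    pairs = [
        run_trial_pair(scenario, preset, animal, esc=esc, mcmc=mcmc, seed=seed + 100 * i)
        for i in range(reps)
    ]
    oc1 = operating_characteristics([p[0] for p in pairs], scenario, region=1)
    oc2 = operating_characteristics([p[1] for p in pairs], scenario, region=2)
    return pairs, oc1, oc2
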