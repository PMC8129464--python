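"""Trial-conduct decision rules.

Pure functions implementing the starting-dose rule, the interim
overdose-controlled recommendation (with the no-skipping cap), the
safety stop and the final MTD declaration.  All rules are deterministic
functions of their inputs; randomness lives entirely in the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "EscalationConfig",
    "TrialState",
    "starting_dose",
    "recommend_next_dose",
    "declare_mtd",
]


@dataclass(frozen=True)
class EscalationConfig:
    """Escalation rule settings.

    ``feasibility`` is the maximum tolerated posterior probability of
    overdosing, P(p >= overdose_cut); a dose is admissible while that
    probability stays at or below it.
    """

    cohort_size: int = 3
    max_patients: int = 24
    overdose_cut: float = 0.33
    feasibility: float = 0.25
    start_under_cut: float = 0.16
    start_confidence: float = 0.85
    target_risk: float = 0.25
    no_skipping: bool = True

    def __post_init__(self):
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.max_patients % self.cohort_size != 0:
            raise ValueError("max_patients must be a multiple of cohort_size")
        if not 0 < self.feasibility < 1:
            raise ValueError("feasibility must lie in (0, 1)")
        if not 0 < self.start_confidence < 1:
            raise ValueError("start_confidence must lie in (0, 1)")


@dataclass
class TrialState:
    """Accrued state of one dose-escalation trial."""

    doses: np.ndarray
    n: np.ndarray = None
    r: np.ndarray = None
    highest_administered: int = -1   # -1 before the first cohort
    cohort: int = 0
    stopped: bool = False
    stop_reason: str = ""

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if self.n is None:
            self.n = np.zeros(len(self.doses), dtype=int)
        if self.r is None:
            self.r = np.zeros(len(self.doses), dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        self.r = np.asarray(self.r, dtype=int)
        if self.highest_administered >= len(self.doses):
            raise ValueError("highest administered index outside the panel")
        if np.any(self.r > self.n) or np.any(self.n < 0):
            raise ValueError("inconsistent count state")

    @property
    def total_patients(self) -> int:
        return int(self.n.sum())

    def record_cohort(self, dose_index: int, size: int, dlts: int) -> None:
        if not 0 <= dose_index < len(self.doses):
            raise ValueError("dose index outside the panel")
        if not 0 <= dlts <= size:
            raise ValueError("DLT count outside cohort size")
        self.n[dose_index] += size
        self.r[dose_index] += dlts
        self.highest_administered = max(self.highest_administered, dose_index)
        self.cohort += 1


def _check_probs(probs: Sequence[float], panel_size: int, name: str) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (panel_size,):
        raise ValueError(f"{name}: need one probability per panel dose")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    return arr


def starting_dose(under_probs: Sequence[float], cfg: EscalationConfig) -> Optional[int]:
    """Highest dose whose under-dose probability exceeds the confidence.

    ``under_probs[j]`` is P(p_j < start_under_cut | co-data).  Returns
    the 0-based index of the highest qualifying dose, or ``None`` when
    no dose qualifies (no safe start).
    """
    arr = _check_probs(under_probs, len(under_probs), "under_probs")
    ok = np.nonzero(arr > cfg.start_confidence)[0]
    return int(ok[-1]) if len(ok) else None


def recommend_next_dose(
    over_probs: Sequence[float], state: TrialState, cfg: EscalationConfig
) -> Optional[int]:
    """Overdose-controlled recommendation for the next cohort.

    The candidate is the highest panel dose with
    P(p >= overdose_cut) <= feasibility, capped (when ``no_skipping``)
    at one level above the highest dose administered so far.
    De-escalation below the current dose is allowed.  Returns ``None``
    iff no dose -- including the lowest -- satisfies the overdose
    constraint, i.e. the trial must stop for safety.
    """
    if state.stopped:
        raise ValueError("trial already stopped")
    arr = _check_probs(over_probs, len(state.doses), "over_probs")
    eligible = np.nonzero(arr <= cfg.feasibility)[0]
    if len(eligible) == 0:
        return None
    candidate = int(eligible[-1])
    if cfg.no_skipping:
        candidate = min(candidate, state.highest_administered + 1)
    if arr[candidate] > cfg.feasibility:
        # The no-skipping cap can only lower the dose, and overdose
        # probabilities are not necessarily monotone in finite samples;
        # fall back to the highest eligible dose at or below the cap.
        below = eligible[eligible <= candidate]
        if len(below) == 0:
            return None
        candidate = int(below[-1])
    return candidate


def declare_mtd(
    medians: Sequence[float],
    over_probs: Sequence[float],
    state: TrialState,
    cfg: EscalationConfig,
) -> Optional[int]:
    """Final MTD declaration after a completed trial.

    Only callable once all ``max_patients`` were treated (returns
    ``None`` otherwise).  Among doses that were administered and comply
    with the overdose constraint, returns the index minimizing
    ``|median - target_risk|``; ties break toward the lower dose.
    """
    if state.total_patients < cfg.max_patients:
        return None
    med = _check_probs(medians, len(state.doses), "medians")
    over = _check_probs(over_probs, len(state.doses), "over_probs")
    eligible = np.nonzero((state.n > 0) & (over <= cfg.feasibility))[0]
    if len(eligible) == 0:
        return None
    dist = np.abs(med[eligible] - cfg.target_risk)
    return int(eligible[np.argmin(dist)])  # argmin takes the first (lower) on ties
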