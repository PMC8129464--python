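"""Synthetic animal-study generators.

The default fixture emulates the preclinical setting of the worked
example: two monkey studies on doses 1/10/30/100 mg/kg with 4-12
animals per group and three rat studies on lower native doses.  True
study curves are calibrated so that, after translation by the median of
the default species priors, the implied human DLT risk is about 25% at
5 mg/kg (monkey) and about 25% at 1 mg/kg (rat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .model_core import DEFAULT_TRANSLATION, AnimalStudyData, dlt_probability

__all__ = [
    "AnimalDesign",
    "generate_animal_studies",
    "default_designs",
    "default_fixture",
    "DEFAULT_FIXTURE_SEED",
]

DEFAULT_FIXTURE_SEED = 1135
_D_REF = 5.0

# Anchor risks of the true study curves at the translated anchor doses
# (5 mg/kg for monkey, 1 mg/kg for rat).  The monkey anchor sits
# slightly below the 25% target so that the *posterior* predictive
# median -- which picks up upward pressure from the heavier right tail
# of the risk scale -- lands close to 25% and within [0.15, 0.35].
_MONKEY_ANCHOR_RISK = 0.22
_RAT_ANCHOR_RISK = 0.25


@dataclass(frozen=True)
class AnimalDesign:
    """Design of one synthetic animal study.

    ``intercept``/``log_slope`` define the study's true dose-toxicity
    curve on the translated (human-equivalent) dose scale; ``scale`` is
    the translation factor applied to native doses (typically the
    median of the species' translation prior).
    """

    study_id: str
    species: str
    doses: Sequence[float]
    n_per_dose: Sequence[int]
    intercept: float
    log_slope: float
    scale: float

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        n = np.asarray(self.n_per_dose, dtype=int)
        if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be positive and strictly increasing")
        if len(n) != len(doses) or np.any(n < 1):
            raise ValueError("need at least one animal per dose group")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def true_probabilities(self) -> np.ndarray:
        return dlt_probability(
            self.intercept, self.log_slope, self.scale, np.asarray(self.doses), _D_REF
        )


def generate_animal_studies(
    designs: Sequence[AnimalDesign], seed: int
) -> List[AnimalStudyData]:
    """Binomial DLT counts per dose group; deterministic given seed."""
    rng = np.random.default_rng(seed)
    studies = []
    for d in designs:
        p = d.true_probabilities()
        n = np.asarray(d.n_per_dose, dtype=int)
        r = rng.binomial(n, p)
        studies.append(
            AnimalStudyData(
                study_id=d.study_id,
                species=d.species,
                doses=np.asarray(d.doses, dtype=float),
                n=n,
                r=r,
            )
        )
    return studies


def default_designs() -> List[AnimalDesign]:
    """Two monkey and three rat study designs, anchored at 25% human
    risk near 5 mg/kg and 1 mg/kg respectively."""
    delta_monkey = float(np.exp(DEFAULT_TRANSLATION["monkey"].meanlog))
    delta_rat = float(np.exp(DEFAULT_TRANSLATION["rat"].meanlog))
    monkey_doses = (1.0, 10.0, 30.0, 100.0)
    rat_doses = (0.5, 5.0, 15.0, 50.0)
    # Monkey anchor: the curve intercept equals the anchor logit when
    # delta*d/d_ref = 1, i.e. at native dose d_ref/delta (~15 mg/kg).
    monkey_icpt = float(np.log(_MONKEY_ANCHOR_RISK / (1 - _MONKEY_ANCHOR_RISK)))
    # Rat anchor: 25% at human-equivalent 1 mg/kg with unit slope
    # shifts the intercept by -log(1/d_ref).
    rat_icpt = float(
        np.log(_RAT_ANCHOR_RISK / (1 - _RAT_ANCHOR_RISK)) - np.log(1.0 / _D_REF)
    )
    return [
        AnimalDesign("monkey-1", "monkey", monkey_doses, (8, 10, 12, 10), monkey_icpt, 0.0, delta_monkey),
        AnimalDesign("monkey-2", "monkey", monkey_doses, (6, 10, 12, 8), monkey_icpt, 0.0, delta_monkey),
        AnimalDesign("rat-1", "rat", rat_doses, (8, 8, 8, 8), rat_icpt, 0.0, delta_rat),
        AnimalDesign("rat-2", "rat", rat_doses, (10, 10, 10, 10), rat_icpt, 0.0, delta_rat),
        AnimalDesign("rat-3", "rat", rat_doses, (6, 8, 8, 6), rat_icpt, 0.0, delta_rat),
    ]


def default_fixture(seed: int = DEFAULT_FIXTURE_SEED) -> List[AnimalStudyData]:
    """The five calibrated rat/monkey studies used throughout."""
    return generate_animal_studies(default_designs(), seed)
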