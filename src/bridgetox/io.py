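"""Reading and writing study tables and model configurations.

Study data travel as delimited tables with columns
``study_id, kind, species_or_subgroup, dose, n, r`` (kind is ``animal``
or ``human``); configurations as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    AnimalStudyData,
    BridgingPrior,
    ExchangeabilityWeights,
    HierarchyPriors,
    HumanTrialData,
    ModelConfig,
    NonExchangeablePrior,
    TranslationPrior,
)

__all__ = [
    "read_study_table",
    "write_study_table",
    "studies_to_frame",
    "config_to_yaml",
    "config_from_yaml",
]

_COLUMNS = ["study_id", "kind", "species_or_subgroup", "dose", "n", "r"]


def studies_to_frame(
    animal: Sequence[AnimalStudyData], human: Sequence[HumanTrialData] = ()
) -> pd.DataFrame:
    rows = []
    for st in animal:
        for d, n, r in zip(st.doses, st.n, st.r):
            rows.append((st.study_id, "animal", st.species, d, int(n), int(r)))
    for tr in human:
        for d, n, r in zip(tr.doses, tr.n, tr.r):
            rows.append((f"human-{tr.subgroup}", "human", str(tr.subgroup), d, int(n), int(r)))
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_study_table(
    path: Union[str, Path],
    animal: Sequence[AnimalStudyData],
    human: Sequence[HumanTrialData] = (),
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    studies_to_frame(animal, human).to_csv(path, sep=sep, index=False)


def read_study_table(
    path: Union[str, Path],
) -> Tuple[List[AnimalStudyData], List[HumanTrialData]]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    animal: List[AnimalStudyData] = []
    human: List[HumanTrialData] = []
    for (study_id, kind), grp in df.groupby(["study_id", "kind"], sort=False):
        grp = grp.sort_values("dose")
        if kind == "animal":
            animal.append(
                AnimalStudyData(
                    study_id=str(study_id),
                    species=str(grp["species_or_subgroup"].iloc[0]),
                    doses=grp["dose"].to_numpy(),
                    n=grp["n"].to_numpy(),
                    r=grp["r"].to_numpy(),
                )
            )
        elif kind == "human":
            human.append(
                HumanTrialData(
                    subgroup=int(grp["species_or_subgroup"].iloc[0]),
                    doses=grp["dose"].to_numpy(),
                    n=grp["n"].to_numpy(),
                    r=grp["r"].to_numpy(),
                )
            )
        else:
            raise ValueError(f"unknown study kind {kind!r}")
    return animal, human


def config_to_yaml(config: ModelConfig, path: Union[str, Path]) -> None:
    hp = config.hierarchy
    doc = {
        "preset": config.preset,
        "species": list(config.species),
        "translation": {
            s: {"meanlog": tp.meanlog, "sdlog": tp.sdlog}
            for s, tp in config.translation.items()
        },
        "hierarchy": {
            k: getattr(hp, k)
            for k in ("b1", "s1", "b2", "s2", "z1", "z2", "z3", "z4", "c1", "c2", "d_ref")
        },
        "subgroups": [
            {
                "weights": {
                    "species": {s: float(w.species.get(s, 0.0)) for s in config.species},
                    "human": float(w.human),
                    "robust": float(w.robust),
                },
                "bridging": {"nu": bp.nu, "lower": bp.lower, "upper": bp.upper},
                "nonex": {
                    "mean": [float(x) for x in ne.mean],
                    "cov": [[float(x) for x in row] for row in ne.cov],
                },
                "fixed_eps": bool(fe),
            }
            for w, bp, ne, fe in zip(
                config.weights, config.bridging, config.nonex, config.fixed_eps
            )
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: Union[str, Path]) -> ModelConfig:
    doc = yaml.safe_load(Path(path).read_text())
    species = tuple(doc.get("species", ()))
    translation = {
        s: TranslationPrior(**spec) for s, spec in doc.get("translation", {}).items()
    }
    hierarchy = HierarchyPriors(**doc.get("hierarchy", {}))
    weights, bridging, nonex, fixed_eps = [], [], [], []
    for sub in doc["subgroups"]:
        w = sub["weights"]
        weights.append(
            ExchangeabilityWeights(
                species=dict(w.get("species", {})),
                human=float(w.get("human", 0.0)),
                robust=float(w.get("robust", 0.0)),
            )
        )
        bridging.append(BridgingPrior(**sub.get("bridging", {})))
        ne = sub.get("nonex")
        nonex.append(
            NonExchangeablePrior(mean=np.array(ne["mean"]), cov=np.array(ne["cov"]))
            if ne
            else NonExchangeablePrior()
        )
        fixed_eps.append(bool(sub.get("fixed_eps", False)))
    return ModelConfig(
        species=species,
        translation=translation,
        weights=tuple(weights),
        bridging=tuple(bridging),
        nonex=tuple(nonex),
        hierarchy=hierarchy,
        preset=doc.get("preset", "custom"),
        fixed_eps=tuple(fixed_eps),
    )
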