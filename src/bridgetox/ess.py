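"""Beta moment-matching of marginal predictive risk distributions.

The effective sample size (ESS) of a predictive distribution for a DLT
probability is obtained by matching a Beta(a, b) to its first two
moments; the ESS is then a + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BetaApprox", "beta_moment_match", "ess_table"]


@dataclass(frozen=True)
class BetaApprox:
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def ess(self) -> float:
        return self.a + self.b

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def sd(self) -> float:
        n = self.a + self.b
        return float(np.sqrt(self.a * self.b / (n * n * (n + 1.0))))


def beta_moment_match(mean: float, sd: float) -> BetaApprox:
    """Beta(a, b) with exactly the given mean and sd.

    Closed form: ``ess = mean*(1-mean)/sd**2 - 1``, ``a = mean*ess``,
    ``b = (1-mean)*ess``.  Raises if no Beta distribution has these
    moments (``sd**2 >= mean*(1-mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"variance {var:.6g} too large for mean {mean:.6g}: no Beta matches"
        )
    ess = mean * (1.0 - mean) / var - 1.0
    return BetaApprox(a=mean * ess, b=(1.0 - mean) * ess)


def ess_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Vectorized moment matching over a per-dose summary table.

    ``summaries`` needs columns ``mean`` and ``sd``; the result carries
    the input columns plus ``a``, ``b`` and ``ess``, rows in input
    order.  Rows violating the moment-match precondition raise with
    their dose (or positional) identification.
    """
    out = summaries.copy()
    a, b, ess = [], [], []
    for idx, row in summaries.iterrows():
        try:
            fit = beta_moment_match(float(row["mean"]), float(row["sd"]))
        except ValueError as exc:
            label = row["dose"] if "dose" in summaries.columns else idx
            raise ValueError(f"row {label}: {exc}") from exc
        a.append(fit.a)
        b.append(fit.b)
        ess.append(fit.ess)
    out["a"] = a
    out["b"] = b
    out["ess"] = ess
    return out
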