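"""Shared result container for the hierarchical regressions."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RegressionResult"]


@dataclass
class RegressionResult:
    """Coefficient table plus random-effects summary for a mixed model.

    ``coefficients`` is indexed by term name with columns
    (estimate, se, stat, p); ``stat`` is a z statistic for the logistic
    model and an approximate-df t statistic for the linear model.
    ``random_variances`` maps random-effect names to variance estimates
    (variances only — no random-effect correlations are modeled).
    ``method`` records which estimation path produced the numbers.
    """

    coefficients: pd.DataFrame
    random_variances: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    method: str = ""
    notes: str = ""

    def estimate(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def stat(self, term: str) -> float:
        return float(self.coefficients.loc[term, "stat"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                term: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                }
                for term, row in self.coefficients.iterrows()
            },
            "random_variances": {k: float(v) for k, v in self.random_variances.items()},
            "converged": bool(self.converged),
            "method": self.method,
            "notes": self.notes,
        }
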