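"""Stratified regression sign analysis of the experiment results.

Within each (community structure, T) stratum, AUC is regressed on patrol
effort E, listening probability L and their interaction by ordinary least
squares, pooling replicates as independent observations.  Coefficients are
reduced to the conventional sign/significance codes: '+++'/'---' for
p <= 0.01, '+'/'-' for 0.01 < p <= 0.05, and '0' otherwise, giving a
3 (skew) x 2 (T) x 3 (term) sign matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TERMS",
    "RegressionSummary",
    "fit_auc_regression",
    "sign_code",
    "table1_report",
    "render_sign_matrix",
]

TERMS = ("Intercept", "E", "L", "E:L")


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of AUC ~ E + L + E:L within one (structure, T) stratum."""

    structure: str
    T: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    n_obs: int

    @property
    def sign_codes(self) -> dict[str, str]:
        return {
            term: sign_code(self.coefficients[term], self.p_values[term])
            for term in TERMS
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": self.structure,
                "T": self.T,
                "term": list(TERMS),
                "coefficient": [self.coefficients[t] for t in TERMS],
                "se": [self.standard_errors[t] for t in TERMS],
                "p": [self.p_values[t] for t in TERMS],
                "code": [self.sign_codes[t] for t in TERMS],
            }
        )


def fit_auc_regression(table: pd.DataFrame, structure: str, T: int) -> RegressionSummary:
    """Fit AUC ~ 1 + E + L + E*L over all rows of one stratum.

    Predictors are on their natural scale; p-values are two-sided t-tests.
    Raises if the stratum is absent or its design is rank-deficient (fewer
    than two distinct E or L values).
    """
    sub = table[(table["structure"] == structure) & (table["T"] == T)]
    if sub.empty:
        raise ValueError(f"no rows for stratum (structure={structure!r}, T={T})")
    if sub["E"].nunique() < 2 or sub["L"].nunique() < 2:
        raise ValueError(
            f"stratum (structure={structure!r}, T={T}) needs >= 2 distinct "
            "E values and >= 2 distinct L values for the interaction model"
        )
    X = np.column_stack(
        [
            np.ones(len(sub)),
            sub["E"].to_numpy(float),
            sub["L"].to_numpy(float),
            sub["E"].to_numpy(float) * sub["L"].to_numpy(float),
        ]
    )
    fit = sm.OLS(sub["auc"].to_numpy(float), X).fit()
    return RegressionSummary(
        structure=structure,
        T=int(T),
        coefficients=dict(zip(TERMS, map(float, fit.params))),
        standard_errors=dict(zip(TERMS, map(float, fit.bse))),
        p_values=dict(zip(TERMS, map(float, fit.pvalues))),
        n_obs=int(fit.nobs),
    )


def sign_code(coefficient: float, p_value: float) -> str:
    """Sign/significance code for one coefficient.

    '+++'/'---' for p <= 0.01, '+'/'-' for 0.01 < p <= 0.05, '0' for
    p > 0.05.  At the p = 0.05 boundary significance wins (the single code).
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p_value <= 0.01:
        return "+++" if coefficient >= 0 else "---"
    if p_value <= 0.05:
        return "+" if coefficient >= 0 else "-"
    return "0"


def table1_report(
    results: pd.DataFrame,
    structures: tuple[str, ...] = ("light", "moderate", "high"),
    T_values: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Sign matrix over all strata: one row per (structure, T), columns E, L, E:L.

    Raises a named error if any stratum is missing from the results table.
    """
    rows = []
    for structure in structures:
        for T in T_values:
            if results[(results["structure"] == structure) & (results["T"] == T)].empty:
                raise ValueError(f"missing stratum: structure={structure!r}, T={T}")
            summ = fit_auc_regression(results, structure, T)
            codes = summ.sign_codes
            rows.append(
                {
                    "structure": structure,
                    "T": T,
                    "E": codes["E"],
                    "L": codes["L"],
                    "E:L": codes["E:L"],
                }
            )
    return pd.DataFrame(rows, columns=["structure", "T", "E", "L", "E:L"])


def render_sign_matrix(matrix: pd.DataFrame) -> str:
    """Aligned-text rendering of the sign matrix (one row per skew level,
    E / L / E:L columns grouped by T)."""
    T_values = sorted(matrix["T"].unique())
    structures = list(dict.fromkeys(matrix["structure"]))
    header = ["skew".ljust(10)] + [
        f"T={T}: E    L    E:L " for T in T_values
    ]
    lines = ["".join(header)]
    for structure in structures:
        cells = [structure.ljust(10)]
        for T in T_values:
            row = matrix[(matrix["structure"] == structure) & (matrix["T"] == T)].iloc[0]
            cells.append(
                f"     {row['E']:<5}{row['L']:<5}{row['E:L']:<5}"
            )
        lines.append("".join(cells))
    return "\n".join(lines)
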