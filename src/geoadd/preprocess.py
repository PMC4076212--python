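"""BMI computation, WHO categorization and analysis-set construction.

The analysis outcome is binary: y = 1 for overweight/obese (BMI >= 25), y = 0
for normal weight (18.5 <= BMI < 25). Underweight women (BMI < 18.5) are
excluded first, then records with any missing model covariate (complete-case
analysis); both exclusions are counted separately in a ledger so that
retained + excluded always reconciles to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BMI_CATEGORIES",
    "AnalysisSet",
    "PipelineError",
    "compute_bmi",
    "categorize_bmi",
    "build_analysis_set",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

# WHO cut points; intervals are half-open on the right: [18.5, 25) is normal,
# [25, 30) overweight, [30, inf) obese. The printed upper bounds "24.9"/"29.9"
# are display rounding of the same convention.
_EDGES = (18.5, 25.0, 30.0)

#: Covariates required for the model (complete-case filter).
MODEL_COVARIATES = (
    "age_respondent",
    "age_partner",
    "educ_respondent",
    "educ_partner",
    "residence",
    "religion",
    "wealth",
    "ethnicity",
    "state",
)


class PipelineError(RuntimeError):
    pass


def compute_bmi(weight_kg, height_m):
    """Body mass index: weight in kilograms divided by height in metres squared."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def categorize_bmi(bmi):
    """Map BMI to WHO category: underweight / normal / overweight / obese.

    Accepts a scalar or array; returns a string or a pandas Categorical.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("BMI must be positive")
    codes = np.digitize(arr, _EDGES, right=False)  # 0..3
    if arr.ndim == 0:
        return BMI_CATEGORIES[int(codes)]
    return pd.Categorical.from_codes(codes, categories=list(BMI_CATEGORIES))


@dataclass
class AnalysisSet:
    """Binary-outcome analysis table with its exclusion ledger."""

    data: pd.DataFrame  # covariates + 'y' + 'bmi' + 'bmi_category'
    ledger: dict[str, int]

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.data)


def build_analysis_set(
    records: pd.DataFrame, covariates: tuple[str, ...] = MODEL_COVARIATES
) -> AnalysisSet:
    """Construct the overweight/obese-vs-normal analysis set.

    Exclusion order: underweight first, then incomplete covariate rows, so the
    underweight count matches a ledger computed on the full sample regardless
    of the missingness pattern.
    """
    n_input = len(records)
    df = records.copy()
    df["bmi_category"] = categorize_bmi(df["bmi"].to_numpy())

    under = df["bmi_category"] == "underweight"
    n_under = int(under.sum())
    df = df.loc[~under]

    present = [c for c in covariates if c in df.columns]
    incomplete = df[present].isna().any(axis=1)
    n_incomplete = int(incomplete.sum())
    df = df.loc[~incomplete].copy()

    if len(df) == 0:
        raise PipelineError("no records retained after exclusions")

    df["y"] = (df["bmi"] >= 25.0).astype(int)
    df = df.reset_index(drop=True)
    ledger = {
        "input": n_input,
        "underweight_excluded": n_under,
        "incomplete_excluded": n_incomplete,
        "retained": len(df),
    }
    assert ledger["retained"] + n_under + n_incomplete == n_input
    return AnalysisSet(df, ledger)
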