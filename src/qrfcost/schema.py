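"""Episode-table schema: column names, category levels, encoding.

One row of an episode table is a 6-month chemotherapy episode with the
eleven risk-adjustment covariates (treatment, demographic and
socio-economic factors) plus the Medicare episode expenditure in dollars.
Category level tuples list the reference level first; the one-hot encoding
used by the forest and the linear quantile-regression design drops the
reference column, so tree splits and effect contrasts share reference
levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: covariate declaration order; used for deterministic tie-breaking
COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "chemo_drug",
    "surgery",
    "insurance",
    "radiation",
    "trial",
    "comorbidity_cat",
    "clean_period_cat",
    "institutional",
    "hrr_relative_cost",
)

RESPONSE = "cost"

COLUMNS: tuple[str, ...] = COVARIATES + (RESPONSE,)

CONTINUOUS: tuple[str, ...] = ("age", "hrr_relative_cost")

#: category levels, reference level first
LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "chemo_drug": ("PartD", "PartB"),
    "surgery": ("no", "yes"),
    "insurance": ("NoPartD", "PartD_LIS", "PartD_NoLIS", "FullDual"),
    "radiation": ("no", "yes"),
    "trial": ("no", "yes"),
    "comorbidity_cat": ("0", "1", "2", "3", "≥4", "new_enrollee"),
    "clean_period_cat": ("62–730", "1–61", ">730_or_none"),
    "institutional": ("no", "yes"),
}

CATEGORICAL: tuple[str, ...] = tuple(c for c in COVARIATES if c in LEVELS)


class TableValidationError(ValueError):
    """Episode table failed validation; ``errors`` lists every offense."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid episode table:\n  " + "\n  ".join(self.errors))


def validate_table(df: pd.DataFrame, require_cost: bool = True) -> None:
    """Validate column presence, category labels, and cost sign.

    Collects *all* offenses (with row indices for label problems) before
    raising, so a malformed file is diagnosed in one pass.
    """
    errors: list[str] = []
    required = COLUMNS if require_cost else COVARIATES
    for col in required:
        if col not in df.columns:
            errors.append(f"missing column {col!r}")
    for col in CATEGORICAL:
        if col not in df.columns:
            continue
        bad = ~df[col].astype(str).isin(LEVELS[col])
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            vals = sorted(set(df.loc[bad, col].astype(str)))
            errors.append(
                f"unknown labels {vals} in column {col!r} at rows {rows}"
            )
    for col in CONTINUOUS + ((RESPONSE,) if require_cost else ()):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()[:10]
            errors.append(f"non-numeric or missing values in {col!r} at rows {rows}")
    if RESPONSE in df.columns and require_cost:
        cost = pd.to_numeric(df[RESPONSE], errors="coerce")
        neg = cost < 0
        if neg.any():
            rows = df.index[neg].tolist()[:10]
            errors.append(f"negative cost at rows {rows}")
    if df.isna().any().any():
        cols = df.columns[df.isna().any()].tolist()
        errors.append(f"missing values in columns {cols}")
    if errors:
        raise TableValidationError(errors)


def encode_design(
    df: pd.DataFrame, covariates: tuple[str, ...] | list[str] | None = None
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """One-hot encode covariates against their reference levels.

    Returns ``(X, column_names, groups)`` where ``groups`` maps each
    covariate name to the indices of its columns in ``X`` (one column per
    non-reference level for categoricals, one column for continuous
    covariates).  Column order follows covariate declaration order.
    """
    if covariates is None:
        covariates = [c for c in COVARIATES if c in df.columns]
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for cov in covariates:
        start = len(names)
        if cov in LEVELS:
            levels: tuple[str, ...] | None = LEVELS[cov]
        elif df[cov].dtype == object or isinstance(df[cov].dtype, pd.CategoricalDtype):
            # ad-hoc categorical (e.g. planted noise covariates): sorted
            # unique labels, first level as reference
            levels = tuple(sorted(df[cov].astype(str).unique()))
        else:
            levels = None
        if levels is not None:
            vals = df[cov].astype(str).to_numpy()
            for level in levels[1:]:
                cols.append((vals == level).astype(float))
                names.append(f"{cov}={level}")
        else:
            cols.append(pd.to_numeric(df[cov]).to_numpy(dtype=float))
            names.append(cov)
        groups[cov] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, groups
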