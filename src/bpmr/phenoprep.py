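"""Phenotype preparation: medication adjustment, derived traits, two-pass
5-SD outlier exclusion, and covariate residualisation.

The preparation mirrors standard biobank BP-GWAS practice: recorded BP of
individuals on BP-lowering medication is adjusted upward by a constant
(+15 mmHg SBP, +10 mmHg DBP), pulse pressure and mean arterial pressure are
derived from the adjusted values, and each trait is residualised on age,
age^2, sex, region, floored ambient temperature and (optionally) BMI, with
individuals more than 5 SD from the mean excluded first on the raw traits
and then on the residuals before a final refit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohortsim import (
    MEDICATION_DBP_MMHG,
    MEDICATION_SBP_MMHG,
    TRAITS,
    DataError,
    derive_map,
    derive_pp,
)

TEMPERATURE_FLOOR_C = 5.0
SD_EXCLUSION = 5.0


class ModelError(ValueError):
    """Ill-posed regression model (e.g. rank-deficient design)."""


def adjust_medication(table: pd.DataFrame) -> pd.DataFrame:
    """Add +15/+10 mmHg to the recorded SBP/DBP of treated individuals.

    Produces ``sbp_adj``/``dbp_adj``; untreated rows are copied unchanged.
    """
    for col in ("sbp_raw", "dbp_raw", "medication"):
        if col not in table.columns:
            raise DataError(f"missing column {col!r}")
    out = table.copy()
    treated = out["medication"].astype(bool).to_numpy()
    out["sbp_adj"] = out["sbp_raw"] + np.where(treated, MEDICATION_SBP_MMHG, 0.0)
    out["dbp_adj"] = out["dbp_raw"] + np.where(treated, MEDICATION_DBP_MMHG, 0.0)
    return out


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Populate PP = SBP - DBP and MAP = (2*DBP + SBP)/3 from adjusted BP."""
    for col in ("sbp_adj", "dbp_adj"):
        if col not in table.columns:
            raise DataError(f"missing column {col!r}")
    out = table.copy()
    out["pp"] = derive_pp(out["sbp_adj"].to_numpy(), out["dbp_adj"].to_numpy())
    out["map"] = derive_map(out["sbp_adj"].to_numpy(), out["dbp_adj"].to_numpy())
    return out


_TRAIT_COLS = {"sbp": "sbp_adj", "dbp": "dbp_adj", "pp": "pp", "map": "map"}


def build_design(table: pd.DataFrame, adjust_bmi: bool = True) -> tuple[np.ndarray, list[str]]:
    """Covariate design: intercept, age, age^2, sex, region indicators
    (first level reference), temperature floored at 5 degC, optionally BMI."""
    age = table["age"].to_numpy(float)
    temp = np.maximum(table["temperature"].to_numpy(float), TEMPERATURE_FLOOR_C)
    cols = [np.ones(len(table)), age, age**2, table["sex"].to_numpy(float), temp]
    names = ["intercept", "age", "age2", "sex", "temperature"]
    regions = pd.Categorical(table["region"])
    for level in regions.categories[1:]:
        cols.append((regions == level).astype(float))
        names.append(f"region[{level}]")
    if adjust_bmi:
        cols.append(table["bmi"].to_numpy(float))
        names.append("bmi")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ModelError(f"rank-deficient covariate design; collinear columns: {bad}")
    return design, names


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns with negligible diagonal in R are dependent
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[piv[k]] for k in range(len(names)) if diag[k] < tol]


def _fit_residuals(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def residualize(table: pd.DataFrame, adjust_bmi: bool = True,
                analysis_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Two-pass residualisation of the four BP traits.

    Pass 1 drops rows with any adjusted trait more than 5 SD from the
    population mean (SDs computed before any exclusion; ties at exactly 5 SD
    retained). The traits are then regressed on the covariate design and
    rows with any residual beyond 5 SD are dropped; the regressions are
    refitted on the retained rows and the final residuals stored in
    ``resid_<trait>`` columns (NaN for excluded rows). ``excl_reason``
    records why a row was removed.

    ``analysis_mask`` optionally restricts the *returned* residuals to an
    analysis subset after fitting, reproducing designs where covariate
    adjustment is performed in the full cohort before genetic analyses.
    """
    table = derive_traits(table) if "pp" not in table.columns else table.copy()
    n = len(table)
    reason = np.array([""] * n, dtype=object)

    traits = np.column_stack([table[_TRAIT_COLS[t]].to_numpy(float) for t in TRAITS])
    mean = traits.mean(axis=0)
    sd = traits.std(axis=0, ddof=0)
    raw_out = (np.abs(traits - mean) > SD_EXCLUSION * sd).any(axis=1)
    reason[raw_out] = "raw_outlier"
    keep = ~raw_out

    design, _names = build_design(table, adjust_bmi=adjust_bmi)
    resid1 = np.full_like(traits, np.nan)
    for k in range(traits.shape[1]):
        resid1[keep, k] = _fit_residuals(design[keep], traits[keep, k])
    r = resid1[keep]
    r_mean = r.mean(axis=0)
    r_sd = r.std(axis=0, ddof=0)
    resid_out_local = (np.abs(r - r_mean) > SD_EXCLUSION * r_sd).any(axis=1)
    keep_idx = np.flatnonzero(keep)
    reason[keep_idx[resid_out_local]] = "resid_outlier"
    keep2 = keep.copy()
    keep2[keep_idx[resid_out_local]] = False

    final = np.full_like(traits, np.nan)
    for k in range(traits.shape[1]):
        final[keep2, k] = _fit_residuals(design[keep2], traits[keep2, k])

    out = table.copy()
    for k, t in enumerate(TRAITS):
        out[f"resid_{t}"] = final[:, k]
    out["excl_reason"] = [r if r else None for r in reason]
    out.attrs["adjust_bmi"] = adjust_bmi
    if analysis_mask is not None:
        mask = np.asarray(analysis_mask, dtype=bool)
        out = out.loc[mask].reset_index(drop=True)
    return out


def exclusions_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row exclusion report (row id, pass, reason) for excluded rows."""
    if "excl_reason" not in table.columns:
        raise DataError("run residualize first")
    excl = table[table["excl_reason"].notna()]
    ids = excl["iid"] if "iid" in excl.columns else excl.index.astype(str)
    return pd.DataFrame(
        {
            "iid": ids.to_numpy(),
            "pass": np.where(excl["excl_reason"] == "raw_outlier", 1, 2),
            "reason": excl["excl_reason"].to_numpy(),
        }
    )


def prepare(table: pd.DataFrame, adjust_bmi: bool = True) -> pd.DataFrame:
    """adjust_medication -> derive_traits -> residualize, in order."""
    return residualize(derive_traits(adjust_medication(table)), adjust_bmi=adjust_bmi)
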