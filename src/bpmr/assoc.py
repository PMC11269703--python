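"""Per-variant association scan, fixed-effect meta-analysis, genomic
inflation, and effect-unit conversion.

Association is simple regression of the residualised trait on the additive
dosage (exact for unrelated simulated individuals; mixed-model machinery is
deliberately out of scope). P-values follow the large-sample normal
approximation, matching GWAS convention.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohortsim import GenotypeMatrix, DataError

logger = logging.getLogger(__name__)

#: Median of the 1-df chi-square distribution, the null reference for lambda_GC.
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

GWAS_SSF_COLUMNS = [
    "chromosome", "base_pair_location", "effect_allele", "other_allele",
    "effect_allele_frequency", "beta", "standard_error", "p_value", "n",
]


class UsageError(ValueError):
    """Operation called with unusable arguments (e.g. empty input)."""


def assoc_scan(geno: GenotypeMatrix, residuals: pd.DataFrame,
               region: str | Sequence[str] | None = None,
               model: str = "bmi_adj") -> pd.DataFrame:
    """Per-variant OLS of each residual column on dosage.

    ``residuals`` has one column per trait (rows aligned with ``geno``);
    rows with NaN residuals (excluded individuals) are dropped per trait.
    ``region`` restricts rows to one label or a sequence of labels.
    Monomorphic variants are skipped with a log entry. Returns a long
    DataFrame with GWAS-style columns (beta in mmHg per alt allele).
    """
    mask = np.ones(geno.n_individuals, dtype=bool)
    if region is not None:
        labels = np.char.add("region", geno.region.astype(str))
        wanted = [region] if isinstance(region, str) else list(region)
        mask &= np.isin(labels, wanted)
        if not mask.any():
            raise DataError(f"no individuals in region {region!r}")

    finite = np.isfinite(residuals.to_numpy(float))
    shared_mask = bool(np.all(finite.min(axis=1) == finite.max(axis=1)))

    # genotype sufficient statistics are reused across traits whenever the
    # traits share the same set of analysed rows (the usual case: whole-row
    # exclusions), which avoids recomputing the expensive dosage moments
    x_cache: dict = {}

    def x_stats(keep: np.ndarray):
        key = keep.tobytes() if not shared_mask else "shared"
        if key not in x_cache:
            x = geno.dosage[keep].astype(np.float64)
            sx = x.sum(axis=0)
            sxx = np.einsum("ij,ij->j", x, x)
            x_cache.clear()
            x_cache[key] = (x, sx, sxx)
        return x_cache[key]

    rows = []
    for k, trait in enumerate(residuals.columns):
        y_full = residuals[trait].to_numpy(float)
        keep = mask & finite[:, k]
        n = int(keep.sum())
        if n == 0:
            raise DataError(f"all residuals missing for trait {trait!r}")
        x, sx, sxx = x_stats(keep)
        y = y_full[keep]
        vx = sxx - sx * sx / n  # centred sum of squares
        mono = vx <= 1e-12
        if mono.any():
            logger.info("skipping %d monomorphic variants (trait %s)",
                        int(mono.sum()), trait)
        sy = y.sum()
        syy = float(y @ y)
        sxy = x.T @ y - sx * sy / n
        vy = syy - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / vx
            sse = vy - beta * sxy
            se = np.sqrt(np.maximum(sse, 0.0) / np.maximum(n - 2, 1) / vx)
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        df = geno.variants[["id", "chrom", "pos", "ref", "alt", "eaf"]].copy()
        df["trait"] = trait.replace("resid_", "")
        df["model"] = model
        df["beta"] = beta
        df["se"] = se
        df["p"] = p
        df["n"] = n
        df = df.loc[~mono].reset_index(drop=True)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def meta_fixed(estimates: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    beta = sum(b/se^2)/sum(1/se^2); se = sum(1/se^2)^(-1/2); two-sided
    normal p-value.
    """
    if len(estimates) == 0:
        raise UsageError("meta_fixed requires at least one estimate")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise DataError("all standard errors must be positive")
    w = 1.0 / (s * s)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def meta_scan(per_region: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse per-region scans variant-by-variant (fixed-effect IVW)."""
    if not per_region:
        raise UsageError("no per-region scans supplied")
    stacked = pd.concat(per_region, ignore_index=True)
    out = []
    for (vid, trait), grp in stacked.groupby(["id", "trait"], sort=False):
        w = 1.0 / grp["se"].to_numpy() ** 2
        beta = float(np.sum(w * grp["beta"].to_numpy()) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)),
                          np.finfo(float).tiny, 1.0))
        first = grp.iloc[0]
        out.append(
            {
                "id": vid, "chrom": first["chrom"], "pos": first["pos"],
                "ref": first["ref"], "alt": first["alt"], "eaf": first["eaf"],
                "trait": trait, "model": first["model"], "beta": beta,
                "se": se, "p": p, "n": int(grp["n"].sum()),
            }
        )
    return pd.DataFrame(out)


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic-inflation factor: median implied chi-square over null median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise UsageError("lambda_gc requires p-values")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def convert_effect_units(beta_sd: float | np.ndarray,
                         trait_sd_mmhg: float) -> float | np.ndarray:
    """Convert an effect expressed in trait-SD units to mmHg (SEs scale the
    same way)."""
    if trait_sd_mmhg <= 0:
        raise DataError("trait SD must be positive")
    return beta_sd * trait_sd_mmhg


def write_gwas_ssf(scan: pd.DataFrame, path: str) -> None:
    """Write a scan in the GWAS-SSF column vocabulary (one trait per call is
    typical; the trait/model columns are appended for multi-trait files)."""
    out = pd.DataFrame(
        {
            "chromosome": scan["chrom"],
            "base_pair_location": scan["pos"],
            "effect_allele": scan["alt"],
            "other_allele": scan["ref"],
            "effect_allele_frequency": scan["eaf"],
            "beta": scan["beta"],
            "standard_error": scan["se"],
            "p_value": scan["p"],
            "n": scan["n"],
            "variant_id": scan["id"],
            "trait": scan["trait"],
            "model": scan["model"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gwas_ssf(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    ren = {
        "chromosome": "chrom", "base_pair_location": "pos",
        "effect_allele": "alt", "other_allele": "ref",
        "effect_allele_frequency": "eaf", "standard_error": "se",
        "p_value": "p", "variant_id": "id",
    }
    return df.rename(columns=ren)
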