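"""Cross-population and cross-trait effect-size comparison.

Deming errors-in-variables regression (optionally forced through the
origin) compares per-allele effects between traits or populations without
the attenuation ordinary least squares suffers when both axes are noisy;
replication of discovery associations is assessed by directional
concordance and Benjamini-Hochberg false-discovery-rate control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import UsageError
from .cohortsim import DataError
from .mr import EstimationError


@dataclass
class DemingFit:
    """Errors-in-variables slope with a bootstrap confidence interval."""

    slope: float
    intercept: float
    delta: float  # error-variance ratio var(err_y) / var(err_x)
    ci: tuple[float, float]
    n: int
    through_origin: bool


def _deming_slope(x: np.ndarray, y: np.ndarray, delta: float,
                  through_origin: bool) -> tuple[float, float]:
    """Closed-form Deming slope from second moments.

    With delta = sigma_y^2 / sigma_x^2 the slope is
    (Syy - delta*Sxx + sqrt((Syy - delta*Sxx)^2 + 4*delta*Sxy^2)) / (2*Sxy),
    using central moments for the free-intercept fit and raw (uncentred)
    moments when forced through the origin.
    """
    if through_origin:
        sxx = float(np.dot(x, x))
        syy = float(np.dot(y, y))
        sxy = float(np.dot(x, y))
    else:
        xm, ym = x.mean(), y.mean()
        sxx = float(np.dot(x - xm, x - xm))
        syy = float(np.dot(y - ym, y - ym))
        sxy = float(np.dot(x - xm, y - ym))
    if sxy == 0.0:
        raise EstimationError("zero cross-moment; Deming slope undefined")
    disc = (syy - delta * sxx) ** 2 + 4.0 * delta * sxy**2
    slope = (syy - delta * sxx + np.sqrt(disc)) / (2.0 * sxy)
    intercept = 0.0 if through_origin else float(y.mean() - slope * x.mean())
    return float(slope), intercept


def deming_fit(x: np.ndarray, y: np.ndarray, delta: float = 1.0,
               through_origin: bool = False, bootstrap_n: int = 2000,
               seed: int = 0) -> DemingFit:
    """Deming regression of y-effects on x-effects.

    ``delta`` is the ratio of error variances (y over x); 1 treats both
    axes as equally noisy. The confidence interval is a seeded percentile
    bootstrap over variant pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise UsageError("deming_fit needs >= 2 paired points")
    if delta <= 0:
        raise UsageError("delta must be positive")
    slope, intercept = _deming_slope(x, y, delta, through_origin)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(bootstrap_n):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            b, _ = _deming_slope(x[idx], y[idx], delta, through_origin)
        except EstimationError:
            continue
        boots.append(b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = slope
    return DemingFit(slope=slope, intercept=intercept, delta=delta,
                     ci=(float(lo), float(hi)), n=int(x.size),
                     through_origin=through_origin)


def delta_from_ses(se_x: np.ndarray, se_y: np.ndarray) -> float:
    """Plug-in error-variance ratio mean(se_y^2)/mean(se_x^2)."""
    return float(np.mean(np.square(se_y)) / np.mean(np.square(se_x)))


def replication_assess(discovery: pd.DataFrame, replication: pd.DataFrame,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Assess replication of discovery associations in an independent scan.

    Joins on (id, trait), flags directional concordance of betas, and
    applies Benjamini-Hochberg step-up control at ``fdr`` to the
    replication p-values of the tested set. The returned frame carries
    ``concordant`` and ``replicated`` per association; summary counts live
    in ``DataFrame.attrs['summary']``.
    """
    keys = ["id", "trait"] if "trait" in discovery.columns else ["id"]
    merged = discovery.merge(replication, on=keys, suffixes=("_disc", "_rep"))
    if merged.empty:
        raise UsageError("no shared associations between discovery and replication")
    if np.any((merged["p_rep"] <= 0) | (merged["p_rep"] > 1)):
        raise DataError("replication p-values must lie in (0, 1]")
    concordant = np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"])
    rej, _, _, _ = multipletests(merged["p_rep"].to_numpy(), alpha=fdr,
                                 method="fdr_bh")
    out = merged[keys].copy()
    out["beta_disc"] = merged["beta_disc"]
    out["beta_rep"] = merged["beta_rep"]
    out["p_rep"] = merged["p_rep"]
    out["concordant"] = concordant.to_numpy()
    out["replicated"] = rej
    out.attrs["summary"] = {
        "n_tested": int(len(out)),
        "n_concordant": int(concordant.sum()),
        "n_replicated": int(rej.sum()),
        "fdr": fdr,
    }
    return out
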