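"""One-sample and multivariable Mendelian randomisation of blood-pressure
traits against binary cardiovascular outcomes, per-region estimation with
fixed-effect meta-analysis, odds-ratio rescaling between per-SD and
per-5 mmHg units, and two-sample IVW / MR-Egger / MVMR estimators on
summary statistics.

One-sample estimates regress the outcome on the genetically predicted
exposure (mmHg) with sex, age and age^2 as covariates by logistic
regression, separately within each recruitment region; regional log-odds
estimates are combined by inverse-variance-weighted fixed-effect
meta-analysis. A conditional F statistic below 10 marks a weak-instrument
pairing whose multivariable estimates require caution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import UsageError, meta_fixed
from .cohortsim import DataError
from .loci import Locus

logger = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0
SELECTION_RULES = ("lowest_p", "prefer_a", "prefer_b")


class EstimationError(RuntimeError):
    """Estimator could not produce a usable estimate."""


@dataclass
class MREstimate:
    """Causal estimate of exposure trait(s) on one outcome."""

    exposure: str
    outcome: str
    logor_per_sd: float
    se_per_sd: float
    trait_sd: float
    per_region: list[dict] = field(default_factory=list)
    f_stat: float | None = None
    conditional_f: float | None = None
    partial_r2: float | None = None
    n_cases: int = 0
    n_controls: int = 0
    weak_instrument: bool = False

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.logor_per_sd))

    @property
    def ci_per_sd(self) -> tuple[float, float]:
        lo = self.logor_per_sd - 1.96 * self.se_per_sd
        hi = self.logor_per_sd + 1.96 * self.se_per_sd
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def or_per_5mmhg(self) -> float:
        return rescale_or(self.or_per_sd, self.trait_sd, 5.0)

    @property
    def ci_per_5mmhg(self) -> tuple[float, float]:
        lo, hi = self.ci_per_sd
        return (rescale_or(lo, self.trait_sd, 5.0),
                rescale_or(hi, self.trait_sd, 5.0))

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.logor_per_sd / self.se_per_sd)))


def _fit_logistic(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Logistic fit (IRLS/Newton); raises EstimationError on separation or
    non-convergence."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-10)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError("logistic fit did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise EstimationError("unstable logistic fit (non-finite SEs)")
    return np.asarray(res.params), np.asarray(res.bse)


def _per_region_logistic(case: np.ndarray, exposures: list[np.ndarray],
                         age: np.ndarray, sex: np.ndarray,
                         region: np.ndarray) -> dict[str, list]:
    """Fit the outcome model in each region; drop regions that separate."""
    y = np.asarray(case, dtype=float)
    fits: dict[str, list] = {"region": [], "beta": [], "se": [], "dropped": []}
    for reg in pd.unique(region):
        rows = region == reg
        yr = y[rows]
        if yr.sum() == 0 or yr.sum() == rows.sum():
            logger.warning("region %s has no cases or no controls; dropped", reg)
            fits["dropped"].append(str(reg))
            continue
        design = np.column_stack(
            [np.ones(rows.sum())] + [e[rows] for e in exposures]
            + [sex[rows], age[rows], age[rows] ** 2]
        )
        try:
            params, bse = _fit_logistic(design, yr)
        except EstimationError as exc:
            logger.warning("region %s dropped: %s", reg, exc)
            fits["dropped"].append(str(reg))
            continue
        fits["region"].append(str(reg))
        fits["beta"].append(params[1:1 + len(exposures)])
        fits["se"].append(bse[1:1 + len(exposures)])
    if not fits["region"]:
        raise EstimationError("all regions dropped from the outcome model")
    return fits


def onesample_mr(case: np.ndarray, predicted: np.ndarray, age: np.ndarray,
                 sex: np.ndarray, region: np.ndarray, trait_sd: float,
                 exposure: str = "", outcome: str = "") -> MREstimate:
    """One-sample MR: per-region logistic regression of the outcome on the
    genetically predicted exposure (mmHg), meta-analysed across regions and
    expressed per 1 SD and per 5 mmHg of the exposure trait."""
    fits = _per_region_logistic(case, [np.asarray(predicted, float)], np.asarray(age, float),
                                np.asarray(sex, float), np.asarray(region))
    per_region = [
        {"region": r, "beta_mmhg": float(b[0]), "se_mmhg": float(s[0])}
        for r, b, s in zip(fits["region"], fits["beta"], fits["se"])
    ]
    beta, se, _ = meta_fixed([(d["beta_mmhg"], d["se_mmhg"]) for d in per_region])
    case_arr = np.asarray(case, bool)
    return MREstimate(
        exposure=exposure, outcome=outcome,
        logor_per_sd=beta * trait_sd, se_per_sd=se * trait_sd,
        trait_sd=trait_sd, per_region=per_region,
        n_cases=int(case_arr.sum()), n_controls=int((~case_arr).sum()),
    )


def mvmr_onesample(case: np.ndarray, predicted_a: np.ndarray,
                   predicted_b: np.ndarray, age: np.ndarray, sex: np.ndarray,
                   region: np.ndarray, sd_a: float, sd_b: float,
                   exposure_a: str = "a", exposure_b: str = "b",
                   outcome: str = "",
                   conditional_f: dict[str, float] | None = None
                   ) -> dict[str, MREstimate]:
    """Multivariable one-sample MR: both genetically predicted exposures in
    one logistic model (mutually adjusted), per region then meta-analysed.

    ``conditional_f`` (per exposure) is attached when supplied; estimates
    with conditional F < 10 carry a prominent weak-instrument flag.
    """
    pa = np.asarray(predicted_a, float)
    pb = np.asarray(predicted_b, float)
    corr = np.corrcoef(pa, pb)[0, 1]
    if abs(corr) > 1.0 - 1e-10:
        raise EstimationError("exposure scores are collinear; not identifiable")
    fits = _per_region_logistic(case, [pa, pb], np.asarray(age, float),
                                np.asarray(sex, float), np.asarray(region))
    case_arr = np.asarray(case, bool)
    out: dict[str, MREstimate] = {}
    for k, (name, sd) in enumerate(((exposure_a, sd_a), (exposure_b, sd_b))):
        per_region = [
            {"region": r, "beta_mmhg": float(b[k]), "se_mmhg": float(s[k])}
            for r, b, s in zip(fits["region"], fits["beta"], fits["se"])
        ]
        beta, se, _ = meta_fixed([(d["beta_mmhg"], d["se_mmhg"]) for d in per_region])
        est = MREstimate(
            exposure=name, outcome=outcome, logor_per_sd=beta * sd,
            se_per_sd=se * sd, trait_sd=sd, per_region=per_region,
            n_cases=int(case_arr.sum()), n_controls=int((~case_arr).sum()),
        )
        if conditional_f is not None and name in conditional_f:
            est.conditional_f = conditional_f[name]
            if est.conditional_f < WEAK_INSTRUMENT_F:
                est.weak_instrument = True
                logger.warning(
                    "conditional F %.2f < %.0f for %s given the paired trait; "
                    "caution is required when interpreting this estimate",
                    est.conditional_f, WEAK_INSTRUMENT_F, name)
        out[name] = est
    return out


def build_paired_instrument(merged_loci: list[Locus], trait_a: str,
                            trait_b: str, selection_rule: str = "lowest_p"
                            ) -> list[str]:
    """One sentinel variant per merged locus for an MVMR trait pair.

    Where a locus carries sentinels for both traits, ``lowest_p`` takes the
    stronger association; the sensitivity rules ``prefer_a``/``prefer_b``
    always take the named trait's sentinel when available.
    """
    if selection_rule not in SELECTION_RULES:
        raise UsageError(f"unknown selection rule {selection_rule!r}")
    chosen: list[str] = []
    for loc in merged_loci:
        sa = loc.sentinels.get(trait_a)
        sb = loc.sentinels.get(trait_b)
        if sa is None and sb is None:
            raise DataError(
                f"locus {loc.chrom}:{loc.start}-{loc.end} has no sentinel for "
                f"{trait_a!r} or {trait_b!r}")
        if sa is None or sb is None:
            pick = sa or sb
        elif selection_rule == "prefer_a":
            pick = sa
        elif selection_rule == "prefer_b":
            pick = sb
        else:
            pick = sa if sa[1] <= sb[1] else sb
        chosen.append(pick[0])
    # a variant can sentinel two adjacent loci only after aggressive merging;
    # dedupe preserving order
    seen: set[str] = set()
    return [v for v in chosen if not (v in seen or seen.add(v))]


def rescale_or(or_per_sd: float, sd_mmhg: float, delta: float = 5.0) -> float:
    """Re-express an odds ratio per 1 SD as an OR per ``delta`` mmHg:
    exp(ln(OR) * delta / sd)."""
    if or_per_sd <= 0 or sd_mmhg <= 0 or delta <= 0:
        raise UsageError("rescale_or requires positive inputs")
    return float(np.exp(np.log(or_per_sd) * delta / sd_mmhg))


# ---------------------------------------------------------------------------
# two-sample estimators on summary statistics


@dataclass
class SummaryInstrument:
    """Harmonised per-variant summary statistics for two-sample MR.

    ``data`` columns: id, ea (shared effect allele), beta_<exposure>,
    se_<exposure> for each exposure, beta_outcome, se_outcome.
    """

    data: pd.DataFrame
    exposures: list[str]

    def __post_init__(self) -> None:
        need = [f"beta_{e}" for e in self.exposures] + \
               [f"se_{e}" for e in self.exposures] + ["beta_outcome", "se_outcome"]
        for col in need:
            if col not in self.data.columns:
                raise DataError(f"summary instrument missing column {col!r}")
        for e in self.exposures:
            if np.any(self.data[f"se_{e}"] <= 0):
                raise DataError("exposure standard errors must be positive")
        if np.any(self.data["se_outcome"] <= 0):
            raise DataError("outcome standard errors must be positive")


_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame,
              exposure_name: str = "exposure") -> SummaryInstrument:
    """Align exposure and outcome summary statistics to a shared effect
    allele: matching alleles pass through, swapped ref/alt flips the outcome
    beta's sign, strand-ambiguous palindromic variants and allele mismatches
    are dropped with a log entry."""
    merged = exposure.merge(outcome, on="id", suffixes=("_x", "_y"))
    rows = []
    for r in merged.itertuples(index=False):
        if (r.alt_x, r.ref_x) in _PALINDROMIC:
            logger.info("dropping palindromic variant %s", r.id)
            continue
        if (r.alt_x, r.ref_x) == (r.alt_y, r.ref_y):
            flip = 1.0
        elif (r.alt_x, r.ref_x) == (r.ref_y, r.alt_y):
            flip = -1.0
        else:
            logger.info("allele mismatch at %s; dropped", r.id)
            continue
        rows.append({"id": r.id, "ea": r.alt_x,
                     f"beta_{exposure_name}": r.beta_x,
                     f"se_{exposure_name}": r.se_x,
                     "beta_outcome": flip * r.beta_y,
                     "se_outcome": r.se_y})
    columns = ["id", "ea", f"beta_{exposure_name}", f"se_{exposure_name}",
               "beta_outcome", "se_outcome"]
    return SummaryInstrument(pd.DataFrame(rows, columns=columns),
                             [exposure_name])


def twosample_ivw(inst: SummaryInstrument) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted estimate.

    estimate = sum(w bx by) / sum(w bx^2), w = se_y^-2;
    se = (sum w bx^2)^(-1/2). Reduces to the Wald ratio for one variant.
    """
    e = inst.exposures[0]
    bx = inst.data[f"beta_{e}"].to_numpy(float)
    by = inst.data["beta_outcome"].to_numpy(float)
    w = inst.data["se_outcome"].to_numpy(float) ** -2.0
    denom = float(np.sum(w * bx * bx))
    if denom == 0:
        raise EstimationError("zero weighted exposure variance")
    est = float(np.sum(w * bx * by) / denom)
    se = denom ** -0.5
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return est, se, p


def twosample_egger(inst: SummaryInstrument
                    ) -> tuple[float, float, float, float, float]:
    """MR-Egger: weighted regression of outcome betas on exposure betas with
    a free intercept (weights se_y^-2, exposure betas oriented
    non-negative). Returns (slope, slope_se, intercept, intercept_se,
    intercept_p); a non-zero intercept indicates unbalanced horizontal
    pleiotropy."""
    e = inst.exposures[0]
    if len(inst.data) < 3:
        raise UsageError("MR-Egger requires at least 3 variants")
    bx = inst.data[f"beta_{e}"].to_numpy(float)
    by = inst.data["beta_outcome"].to_numpy(float)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise EstimationError("all exposure betas equal; slope not identifiable")
    w = inst.data["se_outcome"].to_numpy(float) ** -2.0
    design = np.column_stack([np.ones_like(bx), bx])
    res = sm.WLS(by, design, weights=w).fit()
    # MR convention: scale parameter floored at 1 (multiplicative random
    # effects with no under-dispersion)
    sigma = max(1.0, np.sqrt(res.scale))
    se = res.bse / np.sqrt(res.scale) * sigma
    icpt, slope = res.params
    icpt_p = float(2.0 * stats.norm.sf(abs(icpt / se[0])))
    return float(slope), float(se[1]), float(icpt), float(se[0]), icpt_p


def twosample_mvmr(inst: SummaryInstrument
                   ) -> dict[str, dict[str, float]]:
    """Two-sample multivariable MR for a pair of exposures.

    Weighted regression of outcome betas on both exposures' betas through
    the origin (weights se_y^-2), with a Q-statistic conditional F per
    exposure: Q_A = sum_j w_j (beta_Aj - fitted(beta_Bj))^2 with
    w_j = se_Aj^-2, divided by (L - 1)."""
    if len(inst.exposures) != 2:
        raise UsageError("twosample_mvmr requires exactly two exposures")
    if len(inst.data) < 3:
        raise UsageError("twosample_mvmr requires at least 3 variants")
    a, b = inst.exposures
    ba = inst.data[f"beta_{a}"].to_numpy(float)
    bb = inst.data[f"beta_{b}"].to_numpy(float)
    by = inst.data["beta_outcome"].to_numpy(float)
    wy = inst.data["se_outcome"].to_numpy(float) ** -2.0

    x = np.column_stack([ba, bb])
    if np.ptp(ba) > 0 and np.ptp(bb) > 0:
        corr = np.corrcoef(ba, bb)[0, 1]
        if abs(corr) > 1.0 - 1e-10:
            raise EstimationError(
                "collinear exposure beta vectors; estimates suppressed")
    res = sm.WLS(by, x, weights=wy).fit()

    def cond_f(target: np.ndarray, other: np.ndarray, se_t: np.ndarray) -> float:
        w = se_t ** -2.0
        denom = float(np.sum(w * other * other))
        fitted = (np.sum(w * other * target) / denom) * other if denom > 0 else 0.0
        q = float(np.sum(w * (target - fitted) ** 2))
        return q / (len(target) - 1)

    out: dict[str, dict[str, float]] = {}
    for k, (name, bx, bo) in enumerate(((a, ba, bb), (b, bb, ba))):
        se_x = inst.data[f"se_{name}"].to_numpy(float)
        f = cond_f(bx, bo, se_x)
        est, se = float(res.params[k]), float(res.bse[k])
        out[name] = {
            "estimate": est, "se": se,
            "p": float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else float("nan"),
            "conditional_f": f,
            "weak_instrument": f < WEAK_INSTRUMENT_F,
        }
        if f < WEAK_INSTRUMENT_F:
            logger.warning("two-sample MVMR conditional F %.2f < 10 for %s", f, name)
    return out


def write_mr_report(estimates: list[MREstimate], path: str) -> None:
    """Delimited report mirroring per-trait/per-outcome OR panels."""
    rows = []
    for e in estimates:
        lo_sd, hi_sd = e.ci_per_sd
        lo5, hi5 = e.ci_per_5mmhg
        rows.append({
            "exposure": e.exposure, "outcome": e.outcome,
            "or_per_sd": e.or_per_sd, "ci_lo_per_sd": lo_sd, "ci_hi_per_sd": hi_sd,
            "or_per_5mmhg": e.or_per_5mmhg, "ci_lo_per_5mmhg": lo5,
            "ci_hi_per_5mmhg": hi5, "p": e.p, "trait_sd_mmhg": e.trait_sd,
            "f_stat": e.f_stat, "conditional_f": e.conditional_f,
            "partial_r2": e.partial_r2, "n_cases": e.n_cases,
            "n_controls": e.n_controls, "weak_instrument": e.weak_instrument,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
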