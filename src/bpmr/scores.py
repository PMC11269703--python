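"""Genetic-score construction with a 70/30 split and 100-fold jack-knife
weighting, score scaling to genetically predicted traits, and
instrument-strength diagnostics (F statistic and partial r^2 by SSE
reduction).

Every individual's score uses weights estimated in data excluding that
individual: the 30% holdout receives weights from the full 70% training
subset, and each training fold receives leave-one-fold-out weights. This
removes winner's-curse/overfitting bias that would otherwise pull the
instrument toward the observational association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohortsim import ConfigurationError, DataError, GenotypeMatrix
from .phenoprep import ModelError

HOLDOUT_FOLD = -1


@dataclass
class GeneticScore:
    """Per-trait genetic score with per-fold weights and diagnostics."""

    trait: str
    variant_ids: list[str]
    fold: np.ndarray  # per individual; -1 marks the 30% holdout
    weights: np.ndarray  # folds x variants, leave-one-fold-out (mmHg/allele)
    full_weights: np.ndarray  # variants, estimated on the whole 70%
    orientation: np.ndarray | None = None  # +1 alt is risk allele, -1 flipped
    values: np.ndarray | None = None
    scaling_coef: float | None = None
    predicted: np.ndarray | None = None  # genetically predicted trait (mmHg)
    f_stat: float | None = None
    partial_r2: float | None = None
    extras: dict = field(default_factory=dict)


def _marginal_beta(sx, sxx, sy, sxy, n):
    """Vector of simple-regression slopes from sufficient statistics."""
    with np.errstate(divide="ignore", invalid="ignore"):
        num = sxy - sx * sy / n
        den = sxx - sx * sx / n
        beta = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return beta


def make_weights(geno: GenotypeMatrix, residuals: pd.Series | np.ndarray,
                 sentinels: list[str], trait: str = "",
                 unrelated_frac: float = 0.7, folds: int = 100,
                 seed: int = 0) -> GeneticScore:
    """Estimate per-fold jack-knifed marginal effect sizes at the sentinels.

    Individuals are partitioned (seeded) into a training subset of
    ``unrelated_frac`` and a holdout; within training, folds are assigned
    round-robin along a seeded permutation. The weight vector for fold f is
    the marginal OLS slope of the residualised trait on dosage computed on
    training individuals outside fold f; holdout individuals receive the
    full-training weights.
    """
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    n = geno.n_individuals
    n_train = int(round(unrelated_frac * n))
    if folds > n_train:
        raise ConfigurationError("more folds than training individuals")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.full(n, HOLDOUT_FOLD, dtype=int)
    fold[perm[:n_train]] = np.arange(n_train) % folds

    y = np.asarray(residuals, dtype=float)
    valid = np.isfinite(y)
    idx = geno.index_of(sentinels)
    x = geno.dosage[:, idx].astype(np.float64)
    m = len(sentinels)

    # per-fold sufficient statistics over valid training rows
    sx = np.zeros((folds, m))
    sxx = np.zeros((folds, m))
    sxy = np.zeros((folds, m))
    sy = np.zeros(folds)
    cnt = np.zeros(folds)
    for f in range(folds):
        rows = (fold == f) & valid
        xf = x[rows]
        yf = y[rows]
        sx[f] = xf.sum(axis=0)
        sxx[f] = np.einsum("ij,ij->j", xf, xf)
        sxy[f] = xf.T @ yf
        sy[f] = yf.sum()
        cnt[f] = rows.sum()

    tot_sx, tot_sxx, tot_sxy = sx.sum(0), sxx.sum(0), sxy.sum(0)
    tot_sy, tot_n = sy.sum(), cnt.sum()
    if tot_n < m + 2:
        raise DataError("too few valid training individuals")

    weights = np.empty((folds, m))
    for f in range(folds):
        nf = tot_n - cnt[f]
        weights[f] = _marginal_beta(tot_sx - sx[f], tot_sxx - sxx[f],
                                    tot_sy - sy[f], tot_sxy - sxy[f], nf)
    full_weights = _marginal_beta(tot_sx, tot_sxx, tot_sy, tot_sxy, tot_n)

    return GeneticScore(trait=trait, variant_ids=list(sentinels), fold=fold,
                        weights=weights, full_weights=full_weights)


def compute_gs(geno: GenotypeMatrix, score: GeneticScore) -> GeneticScore:
    """Populate per-individual score values: sum_j dosage_ij * w_j(fold_i).

    Orientation metadata flips alleles so reported weights are
    non-negative; the score itself is computed on the alt-dosage scale,
    which differs from the flipped form only by an additive constant and is
    therefore numerically identical in every downstream regression.
    """
    idx = geno.index_of(score.variant_ids)
    x = geno.dosage[:, idx].astype(np.float64)
    values = np.empty(geno.n_individuals)
    hold = score.fold == HOLDOUT_FOLD
    values[hold] = x[hold] @ score.full_weights
    for f in range(score.weights.shape[0]):
        rows = score.fold == f
        if rows.any():
            values[rows] = x[rows] @ score.weights[f]
    score.orientation = np.where(score.full_weights >= 0, 1, -1)
    score.values = values
    return score


def score_design(covariates: pd.DataFrame, adjust_bmi: bool = True) -> np.ndarray:
    """Covariate design for scaling/strength models: intercept, age, age^2,
    sex, BMI (optional), and region indicators or supplied principal
    components (columns named ``pc*``)."""
    age = covariates["age"].to_numpy(float)
    cols = [np.ones(len(covariates)), age, age**2,
            covariates["sex"].to_numpy(float)]
    if adjust_bmi and "bmi" in covariates.columns:
        cols.append(covariates["bmi"].to_numpy(float))
    pc_cols = [c for c in covariates.columns if c.startswith("pc")]
    if pc_cols:
        for c in pc_cols:
            cols.append(covariates[c].to_numpy(float))
    elif "region" in covariates.columns:
        regions = pd.Categorical(covariates["region"])
        for level in regions.categories[1:]:
            cols.append((regions == level).astype(float))
    return np.column_stack(cols)


def scale_gs(trait_values: np.ndarray, score: GeneticScore,
             covariates: pd.DataFrame | None = None,
             adjust_bmi: bool = True) -> GeneticScore:
    """Scale the score into a genetically predicted trait in mmHg.

    Fits trait ~ score + covariates; the fitted score coefficient scales
    the centred score: predicted = coef * (score - mean(score)).
    """
    if score.values is None:
        raise DataError("compute_gs must run before scale_gs")
    s = score.values
    if np.var(s) <= 0:
        raise ModelError("zero-variance score cannot be scaled")
    y = np.asarray(trait_values, dtype=float)
    keep = np.isfinite(y)
    if covariates is not None:
        base = score_design(covariates[keep].reset_index(drop=True), adjust_bmi)
    else:
        base = np.ones((int(keep.sum()), 1))
    design = np.column_stack([base, s[keep]])
    coef, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
    score.scaling_coef = float(coef[-1])
    score.predicted = score.scaling_coef * (s - s[keep].mean())
    return score


def instrument_strength(trait_values: np.ndarray, score_values: np.ndarray,
                        covariates: pd.DataFrame | None = None,
                        second_score: np.ndarray | None = None,
                        adjust_bmi: bool = True) -> tuple[float, float]:
    """F statistic and partial r^2 of the score by nested-model SSE reduction.

    partial_r2 = (SSE_reduced - SSE_full) / SSE_reduced and
    F = (SSE_reduced - SSE_full) / (SSE_full / df_full). With
    ``second_score`` both models additionally contain the second trait's
    score, yielding the conditional F / partial r^2 used to judge
    multivariable instrument strength.
    """
    y = np.asarray(trait_values, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    base_cols = [np.ones(len(y))]
    if covariates is not None:
        base_cols = [score_design(covariates[keep].reset_index(drop=True), adjust_bmi)]
    if second_score is not None:
        base_cols.append(np.asarray(second_score, float)[keep, None])
    reduced = np.column_stack(base_cols)
    full = np.column_stack([reduced, np.asarray(score_values, float)[keep]])

    def sse(design: np.ndarray) -> float:
        coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if res.size:
            return float(res[0])
        return float(np.sum((y - design @ coef) ** 2))

    sse_r, sse_f = sse(reduced), sse(full)
    df_full = len(y) - full.shape[1]
    if df_full <= 0:
        raise DataError("no residual degrees of freedom")
    partial_r2 = max(0.0, (sse_r - sse_f) / sse_r) if sse_r > 0 else 0.0
    f = (sse_r - sse_f) / (sse_f / df_full) if sse_f > 0 else np.inf
    return float(f), float(partial_r2)


def write_scores(score: GeneticScore, path: str, iids=None) -> None:
    if score.values is None:
        raise DataError("scores not computed")
    n = len(score.values)
    if iids is None:
        iids = [f"id{i:07d}" for i in range(n)]
    pd.DataFrame({"iid": iids, "fold": score.fold, "score": score.values}
                 ).to_csv(path, sep="\t", index=False)


def write_weights(score: GeneticScore, path: str) -> None:
    rows = []
    for f in range(score.weights.shape[0]):
        for j, vid in enumerate(score.variant_ids):
            rows.append({"variant": vid, "fold": f, "weight": score.weights[f, j]})
    for j, vid in enumerate(score.variant_ids):
        rows.append({"variant": vid, "fold": HOLDOUT_FOLD,
                     "weight": score.full_weights[j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
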