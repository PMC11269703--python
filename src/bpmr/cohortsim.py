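"""Synthetic biobank cohort simulator with known genetic and causal truth.

Generates LD-blocked diploid dosages with regional allele-frequency drift,
systolic/diastolic blood pressure with configurable SNP heritability and
between-trait genetic correlation (pulse pressure and mean arterial pressure
derived exactly as PP = SBP - DBP and MAP = (2*DBP + SBP)/3), covariates,
blood-pressure-lowering medication among hypertensives, and binary
cardiovascular outcomes from a logistic model with per-5 mmHg log-odds.

The LD model is a latent multivariate-normal per haplotype with AR(1)
correlation within a block, thresholded at the allele-frequency quantile;
the two haplotypes are summed into an additive dosage in [0, 2]. Regional
allele-frequency drift follows the Balding-Nichols Beta model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

TRAITS = ("sbp", "dbp", "pp", "map")

#: Constants added to the recorded BP of treated individuals during phenotype
#: preparation (mmHg); also the default magnitude of the medication effect.
MEDICATION_SBP_MMHG = 15.0
MEDICATION_DBP_MMHG = 10.0

#: Hypertension definition: SBP >= 140 mmHg or DBP >= 90 mmHg at baseline.
HYPERTENSION_SBP = 140.0
HYPERTENSION_DBP = 90.0


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class DataError(ValueError):
    """Input data violates a precondition."""


def derive_pp(sbp: np.ndarray, dbp: np.ndarray) -> np.ndarray:
    """Pulse pressure: SBP - DBP."""
    return np.asarray(sbp) - np.asarray(dbp)


def derive_map(sbp: np.ndarray, dbp: np.ndarray) -> np.ndarray:
    """Mean arterial pressure: (2*DBP + SBP) / 3."""
    return (2.0 * np.asarray(dbp) + np.asarray(sbp)) / 3.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions of a large Chinese biobank:
    SBP standard deviation 22.3 mmHg, roughly one third of hypertensives on
    BP-lowering medication, SBP-DBP genetic correlation 0.85, SNP
    heritability ~0.16 per trait, ten recruitment regions.
    """

    n_individuals: int = 20_000
    n_variants: int = 2_000
    n_regions: int = 10
    ld_block_size: int = 10
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.01
    n_causal: int = 30
    h2_sbp: float = 0.16
    h2_dbp: float = 0.16
    rg_sbp_dbp: float = 0.85
    resid_corr: float = 0.55
    sd_sbp: float = 22.3
    sd_dbp: float = 11.6
    mean_sbp: float = 130.0
    mean_dbp: float = 78.0
    treat_prob: float = 1.0 / 3.0
    treat_effect_sbp: float = MEDICATION_SBP_MMHG
    treat_effect_dbp: float = MEDICATION_DBP_MMHG
    # outcome -> trait -> log odds ratio per 5 mmHg of the underlying trait
    outcome_logors: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "is": {"sbp": math.log(1.15), "dbp": math.log(1.18)},
            "ich": {"sbp": math.log(1.35)},
        }
    )
    outcome_prev: Mapping[str, float] = field(
        default_factory=lambda: {"is": 0.10, "ich": 0.05}
    )
    # linear covariate effects on the raw traits (units: mmHg per unit)
    covar_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "sbp": {"age": 0.45, "sex": -2.0, "bmi": 0.5, "temperature": -0.30},
            "dbp": {"age": 0.15, "sex": -1.0, "bmi": 0.4, "temperature": -0.15},
        }
    )
    n_chromosomes: int = 2
    variant_spacing_bp: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0 or self.n_regions <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.ld_block_size <= 0:
            raise ConfigurationError("ld_block_size must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.fst < 0:
            raise ConfigurationError("fst must be >= 0")
        for h2 in (self.h2_sbp, self.h2_dbp):
            if not 0.0 <= h2 < 1.0:
                raise ConfigurationError("heritability must be in [0, 1)")
        if not -1.0 <= self.rg_sbp_dbp <= 1.0:
            raise ConfigurationError("rg_sbp_dbp must be in [-1, 1]")
        if not 0.0 <= self.treat_prob <= 1.0:
            raise ConfigurationError("treat_prob must be a probability")
        if self.n_causal < 0 or self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal must be in [0, n_variants]")
        for o, prev in self.outcome_prev.items():
            if not 0.0 < prev < 1.0:
                raise ConfigurationError(f"prevalence for {o!r} outside (0,1)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix plus metadata.

    ``dosage`` holds values in [0, 2]; ``variants`` is a DataFrame with
    columns id, chrom, pos (1-based), ref, alt, eaf; ``region`` is the
    per-individual recruitment-region label.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    region: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def index_of(self, variant_ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(variant_ids))
        missing = [v for v, i in zip(variant_ids, idx) if i < 0]
        if missing:
            raise DataError(f"variants missing from genotypes: {missing[:5]}")
        return idx


@dataclass
class SimulationTruth:
    """Record of every random draw a downstream stage may be tested against."""

    causal_variant_ids: list[str]
    beta_true: pd.DataFrame  # index variant id, columns sbp/dbp/pp/map (mmHg per allele)
    h2_realised: dict[str, float]
    outcome_logors_true: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_intercepts: dict[str, float] = field(default_factory=dict)
    medication: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {
            "causal_variant_ids": self.causal_variant_ids,
            "beta_true": self.beta_true.to_dict(orient="index"),
            "h2_realised": self.h2_realised,
            "outcome_logors_true": self.outcome_logors_true,
            "outcome_intercepts": self.outcome_intercepts,
            "medication": None
            if self.medication is None
            else self.medication.astype(int).tolist(),
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# genotypes


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float,
                restart: np.ndarray) -> np.ndarray:
    """Latent N(0,1) matrix (variants x individuals) with AR(1) correlation
    along the variant axis, restarting where ``restart`` is True (block and
    chromosome boundaries).

    Variant-major layout keeps the recursion on contiguous rows, and the
    update is vectorised across blocks: all variants at the same
    within-block offset advance together, so the loop length is the block
    size, not the variant count.
    """
    z = rng.standard_normal((m, n), dtype=np.float32)
    if rho > 0.0:
        rho32 = np.float32(rho)
        carry = np.float32(math.sqrt(1.0 - rho * rho))
        seg_pos = np.zeros(m, dtype=np.int64)
        for j in range(1, m):
            seg_pos[j] = 0 if restart[j] else seg_pos[j - 1] + 1
        for s in range(1, int(seg_pos.max()) + 1):
            rows = np.flatnonzero(seg_pos == s)
            z[rows] = rho32 * z[rows - 1] + carry * z[rows]
    return z


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw LD-blocked dosages under the thresholded-Gaussian haplotype model.

    Within a block, adjacent latent haplotype correlation is ``ld_rho``;
    across regions, per-variant allele frequencies drift following
    Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F). Hardy-Weinberg holds in
    expectation within a region because haplotypes are i.i.d.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, m, nreg = cfg.n_individuals, cfg.n_variants, cfg.n_regions

    region = rng.integers(0, nreg, size=n)
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    if cfg.fst > 0.0:
        f = cfg.fst
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_reg = rng.beta(a, b, size=(nreg, m))
        p_reg = np.clip(p_reg, 1e-4, 1.0 - 1e-4)
    else:
        p_reg = np.broadcast_to(p_anc, (nreg, m)).copy()

    # chromosome layout: contiguous equal chunks, AR restarts at block and
    # chromosome starts
    chunk = -(-m // cfg.n_chromosomes)
    idx = np.arange(m)
    restart = (idx % cfg.ld_block_size == 0) | (idx % chunk == 0)
    restart[0] = True

    # thresholds per (variant, individual) in the variant-major layout
    thr = stats.norm.ppf(p_reg).astype(np.float32).T[:, region]  # m x n
    dosage_t = np.zeros((m, n), dtype=np.uint8)
    for _hap in range(2):
        z = _ar1_latent(rng, n, m, cfg.ld_rho, restart)
        dosage_t += (z < thr).view(np.uint8)
        del z
    dosage = dosage_t.T.astype(np.float32)
    del dosage_t

    chrom = (idx // chunk + 1).astype(int)
    pos = (idx % chunk + 1) * cfg.variant_spacing_bp
    alleles = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                        ("A", "C"), ("G", "T")], dtype=object)
    which = rng.integers(0, len(alleles), size=m)
    variants = pd.DataFrame(
        {
            "id": [f"var{j:06d}" for j in range(m)],
            "chrom": [str(c) for c in chrom],
            "pos": pos.astype(np.int64),
            "ref": [alleles[w][0] for w in which],
            "alt": [alleles[w][1] for w in which],
            "eaf": dosage.mean(axis=0) / 2.0,
        }
    )
    return GenotypeMatrix(dosage=dosage, variants=variants, region=region)


# ---------------------------------------------------------------------------
# phenotypes


def _draw_covariates(rng: np.random.Generator, n: int, nreg: int,
                     region: np.ndarray) -> pd.DataFrame:
    age = rng.uniform(30.0, 80.0, size=n)  # recruitment window 30-79 years
    sex = (rng.random(n) < 0.572).astype(float)  # 1 = female
    bmi = rng.normal(23.7, 3.5, size=n)
    # seasonal-uniform regional temperature, deliberately including values
    # below the 5 degC analysis floor
    base = rng.uniform(-2.0, 28.0, size=nreg)
    temperature = base[region] + rng.uniform(-8.0, 8.0, size=n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "bmi": bmi, "temperature": temperature}
    )


def simulate_bp(geno: GenotypeMatrix, cfg: SimConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate SBP/DBP with the configured genetic architecture.

    Per-variant (SBP, DBP) effects are drawn bivariate-normal with
    correlation ``rg_sbp_dbp`` and rescaled so the realised genetic variance
    equals h2 * sd^2 exactly in this sample. PP and MAP are derived exactly,
    both at the phenotype and at the effect level.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = geno.n_individuals
    cov = _draw_covariates(rng, n, cfg.n_regions, geno.region)

    causal_idx = np.sort(rng.choice(geno.n_variants, size=cfg.n_causal, replace=False))
    causal_ids = geno.variants["id"].iloc[causal_idx].tolist()
    corr = np.array([[1.0, cfg.rg_sbp_dbp], [cfg.rg_sbp_dbp, 1.0]])
    raw = rng.multivariate_normal(np.zeros(2), corr, size=cfg.n_causal,
                                  method="cholesky") if cfg.n_causal else np.zeros((0, 2))

    x_causal = geno.dosage[:, causal_idx].astype(np.float64)
    beta = {}
    genetic = {}
    for k, (trait, h2, sd) in enumerate(
        (("sbp", cfg.h2_sbp, cfg.sd_sbp), ("dbp", cfg.h2_dbp, cfg.sd_dbp))
    ):
        b = raw[:, k].copy()
        g = x_causal @ b if cfg.n_causal else np.zeros(n)
        var_g = float(np.var(g))
        target = h2 * sd * sd
        if var_g > 0 and target > 0:
            scale = math.sqrt(target / var_g)
        else:
            scale = 0.0
        beta[trait] = b * scale
        g = g * scale
        genetic[trait] = g - g.mean()  # centred so trait mean is mean_<trait>

    cov_effect = {}
    centers = {"age": 55.0, "sex": 0.572, "bmi": 23.7, "temperature": 13.0}
    for trait in ("sbp", "dbp"):
        eff = cfg.covar_effects.get(trait, {})
        contrib = np.zeros(n)
        for name, coef in eff.items():
            contrib += coef * (cov[name].to_numpy() - centers.get(name, 0.0))
        cov_effect[trait] = contrib

    # environmental residual: correlated bivariate normal filling the variance
    # budget sd^2 = h2*sd^2 + var(covariate part) + var(env)
    env = {}
    sds = {"sbp": cfg.sd_sbp, "dbp": cfg.sd_dbp}
    h2s = {"sbp": cfg.h2_sbp, "dbp": cfg.h2_dbp}
    e_sd = {}
    for trait in ("sbp", "dbp"):
        var_env = (1.0 - h2s[trait]) * sds[trait] ** 2 - float(np.var(cov_effect[trait]))
        if var_env <= 0:
            raise ConfigurationError(
                f"covariate effects leave no environmental variance for {trait}"
            )
        e_sd[trait] = math.sqrt(var_env)
    e_corr = np.array([[1.0, cfg.resid_corr], [cfg.resid_corr, 1.0]])
    e = rng.multivariate_normal(np.zeros(2), e_corr, size=n, method="cholesky")
    env["sbp"] = e[:, 0] * e_sd["sbp"]
    env["dbp"] = e[:, 1] * e_sd["dbp"]

    sbp = cfg.mean_sbp + genetic["sbp"] + cov_effect["sbp"] + env["sbp"]
    dbp = cfg.mean_dbp + genetic["dbp"] + cov_effect["dbp"] + env["dbp"]

    pheno = cov.copy()
    pheno.insert(0, "iid", [f"id{i:07d}" for i in range(n)])
    pheno["region"] = np.char.add("region", geno.region.astype(str))
    pheno["sbp_true"] = sbp
    pheno["dbp_true"] = dbp
    pheno["pp_true"] = derive_pp(sbp, dbp)
    pheno["map_true"] = derive_map(sbp, dbp)
    # observed (pre-medication) equals underlying at this stage
    pheno["sbp_raw"] = sbp.copy()
    pheno["dbp_raw"] = dbp.copy()
    pheno["medication"] = False

    beta_df = pd.DataFrame(
        {
            "sbp": beta["sbp"],
            "dbp": beta["dbp"],
            "pp": beta["sbp"] - beta["dbp"],
            "map": (2.0 * beta["dbp"] + beta["sbp"]) / 3.0,
        },
        index=pd.Index(causal_ids, name="variant"),
    )
    h2_realised = {
        "sbp": float(np.var(genetic["sbp"]) / np.var(sbp)) if np.var(sbp) else 0.0,
        "dbp": float(np.var(genetic["dbp"]) / np.var(dbp)) if np.var(dbp) else 0.0,
    }
    truth = SimulationTruth(
        causal_variant_ids=causal_ids, beta_true=beta_df, h2_realised=h2_realised
    )
    return pheno, truth


def assign_medication(pheno: pd.DataFrame, cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      truth: SimulationTruth | None = None) -> pd.DataFrame:
    """Assign BP-lowering medication to hypertensives and lower observed BP.

    Hypertension is SBP >= 140 mmHg or DBP >= 90 mmHg at baseline; among
    hypertensives the medication probability is ``treat_prob``. Treated
    individuals' observed (raw) SBP/DBP are reduced by ``treat_effect_*``;
    the underlying untreated values remain in the ``*_true`` columns.
    """
    for col in ("sbp_raw", "dbp_raw"):
        if col not in pheno.columns:
            raise DataError(f"missing BP column {col!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    out = pheno.copy()
    hyper = (out["sbp_raw"] >= HYPERTENSION_SBP) | (out["dbp_raw"] >= HYPERTENSION_DBP)
    treated = hyper.to_numpy() & (rng.random(len(out)) < cfg.treat_prob)
    out["medication"] = treated
    out.loc[treated, "sbp_raw"] -= cfg.treat_effect_sbp
    out.loc[treated, "dbp_raw"] -= cfg.treat_effect_dbp
    if truth is not None:
        truth.medication = treated
    return out


def _calibrate_intercept(linpred: np.ndarray, prev: float) -> float:
    """Bisection/Brent root-find of alpha with mean expit(alpha+lp) = prev."""

    def f(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + linpred))) - prev

    return float(optimize.brentq(f, -40.0, 40.0, xtol=1e-6))


def simulate_outcomes(pheno: pd.DataFrame, cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      truth: SimulationTruth | None = None) -> pd.DataFrame:
    """Draw binary CVD outcomes from logit(p) = alpha + sum_t theta_t BP_t/5.

    ``theta`` is given per 5 mmHg of the *underlying* (untreated) trait;
    alpha is calibrated by root-finding so the sample prevalence matches
    ``outcome_prev``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    for col in ("sbp_true", "dbp_true", "pp_true", "map_true"):
        if col not in pheno.columns:
            raise DataError(f"missing underlying trait column {col!r}")
    out = pheno.copy()
    for outcome, logors in cfg.outcome_logors.items():
        prev = cfg.outcome_prev[outcome]
        lp = np.zeros(len(out))
        for trait, theta in logors.items():
            lp += theta * out[f"{trait}_true"].to_numpy() / 5.0
        alpha = _calibrate_intercept(lp, prev)
        p = special.expit(alpha + lp)
        out[f"case_{outcome}"] = rng.random(len(out)) < p
        if truth is not None:
            truth.outcome_logors_true[outcome] = dict(logors)
            truth.outcome_intercepts[outcome] = alpha
    return out


def simulate_cohort(cfg: SimConfig
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Full simulation: genotypes, BP traits, medication, outcomes."""
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    pheno, truth = simulate_bp(geno, cfg, rng)
    pheno = assign_medication(pheno, cfg, rng, truth)
    pheno = simulate_outcomes(pheno, cfg, rng, truth)
    return geno, pheno, truth


# ---------------------------------------------------------------------------
# I/O


def write_vcf(geno: GenotypeMatrix, path: str, iids: Sequence[str] | None = None) -> None:
    """Write dosages as a sites+samples VCF with a DS FORMAT field."""
    if iids is None:
        iids = [f"id{i:07d}" for i in range(geno.n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(iids) + "\n")
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            ds = "\t".join(f"{d:.3f}" for d in geno.dosage[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tDS\t{ds}\n")


def read_vcf(path: str, region: np.ndarray | None = None) -> GenotypeMatrix:
    """Read additive dosages from a VCF with a DS FORMAT field (plain or
    bgzipped). ``region`` supplies per-individual labels (default: one
    region)."""
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows = []
    meta = []
    for rec in vf:
        ds = np.array([rec.samples[s].get("DS", 0.0) for s in samples],
                      dtype=np.float32)
        rows.append(ds)
        meta.append((rec.id or f"{rec.chrom}:{rec.pos}", str(rec.chrom),
                     int(rec.pos), rec.ref, rec.alts[0]))
    dosage = np.vstack(rows).T if rows else np.zeros((len(samples), 0), np.float32)
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    variants["eaf"] = dosage.mean(axis=0) / 2.0 if len(meta) else []
    if region is None:
        region = np.zeros(len(samples), dtype=int)
    return GenotypeMatrix(dosage=dosage, variants=variants, region=region)


def read_dosage_table(path: str, region: np.ndarray | None = None) -> GenotypeMatrix:
    """Read a delimited dosage matrix (rows: variants, columns: individuals)
    as written by :func:`write_dosage_table`. Variant metadata beyond the id
    is filled with placeholders."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy(dtype=np.float32).T
    m = dosage.shape[1]
    variants = pd.DataFrame({
        "id": df.index.astype(str), "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1, dtype=np.int64), "ref": ["A"] * m,
        "alt": ["G"] * m, "eaf": dosage.mean(axis=0) / 2.0,
    })
    if region is None:
        region = np.zeros(dosage.shape[0], dtype=int)
    return GenotypeMatrix(dosage=dosage, variants=variants, region=region)


def write_dosage_table(geno: GenotypeMatrix, path: str) -> None:
    """Delimited dosage matrix: one row per variant, columns id + individuals."""
    df = pd.DataFrame(geno.dosage.T, index=geno.variants["id"])
    df.columns = [f"id{i:07d}" for i in range(geno.n_individuals)]
    df.to_csv(path, sep="\t", float_format="%.3f")


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def write_truth(truth: SimulationTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
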