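"""End-to-end orchestration: simulate -> prep -> gwas -> clump -> score ->
mr -> mvmr (-> two-sample MR -> comparisons), with deterministic
per-stage sub-seeding, artifact manifests, and a summary report.

The module exposes both the declarative :func:`run_pipeline` entry point
driven by a :class:`RunConfig` (YAML-loadable) and the individual stage
functions, which operate on in-memory objects and are what the test suite
exercises directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assoc, compare, loci as loci_mod, mr as mr_mod, phenoprep, scores
from .cohortsim import (
    ConfigurationError,
    GenotypeMatrix,
    SimConfig,
    SimulationTruth,
    simulate_cohort,
    write_phenotypes,
    write_truth,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "prep", "gwas", "clump", "score", "mr", "mvmr",
                "mr2s", "compare")
DEFAULT_STAGES = ("simulate", "prep", "gwas", "clump", "score", "mr", "mvmr")

TRAIT_VALUE_COLS = {"sbp": "sbp_adj", "dbp": "dbp_adj", "pp": "pp", "map": "map"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from (seed, stage name)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Declarative pipeline configuration (mirrors stage defaults)."""

    stages: Sequence[str] = DEFAULT_STAGES
    sim: Mapping[str, Any] = field(default_factory=dict)
    adjust_bmi: bool = True
    gwas: Mapping[str, Any] = field(default_factory=dict)       # per_region: bool
    clump: Mapping[str, Any] = field(default_factory=dict)      # p_primary, ...
    score: Mapping[str, Any] = field(default_factory=dict)      # folds, unrelated_frac
    mvmr: Mapping[str, Any] = field(default_factory=lambda: {
        "pairs": [["sbp", "dbp"]], "rule": "lowest_p"})
    out_dir: str = "bpmr_run"
    seed: int = 0

    def validate(self) -> None:
        for st in self.stages:
            if st not in KNOWN_STAGES:
                raise ConfigurationError(f"unknown stage name {st!r}")
        if "prep" in self.stages and "simulate" not in self.stages:
            raise ConfigurationError("prep requires the simulate stage or input files")
        if self.mvmr.get("rule", "lowest_p") not in mr_mod.SELECTION_RULES:
            raise ConfigurationError("unknown MVMR selection rule")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# stage functions (in-memory)


def residual_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    """Residual columns keyed by trait name, aligned with the genotype rows."""
    return pd.DataFrame({t: pheno[f"resid_{t}"] for t in TRAIT_VALUE_COLS})


def gwas_stage(geno: GenotypeMatrix, pheno: pd.DataFrame,
               per_region: bool = False, model: str = "bmi_adj") -> pd.DataFrame:
    resid = residual_frame(pheno)
    if not per_region:
        return assoc.assoc_scan(geno, resid, model=model)
    labels = sorted(pd.unique(np.char.add("region", geno.region.astype(str))))
    per = [assoc.assoc_scan(geno, resid, region=lab, model=model) for lab in labels]
    return assoc.meta_scan(per)


def locus_stage(scan: pd.DataFrame, geno: GenotypeMatrix,
                **clump_kw) -> tuple[dict[str, list], list]:
    per_trait = {}
    for trait in scan["trait"].unique():
        per_trait[trait] = loci_mod.clump_loci(
            scan[scan["trait"] == trait].reset_index(drop=True), geno, **clump_kw)
    merged = loci_mod.merge_loci(per_trait)
    return per_trait, merged


def trait_sd(pheno: pd.DataFrame, trait: str) -> float:
    """SD of the (medication-adjusted) trait among analysed individuals."""
    vals = pheno.loc[pheno["excl_reason"].isna(), TRAIT_VALUE_COLS[trait]]
    return float(vals.std(ddof=1))


def score_stage(geno: GenotypeMatrix, pheno: pd.DataFrame, trait: str,
                sentinel_ids: Sequence[str], seed: int,
                unrelated_frac: float = 0.7, folds: int = 100,
                adjust_bmi: bool = True) -> scores.GeneticScore:
    """Jack-knifed score for one trait at the given sentinels, scaled to a
    genetically predicted trait, with overall strength diagnostics."""
    gs = scores.make_weights(geno, pheno[f"resid_{trait}"], list(sentinel_ids),
                             trait=trait, unrelated_frac=unrelated_frac,
                             folds=folds, seed=seed)
    gs = scores.compute_gs(geno, gs)
    covars = pheno[["age", "sex", "bmi", "region"]]
    gs = scores.scale_gs(pheno[TRAIT_VALUE_COLS[trait]].to_numpy(float), gs,
                         covars, adjust_bmi=adjust_bmi)
    gs.f_stat, gs.partial_r2 = scores.instrument_strength(
        pheno[TRAIT_VALUE_COLS[trait]].to_numpy(float), gs.values, covars,
        adjust_bmi=adjust_bmi)
    return gs


def regional_mean_f(pheno: pd.DataFrame, trait: str, gs: scores.GeneticScore,
                    second: scores.GeneticScore | None = None,
                    adjust_bmi: bool = True) -> float:
    """Mean (conditional) F statistic across recruitment regions."""
    fs = []
    for reg in sorted(pheno["region"].unique()):
        rows = (pheno["region"] == reg).to_numpy()
        covars = pheno.loc[rows, ["age", "sex", "bmi", "region"]].reset_index(drop=True)
        f, _ = scores.instrument_strength(
            pheno.loc[rows, TRAIT_VALUE_COLS[trait]].to_numpy(float),
            gs.values[rows], covars,
            second_score=None if second is None else second.values[rows],
            adjust_bmi=adjust_bmi)
        fs.append(f)
    return float(np.mean(fs))


def sentinels_for_trait(merged_loci: list, trait: str) -> list[str]:
    return [loc.sentinels[trait][0] for loc in merged_loci
            if trait in loc.sentinels]


def mr_stage(pheno: pd.DataFrame, gs: scores.GeneticScore, outcome: str,
             sd: float) -> mr_mod.MREstimate:
    est = mr_mod.onesample_mr(
        pheno[f"case_{outcome}"].to_numpy(bool), gs.predicted,
        pheno["age"].to_numpy(float), pheno["sex"].to_numpy(float),
        pheno["region"].to_numpy(), sd, exposure=gs.trait, outcome=outcome)
    est.f_stat = regional_mean_f(pheno, gs.trait, gs)
    est.partial_r2 = gs.partial_r2
    return est


def mvmr_stage(geno: GenotypeMatrix, pheno: pd.DataFrame, merged_loci: list,
               trait_a: str, trait_b: str, outcome: str, seed: int,
               rule: str = "lowest_p", unrelated_frac: float = 0.7,
               folds: int = 100, adjust_bmi: bool = True
               ) -> dict[str, mr_mod.MREstimate]:
    """Paired-instrument MVMR of two traits on one outcome.

    Both traits' scores are built at the identical paired variant set with
    the same seeded 70/30 split and fold assignment.
    """
    pair_loci = [loc for loc in merged_loci
                 if trait_a in loc.sentinels or trait_b in loc.sentinels]
    variants = mr_mod.build_paired_instrument(pair_loci, trait_a, trait_b, rule)
    gs = {}
    for t in (trait_a, trait_b):
        gs[t] = score_stage(geno, pheno, t, variants, seed,
                            unrelated_frac=unrelated_frac, folds=folds,
                            adjust_bmi=adjust_bmi)
    cond_f = {
        trait_a: regional_mean_f(pheno, trait_a, gs[trait_a], gs[trait_b],
                                 adjust_bmi=adjust_bmi),
        trait_b: regional_mean_f(pheno, trait_b, gs[trait_b], gs[trait_a],
                                 adjust_bmi=adjust_bmi),
    }
    return mr_mod.mvmr_onesample(
        pheno[f"case_{outcome}"].to_numpy(bool),
        gs[trait_a].predicted, gs[trait_b].predicted,
        pheno["age"].to_numpy(float), pheno["sex"].to_numpy(float),
        pheno["region"].to_numpy(), trait_sd(pheno, trait_a),
        trait_sd(pheno, trait_b), exposure_a=trait_a, exposure_b=trait_b,
        outcome=outcome, conditional_f=cond_f)


def outcome_summary_stats(geno: GenotypeMatrix, pheno: pd.DataFrame,
                          outcome: str, variant_ids: Sequence[str]
                          ) -> pd.DataFrame:
    """Per-variant logistic summary statistics for a binary outcome at the
    given variants (covariates: sex, age, age^2)."""
    import statsmodels.api as sm

    idx = geno.index_of(variant_ids)
    y = pheno[f"case_{outcome}"].to_numpy(float)
    age = pheno["age"].to_numpy(float)
    sex = pheno["sex"].to_numpy(float)
    base = np.column_stack([np.ones(len(y)), sex, age, age**2])
    rows = []
    meta = geno.variants.set_index("id")
    for vid, j in zip(variant_ids, idx):
        design = np.column_stack([base, geno.dosage[:, j].astype(float)])
        res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        v = meta.loc[vid]
        rows.append({"id": vid, "chrom": v["chrom"], "pos": v["pos"],
                     "ref": v["ref"], "alt": v["alt"], "eaf": v["eaf"],
                     "beta": float(res.params[-1]), "se": float(res.bse[-1])})
    return pd.DataFrame(rows)


def twosample_stage(scan: pd.DataFrame, outcome_stats: pd.DataFrame,
                    trait: str, variant_ids: Sequence[str]) -> dict[str, Any]:
    """Two-sample IVW and MR-Egger using the cohort's own summary statistics."""
    exp = scan[(scan["trait"] == trait) & scan["id"].isin(variant_ids)]
    exp = exp[["id", "ref", "alt", "beta", "se"]].rename(
        columns={"beta": "beta_x", "se": "se_x"})
    outc = outcome_stats[["id", "ref", "alt", "beta", "se"]].rename(
        columns={"beta": "beta_y", "se": "se_y"})
    inst = mr_mod.harmonise(exp, outc, exposure_name=trait)
    est, se, p = mr_mod.twosample_ivw(inst)
    result = {"ivw": {"estimate": est, "se": se, "p": p,
                      "n_variants": int(len(inst.data))}}
    if len(inst.data) >= 3:
        slope, slope_se, icpt, icpt_se, icpt_p = mr_mod.twosample_egger(inst)
        result["egger"] = {"slope": slope, "slope_se": slope_se,
                           "intercept": icpt, "intercept_se": icpt_se,
                           "intercept_p": icpt_p}
    return result


def compare_stage(geno: GenotypeMatrix, pheno: pd.DataFrame,
                  scan: pd.DataFrame, merged_loci: list, seed: int
                  ) -> dict[str, Any]:
    """Cross-trait Deming slopes at lead variants and a split-sample
    replication assessment (discovery in half the regions, replication in
    the other half)."""
    lead = [loc.sentinel[0] for loc in merged_loci]
    out: dict[str, Any] = {"deming": {}}
    sbp = scan[(scan["trait"] == "sbp") & scan["id"].isin(lead)].set_index("id")
    for other in ("dbp", "pp", "map"):
        oth = scan[(scan["trait"] == other) & scan["id"].isin(lead)].set_index("id")
        shared = sbp.index.intersection(oth.index)
        if len(shared) >= 2:
            fit = compare.deming_fit(oth.loc[shared, "beta"].to_numpy(),
                                     sbp.loc[shared, "beta"].to_numpy(),
                                     through_origin=True, seed=seed)
            out["deming"][f"sbp_vs_{other}"] = {
                "slope": fit.slope, "ci": list(fit.ci), "n": fit.n}

    labels = sorted(pd.unique(np.char.add("region", geno.region.astype(str))))
    half_a, half_b = labels[::2], labels[1::2]
    if half_a and half_b:
        resid = residual_frame(pheno)
        disc = assoc.assoc_scan(geno, resid, region=half_a)
        rep = assoc.assoc_scan(geno, resid, region=half_b)
        hits = disc[disc["p"] < loci_mod.P_GENOME_WIDE]
        if len(hits):
            rep_sub = rep[["id", "trait", "beta", "p"]]
            tab = compare.replication_assess(
                hits[["id", "trait", "beta", "p"]].rename(
                    columns={"beta": "beta_disc", "p": "p_disc"}),
                rep_sub.rename(columns={"beta": "beta_rep", "p": "p_rep"}))
            out["replication"] = tab.attrs["summary"]
    return out


# ---------------------------------------------------------------------------
# declarative runner


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order, writing artifacts, per-stage
    manifests, and a summary report under ``config.out_dir``."""
    config.validate()
    out_dir = pathlib.Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict[str, Any]] = []
    report: dict[str, Any] = {"seed": config.seed}

    state: dict[str, Any] = {}

    def record(stage: str, params: Mapping[str, Any], outputs: list[pathlib.Path]):
        manifest.append({
            "stage": stage,
            "seed": stage_seed(config.seed, stage),
            "params": {k: params[k] for k in sorted(params)},
            "outputs": {p.name: _sha256(p) for p in outputs},
        })

    for stage in config.stages:
        try:
            _run_stage(stage, config, state, report, out_dir, record)
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            (out_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float))
    return report


def _run_stage(stage, config, state, report, out_dir, record) -> None:
    seed = stage_seed(config.seed, stage)
    if stage == "simulate":
        sim_cfg = SimConfig(**{"seed": seed, **dict(config.sim)})
        geno, pheno, truth = simulate_cohort(sim_cfg)
        state.update(geno=geno, pheno_raw=pheno, truth=truth, sim_cfg=sim_cfg)
        p1 = out_dir / "phenotypes_raw.tsv"
        write_phenotypes(pheno, p1)
        p2 = out_dir / "truth.json"
        write_truth(truth, p2)
        report["n_individuals"] = geno.n_individuals
        report["n_variants"] = geno.n_variants
        record(stage, {"sim": dict(config.sim)}, [p1, p2])
    elif stage == "prep":
        pheno = phenoprep.prepare(state["pheno_raw"], adjust_bmi=config.adjust_bmi)
        state["pheno"] = pheno
        p = out_dir / "phenotypes_prepared.tsv"
        write_phenotypes(pheno, p)
        rep = phenoprep.exclusions_report(pheno)
        p2 = out_dir / "exclusions.tsv"
        rep.to_csv(p2, sep="\t", index=False)
        report["n_excluded"] = int(len(rep))
        record(stage, {"adjust_bmi": config.adjust_bmi}, [p, p2])
    elif stage == "gwas":
        scan = gwas_stage(state["geno"], state["pheno"],
                          per_region=config.gwas.get("per_region", False))
        state["scan"] = scan
        p = out_dir / "gwas_summary.tsv"
        assoc.write_gwas_ssf(scan, p)
        report["lambda_gc"] = {
            t: assoc.lambda_gc(scan.loc[scan["trait"] == t, "p"].to_numpy())
            for t in scan["trait"].unique()}
        record(stage, dict(config.gwas), [p])
    elif stage == "clump":
        per_trait, merged = locus_stage(state["scan"], state["geno"],
                                        **dict(config.clump))
        state["merged_loci"] = merged
        p = out_dir / "loci.bed"
        loci_mod.write_bed(merged, p)
        p2 = out_dir / "sentinels.tsv"
        loci_mod.write_sentinels(merged, p2)
        report["n_loci"] = len(merged)
        report["loci_per_trait"] = {t: len(l) for t, l in per_trait.items()}
        record(stage, dict(config.clump), [p, p2])
    elif stage == "score":
        gs_all = {}
        strength = {}
        for trait in TRAIT_VALUE_COLS:
            sent = sentinels_for_trait(state["merged_loci"], trait)
            if not sent:
                logger.warning("no sentinels for %s; score skipped", trait)
                continue
            gs = score_stage(state["geno"], state["pheno"], trait, sent, seed,
                             adjust_bmi=config.adjust_bmi,
                             **dict(config.score))
            gs_all[trait] = gs
            strength[trait] = {"f_stat": gs.f_stat, "partial_r2": gs.partial_r2,
                               "n_variants": len(gs.variant_ids)}
        state["scores"] = gs_all
        outs = []
        for trait, gs in gs_all.items():
            p = out_dir / f"score_{trait}.tsv"
            scores.write_scores(gs, p, iids=state["pheno"]["iid"])
            outs.append(p)
        report["scores"] = strength
        record(stage, dict(config.score), outs)
    elif stage == "mr":
        pheno = state["pheno"]
        outcomes = [c.removeprefix("case_") for c in pheno.columns
                    if c.startswith("case_")]
        ests = []
        for outcome in outcomes:
            for trait, gs in state["scores"].items():
                ests.append(mr_stage(pheno, gs, outcome, trait_sd(pheno, trait)))
        state["mr_estimates"] = ests
        p = out_dir / "mr_report.tsv"
        mr_mod.write_mr_report(ests, p)
        report["mr"] = [
            {"exposure": e.exposure, "outcome": e.outcome,
             "or_per_sd": e.or_per_sd, "ci_per_sd": list(e.ci_per_sd),
             "or_per_5mmhg": e.or_per_5mmhg, "f_stat": e.f_stat}
            for e in ests]
        record(stage, {}, [p])
    elif stage == "mvmr":
        pheno = state["pheno"]
        outcomes = [c.removeprefix("case_") for c in pheno.columns
                    if c.startswith("case_")]
        rule = config.mvmr.get("rule", "lowest_p")
        results = []
        for pair in config.mvmr.get("pairs", [["sbp", "dbp"]]):
            a, b = pair
            for outcome in outcomes:
                ests = mvmr_stage(state["geno"], pheno, state["merged_loci"],
                                  a, b, outcome, seed, rule=rule,
                                  adjust_bmi=config.adjust_bmi,
                                  **dict(config.score))
                results.extend(ests.values())
        state["mvmr_estimates"] = results
        p = out_dir / "mvmr_report.tsv"
        mr_mod.write_mr_report(results, p)
        report["mvmr"] = [
            {"exposure": e.exposure, "outcome": e.outcome,
             "or_per_sd": e.or_per_sd, "ci_per_sd": list(e.ci_per_sd),
             "conditional_f": e.conditional_f,
             "weak_instrument": e.weak_instrument}
            for e in results]
        record(stage, dict(config.mvmr), [p])
    elif stage == "mr2s":
        pheno = state["pheno"]
        geno = state["geno"]
        outcomes = [c.removeprefix("case_") for c in pheno.columns
                    if c.startswith("case_")]
        two = {}
        for outcome in outcomes:
            two[outcome] = {}
            for trait in state["scores"]:
                vids = state["scores"][trait].variant_ids
                ostats = outcome_summary_stats(geno, pheno, outcome, vids)
                two[outcome][trait] = twosample_stage(state["scan"], ostats,
                                                      trait, vids)
        report["two_sample"] = two
        record(stage, {}, [])
    elif stage == "compare":
        res = compare_stage(state["geno"], state["pheno"], state["scan"],
                            state["merged_loci"], seed)
        report["compare"] = res
        p = out_dir / "compare.json"
        p.write_text(json.dumps(res, indent=1, default=float))
        record(stage, {}, [p])
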