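"""Mendelian-randomisation estimators: one-sample recovery of simulator
truth, paired-instrument selection rules, OR rescaling against the printed
conversion, and two-sample IVW / Egger / MVMR against independent
weighted-least-squares oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from bpmr import (
    SummaryInstrument,
    build_paired_instrument,
    harmonise,
    mvmr_onesample,
    onesample_mr,
    rescale_or,
    twosample_egger,
    twosample_ivw,
    twosample_mvmr,
)
from bpmr.assoc import UsageError
from bpmr.loci import Locus
from bpmr.mr import EstimationError


class TestRescaleOR:
    def test_printed_per_sd_to_per_5mmhg_conversion(self):
        # OR 1.84 per 1 SD (22.3 mmHg) of SBP re-expressed per 5 mmHg
        assert rescale_or(1.84, 22.3, 5.0) == pytest.approx(1.15, abs=5e-3)

    def test_unit_or_is_fixed_point(self):
        assert rescale_or(1.0, 22.3, 5.0) == 1.0

    def test_round_trip_identity(self):
        once = rescale_or(1.84, 22.3, 5.0)
        back = rescale_or(once, 5.0, 22.3)
        assert back == pytest.approx(1.84, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(UsageError):
            rescale_or(0.0, 22.3, 5.0)


def simulate_onesample(n=100_000, theta_per5=np.log(1.15), seed=0, regions=4):
    """Exposure with a known per-5 mmHg causal log-OR on the outcome."""
    rng = np.random.default_rng(seed)
    predicted = rng.normal(0, 8.0, n)  # genetically predicted BP, mmHg
    resid_bp = rng.normal(0, 6.0, n)   # residual BP variation (kept modest)
    age = rng.uniform(30, 80, n)
    sex = (rng.random(n) < 0.5).astype(float)
    region = rng.integers(0, regions, n).astype(str)
    lp = -2.0 + theta_per5 / 5.0 * (predicted + resid_bp)
    case = rng.random(n) < expit(lp)
    return case, predicted, age, sex, region


class TestOneSampleMR:
    def test_recovers_simulated_log_or(self):
        theta = np.log(1.15)
        case, predicted, age, sex, region = simulate_onesample(theta_per5=theta)
        est = onesample_mr(case, predicted, age, sex, region, trait_sd=22.3)
        # slight attenuation from residual-BP non-collapsibility is within
        # sampling noise at this residual scale
        per5 = np.log(est.or_per_5mmhg)
        se5 = est.se_per_sd / 22.3 * 5
        assert abs(per5 - theta) < 3 * se5

    def test_single_region_meta_equals_single_fit(self):
        case, predicted, age, sex, _ = simulate_onesample(n=20_000, seed=1)
        region = np.array(["only"] * len(case))
        est = onesample_mr(case, predicted, age, sex, region, trait_sd=20.0)
        assert len(est.per_region) == 1
        assert est.logor_per_sd == pytest.approx(
            est.per_region[0]["beta_mmhg"] * 20.0, rel=1e-12)

    def test_meta_invariant_to_region_relabelling(self):
        case, predicted, age, sex, region = simulate_onesample(n=30_000, seed=2)
        est1 = onesample_mr(case, predicted, age, sex, region, trait_sd=20.0)
        relabel = {"0": "z", "1": "y", "2": "x", "3": "w"}
        region2 = np.array([relabel[r] for r in region])
        est2 = onesample_mr(case, predicted, age, sex, region2, trait_sd=20.0)
        assert est1.logor_per_sd == pytest.approx(est2.logor_per_sd, rel=1e-10)

    def test_per_sd_and_per_5mmhg_mutually_consistent(self):
        case, predicted, age, sex, region = simulate_onesample(n=20_000, seed=3)
        est = onesample_mr(case, predicted, age, sex, region, trait_sd=22.3)
        assert est.or_per_5mmhg == pytest.approx(
            rescale_or(est.or_per_sd, 22.3, 5.0), rel=1e-12)

    def test_null_exposure_covers_one(self):
        case, predicted, age, sex, region = simulate_onesample(
            n=30_000, theta_per5=0.0, seed=4)
        est = onesample_mr(case, predicted, age, sex, region, trait_sd=20.0)
        lo, hi = est.ci_per_sd
        assert lo < 1.0 < hi


class TestPairedInstrument:
    def locus(self, chrom, start, end, sents):
        return Locus(chrom, start, end, [v for v, _ in sents.values()],
                     sents, set(sents))

    def test_union_when_disjoint(self):
        loci = [self.locus("1", 1, 100, {"sbp": ("a", 1e-9)}),
                self.locus("1", 500, 600, {"dbp": ("b", 1e-10)})]
        assert build_paired_instrument(loci, "sbp", "dbp") == ["a", "b"]

    def test_lowest_p_rule(self):
        loci = [self.locus("1", 1, 100,
                           {"sbp": ("a", 1e-12), "dbp": ("b", 1e-9)})]
        assert build_paired_instrument(loci, "sbp", "dbp", "lowest_p") == ["a"]

    def test_prefer_b_rule(self):
        loci = [self.locus("1", 1, 100,
                           {"sbp": ("a", 1e-12), "dbp": ("b", 1e-9)})]
        assert build_paired_instrument(loci, "sbp", "dbp", "prefer_b") == ["b"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(UsageError):
            build_paired_instrument([], "sbp", "dbp", "bogus")


class TestMVMROneSample:
    def test_orthogonal_second_exposure_leaves_estimate_unchanged(self):
        # construct a second exposure orthogonal to the single-variable
        # score equations: the joint MLE is then (beta_sv, 0) exactly
        rng = np.random.default_rng(99)
        n = 20_000
        case, pred_a, age, sex, _ = simulate_onesample(n=n, seed=5)
        region = np.array(["r"] * n)
        design = np.column_stack([np.ones(n), pred_a, sex, age, age**2])
        fit = sm.Logit(case.astype(float), design).fit(disp=0)
        u = case - expit(design @ fit.params)
        v = rng.standard_normal(n)
        pred_b = v - (v @ u) / (u @ u) * u  # orthogonal to the score resid
        ests = mvmr_onesample(case, pred_a, pred_b, age, sex, region,
                              sd_a=20.0, sd_b=20.0, exposure_a="a",
                              exposure_b="b")
        sv = onesample_mr(case, pred_a, age, sex, region, trait_sd=20.0)
        assert ests["a"].logor_per_sd == pytest.approx(sv.logor_per_sd,
                                                       abs=1e-6)

    def test_duplicated_exposure_not_identifiable(self):
        case, pred, age, sex, region = simulate_onesample(n=5_000, seed=6)
        with pytest.raises(EstimationError):
            mvmr_onesample(case, pred, pred.copy(), age, sex, region,
                           sd_a=20.0, sd_b=20.0)

    def test_weak_instrument_flag_attached(self):
        case, pred_a, age, sex, region = simulate_onesample(n=10_000, seed=7)
        rng = np.random.default_rng(8)
        pred_b = pred_a + rng.normal(0, 0.5, len(pred_a))
        ests = mvmr_onesample(case, pred_a, pred_b, age, sex, region,
                              sd_a=20.0, sd_b=20.0, exposure_a="a",
                              exposure_b="b",
                              conditional_f={"a": 3.0, "b": 120.0})
        assert ests["a"].weak_instrument
        assert not ests["b"].weak_instrument


def make_instrument(bx, se_x, by, se_y, name="sbp"):
    df = pd.DataFrame({
        "id": [f"v{k}" for k in range(len(bx))],
        "ea": ["G"] * len(bx),
        f"beta_{name}": bx, f"se_{name}": se_x,
        "beta_outcome": by, "se_outcome": se_y,
    })
    return SummaryInstrument(df, [name])


class TestTwoSampleIVW:
    def test_single_variant_is_wald_ratio(self):
        inst = make_instrument([0.5], [0.05], [0.2], [0.04])
        est, _, _ = twosample_ivw(inst)
        assert est == pytest.approx(0.2 / 0.5, rel=1e-12)

    def test_equal_wald_ratios_returned_exactly(self, rng):
        bx = rng.uniform(0.2, 1.0, 8)
        inst = make_instrument(bx, bx * 0 + 0.05, 0.3 * bx,
                               rng.uniform(0.02, 0.1, 8))
        est, _, _ = twosample_ivw(inst)
        assert est == pytest.approx(0.3, rel=1e-10)

    def test_matches_wls_through_origin_oracle(self, rng):
        bx = rng.normal(0, 0.5, 10)
        by = 0.4 * bx + rng.normal(0, 0.05, 10)
        se_y = rng.uniform(0.02, 0.1, 10)
        inst = make_instrument(bx, np.full(10, 0.05), by, se_y)
        est, se, _ = twosample_ivw(inst)
        oracle = sm.WLS(by, bx[:, None], weights=se_y**-2).fit()
        assert est == pytest.approx(float(oracle.params[0]), rel=1e-10)


class TestTwoSampleEgger:
    def test_directional_pleiotropy_recovered(self, rng):
        m, c, slope = 100, 0.08, 0.4
        bx = rng.uniform(0.1, 1.0, m)
        se_y = np.full(m, 0.05)
        by = c + slope * bx + rng.normal(0, 0.05, m)
        inst = make_instrument(bx, np.full(m, 0.02), by, se_y)
        sl, sl_se, icpt, icpt_se, icpt_p = twosample_egger(inst)
        assert abs(icpt - c) < 3 * icpt_se
        assert abs(sl - slope) < 3 * sl_se
        assert icpt_p < 0.05

    def test_null_intercept_not_flagged(self, rng):
        m = 50
        bx = rng.uniform(0.1, 1.0, m)
        by = 0.4 * bx + rng.normal(0, 0.05, m)
        inst = make_instrument(bx, np.full(m, 0.02), by, np.full(m, 0.05))
        *_, icpt_p = twosample_egger(inst)
        assert icpt_p > 0.001

    def test_degenerate_design_rejected(self):
        inst = make_instrument([0.5, 0.5, 0.5], [0.1] * 3, [0.1, 0.2, 0.3],
                               [0.05] * 3)
        with pytest.raises(EstimationError):
            twosample_egger(inst)

    def test_too_few_variants_rejected(self):
        inst = make_instrument([0.5, 0.6], [0.1] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(UsageError):
            twosample_egger(inst)


def make_mvmr_instrument(ba, bb, by, se_y, se_a=None, se_b=None):
    m = len(ba)
    df = pd.DataFrame({
        "id": [f"v{k}" for k in range(m)], "ea": ["G"] * m,
        "beta_sbp": ba, "se_sbp": se_a if se_a is not None else np.full(m, 0.05),
        "beta_dbp": bb, "se_dbp": se_b if se_b is not None else np.full(m, 0.05),
        "beta_outcome": by, "se_outcome": se_y,
    })
    return SummaryInstrument(df, ["sbp", "dbp"])


class TestTwoSampleMVMR:
    def test_zero_second_exposure_reduces_to_ivw(self, rng):
        m = 12
        ba = rng.normal(0, 0.5, m)
        by = 0.3 * ba + rng.normal(0, 0.03, m)
        se_y = rng.uniform(0.02, 0.08, m)
        res = twosample_mvmr(make_mvmr_instrument(ba, np.zeros(m), by, se_y))
        single = make_instrument(ba, np.full(m, 0.05), by, se_y)
        ivw, _, _ = twosample_ivw(single)
        assert res["sbp"]["estimate"] == pytest.approx(ivw, rel=1e-8)

    def test_second_trait_null_covered(self, rng):
        m = 40
        ba = rng.normal(0, 0.5, m)
        bb = 0.3 * ba + rng.normal(0, 0.4, m)  # correlated but distinct
        by = 0.5 * ba + rng.normal(0, 0.04, m)
        se_y = np.full(m, 0.04)
        res = twosample_mvmr(make_mvmr_instrument(ba, bb, by, se_y))
        est_b = res["dbp"]
        assert abs(est_b["estimate"]) < 3 * est_b["se"]
        assert abs(res["sbp"]["estimate"] - 0.5) < 3.5 * res["sbp"]["se"]

    def test_proportional_exposures_suppressed(self, rng):
        m = 10
        ba = rng.normal(0, 0.5, m)
        with pytest.raises(EstimationError):
            twosample_mvmr(make_mvmr_instrument(ba, 2.0 * ba,
                                                0.3 * ba, np.full(m, 0.05)))

    def test_conditional_f_low_for_nearly_proportional(self, rng):
        m = 30
        ba = rng.normal(0, 0.5, m)
        bb = ba * 1.5 + rng.normal(0, 0.01, m)
        by = 0.3 * ba + rng.normal(0, 0.05, m)
        res = twosample_mvmr(make_mvmr_instrument(ba, bb, by, np.full(m, 0.05)))
        assert res["sbp"]["weak_instrument"]
        assert res["dbp"]["weak_instrument"]


class TestHarmonise:
    def frame(self, ids, ref, alt, beta):
        return pd.DataFrame({"id": ids, "ref": ref, "alt": alt,
                             "beta": beta, "se": [0.1] * len(ids)})

    def test_swapped_alleles_flip_outcome_sign(self):
        exp = self.frame(["v1"], ["A"], ["G"], [0.5])
        out = self.frame(["v1"], ["G"], ["A"], [0.2])
        inst = harmonise(exp, out)
        assert inst.data["beta_outcome"].iloc[0] == pytest.approx(-0.2)

    def test_palindromic_dropped(self):
        exp = self.frame(["v1", "v2"], ["A", "C"], ["T", "G"], [0.5, 0.4])
        out = self.frame(["v1", "v2"], ["A", "C"], ["T", "G"], [0.2, 0.1])
        inst = harmonise(exp, out)
        assert list(inst.data["id"]) == []  # both palindromic

    def test_matching_alleles_pass_through(self):
        exp = self.frame(["v1"], ["A"], ["G"], [0.5])
        out = self.frame(["v1"], ["A"], ["G"], [0.2])
        inst = harmonise(exp, out)
        assert inst.data["beta_outcome"].iloc[0] == pytest.approx(0.2)
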