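import numpy as np
import pytest

from bpmr import SimConfig, prepare, simulate_cohort
from bpmr.pipeline import gwas_stage, locus_stage


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but non-trivial cohort: enough signal for loci to form."""
    return SimConfig(n_individuals=6000, n_variants=600, n_regions=4,
                     n_causal=20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    geno, pheno, truth = simulate_cohort(small_cfg)
    return geno, pheno, truth


@pytest.fixture(scope="session")
def prepared(small_cohort):
    geno, pheno, truth = small_cohort
    return geno, prepare(pheno), truth


@pytest.fixture(scope="session")
def scanned(prepared):
    geno, pheno, truth = prepared
    scan = gwas_stage(geno, pheno)
    return geno, pheno, truth, scan


@pytest.fixture(scope="session")
def with_loci(scanned):
    geno, pheno, truth, scan = scanned
    per_trait, merged = locus_stage(scan, geno)
    return geno, pheno, truth, scan, per_trait, merged


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
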