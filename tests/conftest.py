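import numpy as np
import pandas as pd
import pytest

from snpset_generalist.io import GenotypeMatrix, PhenotypeTable, SnpInfo
from snpset_generalist.simcohort import (MissingnessSpec, SimulationSpec,
                                         TraitSpec, simulate_cohort,
                                         simulate_genotypes)


def make_snp(snp_id="rs1", chrom="1", pos=100, alleles=("A", "G"),
             increaser=None, plex="plex26") -> SnpInfo:
    a, b = alleles
    return SnpInfo(snp_id=snp_id, chrom=chrom, pos=pos, allele_a=a,
                   allele_b=b, increaser_allele=increaser or b, plex=plex)


@pytest.fixture
def two_snp_panel():
    return [make_snp("rs1", "1", 100, ("A", "G")),
            make_snp("rs2", "2", 200, ("C", "T"), plex="plex33")]


@pytest.fixture
def tiny_gm(two_snp_panel):
    """3 individuals x 2 SNPs with one missing call."""
    calls = np.array([["AG", "CT"],
                      ["GG", "NN"],
                      ["AA", "TT"]], dtype="<U2")
    return GenotypeMatrix(["i1", "i2", "i3"], two_snp_panel, calls)


@pytest.fixture(scope="session")
def simulated_gm():
    """50 x 10 complete simulated matrix for round-trip checks."""
    rng = np.random.default_rng(42)
    return simulate_genotypes(rng.uniform(0.1, 0.5, 10), 50, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """A clean cohort (no missingness, no covariate effects) shared across
    tests that only need realistic joint structure."""
    spec = SimulationSpec(
        n_individuals=600, n_snps=12, target_r=0.3,
        trait_specs=[TraitSpec("focal", 1.0), TraitSpec("half", 0.5),
                     TraitSpec("null", 0.0)],
        sex_effect=0.0, age_slope=0.0, missingness=MissingnessSpec(), seed=7)
    return simulate_cohort(spec)


@pytest.fixture
def pheno_table():
    rng = np.random.default_rng(3)
    n = 200
    df = pd.DataFrame(
        {"sex": rng.integers(0, 2, n),
         "age_m1": rng.uniform(9.5, 10.5, n),
         "m1": rng.standard_normal(n),
         "m2": rng.standard_normal(n)},
        index=pd.Index([f"p{i}" for i in range(n)], name="individual_id"))
    df.loc[df.index[:10], "m2"] = np.nan
    return PhenotypeTable(df)
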