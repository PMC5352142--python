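import numpy as np
import pandas as pd
import pytest

from pairedqtl import mapping, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample cohort with two shared cis effects and one A-only effect."""
    arch = simulate.EqtlArchitecture(
        n_samples=300,
        n_snps=100,
        n_probes=20,
        seed=42,
        maf_range=(0.2, 0.5),  # keeps every injected effect comfortably detectable
        cis_effects=((5, 1, 1.0, 1.0), (40, 8, 0.9, 0.9), (70, 14, 0.8, 0.0)),
    )
    return simulate.simulate_cohort(arch)


@pytest.fixture(scope="session")
def residualized(small_cohort):
    eA = mapping.residualize(small_cohort.expression_cellA, small_cohort.covariates)
    eB = mapping.residualize(small_cohort.expression_cellB, small_cohort.covariates)
    return eA, eB


@pytest.fixture(scope="session")
def mediation_study():
    """The full replicated mediation simulation at its default settings."""
    from pairedqtl.mediation import run_mediation_study

    return run_mediation_study(simulate.MediationSimConfig(seed=7))


def make_genotypes(dosages: np.ndarray, chrom="chr1", positions=None) -> "simulate.GenotypeMatrix":
    """Small handmade genotype matrix for unit tests."""
    from pairedqtl.matrices import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = pd.Index([f"S{i}" for i in range(n)], name="sample")
    snps = pd.Index([f"v{j}" for j in range(m)], name="snp")
    if positions is None:
        positions = 1000 * (1 + np.arange(m))
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "coded_allele": "A", "other_allele": "G"},
        index=snps,
    )
    return GenotypeMatrix(dosages=pd.DataFrame(dosages, index=samples, columns=snps), snp_meta=meta)


def make_expression(values: np.ndarray, chrom="chr1", midpoints=None) -> "simulate.ExpressionMatrix":
    from pairedqtl.matrices import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = pd.Index([f"S{i}" for i in range(n)], name="sample")
    probes = pd.Index([f"pr{j}" for j in range(m)], name="probe")
    if midpoints is None:
        midpoints = 1500 * (1 + np.arange(m))
    meta = pd.DataFrame(
        {"chrom": chrom, "midpoint": midpoints, "gene": [f"G{j}" for j in range(m)]},
        index=probes,
    )
    return ExpressionMatrix(values=pd.DataFrame(values, index=samples, columns=probes), probe_meta=meta)
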