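"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the paired T-cell eQTL analysis assumes:
Hardy-Weinberg genotypes at configurable MAF on a single synthetic
chromosome (one SNP per kb), paired two-cell-type expression with shared or
cell-specific cis effects plus an optional trans-hub locus, methylation
anti-correlated with the genetic component of expression, small additive
sex/age/batch covariate effects, and the SNP -> gene1 -> gene2 mediation
triplet used in the simulation study of the IL27-IRF1-STAT1 axis.

Randomness: one root seed per cohort; per-stream child generators are
derived deterministically via ``numpy.random.SeedSequence.spawn`` in a
fixed order (genotypes, individual intercepts, expression noise A,
expression noise B, methylation, covariates), so identical seed + config
gives byte-identical output and stages can be re-drawn independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "MediationSimConfig",
    "EqtlArchitecture",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_mediation",
    "write_cohort",
]

SNP_SPACING_BP = 1000  # synthetic chromosome: one SNP every kb


@dataclass(frozen=True)
class MediationSimConfig:
    """Settings of the SNP -> gene1 -> gene2 mediation simulation.

    Defaults are the printed study settings: 1000 replicates of n = 1000,
    genotype = sum of two Bernoulli(0.37) draws, gene1 = 0.903 - 1.237*snp
    + N(0,1), gene2 = 0.031 - 0.534*gene1 + N(0,1).  The gene1 -> gene2
    slope sign is a config field (the source prints both signs; magnitude
    is what the downstream analysis uses).
    """

    n_samples: int = 1000
    n_replicates: int = 1000
    allele_prob: float = 0.37
    intercept_g1: float = 0.903
    beta_snp_g1: float = -1.237
    intercept_g2: float = 0.031
    beta_g1_g2: float = -0.534
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_prob < 1.0:
            raise ValueError("allele_prob must be in (0, 1)")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class EqtlArchitecture:
    """Ground-truth genetic architecture of a paired-cell-type cohort.

    ``cis_effects`` entries are (snp_index, probe_index, beta_cellA,
    beta_cellB); ``trans_hub`` is (snp_index, [(probe_index, beta_cellA,
    beta_cellB), ...]) for a locus driving many distal probes.
    """

    n_samples: int = 200
    n_snps: int = 500
    n_probes: int = 50
    maf_range: tuple = (0.05, 0.5)
    cis_effects: tuple = ()
    trans_hub: Optional[tuple] = None
    residual_sd: float = 1.0
    shared_individual_sd: float = 0.5
    covariate_effect_sd: float = 0.1
    methylation_pairs: tuple = ()  # (probe_index, slope [negative], noise_sd)
    # probes listed here anchor on a second chromosome, so trans pairs
    # (different chromosome) exist at toy scale; SNPs all stay on chr1
    distal_probe_indices: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.shared_individual_sd < 0:
            raise ValueError("shared_individual_sd must be >= 0")
        seen = set()
        for snp_i, probe_i, _, _ in self.cis_effects:
            if not (0 <= snp_i < self.n_snps and 0 <= probe_i < self.n_probes):
                raise ValueError(f"effect index out of bounds: ({snp_i}, {probe_i})")
            if (snp_i, probe_i) in seen:
                raise ValueError(f"duplicate effect entry ({snp_i}, {probe_i})")
            seen.add((snp_i, probe_i))
        if self.trans_hub is not None:
            hub_snp, targets = self.trans_hub
            if not 0 <= hub_snp < self.n_snps:
                raise ValueError("trans hub SNP index out of bounds")
            for probe_i, _, _ in targets:
                if not 0 <= probe_i < self.n_probes:
                    raise ValueError("trans hub probe index out of bounds")
                if (hub_snp, probe_i) in seen:
                    raise ValueError(
                        f"duplicate effect entry ({hub_snp}, {probe_i})"
                    )
                seen.add((hub_snp, probe_i))


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    expression_cellA: ExpressionMatrix
    expression_cellB: ExpressionMatrix
    covariates: pd.DataFrame
    truth: EqtlArchitecture
    methylation: Optional[pd.DataFrame] = None
    methylation_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = self.genotypes.samples
        for mat in (self.expression_cellA, self.expression_cellB):
            if not ids.equals(mat.samples):
                raise ValueError("sample ids differ across matrices")
        if not ids.equals(self.covariates.index):
            raise ValueError("sample ids differ between genotypes and covariates")


def _snp_positions(n_snps: int) -> np.ndarray:
    return SNP_SPACING_BP * (1 + np.arange(n_snps))


def simulate_genotypes(
    n_samples: int, mafs: Sequence[float], seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages: SNP j is the sum of two Bernoulli(maf_j).

    SNPs are placed every kb on one synthetic chromosome ("chr1"); the
    coded allele is the minor allele by construction.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or mafs.size == 0:
        raise ValueError("mafs must be a non-empty 1-d sequence")
    if (mafs <= 0).any() or (mafs > 0.5).any():
        raise ValueError("each maf must lie in (0, 0.5]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.random((2, n_samples, mafs.size)) < mafs
    dosage = draws.sum(axis=0).astype(float)
    samples = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample")
    snp_ids = pd.Index([f"snp{j:05d}" for j in range(mafs.size)], name="snp")
    meta = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": _snp_positions(mafs.size),
            "coded_allele": "A",
            "other_allele": "G",
        },
        index=snp_ids,
    )
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosage, index=samples, columns=snp_ids),
        snp_meta=meta,
    )


def _probe_meta(
    n_probes: int, n_snps: int, distal: Sequence[int] = ()
) -> pd.DataFrame:
    # probe midpoints interleaved between SNPs so cis windows are meaningful
    span = SNP_SPACING_BP * (n_snps + 1)
    mids = np.linspace(SNP_SPACING_BP // 2, span, n_probes, dtype=int)
    ids = pd.Index([f"probe{k:04d}" for k in range(n_probes)], name="probe")
    chroms = np.array(["chr1"] * n_probes, dtype=object)
    chroms[list(distal)] = "chr2"
    return pd.DataFrame(
        {"chrom": chroms, "midpoint": mids, "gene": [f"GENE{k}" for k in range(n_probes)]},
        index=ids,
    )


def simulate_cohort(arch: EqtlArchitecture) -> SyntheticCohort:
    """Generate a paired two-cell-type cohort from a truth architecture.

    Expression of probe k in cell type c is the sum of its genetic effects
    (beta * dosage), a per-individual random intercept shared between the
    two cell types, small additive covariate effects, and Gaussian noise.
    Methylation for coupled CpGs is a negative-slope transform of the
    probe's genetic component plus noise.
    """
    root = np.random.SeedSequence(arch.seed)
    (ss_maf, ss_geno, ss_indiv, ss_noiseA, ss_noiseB, ss_meth, ss_cov) = root.spawn(7)
    rng_geno = np.random.default_rng(ss_geno)
    mafs = np.random.default_rng(ss_maf).uniform(
        arch.maf_range[0], arch.maf_range[1], arch.n_snps
    )
    geno = simulate_genotypes(arch.n_samples, mafs, rng_geno)
    dos = geno.dosages.to_numpy()

    effects = list(arch.cis_effects)
    if arch.trans_hub is not None:
        hub_snp, targets = arch.trans_hub
        effects += [(hub_snp, p, bA, bB) for p, bA, bB in targets]
    genetic = {
        "A": np.zeros((arch.n_samples, arch.n_probes)),
        "B": np.zeros((arch.n_samples, arch.n_probes)),
    }
    for snp_i, probe_i, bA, bB in effects:
        genetic["A"][:, probe_i] += bA * dos[:, snp_i]
        genetic["B"][:, probe_i] += bB * dos[:, snp_i]

    indiv = np.random.default_rng(ss_indiv).normal(
        0.0, arch.shared_individual_sd, (arch.n_samples, arch.n_probes)
    )
    rng_cov = np.random.default_rng(ss_cov)
    covariates = pd.DataFrame(
        {
            "sex": rng_cov.integers(0, 2, arch.n_samples),
            "age": rng_cov.uniform(20, 80, arch.n_samples),
            "batch_chip": rng_cov.integers(0, 4, arch.n_samples),
            "batch_position": rng_cov.integers(0, 12, arch.n_samples),
        },
        index=geno.samples,
    )
    cov_loadings = rng_cov.normal(
        0.0, arch.covariate_effect_sd, (4, arch.n_probes)
    )
    cov_design = np.column_stack(
        [
            covariates["sex"].to_numpy(float),
            (covariates["age"].to_numpy(float) - 50.0) / 20.0,
            covariates["batch_chip"].to_numpy(float),
            covariates["batch_position"].to_numpy(float) / 12.0,
        ]
    )
    cov_term = cov_design @ cov_loadings

    probe_meta = _probe_meta(arch.n_probes, arch.n_snps, arch.distal_probe_indices)
    expr = {}
    for cell, ss_noise in (("A", ss_noiseA), ("B", ss_noiseB)):
        noise = np.random.default_rng(ss_noise).normal(
            0.0, arch.residual_sd, (arch.n_samples, arch.n_probes)
        )
        expr[cell] = ExpressionMatrix(
            values=pd.DataFrame(
                genetic[cell] + indiv + cov_term + noise,
                index=geno.samples,
                columns=probe_meta.index,
            ),
            probe_meta=probe_meta,
        )

    methylation = None
    meth_meta = None
    if arch.methylation_pairs:
        rng_meth = np.random.default_rng(ss_meth)
        cols, meta_rows = [], []
        vals = np.empty((arch.n_samples, len(arch.methylation_pairs)))
        for j, (probe_i, slope, noise_sd) in enumerate(arch.methylation_pairs):
            if slope >= 0:
                raise ValueError("methylation coupling slopes must be negative")
            vals[:, j] = slope * genetic["A"][:, probe_i] + rng_meth.normal(
                0.0, noise_sd, arch.n_samples
            )
            cols.append(f"cg{j:04d}")
            meta_rows.append(
                {
                    "chrom": "chr1",
                    "pos": int(probe_meta["midpoint"].iloc[probe_i]) + 100,
                    "probe": probe_meta.index[probe_i],
                }
            )
        methylation = pd.DataFrame(vals, index=geno.samples, columns=cols)
        meth_meta = pd.DataFrame(meta_rows, index=cols)

    return SyntheticCohort(
        genotypes=geno,
        expression_cellA=expr["A"],
        expression_cellB=expr["B"],
        covariates=covariates,
        truth=arch,
        methylation=methylation,
        methylation_meta=meth_meta,
    )


def simulate_mediation(config: MediationSimConfig) -> pd.DataFrame:
    """Draw the mediation-triplet replicates as one long table.

    Returns a DataFrame with columns (replicate, snp, g1, g2):
    snp = Bernoulli(p) + Bernoulli(p); g1 = a0 + a1*snp + noise;
    g2 = b0 + b1*g1 + noise.  Replicates are independent given the seed.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_replicates, config.n_samples)
    snp = (
        (rng.random(shape) < config.allele_prob).astype(float)
        + (rng.random(shape) < config.allele_prob)
    )
    g1 = (
        config.intercept_g1
        + config.beta_snp_g1 * snp
        + rng.normal(0.0, config.noise_sd, shape)
    )
    g2 = (
        config.intercept_g2
        + config.beta_g1_g2 * g1
        + rng.normal(0.0, config.noise_sd, shape)
    )
    rep = np.repeat(np.arange(config.n_replicates), config.n_samples)
    return pd.DataFrame(
        {
            "replicate": rep,
            "snp": snp.ravel(),
            "g1": g1.ravel(),
            "g2": g2.ravel(),
        }
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write cohort matrices as TSV (sample ids in the first column).

    Returns a dict of the paths written.  The truth table lists every
    injected effect as (snp, probe, beta_cellA, beta_cellB, kind).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(df: pd.DataFrame, name: str, index_label: str = "sample"):
        p = outdir / name
        df.to_csv(p, sep="\t", index_label=index_label, na_rep=".")
        paths[name] = p

    _write(cohort.genotypes.dosages, "genotypes.tsv")
    _write(cohort.genotypes.snp_meta, "snp_annotation.tsv", index_label="snp")
    _write(cohort.expression_cellA.values, "expression_cellA.tsv")
    _write(cohort.expression_cellB.values, "expression_cellB.tsv")
    _write(
        cohort.expression_cellA.probe_meta, "probe_annotation.tsv", index_label="probe"
    )
    _write(cohort.covariates, "covariates.tsv")
    if cohort.methylation is not None:
        _write(cohort.methylation, "methylation.tsv")
        _write(cohort.methylation_meta, "cpg_annotation.tsv", index_label="cpg")

    arch = cohort.truth
    rows = [
        {
            "snp": cohort.genotypes.snp_ids[s],
            "probe": cohort.expression_cellA.probe_ids[p],
            "beta_cellA": bA,
            "beta_cellB": bB,
            "kind": "cis",
        }
        for s, p, bA, bB in arch.cis_effects
    ]
    if arch.trans_hub is not None:
        hub, targets = arch.trans_hub
        rows += [
            {
                "snp": cohort.genotypes.snp_ids[hub],
                "probe": cohort.expression_cellA.probe_ids[p],
                "beta_cellA": bA,
                "beta_cellB": bB,
                "kind": "trans",
            }
            for p, bA, bB in targets
        ]
    truth = pd.DataFrame(rows, columns=["snp", "probe", "beta_cellA", "beta_cellB", "kind"])
    tp = outdir / "truth.tsv"
    truth.to_csv(tp, sep="\t", index=False)
    paths["truth.tsv"] = tp
    return paths
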