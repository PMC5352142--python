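"""Core in-memory containers: genotype dosages and expression values.

Both containers wrap a samples-by-features :class:`pandas.DataFrame` plus a
feature-metadata frame, and validate their invariants on construction.
Coordinates are 1-based throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "ExpressionMatrix"]


@dataclass
class GenotypeMatrix:
    """Sample-by-SNP coded-allele dosages in [0, 2], NaN for missing calls.

    ``snp_meta`` is indexed by SNP id with columns ``chrom``, ``pos``
    (1-based), ``coded_allele`` and ``other_allele``.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.is_unique:
            dupes = self.dosages.columns[self.dosages.columns.duplicated()]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dupes))}")
        if not self.dosages.index.is_unique:
            raise ValueError("duplicate sample ids in genotype matrix")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2] (or be missing)")
        missing = set(self.dosages.columns) - set(self.snp_meta.index)
        if missing:
            raise ValueError(f"SNPs without metadata: {sorted(missing)[:5]}")
        self.snp_meta = self.snp_meta.loc[self.dosages.columns]
        pos = self.snp_meta["pos"]
        if (pos <= 0).any() or not np.allclose(pos, pos.astype(int)):
            raise ValueError("SNP positions must be positive integers")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    @property
    def n_snps(self) -> int:
        return len(self.dosages.columns)

    def maf(self) -> pd.Series:
        """Allele frequency of the coded allele folded to [0, 0.5].

        Estimated as mean dosage / 2 over non-missing samples.
        """
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(
            dosages=self.dosages[snp_ids], snp_meta=self.snp_meta.loc[snp_ids]
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[list(sample_ids)], snp_meta=self.snp_meta
        )


@dataclass
class ExpressionMatrix:
    """Sample-by-probe expression values with probe genomic anchors.

    ``probe_meta`` is indexed by probe id with columns ``chrom``,
    ``midpoint`` (1-based probe midpoint) and ``gene``.
    """

    values: pd.DataFrame
    probe_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate probe ids: {sorted(set(dupes))}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = set(self.values.columns) - set(self.probe_meta.index)
        if missing:
            raise ValueError(f"probes without metadata: {sorted(missing)[:5]}")
        self.probe_meta = self.probe_meta.loc[self.values.columns]

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    @property
    def n_probes(self) -> int:
        return len(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(sample_ids)], probe_meta=self.probe_meta
        )
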