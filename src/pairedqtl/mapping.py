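"""SNP QC, normalization, and cis/trans Spearman eQTL scans.

The association scan follows the classical array-eQTL recipe: rank-based
(Spearman) correlation between coded-allele dosage and residualized
expression, cis pairs defined by probe midpoint within 1 Mb of the SNP
(inclusive), trans pairs by > 5 Mb separation or different chromosomes,
multiple testing controlled by a probe-level permutation FDR, and cis
effects regressed out of expression before the trans scan.

Scan results are returned as a DataFrame whose rows are
:class:`EqtlRecord` fields (``snp_id, probe_id, n_used, rho, p_nominal,
q_value, scope``).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "FilterThresholds",
    "EqtlRecord",
    "SnpFilterResult",
    "NoSnpsRetainedError",
    "filter_snps",
    "hwe_pvalue",
    "quantile_normalize_log2",
    "residualize",
    "map_cis",
    "map_trans",
    "correct_cis_effects",
    "probe_level_fdr",
    "pairwise_r2",
    "spearman_exact_p",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["snp_id", "probe_id", "n_used", "rho", "p_nominal", "q_value", "scope"]


class EqtlRecord(NamedTuple):
    """One SNP-probe association test."""

    snp_id: str
    probe_id: str
    n_used: int
    rho: float
    p_nominal: float
    q_value: float
    scope: str


@dataclass(frozen=True)
class FilterThresholds:
    """SNP inclusion thresholds: MAF > 0.05, call rate > 0.95, HWE p > 0.001."""

    min_maf: float = 0.05
    min_call_rate: float = 0.95
    min_hwe_p: float = 0.001

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SnpFilterResult:
    genotypes: GenotypeMatrix
    log: pd.DataFrame  # columns: snp_id, status, reason


class NoSnpsRetainedError(RuntimeError):
    """Raised when every SNP fails QC — an empty scan would be meaningless."""


def hwe_pvalue(dosages: np.ndarray) -> float:
    """1-df chi-square Hardy-Weinberg test on dosages rounded to hard calls."""
    d = dosages[~np.isnan(dosages)]
    if d.size == 0:
        return np.nan
    calls = np.clip(np.rint(d), 0, 2).astype(int)
    n = calls.size
    counts = np.bincount(calls, minlength=3)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: HWE trivially satisfied
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


# imputed dosages far from hard calls make the chi-square HWE test
# ill-defined; such SNPs skip the HWE filter (logged)
_HWE_SOFT_FRACTION = 0.05
_HWE_SOFT_DISTANCE = 0.1


def filter_snps(g: GenotypeMatrix, t: FilterThresholds = FilterThresholds()) -> SnpFilterResult:
    """Apply MAF / call-rate / HWE filters; log the per-SNP decision.

    Raises :class:`NoSnpsRetainedError` when nothing survives.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf().to_numpy()
    call = g.call_rate().to_numpy()
    rows = []
    keep = []
    for j, snp in enumerate(g.snp_ids):
        if not maf[j] > t.min_maf:
            rows.append((snp, "removed", "maf"))
            continue
        if not call[j] > t.min_call_rate:
            rows.append((snp, "removed", "call_rate"))
            continue
        d = g.dosages.iloc[:, j].to_numpy(dtype=float)
        dd = d[~np.isnan(d)]
        soft = np.abs(dd - np.rint(dd)) > _HWE_SOFT_DISTANCE
        if soft.mean() > _HWE_SOFT_FRACTION:
            rows.append((snp, "kept", "hwe_skipped_soft_dosages"))
            keep.append(snp)
            continue
        if not hwe_pvalue(d) > t.min_hwe_p:
            rows.append((snp, "removed", "hwe"))
            continue
        rows.append((snp, "kept", ""))
        keep.append(snp)
    log = pd.DataFrame(rows, columns=["snp_id", "status", "reason"])
    if not keep:
        raise NoSnpsRetainedError("all SNPs removed by QC filters")
    return SnpFilterResult(genotypes=g.subset_snps(keep), log=log)


def quantile_normalize_log2(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Across-sample quantile normalization followed by log2.

    Each sample's sorted intensities are replaced by the across-sample mean
    of the order statistics; tied values receive the mean of their span.
    After normalization every sample holds the same multiset of values.
    """
    v = raw.values.to_numpy(dtype=float)
    if (v <= 0).any():
        raise ValueError("quantile_normalize_log2 requires strictly positive intensities")
    mean_sorted = np.sort(v, axis=1).mean(axis=0)
    out = np.empty_like(v)
    for i in range(v.shape[0]):
        order = np.argsort(v[i], kind="stable")
        row = np.empty_like(mean_sorted)
        row[order] = mean_sorted
        # ties: average the reference values over the tied span
        sorted_vals = v[i, order]
        k = 0
        while k < sorted_vals.size:
            k2 = k
            while k2 + 1 < sorted_vals.size and sorted_vals[k2 + 1] == sorted_vals[k]:
                k2 += 1
            if k2 > k:
                row[order[k : k2 + 1]] = mean_sorted[k : k2 + 1].mean()
            k = k2 + 1
        out[i] = row
    return ExpressionMatrix(
        values=pd.DataFrame(np.log2(out), index=raw.values.index, columns=raw.values.columns),
        probe_meta=raw.probe_meta,
    )


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    bad = []
    cols = [X[:, :1]]
    for j in range(1, X.shape[1]):
        cand = np.column_stack(cols + [X[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) == len(cols):
            bad.append(names[j - 1] if j >= 1 else "intercept")
        else:
            cols.append(X[:, j : j + 1])
    raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")


def residualize(
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
    n_expression_pcs: int = 0,
) -> ExpressionMatrix:
    """Per-probe OLS residuals on an intercept plus covariate columns.

    Optionally appends the first ``n_expression_pcs`` principal components
    of the (centred) expression matrix as latent covariates.  Residuals are
    exactly orthogonal to every covariate column.
    """
    Y = expr.values.to_numpy(dtype=float)
    n = Y.shape[0]
    parts = [np.ones((n, 1))]
    names: list[str] = []
    if covariates is not None:
        cov = covariates.loc[expr.samples]
        if cov.isna().any().any():
            raise ValueError("covariates contain missing values for used samples")
        parts.append(cov.to_numpy(dtype=float))
        names += list(cov.columns)
    if n_expression_pcs > 0:
        centred = Y - Y.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        parts.append(centred @ vt[:n_expression_pcs].T)
        names += [f"expr_pc{k + 1}" for k in range(n_expression_pcs)]
    X = np.column_stack(parts)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return ExpressionMatrix(
        values=pd.DataFrame(resid, index=expr.values.index, columns=expr.values.columns),
        probe_meta=expr.probe_meta,
    )


# ---------------------------------------------------------------------------
# Spearman scan core


def _standardized_ranks(mat: np.ndarray) -> np.ndarray:
    """Columnwise midranks, centred and scaled to unit norm (NaN-free input)."""
    r = stats.rankdata(mat, axis=0)
    r = r - r.mean(axis=0)
    norms = np.sqrt((r**2).sum(axis=0))
    norms[norms == 0] = np.inf  # constant column -> zero vector -> rho 0
    return r / norms


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (testing hook, n <= 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p restricted to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def _pair_table(
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    *,
    scope: str,
    window_bp: int,
    min_distance_bp: int,
    snp_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Enumerate testable (snp, probe) pairs in a deterministic order."""
    smeta = g.snp_meta.copy()
    smeta["snp_id"] = smeta.index
    smeta = smeta.sort_values(["chrom", "pos", "snp_id"])
    if snp_subset is not None:
        subset = list(snp_subset)
        missing = sorted(set(subset) - set(smeta.index))
        if missing:
            raise KeyError(f"SNP ids absent from genotypes: {missing}")
        smeta = smeta.loc[smeta["snp_id"].isin(subset)]
    pmeta = expr.probe_meta.copy()
    pmeta["probe_id"] = pmeta.index
    pmeta = pmeta.sort_values(["chrom", "midpoint", "probe_id"])

    rows = []
    for chrom_s, s_grp in smeta.groupby("chrom", sort=True):
        for chrom_p, p_grp in pmeta.groupby("chrom", sort=True):
            spos = s_grp["pos"].to_numpy()[:, None]
            ppos = p_grp["midpoint"].to_numpy()[None, :]
            if scope == "cis":
                if chrom_s != chrom_p:
                    continue
                mask = np.abs(spos - ppos) <= window_bp
            else:
                if chrom_s != chrom_p:
                    mask = np.ones((len(s_grp), len(p_grp)), dtype=bool)
                else:
                    mask = np.abs(spos - ppos) > min_distance_bp
            si, pi = np.nonzero(mask)
            if si.size:
                rows.append(
                    pd.DataFrame(
                        {
                            "snp_id": s_grp["snp_id"].to_numpy()[si],
                            "probe_id": p_grp["probe_id"].to_numpy()[pi],
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(columns=["snp_id", "probe_id"])
    return pd.concat(rows, ignore_index=True)


def _scan_pairs(
    g: GenotypeMatrix, expr: ExpressionMatrix, pairs: pd.DataFrame, scope: str
) -> pd.DataFrame:
    """Spearman rho + t-approximation p for each pair, pairwise-complete."""
    common = expr.samples.intersection(g.samples)
    dos = g.dosages.loc[common]
    vals = expr.values.loc[common]
    n = len(common)
    records = []

    snp_has_missing = dos.isna().any()
    clean_snps = [s for s in pairs["snp_id"].unique() if not snp_has_missing[s]]
    dirty_pairs = pairs[pairs["snp_id"].map(snp_has_missing)]
    clean_pairs = pairs[~pairs["snp_id"].map(snp_has_missing)]

    if len(clean_pairs) and n >= 3:
        zg = pd.DataFrame(
            _standardized_ranks(dos[clean_snps].to_numpy(float)),
            index=common,
            columns=clean_snps,
        )
        probes = list(clean_pairs["probe_id"].unique())
        ze = pd.DataFrame(
            _standardized_ranks(vals[probes].to_numpy(float)),
            index=common,
            columns=probes,
        )
        rho_mat = zg.to_numpy().T @ ze.to_numpy()
        p_mat = _t_pvalue(rho_mat, n)
        sidx = {s: i for i, s in enumerate(clean_snps)}
        pidx = {p: i for i, p in enumerate(probes)}
        si = clean_pairs["snp_id"].map(sidx).to_numpy()
        pi = clean_pairs["probe_id"].map(pidx).to_numpy()
        records.append(
            pd.DataFrame(
                {
                    "snp_id": clean_pairs["snp_id"].to_numpy(),
                    "probe_id": clean_pairs["probe_id"].to_numpy(),
                    "n_used": n,
                    "rho": rho_mat[si, pi],
                    "p_nominal": p_mat[si, pi],
                }
            )
        )

    skipped = 0
    for snp, probe in dirty_pairs.itertuples(index=False):
        x = dos[snp].to_numpy(float)
        y = vals[probe].to_numpy(float)
        ok = ~np.isnan(x)
        if ok.sum() < 3:
            skipped += 1
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        records.append(
            pd.DataFrame(
                {
                    "snp_id": [snp],
                    "probe_id": [probe],
                    "n_used": int(ok.sum()),
                    "rho": rho,
                    "p_nominal": p,
                }
            )
        )
    if skipped:
        logger.warning("skipped %d pairs with < 3 complete observations", skipped)

    if not records:
        logger.warning("no testable %s pair", scope)
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    out["q_value"] = np.nan
    out["scope"] = scope
    return out.sort_values(["probe_id", "snp_id"], ignore_index=True)[RECORD_COLUMNS]


def map_cis(
    g: GenotypeMatrix, expr: ExpressionMatrix, window_bp: int = 1_000_000
) -> pd.DataFrame:
    """Scan SNP-probe pairs with |SNP pos − probe midpoint| ≤ window (same chrom)."""
    pairs = _pair_table(
        g, expr, scope="cis", window_bp=window_bp, min_distance_bp=0
    )
    return _scan_pairs(g, expr, pairs, "cis")


def map_trans(
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    snp_subset: Sequence[str],
    min_distance_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Scan subset SNPs against probes > min_distance away or on other chromosomes.

    Expression should already be cis-corrected (see
    :func:`correct_cis_effects`); this is the caller's responsibility.
    """
    pairs = _pair_table(
        g,
        expr,
        scope="trans",
        window_bp=0,
        min_distance_bp=min_distance_bp,
        snp_subset=snp_subset,
    )
    return _scan_pairs(g, expr, pairs, "trans")


def correct_cis_effects(
    expr: ExpressionMatrix,
    g: GenotypeMatrix,
    cis_hits: pd.DataFrame,
    q_level: float = 0.05,
) -> ExpressionMatrix:
    """Regress each probe on its top significant cis SNP dosage.

    Top SNP per probe = lowest nominal p among hits with q ≤ ``q_level``
    (ties broken by smallest genomic position).  Probes without a
    significant cis SNP pass through unchanged.
    """
    out = expr.values.copy()
    sig = cis_hits[cis_hits["q_value"] <= q_level]
    if sig.empty:
        return ExpressionMatrix(values=out, probe_meta=expr.probe_meta)
    sig = sig.assign(pos=sig["snp_id"].map(g.snp_meta["pos"]))
    for probe, grp in sig.groupby("probe_id"):
        top = grp.sort_values(["p_nominal", "pos"]).iloc[0]
        x = g.dosages[top["snp_id"]].loc[expr.samples].to_numpy(float)
        y = out[probe].to_numpy(float)
        ok = ~np.isnan(x)
        X = np.column_stack([np.ones(int(ok.sum())), x[ok]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        y[ok] = y[ok] - X @ beta  # mean-zero residual, orthogonal to dosage
        y[~ok] = y[~ok] - y[~ok].mean() if (~ok).any() else y[~ok]
        out[probe] = y
    return ExpressionMatrix(values=out, probe_meta=expr.probe_meta)


def probe_level_fdr(
    records: pd.DataFrame,
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    level: float = 0.05,
) -> pd.DataFrame:
    """Permutation probe-level FDR: q per probe from its minimum p.

    The null is built by permuting expression sample labels (genotypes
    fixed, preserving LD) and recording each probe's minimum p per
    permutation.  For each observed probe min-p threshold τ,
    FDR(τ) = mean permuted #{min p ≤ τ} / observed #{min p ≤ τ},
    monotonized to be non-decreasing in τ; every record of a probe gets
    the probe's FDR value as its q.  A boolean ``significant`` column
    marks individual pairs reported at ``level``: the probe's q must be
    ≤ level and the pair's own nominal p must reach τ*, the largest
    threshold still controlling FDR at ``level`` (so a significant
    probe's unassociated SNPs are not dragged along).
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10 (null too unstable below)")
    if records.empty:
        return records.copy()
    common = expr.samples.intersection(g.samples)
    dos = g.dosages.loc[common]
    vals = expr.values.loc[common]
    n = len(common)
    rng = np.random.default_rng(seed)

    snps = list(records["snp_id"].unique())
    probes = list(records["probe_id"].unique())
    if dos[snps].isna().any().any():
        raise NotImplementedError(
            "permutation FDR requires complete dosages for tested SNPs"
        )
    zg = _standardized_ranks(dos[snps].to_numpy(float))
    ze = _standardized_ranks(vals[probes].to_numpy(float))
    sidx = {s: i for i, s in enumerate(snps)}
    pidx = {p: i for i, p in enumerate(probes)}
    si = records["snp_id"].map(sidx).to_numpy()
    pi = records["probe_id"].map(pidx).to_numpy()
    mask = np.full((len(snps), len(probes)), np.inf)
    mask[si, pi] = 1.0  # only tested pairs enter the minimum

    def min_p_per_probe(ze_mat: np.ndarray) -> np.ndarray:
        rho = zg.T @ ze_mat
        p = np.where(np.isinf(mask), np.inf, _t_pvalue(rho, n))
        return p.min(axis=0)

    obs_min = min_p_per_probe(ze)
    order = np.argsort(obs_min)
    thresholds = obs_min[order]
    perm_counts = np.zeros(thresholds.size)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        null_sorted = np.sort(min_p_per_probe(ze[perm]))
        # permuted probes with min p <= each observed threshold
        perm_counts += np.searchsorted(null_sorted, thresholds, side="right")
    perm_counts /= n_permutations
    obs_counts = np.arange(1, thresholds.size + 1, dtype=float)
    fdr = np.minimum(perm_counts / obs_counts, 1.0)
    # step-up monotonization: non-decreasing in the threshold
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    q_by_probe = np.empty_like(obs_min)
    q_by_probe[order] = fdr
    out = records.copy()
    out["q_value"] = out["probe_id"].map(
        {p: q_by_probe[pidx[p]] for p in probes}
    )
    passing = thresholds[fdr <= level]
    tau_star = passing.max() if passing.size else -np.inf
    out["significant"] = (out["q_value"] <= level) & (out["p_nominal"] <= tau_star)
    return out


def pairwise_r2(g: GenotypeMatrix, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Pairwise-complete squared Pearson correlation of dosages (LD r²).

    Zero-variance SNPs yield NaN entries (undefined correlation);
    the diagonal is 1 for well-defined SNPs.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) < 2:
        raise ValueError("pairwise_r2 needs at least 2 SNPs")
    dos = g.dosages[snp_ids]
    r2 = np.empty((len(snp_ids), len(snp_ids)))
    for i in range(len(snp_ids)):
        r2[i, i] = 1.0
        for j in range(i + 1, len(snp_ids)):
            x = dos.iloc[:, i].to_numpy(float)
            y = dos.iloc[:, j].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete samples for ({snp_ids[i]}, {snp_ids[j]})"
                )
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                r2[i, j] = r2[j, i] = np.nan
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            r2[i, j] = r2[j, i] = r * r
        x = dos.iloc[:, i].to_numpy(float)
        if np.nanstd(x) == 0:
            r2[i, :] = np.nan
            r2[:, i] = np.nan
    return pd.DataFrame(r2, index=snp_ids, columns=snp_ids)
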