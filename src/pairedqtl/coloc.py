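"""Single-causal-variant colocalization from summary statistics.

Given regional association summaries for two traits (e.g. disease GWAS
and an eQTL scan), computes per-SNP approximate Bayes factors under a
normal effect-size prior and the posterior probabilities of the five
hypotheses:

  H0 neither trait associated; H1 trait 1 only; H2 trait 2 only;
  H3 both, distinct causal variants; H4 both, one shared causal variant.

Default per-SNP priors follow the convention of the underlying framework:
p1 = 1e-4, p2 = 1e-5 (trans-eQTL), p12 = 1e-6, with a sensitivity sweep
over p2 in {1e-4, 1e-5} x p12 in {1e-5, 1e-6}.  All hypothesis sums are
carried in log space.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "RegionalAssoc",
    "ColocPriors",
    "ColocResult",
    "wakefield_abf",
    "coloc_region",
    "prior_sensitivity",
]

logger = logging.getLogger(__name__)

DEFAULT_W_CC = 0.15  # prior effect SD on the log-odds scale (case-control)
DEFAULT_W_QT = 0.20  # prior effect SD in trait-SD units (quantitative)


@dataclass
class RegionalAssoc:
    """Per-SNP association summary for one trait in one region.

    ``table`` needs columns ``snp_id`` and ``pos`` plus either
    (``beta``, ``se``) or (``p``, ``maf``, ``n``); for case-control traits
    set ``case_control=True`` and ``case_fraction``.
    """

    trait: str
    table: pd.DataFrame
    case_control: bool = False
    case_fraction: Optional[float] = None
    prior_sd: Optional[float] = None

    def __post_init__(self) -> None:
        t = self.table
        if t["snp_id"].duplicated().any():
            raise ValueError("one record per SNP required")
        self.has_beta = {"beta", "se"} <= set(t.columns) and t["se"].notna().all()
        if self.has_beta and (t["se"] <= 0).any():
            raise ValueError("standard errors must be > 0")
        if not self.has_beta:
            for col in ("p", "maf", "n"):
                if col not in t.columns:
                    raise ValueError("need (beta, se) or (p, maf, n) columns")
            if ((t["maf"] <= 0) | (t["maf"] > 0.5)).any():
                raise ValueError("MAF must lie in (0, 0.5]")

    def effective_w(self) -> float:
        if self.prior_sd is not None:
            return self.prior_sd
        return DEFAULT_W_CC if self.case_control else DEFAULT_W_QT

    def log_abfs(self) -> pd.Series:
        t = self.table
        W = self.effective_w()
        if self.has_beta:
            beta = t["beta"].to_numpy(float)
            se = t["se"].to_numpy(float)
        else:
            # reconstruct |z| from p; SE from the variance explained under HWE
            z = stats.norm.isf(t["p"].to_numpy(float) / 2.0)
            maf = t["maf"].to_numpy(float)
            n = t["n"].to_numpy(float)
            if self.case_control:
                s = float(self.case_fraction)
                se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * s * (1.0 - s))
            else:
                se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
            beta = z * se
        vals = wakefield_abf(beta, se, W)
        return pd.Series(vals, index=t["snp_id"].to_numpy())


@dataclass(frozen=True)
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-5
    p12: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_snps: int
    best_causal_t1: str
    best_causal_t2: str
    priors: ColocPriors

    def __post_init__(self) -> None:
        assert abs(self.pp.sum() - 1.0) < 1e-10

    def as_dict(self) -> dict:
        d = {f"PP{i}": float(self.pp[i]) for i in range(5)}
        d.update(
            n_snps=self.n_snps,
            best_causal_t1=self.best_causal_t1,
            best_causal_t2=self.best_causal_t2,
            priors={"p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12},
        )
        return d


def wakefield_abf(beta, se, prior_sd_w: float):
    """Log approximate Bayes factor for association from (beta, se).

    log ABF = 1/2 log(se^2/(se^2+W^2)) + (z^2/2) * W^2/(se^2+W^2),
    the marginal-likelihood ratio of N(0, se^2 + W^2) vs N(0, se^2) at
    the observed effect estimate.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be > 0")
    if prior_sd_w <= 0:
        raise ValueError("prior SD W must be > 0")
    w2 = prior_sd_w**2
    z2 = (beta / se) ** 2
    shrink = w2 / (se**2 + w2)
    return 0.5 * np.log(se**2 / (se**2 + w2)) + 0.5 * z2 * shrink


def coloc_region(
    t1: RegionalAssoc, t2: RegionalAssoc, priors: ColocPriors = ColocPriors()
) -> ColocResult:
    """Posterior probabilities PP0..PP4 for one region.

    SNPs are intersected on id; with per-SNP log ABFs l1, l2 the
    unnormalized hypothesis weights are 1, p1*sum_j e^{l1_j},
    p2*sum_j e^{l2_j}, p1*p2*sum_{j != k} e^{l1_j + l2_k},
    p12*sum_j e^{l1_j + l2_j}, evaluated with log-sum-exp.
    """
    a1 = t1.log_abfs()
    a2 = t2.log_abfs()
    shared = a1.index.intersection(a2.index)
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared SNPs between {t1.trait} and {t2.trait}"
        )
    logger.info("%d shared SNPs in region (%s vs %s)", len(shared), t1.trait, t2.trait)
    l1 = a1.loc[shared].to_numpy()
    l2 = a2.loc[shared].to_numpy()

    log_l1 = logsumexp(l1)
    log_l2 = logsumexp(l2)
    log_l4 = logsumexp(l1 + l2)
    # sum_{j != k} = (sum_j)(sum_k) - sum_j (joint), kept in log space
    diff = log_l4 - (log_l1 + log_l2)
    if diff >= 0:
        log_l3 = -np.inf  # single-SNP corner case: no distinct-variant term
    else:
        log_l3 = log_l1 + log_l2 + np.log1p(-np.exp(diff))

    terms = np.array(
        [
            0.0,
            np.log(priors.p1) + log_l1,
            np.log(priors.p2) + log_l2,
            np.log(priors.p1) + np.log(priors.p2) + log_l3,
            np.log(priors.p12) + log_l4,
        ]
    )
    pp = np.exp(terms - logsumexp(terms))
    return ColocResult(
        pp=pp,
        n_snps=len(shared),
        best_causal_t1=str(shared[np.argmax(l1)]),
        best_causal_t2=str(shared[np.argmax(l2)]),
        priors=priors,
    )


def prior_sensitivity(
    t1: RegionalAssoc,
    t2: RegionalAssoc,
    p1: float = 1e-4,
    p2_values: Sequence[float] = (1e-4, 1e-5),
    p12_values: Sequence[float] = (1e-5, 1e-6),
) -> pd.DataFrame:
    """Colocalization under each (p2, p12) prior combination.

    Returns one row per combination with the minimum p per trait, the
    best-causal SNPs, and PP3/PP4 — the consistency table reported for
    the disease/eQTL analysis.
    """
    rows = []
    for p2 in p2_values:
        for p12 in p12_values:
            res = coloc_region(t1, t2, ColocPriors(p1=p1, p2=p2, p12=p12))
            rows.append(
                {
                    "p1": p1,
                    "p2": p2,
                    "p12": p12,
                    f"{t1.trait}_best_snp": res.best_causal_t1,
                    f"{t2.trait}_best_snp": res.best_causal_t2,
                    "best_causal": res.best_causal_t1
                    if res.pp[4] >= 0.5
                    else res.best_causal_t2,
                    "PP3": float(res.pp[3]),
                    "PP4": float(res.pp[4]),
                }
            )
    return pd.DataFrame(rows)
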