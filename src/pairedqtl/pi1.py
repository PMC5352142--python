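"""Storey-style estimation of the proportion of true positives (pi1).

pi0 (the fraction of tests following the Uniform(0,1) null) is estimated
from the p-value histogram tail over a lambda grid and smoothed; pi1 =
1 - pi0 quantifies replication / sharing when applied to the replication
p-values of a discovery-significant SNP-probe list.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["Pi1Result", "estimate_pi0", "replication_rate"]

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
SPLINE_MIN_M = 100
FALLBACK_LAMBDA = 0.5


@dataclass
class Pi1Result:
    lambda_grid: np.ndarray
    pi0_at_lambda: np.ndarray
    pi0: float
    pi1: float
    m: int
    mode: str  # "spline" or "fixed_lambda"

    def __post_init__(self) -> None:
        assert 0.0 <= self.pi0 <= 1.0
        assert abs(self.pi0 + self.pi1 - 1.0) < 1e-12

    def to_dict(self) -> dict:
        return {"pi0": self.pi0, "pi1": self.pi1, "m": self.m, "mode": self.mode}


def estimate_pi0(
    pvalues: Sequence[float], lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> Pi1Result:
    """Estimate pi0 from a p-value list.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)).  The final estimate is
    a 3-df cubic smoother of pi0(lambda) evaluated at max(lambda), clipped
    to [0, 1].  For m < 100 the tail is too sparse for smoothing and a
    fixed lambda = 0.5 estimate is used instead (logged).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size < 1 or (np.diff(lam) <= 0).any() or lam.min() <= 0 or lam.max() >= 1:
        raise ValueError("lambda_grid must be strictly increasing within (0, 1)")
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])

    if m >= SPLINE_MIN_M and lam.size >= 4:
        coefs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coefs, lam.max()))
        mode = "spline"
    else:
        l0 = lam[np.argmin(np.abs(lam - FALLBACK_LAMBDA))]
        pi0 = float((p > l0).sum() / (m * (1.0 - l0)))
        mode = "fixed_lambda"
        logger.info("m=%d below spline threshold; fixed-lambda=%g pi0 used", m, l0)
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Result(
        lambda_grid=lam,
        pi0_at_lambda=pi0_lam,
        pi0=pi0,
        pi1=1.0 - pi0,
        m=m,
        mode=mode,
    )


def replication_rate(
    discovery: pd.DataFrame,
    replication_pvalues: Mapping[Tuple[str, str], float],
    q_level: float = 0.05,
) -> Pi1Result:
    """pi1 of the replication p-values of discovery-significant pairs.

    ``discovery`` is an eQTL record frame (snp_id, probe_id, q_value and,
    when produced by the permutation FDR, a pair-level ``significant``
    flag, which is preferred); pairs absent from the replication map are
    dropped and counted.
    """
    if "significant" in discovery.columns:
        sig = discovery[discovery["significant"]]
    else:
        sig = discovery[discovery["q_value"] <= q_level]
    pvals = []
    dropped = 0
    for snp, probe in sig[["snp_id", "probe_id"]].itertuples(index=False):
        key = (snp, probe)
        if key in replication_pvalues:
            pvals.append(replication_pvalues[key])
        else:
            dropped += 1
    if dropped:
        logger.warning("%d discovery pairs missing from replication map", dropped)
    if not pvals:
        raise ValueError("no overlap between discovery pairs and replication p-values")
    return estimate_pi0(pvals)
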