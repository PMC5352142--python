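"""Joint two-cell-type eQTL discovery by Bayesian model averaging.

For every cis SNP-probe pair and every "configuration" (eQTL active in
cell type A only, B only, or both) a Bayes factor is computed from the
per-tissue regression summary statistics under a bivariate normal
effect-size prior, averaged over a grid of prior scales.  A hierarchical
EM then estimates the configuration probabilities eta across probes, and
Bayesian model averaging yields per-probe posteriors of having an eQTL,
the configuration split, and the best SNP.  The probability pi0 that a
probe has no eQTL in either cell type comes from probe-level permutation
p-values fed to the Storey pi0 estimator.

Configurations are indexed by the tuple of active tissues: ("A",),
("B",), ("A", "B").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .matrices import ExpressionMatrix, GenotypeMatrix
from . import mapping
from .pi1 import estimate_pi0

__all__ = [
    "CONFIGURATIONS",
    "BmaGrid",
    "BmaFit",
    "ProbePosterior",
    "default_grid",
    "compute_summary_stats",
    "configuration_bf",
    "log_bf_table",
    "em_fit",
    "estimate_pi0_perm",
    "probe_posteriors",
]

logger = logging.getLogger(__name__)

CONFIGURATIONS: Tuple[Tuple[str, ...], ...] = (("A",), ("B",), ("A", "B"))
SE_FLOOR = 1e-8  # guards exact-fit degeneracies


@dataclass(frozen=True)
class BmaGrid:
    """Effect-size prior grid: (phi2, omega2) = (heterogeneity, shared) variances."""

    points: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        for phi2, omega2 in self.points:
            if phi2 < 0 or omega2 < 0 or phi2 + omega2 <= 0:
                raise ValueError("each grid point needs phi2, omega2 >= 0, not both 0")


def default_grid() -> BmaGrid:
    """Total prior SD in {0.1, 0.2, 0.4, 0.8} crossed with heterogeneity
    fraction phi2/(phi2+omega2) in {0, 1/4, 1/2, 3/4, 1}."""
    pts = []
    for total_sd in (0.1, 0.2, 0.4, 0.8):
        w = total_sd**2
        for h in (0.0, 0.25, 0.5, 0.75, 1.0):
            pts.append((h * w, (1.0 - h) * w))
    return BmaGrid(points=tuple(pts))


@dataclass
class BmaFit:
    eta: Dict[Tuple[str, ...], float]
    pi0: float
    loglik_trace: List[float]
    converged: bool
    flat_likelihood: bool = False
    n_iter: int = 0
    snp_bf_pooling: str = "average"  # probe-level BF = mean over the probe's SNPs

    def __post_init__(self) -> None:
        total = sum(self.eta.values())
        assert abs(total - 1.0) < 1e-9 and all(v >= 0 for v in self.eta.values())
        assert 0.0 <= self.pi0 <= 1.0


@dataclass
class ProbePosterior:
    probe_id: str
    posterior_has_eqtl: float
    posterior_config: Dict[Tuple[str, ...], float]
    best_snp_id: str
    posterior_best_snp: float


def compute_summary_stats(
    g: GenotypeMatrix,
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-tissue simple-regression slope and SE of expression on dosage.

    ``pairs`` has columns (snp_id, probe_id); returns one row per pair
    with betaA, seA, nA, betaB, seB, nB.  Pairs with fewer than 3 complete
    samples in a tissue are skipped and logged.
    """
    rows = []
    skipped = 0
    for snp, probe in pairs[["snp_id", "probe_id"]].itertuples(index=False):
        rec = {"snp_id": snp, "probe_id": probe}
        ok_any = True
        for tag, expr in (("A", exprA), ("B", exprB)):
            common = expr.samples.intersection(g.samples)
            x = g.dosages[snp].loc[common].to_numpy(float)
            y = expr.values[probe].loc[common].to_numpy(float)
            m = ~np.isnan(x)
            n = int(m.sum())
            if n < 3:
                ok_any = False
                break
            xs, ys = x[m], y[m]
            xc = xs - xs.mean()
            sxx = float(xc @ xc)
            if sxx == 0:
                ok_any = False
                break
            beta = float(xc @ ys / sxx)
            resid = ys - ys.mean() - beta * xc
            dof = n - 2
            se = np.sqrt(float(resid @ resid) / dof / sxx) if dof > 0 else 0.0
            rec[f"beta{tag}"] = beta
            rec[f"se{tag}"] = max(se, SE_FLOOR)
            rec[f"n{tag}"] = n
        if ok_any:
            rows.append(rec)
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d pairs with insufficient data", skipped)
    return pd.DataFrame(
        rows, columns=["snp_id", "probe_id", "betaA", "seA", "nA", "betaB", "seB", "nB"]
    )


def _log_mvn_ratio(beta: np.ndarray, V: np.ndarray, prior: np.ndarray) -> float:
    """log N(beta; 0, V + prior) - log N(beta; 0, V)."""
    num = V + prior
    sign, logdet_num = np.linalg.slogdet(num)
    if sign <= 0:
        raise ValueError(f"singular prior+error covariance at grid point {prior}")
    sign_v, logdet_v = np.linalg.slogdet(V)
    q_num = float(beta @ np.linalg.solve(num, beta))
    q_v = float(beta @ np.linalg.solve(V, beta))
    return -0.5 * (logdet_num - logdet_v) - 0.5 * (q_num - q_v)


def configuration_bf(
    stat: pd.Series | dict, grid: BmaGrid
) -> Dict[Tuple[str, ...], float]:
    """Natural-log Bayes factor per configuration, averaged over the grid.

    For configuration gamma, the prior covariance of the true effects has
    omega2 + phi2 on the diagonal and omega2 off-diagonal (restricted to
    gamma's tissues); the BF is the ratio of the marginal density of the
    observed betas under N(0, V + Sigma_prior) vs N(0, V), V = diag(SE^2).
    The grid average is arithmetic, computed in log space.
    """
    betas = {"A": float(stat["betaA"]), "B": float(stat["betaB"])}
    ses = {"A": max(float(stat["seA"]), SE_FLOOR), "B": max(float(stat["seB"]), SE_FLOOR)}
    out = {}
    for gamma in CONFIGURATIONS:
        b = np.array([betas[t] for t in gamma])
        V = np.diag([ses[t] ** 2 for t in gamma])
        logs = []
        for phi2, omega2 in grid.points:
            k = len(gamma)
            prior = np.full((k, k), omega2) + np.eye(k) * phi2
            logs.append(_log_mvn_ratio(b, V, prior))
        out[gamma] = float(logsumexp(logs) - np.log(len(logs)))
    return out


def _univariate_log_bf(beta: np.ndarray, se2: np.ndarray, W: np.ndarray) -> np.ndarray:
    """log ABF for one tissue, vectorized over pairs x grid points."""
    z2 = beta[:, None] ** 2 / se2[:, None]
    shrink = W[None, :] / (se2[:, None] + W[None, :])
    return 0.5 * np.log(se2[:, None] / (se2[:, None] + W[None, :])) + 0.5 * z2 * shrink


def log_bf_table(stats_frame: pd.DataFrame, grid: Optional[BmaGrid] = None) -> pd.DataFrame:
    """Configuration log-BFs for every summary-stat row.

    Vectorized closed forms of the same densities as
    :func:`configuration_bf` (checked against it in the test suite).
    """
    grid = grid or default_grid()
    phi2 = np.array([p for p, _ in grid.points])
    omega2 = np.array([o for _, o in grid.points])
    W = phi2 + omega2
    bA = stats_frame["betaA"].to_numpy(float)
    bB = stats_frame["betaB"].to_numpy(float)
    a = np.maximum(stats_frame["seA"].to_numpy(float), SE_FLOOR) ** 2
    b = np.maximum(stats_frame["seB"].to_numpy(float), SE_FLOOR) ** 2

    n_grid = len(grid.points)
    logs = {
        "logbf_A": _univariate_log_bf(bA, a, W),
        "logbf_B": _univariate_log_bf(bB, b, W),
    }
    # both-tissue configuration: V = diag(a, b), prior [[W, w], [w, W]]
    w = omega2[None, :]
    aW = a[:, None] + W[None, :]
    bW = b[:, None] + W[None, :]
    det_m = aW * bW - w**2
    q_v = bA[:, None] ** 2 / a[:, None] + bB[:, None] ** 2 / b[:, None]
    q_m = (
        bA[:, None] ** 2 * bW - 2.0 * bA[:, None] * bB[:, None] * w + bB[:, None] ** 2 * aW
    ) / det_m
    logs["logbf_AB"] = -0.5 * (np.log(det_m) - np.log(a[:, None] * b[:, None])) - 0.5 * (
        q_m - q_v
    )
    out = stats_frame[["snp_id", "probe_id"]].copy()
    for col, mat in logs.items():
        out[col] = logsumexp(mat, axis=1) - np.log(n_grid)
    return out


_CONFIG_COLS = {("A",): "logbf_A", ("B",): "logbf_B", ("A", "B"): "logbf_AB"}


def _probe_log_bf(bf_table: pd.DataFrame) -> pd.DataFrame:
    """Probe-level log BF per configuration: mean over the probe's SNPs
    (uniform prior on which SNP is the eQTL), in log space."""
    rows = []
    for probe, grp in bf_table.groupby("probe_id", sort=True):
        row = {"probe_id": probe, "n_snps": len(grp)}
        for gamma, col in _CONFIG_COLS.items():
            row[col] = float(logsumexp(grp[col].to_numpy()) - np.log(len(grp)))
        rows.append(row)
    return pd.DataFrame(rows)


def em_fit(
    bf_table: pd.DataFrame,
    pi0: float,
    init_eta: Optional[Dict[Tuple[str, ...], float]] = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    allowed_configs: Sequence[Tuple[str, ...]] = CONFIGURATIONS,
) -> BmaFit:
    """Maximum-likelihood configuration probabilities by EM.

    The probe-level likelihood is
    ``pi0 + (1 - pi0) * sum_gamma eta_gamma * BFbar_gamma(probe)`` with
    BFbar the probe's SNP-averaged configuration BF; pi0 is held fixed
    (estimated separately from permutations).  The log-likelihood is
    non-decreasing across iterations; non-convergence returns the best
    iterate flagged.
    """
    if bf_table.empty:
        raise ValueError("need at least one probe")
    if not np.isfinite(bf_table[list(_CONFIG_COLS.values())].to_numpy()).all():
        raise ValueError("log BFs must be finite")
    allowed = [g for g in CONFIGURATIONS if g in tuple(allowed_configs)]
    probe_bf = _probe_log_bf(bf_table)
    L = probe_bf[[_CONFIG_COLS[g] for g in allowed]].to_numpy()  # log BFbar per probe

    if init_eta is None:
        eta = np.full(len(allowed), 1.0 / len(allowed))
    else:
        eta = np.array([init_eta[g] for g in allowed], dtype=float)
        eta = eta / eta.sum()

    def loglik(eta_vec: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            log_mix = logsumexp(L + np.log(eta_vec + 1e-300), axis=1)
        per_probe = np.logaddexp(
            np.log(pi0) if pi0 > 0 else -np.inf,
            (np.log1p(-pi0) if pi0 < 1 else -np.inf) + log_mix,
        )
        return float(per_probe.sum())

    trace = [loglik(eta)]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        # E-step: responsibilities of each configuration (and the null)
        with np.errstate(divide="ignore"):
            log_num = L + np.log(eta + 1e-300) + (np.log1p(-pi0) if pi0 < 1 else -np.inf)
        log_den = np.logaddexp(
            np.log(pi0) if pi0 > 0 else -np.inf, logsumexp(log_num, axis=1)
        )
        resp = np.exp(log_num - log_den[:, None])
        total = resp.sum()
        if total <= 0:
            break  # pi0 = 1: likelihood flat in eta
        new_eta = resp.sum(axis=0) / total
        ll = loglik(new_eta)
        trace.append(ll)
        delta = ll - trace[-2]
        eta = new_eta
        if abs(delta) < tol:
            converged = True
            break
    flat = len(trace) >= 2 and abs(trace[-1] - trace[0]) < 1e-12
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    eta_dict = {g: 0.0 for g in CONFIGURATIONS}
    for g, v in zip(allowed, eta):
        eta_dict[g] = float(v)
    s = sum(eta_dict.values())
    eta_dict = {g: v / s for g, v in eta_dict.items()}
    return BmaFit(
        eta=eta_dict,
        pi0=pi0,
        loglik_trace=trace,
        converged=converged,
        flat_likelihood=flat,
        n_iter=n_iter,
    )


def estimate_pi0_perm(
    g: GenotypeMatrix,
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    window_bp: int = 1_000_000,
):
    """Probe-level permutation p-values (joint over both cell types) -> pi0.

    For each probe the statistic is the minimum nominal p across its cis
    SNPs and both tissues; the null permutes sample labels of both
    expression matrices simultaneously.  p = (1 + #{null <= obs}) /
    (1 + n_permutations), fed to the Storey estimator.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    rng = np.random.default_rng(seed)
    commonA = exprA.samples.intersection(g.samples)
    commonB = exprB.samples.intersection(g.samples)
    shared = commonA.intersection(commonB)
    mats = []
    for expr, common in ((exprA, commonA), (exprB, commonB)):
        pairs = mapping._pair_table(
            g, expr, scope="cis", window_bp=window_bp, min_distance_bp=0
        )
        dos = g.dosages.loc[common]
        vals = expr.values.loc[common]
        snps = list(pairs["snp_id"].unique())
        probes = list(pairs["probe_id"].unique())
        zg = mapping._standardized_ranks(dos[snps].to_numpy(float))
        ze = mapping._standardized_ranks(vals[probes].to_numpy(float))
        sidx = {s: i for i, s in enumerate(snps)}
        pidx = {p: i for i, p in enumerate(probes)}
        mask = np.full((len(snps), len(probes)), np.inf)
        mask[pairs["snp_id"].map(sidx), pairs["probe_id"].map(pidx)] = 1.0
        mats.append((zg, ze, mask, probes, len(common), common))

    probes_all = sorted(set(mats[0][3]) | set(mats[1][3]))

    def joint_min_p(perms) -> pd.Series:
        best = pd.Series(np.inf, index=probes_all)
        for (zg, ze, mask, probes, n, _), perm in zip(mats, perms):
            zep = ze if perm is None else ze[perm]
            rho = zg.T @ zep
            p = np.where(np.isinf(mask), np.inf, mapping._t_pvalue(rho, n))
            best.loc[probes] = np.minimum(best.loc[probes], p.min(axis=0))
        return best

    def simultaneous_perms():
        # one draw permutes the samples shared by both tissues identically
        # (their statistics are correlated through shared individuals);
        # tissue-specific extras are permuted among themselves
        sigma_shared = dict(zip(shared, shared[rng.permutation(len(shared))]))
        perms = []
        for _, _, _, _, n, common in mats:
            extras = common.difference(shared)
            sigma = dict(sigma_shared)
            sigma.update(zip(extras, extras[rng.permutation(len(extras))]))
            lookup = {s: i for i, s in enumerate(common)}
            perms.append(np.array([lookup[sigma[s]] for s in common]))
        return perms

    obs = joint_min_p([None, None])
    exceed = pd.Series(0.0, index=probes_all)
    for _ in range(n_permutations):
        null = joint_min_p(simultaneous_perms())
        exceed += (null <= obs).astype(float)
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    return estimate_pi0(pvals.to_numpy())


def probe_posteriors(
    bf_table: pd.DataFrame, fit: BmaFit, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Bayesian model averaging: per-probe posteriors and best SNP.

    posterior_has_eqtl = (1-pi0) Bbar / (pi0 + (1-pi0) Bbar) with Bbar the
    eta-weighted SNP-averaged BF; configuration split proportional to
    eta_gamma BFbar_gamma; best SNP by the per-SNP BMA BF with posterior
    mass normalized over the probe's SNPs.  ``declared`` marks the largest
    posterior-ranked set whose mean (1 - posterior) stays <= fdr_level.
    """
    eta = np.array([fit.eta[g] for g in CONFIGURATIONS])
    rows = []
    for probe, grp in bf_table.groupby("probe_id", sort=True):
        log_bf_cfg = np.array(
            [
                logsumexp(grp[_CONFIG_COLS[g]].to_numpy()) - np.log(len(grp))
                for g in CONFIGURATIONS
            ]
        )
        with np.errstate(divide="ignore"):
            log_weighted = log_bf_cfg + np.log(eta + 1e-300)
        log_bbar = logsumexp(log_weighted)
        if fit.pi0 >= 1.0:
            post_eqtl = 0.0
        elif fit.pi0 <= 0.0:
            post_eqtl = 1.0
        else:
            log_odds = np.log1p(-fit.pi0) + log_bbar - np.log(fit.pi0)
            post_eqtl = float(1.0 / (1.0 + np.exp(-log_odds)))
        cfg_weights = np.exp(log_weighted - log_bbar)
        cfg_post = cfg_weights * post_eqtl

        # per-SNP BMA BF -> posterior over "which SNP is the eQTL"
        snp_log = logsumexp(
            grp[["logbf_A", "logbf_B", "logbf_AB"]].to_numpy()
            + np.log(eta + 1e-300)[None, :],
            axis=1,
        )
        snp_post = np.exp(snp_log - logsumexp(snp_log))
        best = int(np.argmax(snp_post))
        rows.append(
            {
                "probe_id": probe,
                "posterior_has_eqtl": post_eqtl,
                "posterior_A": float(cfg_post[0]),
                "posterior_B": float(cfg_post[1]),
                "posterior_AB": float(cfg_post[2]),
                "best_snp_id": grp["snp_id"].to_numpy()[best],
                "posterior_best_snp": float(snp_post[best]),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "posterior_has_eqtl", ascending=False, ignore_index=True
    )
    lfdr = 1.0 - out["posterior_has_eqtl"].to_numpy()
    mean_lfdr = np.cumsum(lfdr) / np.arange(1, len(lfdr) + 1)
    declared = mean_lfdr <= fdr_level
    if declared.any():
        cutoff = np.max(np.nonzero(declared)[0])
        declared = np.arange(len(lfdr)) <= cutoff
    out["declared"] = declared
    return out
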