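"""Paired mixed-model contrasts between conditions (cell types or alleles).

Estimates the mean within-subject difference in expression or methylation
between two conditions (e.g. CD4+ vs CD8+ T cells, or mutant vs wild-type
construct) with a random intercept per subject and fixed sex/age/batch
covariates, fitted by REML; and expression-methylation correlations for
coupled (probe, CpG) pairs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .matrices import ExpressionMatrix

__all__ = [
    "ContrastEstimate",
    "mixed_difference",
    "mutant_effect",
    "contrast_all_features",
    "expr_meth_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class ContrastEstimate:
    feature_id: str
    delta: float  # mean condition difference, second condition minus first
    se: float
    p: float
    n_subjects: int
    conditions: Tuple[str, str]


def _prepare(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    d = table[table["feature"] == feature].copy()
    if d.empty:
        raise ValueError(f"feature {feature!r} not present")
    conds = sorted(d["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    both = set(d.loc[d["condition"] == conds[0], "subject"]) & set(
        d.loc[d["condition"] == conds[1], "subject"]
    )
    if not both:
        raise ValueError(
            "no subject observed in both conditions; the paired design requires "
            "within-subject contrasts"
        )
    if len(both) < 3:
        raise ValueError("need >= 3 subjects observed in both conditions")
    return d


def mixed_difference(
    table: pd.DataFrame,
    feature: str,
    covariates: Sequence[str] = (),
) -> ContrastEstimate:
    """Random-intercept-per-subject estimate of the condition difference.

    ``table`` is long-format with columns subject, condition, feature,
    value (plus any covariate columns).  ``delta`` is the fixed condition
    coefficient (second condition label, sorted, minus the first) from a
    REML fit; p is the Wald test of delta = 0.
    """
    d = _prepare(table, feature)
    conds = sorted(d["condition"].unique())
    d["_cond"] = (d["condition"] == conds[1]).astype(float)
    cols = ["_cond"] + list(covariates)
    X = sm.add_constant(d[cols].astype(float), has_constant="add")
    model = MixedLM(d["value"].astype(float), X, groups=d["subject"])
    res = model.fit(reml=True)
    return ContrastEstimate(
        feature_id=feature,
        delta=float(res.params["_cond"]),
        se=float(res.bse["_cond"]),
        p=float(res.pvalues["_cond"]),
        n_subjects=d["subject"].nunique(),
        conditions=(conds[0], conds[1]),
    )


def mutant_effect(
    table: pd.DataFrame,
    feature: str,
    covariates: Sequence[str] = (),
) -> ContrastEstimate:
    """Allele (mutant vs wild-type) effect from replicated qPCR reactions.

    Same estimator as :func:`mixed_difference` with the sample as the
    random-intercept unit and replicate reactions as repeated measures.
    """
    return mixed_difference(table, feature, covariates=covariates)


def contrast_all_features(
    table: pd.DataFrame,
    covariates: Sequence[str] = (),
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-feature condition contrasts with Benjamini-Hochberg FDR."""
    rows = []
    for feature in sorted(table["feature"].unique()):
        try:
            est = mixed_difference(table, feature, covariates=covariates)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("feature %s skipped: %s", feature, exc)
            continue
        rows.append(
            {
                "feature": est.feature_id,
                "delta": est.delta,
                "se": est.se,
                "p": est.p,
                "n_subjects": est.n_subjects,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        reject, qvals, *_ = multipletests(out["p"], alpha=fdr_level, method="fdr_bh")
        out["q_bh"] = qvals
        out["significant"] = reject
    return out


def expr_meth_correlation(
    expr: ExpressionMatrix,
    meth: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]],
    condition_labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlation for coupled (probe, CpG) pairs.

    Computed on the samples shared by both matrices; when
    ``condition_labels`` (indexed by sample) is given, correlations are
    reported separately per condition.
    """
    unknown = [
        (p, c)
        for p, c in pairs
        if p not in expr.values.columns or c not in meth.columns
    ]
    if unknown:
        raise KeyError(f"pairs referencing unknown ids: {unknown}")
    shared = expr.samples.intersection(meth.index)
    groups = (
        {"all": shared}
        if condition_labels is None
        else {
            str(lvl): shared[condition_labels.loc[shared] == lvl]
            for lvl in condition_labels.loc[shared].unique()
        }
    )
    rows = []
    for probe, cpg in pairs:
        for label, samples in groups.items():
            x = expr.values.loc[samples, probe].to_numpy(float)
            y = meth.loc[samples, cpg].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete samples for ({probe}, {cpg}) in {label}"
                )
            r, p_r = stats.pearsonr(x[ok], y[ok])
            rho, _ = stats.spearmanr(x[ok], y[ok])
            rows.append(
                {
                    "probe": probe,
                    "cpg": cpg,
                    "condition": label,
                    "pearson_r": float(r),
                    "spearman_rho": float(rho),
                    "p": float(p_r),
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)
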