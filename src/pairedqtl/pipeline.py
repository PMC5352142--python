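"""End-to-end orchestration of the paired-cell-type eQTL analysis.

Stage order mirrors the analysis: SNP QC -> (optional) quantile
normalization -> covariate residualization -> cis scan + probe-level FDR
per cell type -> cis-effect correction -> trans scan + FDR on candidate
SNPs -> cross-cell-type pi1 replication -> joint Bayesian model averaging
-> (optional) colocalization, methylation correlations and mediation.
Every stage writes its artifact under ``out/<stage>/`` and is recorded in
a run manifest (JSON) that is written even when a stage fails.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bma, coloc, contrasts, io, mapping, mediation, pi1
from .mapping import FilterThresholds

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str
    expression_cellA: str
    expression_cellB: str
    probe_annotation: str
    snp_annotation: Optional[str] = None  # unused for VCF input
    covariates: Optional[str] = None
    methylation: Optional[str] = None
    methylation_pairs: Optional[str] = None  # TSV: probe, cpg
    gwas_snp_list: Optional[str] = None  # TSV with column snp_id
    summary_stats: Optional[str] = None  # regional stats for colocalization
    mediation_triplet: Optional[dict] = None  # {snp, probe1, probe2}
    cis_window_bp: int = 1_000_000
    trans_min_distance_bp: int = 5_000_000
    min_maf: float = 0.05
    min_call_rate: float = 0.95
    min_hwe_p: float = 0.001
    n_permutations: int = 100
    fdr_level: float = 0.05
    quantile_normalize: bool = False
    coloc_p12: float = 1e-6
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.cis_window_bp <= 0 or self.trans_min_distance_bp <= 0:
            raise ValueError("windows must be > 0")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    seed: int = 0
    status: str = "running"

    def start(self, name: str) -> dict:
        entry = {"stage": name, "status": "running", "start": time.time()}
        self.stages.append(entry)
        return entry

    def finish(self, entry: dict, status: str = "done", error: str = "") -> None:
        entry.update(status=status, end=time.time())
        if error:
            entry["error"] = error

    def add_artifact(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _align_samples(g, exprs, covariates):
    common = g.samples
    for e in exprs:
        common = common.intersection(e.samples)
    if covariates is not None:
        common = common.intersection(covariates.index)
    dropped = max(len(g.samples), *(len(e.samples) for e in exprs)) - len(common)
    if dropped:
        logger.info("sample alignment dropped %d non-shared ids", dropped)
    return common


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk).

    A stage failure stops everything downstream; the manifest records the
    partial completion and the error.
    """
    outdir = Path(config.outdir)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)
    manifest_path = outdir / "manifest.json"
    state: dict = {}

    def stage(name):
        def wrap(fn):
            return (name, fn)

        return wrap

    def load(_):
        if config.genotypes.endswith(".vcf") or config.genotypes.endswith(".vcf.gz"):
            g = io.read_vcf(config.genotypes)
        else:
            if config.snp_annotation is None:
                raise ValueError("snp_annotation is required for dosage TSV input")
            g = io.read_dosage_tsv(config.genotypes, config.snp_annotation)
        exprA = io.read_expression_tsv(config.expression_cellA, config.probe_annotation)
        exprB = io.read_expression_tsv(config.expression_cellB, config.probe_annotation)
        cov = io.read_covariates_tsv(config.covariates) if config.covariates else None
        common = _align_samples(g, [exprA, exprB], cov)
        state["g"] = g.subset_samples(common)
        state["exprA"] = exprA.subset_samples(common)
        state["exprB"] = exprB.subset_samples(common)
        state["cov"] = cov.loc[common] if cov is not None else None

    def qc(d):
        res = mapping.filter_snps(
            state["g"],
            FilterThresholds(config.min_maf, config.min_call_rate, config.min_hwe_p),
        )
        state["g"] = res.genotypes
        p = d / "snp_filter_log.tsv"
        res.log.to_csv(p, sep="\t", index=False)
        manifest.add_artifact("snp_filter_log", p)

    def normalize(d):
        if config.quantile_normalize:
            for key in ("exprA", "exprB"):
                state[key] = mapping.quantile_normalize_log2(state[key])
        if state["cov"] is not None:
            for key in ("exprA", "exprB"):
                state[key] = mapping.residualize(state[key], state["cov"])

    def cis_scan(d):
        for key, tag in (("exprA", "cellA"), ("exprB", "cellB")):
            recs = mapping.map_cis(state["g"], state[key], config.cis_window_bp)
            recs = mapping.probe_level_fdr(
                recs,
                state["g"],
                state[key],
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            state[f"cis_{tag}"] = recs
            p = d / f"cis_{tag}.tsv"
            io.write_eqtl_records(recs, state["g"], state[key], p)
            manifest.add_artifact(f"cis_{tag}", p)

    def cis_correct(d):
        for key, tag in (("exprA", "cellA"), ("exprB", "cellB")):
            state[f"{key}_corrected"] = mapping.correct_cis_effects(
                state[key], state["g"], state[f"cis_{tag}"], config.fdr_level
            )

    def trans_scan(d):
        if config.gwas_snp_list is None:
            raise _SkipStage("no GWAS SNP list configured")
        snps = pd.read_csv(config.gwas_snp_list, sep="\t")["snp_id"]
        snps = [s for s in snps if s in set(state["g"].snp_ids)]
        if not snps:
            raise _SkipStage("no GWAS SNP present after QC")
        for key, tag in (("exprA_corrected", "cellA"), ("exprB_corrected", "cellB")):
            recs = mapping.map_trans(
                state["g"], state[key], snps, config.trans_min_distance_bp
            )
            if recs.empty:
                continue
            recs = mapping.probe_level_fdr(
                recs,
                state["g"],
                state[key],
                n_permutations=config.n_permutations,
                seed=config.seed + 1,
            )
            state[f"trans_{tag}"] = recs
            p = d / f"trans_{tag}.tsv"
            io.write_eqtl_records(recs, state["g"], state[key], p)
            manifest.add_artifact(f"trans_{tag}", p)

    def replication(d):
        recsA, recsB = state["cis_cellA"], state["cis_cellB"]
        out = {}
        for disc, rep, tag in ((recsA, recsB, "A_in_B"), (recsB, recsA, "B_in_A")):
            if not (disc["q_value"] <= config.fdr_level).any():
                out[tag] = {"note": "no significant discovery pairs"}
                continue
            repmap = {
                (r.snp_id, r.probe_id): r.p_nominal for r in rep.itertuples(index=False)
            }
            try:
                res = pi1.replication_rate(disc, repmap, q_level=config.fdr_level)
                out[tag] = res.to_dict()
            except ValueError as exc:
                out[tag] = {"note": str(exc)}
        p = d / "pi1.json"
        with open(p, "w") as fh:
            json.dump(out, fh, indent=2)
        manifest.add_artifact("pi1", p)

    def joint_bma(d):
        pairs = pd.concat(
            [state["cis_cellA"], state["cis_cellB"]], ignore_index=True
        )[["snp_id", "probe_id"]].drop_duplicates()
        stats_frame = bma.compute_summary_stats(
            state["g"], state["exprA"], state["exprB"], pairs
        )
        bf_table = bma.log_bf_table(stats_frame)
        pi0_res = bma.estimate_pi0_perm(
            state["g"],
            state["exprA"],
            state["exprB"],
            n_permutations=config.n_permutations,
            seed=config.seed + 2,
            window_bp=config.cis_window_bp,
        )
        fit = bma.em_fit(bf_table, pi0=pi0_res.pi0)
        post = bma.probe_posteriors(bf_table, fit, fdr_level=config.fdr_level)
        p = d / "probe_posteriors.tsv"
        post.to_csv(p, sep="\t", index=False)
        manifest.add_artifact("bma_posteriors", p)
        p2 = d / "bma_fit.json"
        with open(p2, "w") as fh:
            json.dump(
                {
                    "eta": {"+".join(k): v for k, v in fit.eta.items()},
                    "pi0": fit.pi0,
                    "iterations": fit.n_iter,
                    "converged": fit.converged,
                    "snp_bf_pooling": fit.snp_bf_pooling,
                },
                fh,
                indent=2,
            )
        manifest.add_artifact("bma_fit", p2)

    def colocalization(d):
        if config.summary_stats is None:
            raise _SkipStage("no GWAS summary statistics configured")
        t1 = io.read_summary_stats(config.summary_stats, trait="trait1")
        # trait 2: the strongest trans (or cis) probe's per-SNP stats
        source = state.get("trans_cellA", state["cis_cellA"])
        top_probe = source.loc[source["p_nominal"].idxmin(), "probe_id"]
        sub = source[source["probe_id"] == top_probe]
        pairs = sub[["snp_id", "probe_id"]]
        st = bma.compute_summary_stats(
            state["g"], state["exprA"], state["exprB"], pairs
        )
        t2 = coloc.RegionalAssoc(
            trait="eqtl",
            table=pd.DataFrame(
                {
                    "snp_id": st["snp_id"],
                    "pos": st["snp_id"].map(state["g"].snp_meta["pos"]),
                    "beta": st["betaA"],
                    "se": st["seA"],
                }
            ),
        )
        sens = coloc.prior_sensitivity(t1, t2)
        p = d / "coloc_sensitivity.tsv"
        sens.to_csv(p, sep="\t", index=False)
        manifest.add_artifact("coloc_sensitivity", p)

    def methylation(d):
        if config.methylation is None or config.methylation_pairs is None:
            raise _SkipStage("no methylation input configured")
        meth = io.read_covariates_tsv(config.methylation)
        pairs = [
            (r.probe, r.cpg)
            for r in pd.read_csv(config.methylation_pairs, sep="\t").itertuples()
        ]
        tab = contrasts.expr_meth_correlation(state["exprA"], meth, pairs)
        p = d / "expr_meth_correlation.tsv"
        tab.to_csv(p, sep="\t", index=False)
        manifest.add_artifact("expr_meth_correlation", p)

    def mediation_stage(d):
        t = config.mediation_triplet
        if not t:
            raise _SkipStage("no mediation triplet configured")
        data = pd.DataFrame(
            {
                "snp": state["g"].dosages[t["snp"]],
                "g1": state["exprA"].values[t["probe1"]],
                "g2": state["exprA"].values[t["probe2"]],
            }
        ).dropna()
        ranking = mediation.compare_models(data)
        best = ranking.iloc[0]["fit"]
        est = best.estimates.set_index(["parent", "child"])
        report = {
            "ranking": ranking[["model", "aic", "chi2", "df", "cfi", "tli", "rmsea"]]
            .to_dict(orient="records"),
        }
        if ("snp", "g1") in est.index and ("g1", "g2") in est.index:
            sob = mediation.sobel_test(
                est.loc[("snp", "g1"), "estimate"],
                est.loc[("snp", "g1"), "se"],
                est.loc[("g1", "g2"), "estimate"],
                est.loc[("g1", "g2"), "se"],
            )
            report["sobel"] = {"z": sob.z, "p": sob.p}
        p = d / "mediation.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=2)
        manifest.add_artifact("mediation", p)

    stages = [
        ("load", load),
        ("snp_qc", qc),
        ("normalize", normalize),
        ("cis_scan", cis_scan),
        ("cis_correct", cis_correct),
        ("trans_scan", trans_scan),
        ("replication_pi1", replication),
        ("bma", joint_bma),
        ("colocalization", colocalization),
        ("methylation", methylation),
        ("mediation", mediation_stage),
    ]
    failed = False
    for name, fn in stages:
        entry = manifest.start(name)
        if failed:
            manifest.finish(entry, status="not_run")
            continue
        d = outdir / name
        d.mkdir(parents=True, exist_ok=True)
        try:
            fn(d)
        except _SkipStage as exc:
            logger.info("stage %s skipped: %s", name, exc)
            manifest.finish(entry, status="skipped", error=str(exc))
        except Exception as exc:  # noqa: BLE001 - manifest must record failures
            logger.error("stage %s failed: %s", name, exc)
            manifest.finish(entry, status="failed", error=traceback.format_exc())
            failed = True
        else:
            manifest.finish(entry)
    manifest.status = "failed" if failed else "done"
    manifest.write(manifest_path)
    return manifest


class _SkipStage(Exception):
    """Raised inside a stage to mark it skipped (optional input absent)."""
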