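"""End-to-end pipeline orchestration with a validated run configuration.

``run_all`` executes: 5hmC/5mC quantification -> region detection on both
channels -> enhancer enrichment -> consensus clustering -> expression
integration (skipped with notice when no expression matrix is given) ->
hMeDIP windows (when read files are given), and writes a machine-readable
summary JSON carrying the config echo, its hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import (
    Cohort,
    bumphunt,
    classify_groups,
    cluster_probes,
    compute_5hmc,
    compute_5mc,
    consensus_cluster,
    differential_expression,
    expression_association,
    filter_probes,
    gcimp_contribution,
    read_annotation,
    read_beta_matrix,
    read_gene_set,
    read_sample_sheet,
    regions_to_genes,
    select_consensus_probes,
    stratify_counts,
    top_expressed_genes,
    top_fraction_probes,
    volcano_stats,
    write_beta_matrix,
    write_regions_bed,
)
from .io import Channel
from .stats import Table2x2, cmh_test, odds_ratio_ci

log = logging.getLogger("hmcpipe")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and tunables for a full run; unknown keys are rejected."""

    bs_path: str
    oxbs_path: str
    sheet_path: str
    annotation_path: str
    out_dir: str
    expr_path: str | None = None
    geneset_path: str | None = None

    drop_snp: bool = True
    drop_sex: bool = True
    top_fraction: float = 0.01
    min_probes: int = 7
    cutoff_quantile: float = 0.99
    smooth_window: int = 3
    n_perm: int = 250
    alpha: float = 0.05
    max_gap: int = 1000
    k_min: int = 2
    k_max: int = 5
    n_resample: int = 1000
    subsample_fraction: float = 0.8
    fc_threshold: float = 2.0
    rs_threshold: float = 0.5
    min_total_methylation: float = 0.3
    strata_column: str = "cpg_feature"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so re-running into a different directory matches)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _enrichment_report(probe_set, ann, strata_column):
    """Per-enhancer-source OR/CI/p with a CMH test stratified on
    ``strata_column``."""
    sources = [c for c in ann.columns if c.startswith("enhancer_")]
    in_set = ann.index.isin(set(probe_set))
    out = []
    for src in sources:
        flag = ann[src].to_numpy()
        t = Table2x2(
            int((in_set & flag).sum()), int((in_set & ~flag).sum()),
            int((~in_set & flag).sum()), int((~in_set & ~flag).sum()),
        )
        res = odds_ratio_ci(t)
        strata = []
        for _, sub in ann.groupby(strata_column):
            s_in = sub.index.isin(set(probe_set))
            s_flag = sub[src].to_numpy()
            tbl = (
                int((s_in & s_flag).sum()), int((s_in & ~s_flag).sum()),
                int((~s_in & s_flag).sum()), int((~s_in & ~s_flag).sum()),
            )
            if sum(tbl) > 0 and (tbl[0] + tbl[1]) > 0 and (tbl[2] + tbl[3]) > 0:
                strata.append(Table2x2(*tbl))
        try:
            cmh = cmh_test(strata)
            cmh_or, cmh_p = cmh.odds_ratio, cmh.p_value
        except ValueError:
            cmh_or, cmh_p = float("nan"), float("nan")
        out.append(
            {
                "source": src, "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "cmh_odds_ratio": cmh_or,
                "cmh_p_value": cmh_p, "strata": strata_column,
            }
        )
    return pd.DataFrame(out)


def run_all(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(config), "config_hash": config.digest(),
            "seed": config.seed, "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        meta["stages"].append(name)

    try:
        stage("load")
        sheet = read_sample_sheet(config.sheet_path)
        ann = read_annotation(config.annotation_path)
        bs = read_beta_matrix(config.bs_path, Channel.BS, sheet)
        oxbs = read_beta_matrix(config.oxbs_path, Channel.OXBS, sheet)

        stage("hydroxy")
        bs = filter_probes(bs, ann, config.drop_snp, config.drop_sex)
        oxbs = filter_probes(oxbs, ann, config.drop_snp, config.drop_sex)
        hmc = compute_5hmc(bs, oxbs)
        mc = compute_5mc(oxbs)
        write_beta_matrix(out / "5hmc.tsv", hmc)
        write_beta_matrix(out / "5mc.tsv", mc)
        top_mt = top_fraction_probes(
            hmc, sheet.cohort_mask(Cohort.MT), config.top_fraction, "MT"
        )
        top_wt = top_fraction_probes(
            hmc, sheet.cohort_mask(Cohort.WT), config.top_fraction, "WT"
        )
        volcano = volcano_stats(hmc, sheet)
        volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        strat = stratify_counts(top_mt, ann)
        strat.to_csv(out / "top_mt_cpg_features.tsv", sep="\t")

        stage("regions")
        clusters = cluster_probes(ann.loc[hmc.probe_ids], config.max_gap)
        dhmrs = bumphunt(
            hmc, sheet, clusters, config.min_probes, config.cutoff_quantile,
            None, config.smooth_window, config.n_perm, config.alpha,
            config.seed, ann,
        )
        dmrs = bumphunt(
            mc, sheet, clusters, config.min_probes, config.cutoff_quantile,
            None, config.smooth_window, config.n_perm, config.alpha,
            config.seed, ann,
        )
        write_regions_bed(out / "dhmrs.bed", dhmrs)
        write_regions_bed(out / "dmrs.bed", dmrs)
        dhmr_probes = {p for r in dhmrs for p in r.probe_ids}
        dhmr_genes = regions_to_genes(dhmrs, ann)

        stage("enrich")
        enrich = _enrichment_report(dhmr_probes, ann.loc[hmc.probe_ids],
                                    config.strata_column)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage("cluster")
        consensus_probes = select_consensus_probes(
            dhmr_probes or set(hmc.probe_ids),
            set(top_mt.probe_ids), set(top_wt.probe_ids),
        ) if dhmr_probes else set()
        summary_cluster = None
        if len(consensus_probes) >= 2:
            cons = consensus_cluster(
                hmc.values.loc[sorted(consensus_probes)],
                range(config.k_min, config.k_max + 1),
                config.n_resample, config.subsample_fraction, config.seed,
            )
            for k, m in cons.consensus_matrices.items():
                m.to_csv(out / f"consensus_k{k}.tsv", sep="\t")
            pd.DataFrame(cons.assignments).to_csv(out / "assignments.tsv", sep="\t")
            summary_cluster = {
                "chosen_k": cons.chosen_k,
                "silhouette": cons.silhouette,
                "cdf_auc": {k: v["auc"] for k, v in cons.cdf_summaries.items()},
                "n_consensus_probes": len(consensus_probes),
            }
        else:
            log.info("cluster: fewer than 2 consensus probes; skipped")

        summary_integration = None
        if config.expr_path is not None and Path(config.expr_path).exists():
            stage("integrate")
            expr = pd.read_csv(config.expr_path, sep="\t", index_col=0)
            de = differential_expression(expr, sheet, config.fc_threshold,
                                         config.alpha)
            de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
            top20 = top_expressed_genes(expr)
            assoc = expression_association(
                set(top_mt.probe_ids) | set(top_wt.probe_ids),
                ann.loc[hmc.probe_ids], top20, set(expr.index),
            )
            records, table, p_assoc = classify_groups(
                hmc, mc, expr, de, dhmr_probes or set(hmc.probe_ids),
                ann, config.rs_threshold,
            )
            records.to_csv(out / "correlation_records.tsv", sep="\t", index=False)
            summary_integration = {
                "n_de_selected": int(de["selected"].sum()),
                "top20_association_or": assoc.odds_ratio,
                "top20_association_p": assoc.p_value,
                "group_counts": {
                    "G1": int(table.iloc[0, 0]), "G2": int(table.iloc[0, 1]),
                    "G3": int(table.iloc[1, 0]), "G4": int(table.iloc[1, 1]),
                },
                "group_table_p": p_assoc,
            }
            if config.geneset_path:
                genes = read_gene_set(config.geneset_path)
                contrib = gcimp_contribution(
                    hmc, mc, genes, ann, config.min_total_methylation,
                    "per_cohort", sheet,
                )
                contrib.to_csv(out / "gcimp_contribution.tsv", sep="\t", index=False)
                kept = contrib[~contrib["excluded"]]
                if len(kept):
                    summary_integration["gcimp_pct_range"] = [
                        float(kept["pct_5hmc"].min()), float(kept["pct_5hmc"].max())
                    ]
        else:
            log.info("integrate: no expression matrix; skipped")

        summary = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_probes_analyzed": len(hmc.probe_ids),
            "cohort_counts": sheet.counts(),
            "mean_5hmc": {
                "MT": float(hmc.values.loc[:, sheet.cohort_ids(Cohort.MT)]
                            .to_numpy().mean()),
                "WT": float(hmc.values.loc[:, sheet.cohort_ids(Cohort.WT)]
                            .to_numpy().mean()),
            },
            "n_dhmrs": len(dhmrs),
            "n_dmrs": len(dmrs),
            "n_dhmr_probes": len(dhmr_probes),
            "n_dhmr_genes": len(dhmr_genes),
            "clustering": summary_cluster,
            "integration": summary_integration,
            "meta": {
                **meta,
                # summary stays byte-identical across output locations;
                # the verbatim echo lives in run_manifest.json
                "config": {k: v for k, v in meta["config"].items()
                           if k != "out_dir"},
            },
        }
        (out / "run_manifest.json").write_text(json.dumps(meta, indent=1,
                                                          sort_keys=True))
        (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
        return out
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {meta['stages'][-1]!r} "
            f"(config {config.digest()}): {exc}"
        ) from exc
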