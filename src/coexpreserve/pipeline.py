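"""End-to-end orchestration: network preservation, enrichment, qPCR reports.

Each stage reads the documented TSV/GMT inputs, runs the corresponding library
modules, and writes tabular outputs plus a JSON run manifest capturing the
configuration, seed, package version and SHA-256 checksums of every input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexnet import network_summary, node_stats, pearson_matrix, threshold_adjacency
from .enrich import bh_adjust, fisher_enrichment, select_de_genes
from .errors import ConfigurationError, DataError
from .exprio import (
    CountMatrix,
    ExpressionMatrix,
    cpm_log2,
    filter_low_expression,
    read_counts,
    read_gene_sets,
    read_pvalue_table,
    subset_to_gene_set,
)
from .preserve import compare_node_stats, permutation_preservation_test
from .qpcr import analyze_qpcr

logger = logging.getLogger("coexpreserve")

__all__ = [
    "PipelineConfig",
    "run_network_preservation",
    "run_enrichment",
    "run_qpcr",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    counts: str | None = None
    sample_map: str | None = None
    gene_sets: str | None = None
    de_pvalues: str | None = None
    ct_table: str | None = None
    outdir: str = "results"
    gene_set_name: str | None = None
    r_min: float = 0.5
    p_max: float = 0.05
    de_q: float = 0.05
    require_annotation: bool = True
    adjust_terms: bool = False
    min_cpm: float = 1.0
    min_samples: int | None = None
    drop_isolated: bool = False
    n_perm: int = 999
    seed: int = 0
    control_group: str = "control"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"config field {name!r} is required for this stage")
            if not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, stage: str, inputs: dict[str, str], outdir: Path) -> None:
    manifest = {
        "stage": stage,
        "package": "coexpreserve",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _load_focal_expression(config: PipelineConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    cm = read_counts(config.counts, config.sample_map)
    conditions = cm.conditions
    if len(conditions) != 2:
        raise DataError(f"two-condition analysis requires exactly 2 conditions, got {conditions}")
    cm = filter_low_expression(cm, min_cpm=config.min_cpm, min_samples=config.min_samples)
    sets = read_gene_sets(config.gene_sets)
    if config.gene_set_name is None:
        if len(sets) != 1 and not sets.names():
            raise ConfigurationError("gene_set_name required: GMT holds no sets")
        set_name = sets.names()[0]
        if len(sets) > 1:
            logger.info("gene_set_name not given; using first set %r", set_name)
    else:
        if config.gene_set_name not in sets.names():
            raise ConfigurationError(f"gene set {config.gene_set_name!r} not in GMT")
        set_name = config.gene_set_name
    expr = cpm_log2(cm)
    focal, absent = subset_to_gene_set(expr, sets[set_name])
    if absent:
        logger.info("%d gene-set members absent from the filtered matrix", len(absent))
    cond_a, cond_b = conditions
    expr_a = ExpressionMatrix(focal.data[cm.samples_in(cond_a)])
    expr_b = ExpressionMatrix(focal.data[cm.samples_in(cond_b)])
    return expr_a, expr_b, conditions


def run_network_preservation(config: PipelineConfig) -> dict:
    """Subset -> correlate -> threshold -> node stats -> compare -> permutation test.

    Writes per-condition edge lists, a node-stats table, the preservation
    report and a JSON summary to the output directory.
    """
    config.require("counts", "sample_map", "gene_sets")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_a, expr_b, conditions = _load_focal_expression(config)
    logger.info(
        "network preservation: %d genes, conditions %s, r_min=%s p_max=%s n_perm=%d seed=%d",
        len(expr_a.gene_ids), conditions, config.r_min, config.p_max, config.n_perm, config.seed,
    )

    stats, summaries = [], {}
    for label, expr in zip(conditions, (expr_a, expr_b)):
        corr = pearson_matrix(expr)
        net = threshold_adjacency(corr, r_min=config.r_min, p_max=config.p_max)
        pd.DataFrame(net.edge_list(), columns=["gene_i", "gene_j"]).to_csv(
            outdir / f"edges_{label}.tsv", sep="\t", index=False
        )
        stats.append(node_stats(net))
        summaries[label] = network_summary(net)
    if stats[0].gene_ids != stats[1].gene_ids:
        raise DataError(
            "gene lists diverge between condition networks (constant-gene exclusion); "
            "filter constant genes upstream"
        )
    report = compare_node_stats(stats[0], stats[1])
    if config.drop_isolated:
        # distribution means over connected nodes only, per condition
        for suffix, ns in zip(("A", "B"), stats):
            connected = ns.k > 0
            report.means[f"mean_k_{suffix}"] = (
                float(ns.k[connected].mean()) if connected.any() else 0.0
            )
    perm = permutation_preservation_test(
        expr_a, expr_b, n_perm=config.n_perm, seed=config.seed,
        r_min=config.r_min, p_max=config.p_max,
    )
    report.p_values = {"p_delta_k": perm["p_delta_k"], "p_delta_c": perm["p_delta_c"]}
    report.n_permutations = config.n_perm
    report.seed = config.seed

    node_table = report.table.rename(
        columns={
            "k_A": f"k_{conditions[0]}", "k_B": f"k_{conditions[1]}",
            "c_A": f"c_{conditions[0]}", "c_B": f"c_{conditions[1]}",
        }
    )
    node_table.to_csv(outdir / "preservation.tsv", sep="\t", index=False, na_rep="NA")
    summary = {
        "conditions": list(conditions),
        "network_summaries": summaries,
        "means": report.means,
        "observed": {"delta_mean_k": perm["t_obs_k"], "delta_mean_c": perm["t_obs_c"]},
        "permutation": {
            "p_delta_k": perm["p_delta_k"],
            "p_delta_c": perm["p_delta_c"],
            "n_permutations": config.n_perm,
            "seed": config.seed,
        },
    }
    (outdir / "preservation_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(
        config, "network",
        {"counts": config.counts, "sample_map": config.sample_map, "gene_sets": config.gene_sets},
        outdir,
    )
    return summary


def run_enrichment(config: PipelineConfig) -> pd.DataFrame:
    """DE selection at FDR ``de_q`` plus per-set Fisher overrepresentation test."""
    config.require("de_pvalues", "gene_sets")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_table = read_pvalue_table(config.de_pvalues)
    sets = read_gene_sets(config.gene_sets)
    if config.require_annotation and "annotated" in de_table.columns:
        background = de_table.loc[de_table["annotated"], "gene_id"].tolist()
        de_table_bg = de_table
    else:
        background = de_table["gene_id"].tolist()
        de_table_bg = de_table
    de_genes = select_de_genes(de_table_bg, q=config.de_q, require_annotation=config.require_annotation)
    _, _, cutoff = bh_adjust(de_table["p_value"].to_numpy(float), q=config.de_q)
    logger.info("selected %d DE genes at FDR <= %s (implied p cutoff %.3g)", len(de_genes), config.de_q, cutoff)
    results = fisher_enrichment(de_genes, background, sets)
    out = pd.DataFrame(
        [
            {"set_name": r.set_name, "N": r.N, "K": r.K, "n": r.n, "x": r.x, "p_fisher": r.p_fisher}
            for r in results
        ]
    )
    if config.adjust_terms and len(out):
        qv, _, _ = bh_adjust(out["p_fisher"].to_numpy(float), q=config.de_q)
        out["q_fisher"] = qv
    out.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": de_genes}).to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
    _write_manifest(
        config, "enrich",
        {"de_pvalues": config.de_pvalues, "gene_sets": config.gene_sets},
        outdir,
    )
    return out


def run_qpcr(config: PipelineConfig) -> pd.DataFrame:
    """Per-gene dCt/fold-change/LRT report from a Ct table.

    The Ct table may carry an optional ``gene`` column for multi-gene panels;
    without it the table is treated as a single target gene.
    """
    config.require("ct_table")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(config.ct_table, sep="\t", comment="#")
    gene_groups = table.groupby("gene") if "gene" in table.columns else [("target", table)]
    rows = []
    for gene, sub in gene_groups:
        res = analyze_qpcr(sub, control_group=config.control_group)
        rows.append(
            {
                "gene": gene,
                "fold_change": res["fold_treatment_vs_control"],
                "lrt_statistic": res["lrt_statistic"],
                "lrt_p": res["lrt_p"],
                "n_samples": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "qpcr_report.tsv", sep="\t", index=False)
    _write_manifest(config, "qpcr", {"ct_table": config.ct_table}, outdir)
    return out


def run_all(config: PipelineConfig) -> dict:
    """All three analysis stages; returns their summaries keyed by stage."""
    summary = {"network": run_network_preservation(config)}
    summary["enrichment"] = run_enrichment(config).to_dict(orient="records")
    summary["qpcr"] = run_qpcr(config).to_dict(orient="records")
    return summary
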