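"""End-to-end orchestration: simulate/load -> DGE -> BIC -> enrichment ->
network -> parental tests, with per-stage TSV outputs and a JSON summary.

Stage order mirrors the analysis: quantile normalization (when raw
intensities are supplied), PCA quality control, per-probe mixed-model
F-tests with Bonferroni DEP calling, BIC sub-model classification of the
DEPs, fold-change-filtered gene lists and hypergeometric enrichment for
the sub-model-1 genes, the |r|-thresholded relevance network over the
sub-model-1 genes (one probe per gene, the highest-variance one), and the
parental-genome interaction tests over all probes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io, qpcr as qpcr_mod
from .dge import MixedDifferentialExpression
from .enrichment import (
    DEFAULT_FC_THRESHOLD,
    GeneSetCollection,
    collapse_probes_to_genes,
    enrich,
    select_regulated,
)
from .network import RelevanceNetwork
from .parental import ParentalEffectTester
from .simulate import SimulationConfig, simulate_design, simulate_expression, simulate_genesets, simulate_qpcr
from .submodel import SubmodelClassifier

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for a pipeline run."""

    expression: str | None = None
    design: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    qpcr_ct: str | None = None
    qpcr_dilution: str | None = None
    qpcr_reference_gene: str = "HPRT"
    alpha_bonferroni: float = 0.01
    fdr: float = 0.01
    fold_change: float = 1.4
    r_threshold: float = 0.98
    normalize: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_bonferroni < 1 or not 0 < self.fdr < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.fold_change < 1:
            raise ValueError("fold_change is on the linear scale and must be >= 1")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")


def _write(df: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t")


def run_pipeline(
    expr: io.ExpressionMatrix,
    design: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    qpcr_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    *,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on in-memory inputs; returns the result bundle."""
    cfg = config or PipelineConfig()
    outdir = None
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    design = io.validate_design(design)
    summary: dict = {"n_samples": len(design), "n_probes": len(expr.probe_ids)}
    bundle: dict = {"config": cfg}

    values = expr.values
    if cfg.normalize:
        values = io.quantile_normalize(values)
        values = np.log2(values) if (values.to_numpy() > 0).all() else values
        expr = io.ExpressionMatrix(values=pd.DataFrame(values, index=expr.values.index,
                                                       columns=expr.values.columns),
                                   annotation=expr.annotation)
    scores, varfrac = io.pca_scores(expr, n_components=min(4, len(design) - 1))
    bundle["pca_scores"] = scores
    summary["pca_variance_fractions"] = [round(float(v), 4) for v in varfrac]
    _write(scores, outdir, "pca_scores.tsv")

    # stage: mixed-model differential expression
    dge = MixedDifferentialExpression(alpha=cfg.alpha_bonferroni, correction="bonferroni")
    dge.fit(expr, design)
    bundle["dge"] = dge
    deps = dge.deps_
    summary["n_tested"] = dge.n_tested_
    summary["n_deps_bonferroni"] = len(deps)
    logger.info("DEP call: %d of %d tested probes", len(deps), dge.n_tested_)
    _write(dge.results_, outdir, "dge_results.tsv")

    # stage: BIC sub-model classification of the DEPs
    sub = SubmodelClassifier()
    if deps:
        sub.fit(expr.X[deps], design)
        bundle["submodel"] = sub
        proportions = sub.proportions_
        submodel1 = list(sub.labels_.index[sub.labels_ == 1])
        _write(sub.results_, outdir, "submodel_bic.tsv")
    else:
        bundle["submodel"] = None
        proportions = pd.Series(0.0, index=[1, 2, 3, 4])
        submodel1 = []
    summary["submodel_proportions"] = {int(k): round(float(v), 4) for k, v in proportions.items()}
    summary["n_submodel1"] = len(submodel1)
    bundle["submodel1_probes"] = submodel1

    # stage: fold-change-filtered gene lists and enrichment
    annotation = expr.annotation if expr.annotation is not None else pd.Series(dtype=str)
    sub1_results = dge.results_.loc[submodel1]
    per_gene = collapse_probes_to_genes(sub1_results, annotation)
    fc_threshold = float(np.log2(cfg.fold_change))
    up110, up90 = select_regulated(per_gene, fc_threshold)
    bundle["per_gene"] = per_gene
    bundle["up_at_d110"], bundle["up_at_d90"] = up110, up90
    summary["n_genes_submodel1"] = len(per_gene)
    summary["n_up_d110"], summary["n_up_d90"] = len(up110), len(up90)
    _write(per_gene, outdir, "submodel1_genes.tsv")

    if gene_sets:
        universe = set(annotation.values)
        collection = GeneSetCollection(sets=gene_sets, universe=universe)
        enr110 = enrich(up110, collection, q_threshold=cfg.fdr) if up110 else pd.DataFrame()
        enr90 = enrich(up90, collection, q_threshold=cfg.fdr) if up90 else pd.DataFrame()
        bundle["enrichment_up_d110"], bundle["enrichment_up_d90"] = enr110, enr90
        summary["n_enriched_up_d110"] = int(enr110["significant"].sum()) if len(enr110) else 0
        summary["n_enriched_up_d90"] = int(enr90["significant"].sum()) if len(enr90) else 0
        _write(enr110, outdir, "enrichment_up_d110.tsv")
        _write(enr90, outdir, "enrichment_up_d90.tsv")

    # stage: relevance network over sub-model-1 genes (one probe per gene:
    # the highest-variance one; unannotated probes represent themselves)
    net = None
    if submodel1:
        sub_expr = expr.values.loc[submodel1]
        gene_of = [expr.gene_of(p) for p in submodel1]
        variances = sub_expr.var(axis=1)
        rep = {}
        for probe, gene in zip(submodel1, gene_of):
            key = gene if gene != "unannotated" else probe
            if key not in rep or variances[probe] > variances[rep[key]]:
                rep[key] = probe
        node_expr = sub_expr.loc[list(rep.values())].T
        node_expr.columns = list(rep.keys())
        net = RelevanceNetwork(threshold=cfg.r_threshold).fit(node_expr)
        bundle["network"] = net
        summary["network_nodes_total"] = net.graph_.number_of_nodes()
        summary["network_edges_total"] = net.graph_.number_of_edges()
        summary["network_largest_component_nodes"] = net.largest_component_.number_of_nodes()
        summary["network_largest_component_edges"] = net.largest_component_.number_of_edges()
        summary["network_n_communities"] = len(net.communities_)
        summary["network_modularity"] = round(float(net.modularity_), 4)
        if outdir is not None:
            net.edge_list().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            _write(net.hub_table_, outdir, "network_hubs.tsv")
    else:
        bundle["network"] = None

    # stage: parental-genome interaction tests
    par = ParentalEffectTester(q_threshold=cfg.fdr).fit(expr, design)
    bundle["parental"] = par
    counts = par.results_["call"].value_counts()
    summary["parental_calls"] = {
        k: int(counts.get(k, 0)) for k in ("maternal", "paternal", "both", "none")
    }
    _write(par.results_, outdir, "parental_results.tsv")

    # stage: qPCR validation (optional)
    if qpcr_tables is not None:
        ct_table, dilution = qpcr_tables
        effs = {}
        for gene, grp in dilution.groupby("gene"):
            effs[gene] = qpcr_mod.estimate_efficiency(grp["concentration"], grp["Ct"], gene).E
        ratios = qpcr_mod.relative_expression(ct_table, effs, cfg.qpcr_reference_gene)
        bundle["qpcr_efficiencies"] = effs
        bundle["qpcr_ratios"] = ratios
        summary["qpcr_genes"] = len(ratios.columns)
        if outdir is not None:
            ratios.to_csv(outdir / "qpcr_ratios.tsv", sep="\t")

    bundle["summary"] = summary
    if outdir is not None:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return bundle


def simulate_and_run(sim_cfg: SimulationConfig, config: PipelineConfig | None = None) -> dict:
    """Generate a synthetic study, run the pipeline, and score recovery.

    Adds to the bundle: the truth table and a ``recovery`` dict with DEP
    sensitivity, the sub-model confusion matrix, parental-call rates, the
    network community ARI against planted blocks, and the qPCR validation
    correlation.
    """
    cfg = config or PipelineConfig(seed=sim_cfg.seed)
    design = simulate_design(sim_cfg)
    expr, truth = simulate_expression(sim_cfg, design)
    gene_sets, planted_name = simulate_genesets(sim_cfg, truth)
    ct_table, dilution, true_eff, assayed = simulate_qpcr(sim_cfg, truth, expr)
    bundle = run_pipeline(expr, design, gene_sets, (ct_table, dilution), config=cfg)
    bundle["truth"] = truth
    bundle["planted_set"] = planted_name
    bundle["true_efficiencies"] = true_eff

    recovery: dict = {}
    deps = set(bundle["dge"].deps_)
    non_null = truth.index[truth["class"] != "null"]
    recovery["dep_sensitivity"] = float(np.mean([p in deps for p in non_null]))
    null_probes = truth.index[truth["class"] == "null"]
    recovery["dep_false_positive_rate"] = float(np.mean([p in deps for p in null_probes]))

    # sub-model confusion: planted class x assigned label ("none" if not a DEP)
    sub = bundle["submodel"]
    confusion = {}
    for m in (1, 2, 3, 4):
        planted = truth.index[truth["class"] == f"submodel{m}"]
        row = {str(lbl): 0 for lbl in (1, 2, 3, 4, "none")}
        for p in planted:
            if sub is not None and p in sub.labels_.index:
                row[str(int(sub.labels_[p]))] += 1
            else:
                row["none"] += 1
        confusion[str(m)] = row
    recovery["submodel_confusion"] = confusion
    recovery["submodel_accuracy"] = {
        str(m): (confusion[str(m)][str(m)] / max(1, sum(confusion[str(m)].values())))
        for m in (1, 2, 3, 4)
    }

    par = bundle["parental"].results_
    for side in ("maternal", "paternal"):
        planted = truth.index[truth["class"] == f"{side}_interaction"]
        calls = par.loc[planted, "call"]
        recovery[f"{side}_sensitivity"] = float(calls.isin([side, "both"]).mean()) if len(planted) else np.nan
        other = "paternal" if side == "maternal" else "maternal"
        recovery[f"{side}_cross_called_{other}"] = float((calls == other).mean()) if len(planted) else np.nan

    # network: ARI of communities (full graph) against planted blocks
    net = bundle["network"]
    block_truth = truth[truth["block"] != ""]
    if net is not None and len(block_truth):
        from .network import fastgreedy_communities

        partition, _ = fastgreedy_communities(net.graph_)
        label_of = {}
        for ci, comm in enumerate(partition):
            for v in comm:
                label_of[v] = ci
        gene_to_block = {}
        for p, row in block_truth.iterrows():
            key = row["gene"] if row["gene"] != "unannotated" else p
            gene_to_block[key] = row["block"]
        common = [g for g in gene_to_block if g in label_of]
        if common:
            recovery["network_ari"] = float(
                adjusted_rand_score([gene_to_block[g] for g in common],
                                    [label_of[g] for g in common])
            )
    # qPCR: correlation of recovered log2 ratios with simulated expression
    if "qpcr_ratios" in bundle and len(assayed):
        rs = []
        for gene, probe in assayed.items():
            if gene in bundle["qpcr_ratios"].columns:
                r, _, _ = qpcr_mod.validate_against_microarray(
                    bundle["qpcr_ratios"][gene].to_numpy(),
                    expr.values.loc[probe].to_numpy(),
                )
                rs.append(r)
        if rs:
            recovery["qpcr_mean_validation_r"] = float(np.mean(rs))

    # enrichment: planted set recovered?
    enr = bundle.get("enrichment_up_d110")
    if enr is not None and len(enr) and planted_name in enr.index:
        recovery["planted_set_significant"] = bool(enr.loc[planted_name, "significant"])
        recovery["n_decoys_significant"] = int(
            enr.loc[enr.index != planted_name, "significant"].sum()
        )
    bundle["recovery"] = recovery
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        (outdir / "recovery.json").write_text(
            json.dumps(recovery, indent=2, sort_keys=True, default=str)
        )
    return bundle
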