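"""One-command end-to-end run.

Stage order mirrors the analysis: (simulate) -> normalization and DE per
timepoint contrast -> DE filtering, Venn partition and cross-arm logFC
tests -> per-condition co-expression networks with matched controls ->
differential network comparison -> walktrap communities -> hub scoring
and selection -> hub-removal robustness -> optional term enrichment.
Every intermediate artifact is written under the run directory; a
summary JSON and a run log capture thresholds, seed, versions, and
warnings. Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .communities import best_partition, large_communities, walktrap_dendrogram
from .diffexpr import (
    GeneSet,
    compare_logfc,
    de_test,
    estimate_dispersions,
    filter_de,
    log_cpm,
    tmm_factors,
    venn_partition,
)
from .diffnet import compare_networks, matched_networks
from .enrichment import fisher_enrichment, read_gmt
from .hubs import centralities, hub_scores, removal_report, select_hubs
from .io import (
    PipelineConfig,
    atomic_write_text,
    read_counts,
    read_design,
    write_counts,
    write_design,
    write_edge_list,
    write_gene_set,
    write_graphml,
    write_json,
)
from .network import network_summary
from .synthetic import CountMatrix, GeneratorParams, simulate_experiment, make_design

logger = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage: %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("input")
def _load_inputs(config: PipelineConfig, out: Path):
    if config.mode == "synthetic":
        gen = dict(config.generator)
        gen.setdefault("seed", config.seed)
        params = GeneratorParams(**gen)
        design = make_design()
        cm, truth = simulate_experiment(design, params)
        truth.to_json(out / "truth.json")
    else:
        design = read_design(config.design_path)
        cm = read_counts(config.counts_path, design)
        truth = None
    write_counts(out / "counts.tsv", cm)
    write_design(out / "design.csv", cm.design)
    return cm, truth


@_stage("diffexpr")
def _run_de(config: PipelineConfig, cm: CountMatrix, out: Path):
    factors = tmm_factors(cm)
    atomic_write_text(
        out / "norm_factors.tsv", factors.rename_axis("sample_id").to_csv(sep="\t")
    )
    dispersions = estimate_dispersions(cm, factors=factors)
    expr = log_cpm(cm, factors)
    treated = sorted(set(cm.design["condition"]) - {"control"})
    timepoints = sorted(set(cm.design["timepoint"]))
    de_dir = out / "de"
    tables: dict[str, dict[int, pd.DataFrame]] = {}
    de_sets: dict[str, dict[str, frozenset]] = {}
    for cond in treated:
        tables[cond] = {}
        up_all: set = set()
        down_all: set = set()
        for tp in timepoints:
            tab = de_test(cm, (cond, tp), factors=factors, dispersions=dispersions)
            tables[cond][tp] = tab
            atomic_write_text(de_dir / f"{cond}_{tp}h.tsv", tab.to_csv(sep="\t", index=False))
            up, down = filter_de(tab, fdr_max=config.de_fdr, lfc_min=config.de_lfc)
            up_all |= up.genes
            down_all |= down.genes
        de_sets[cond] = {"up": frozenset(up_all), "down": frozenset(down_all)}
        write_gene_set(de_dir / f"{cond}_up.txt", GeneSet(cond, frozenset(up_all), "up"))
        write_gene_set(de_dir / f"{cond}_down.txt", GeneSet(cond, frozenset(down_all), "down"))
    return factors, expr, tables, de_sets


@_stage("venn_compare")
def _run_comparisons(cm, tables, de_sets, out: Path):
    treated = sorted(de_sets)
    result: dict = {}
    if len(treated) == 2:
        a, b = treated
        for direction in ("up", "down"):
            ga = GeneSet(a, de_sets[a][direction], direction)
            gb = GeneSet(b, de_sets[b][direction], direction)
            only_a, shared, only_b = venn_partition(ga, gb)
            result[f"venn_{direction}"] = {
                f"only_{a}": len(only_a),
                "shared": len(shared),
                f"only_{b}": len(only_b),
            }
            if direction == "up" and len(shared) >= 3:
                mean_lfc = {}
                for cond in (a, b):
                    per_tp = pd.concat(tables[cond].values())
                    per_tp = per_tp[per_tp["gene_id"].isin(shared)]
                    mean_lfc[cond] = (
                        per_tp.groupby("gene_id")["logFC"].mean().sort_index()
                    )
                t_stat, t_p = compare_logfc(
                    mean_lfc[a].to_numpy(), mean_lfc[b].to_numpy(), "t", paired=True
                )
                try:
                    w_stat, w_p = compare_logfc(
                        mean_lfc[a].to_numpy(), mean_lfc[b].to_numpy(), "wilcoxon", paired=True
                    )
                except ValueError:
                    w_stat, w_p = float("nan"), float("nan")
                result["shared_up_logfc_tests"] = {
                    "n_shared": len(shared),
                    "paired_t": {"statistic": t_stat, "pvalue": t_p},
                    "wilcoxon": {"statistic": w_stat, "pvalue": w_p},
                }
    write_json(out / "de" / "comparisons.json", result)
    return result


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises :class:`PipelineStageError` naming the
    stage, with earlier artifacts left on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    warnings_log: list[str] = []
    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            "de_fdr": config.de_fdr,
            "de_lfc": config.de_lfc,
            "net_fdr": config.net_fdr,
            "rho_min": config.rho_min,
            "min_community": config.min_community,
            "hub_k": config.hub_k,
            "walktrap_t": config.walktrap_t,
        },
        "versions": _versions(),
    }

    cm, truth = _load_inputs(config, out)
    summary["design"] = {
        "n_genes": len(cm.genes),
        "n_samples": len(cm.samples),
        "conditions": sorted(set(cm.design["condition"])),
        "timepoints": sorted(int(t) for t in set(cm.design["timepoint"])),
    }

    factors, expr, tables, de_sets = _run_de(config, cm, out)
    summary["de"] = {
        cond: {"n_up": len(s["up"]), "n_down": len(s["down"])} for cond, s in de_sets.items()
    }
    summary["comparisons"] = _run_comparisons(cm, tables, de_sets, out)

    annotation = None
    if config.annotation_path:
        annotation = read_gmt(config.annotation_path, universe=cm.genes)

    summary["networks"] = {}
    summary["communities"] = {}
    summary["hubs"] = {}
    summary["removal"] = {}
    summary["diffnet"] = {}
    enrichment_rows = []
    design = cm.design
    control_samples = design.loc[design["condition"] == "control", "sample_id"].tolist()

    for cond in sorted(de_sets):
        net_genes = sorted(de_sets[cond]["up"] | de_sets[cond]["down"])
        if len(net_genes) < 3:
            warnings_log.append(f"{cond}: fewer than 3 DE genes; network skipped")
            continue
        treat_samples = design.loc[design["condition"] == cond, "sample_id"].tolist()
        net_control, net_treat = _build_networks(
            config, net_genes, expr, control_samples, treat_samples, cond, out
        )
        for label, net in ((f"{cond}", net_treat), (f"control_{cond}", net_control)):
            summary["networks"][label] = network_summary(net).to_dict() if len(net) > 1 else {}
        if net_treat.number_of_edges() == 0:
            warnings_log.append(f"{cond}: network has no edges at current thresholds")
        comparison = _run_diffnet(net_control, net_treat, cond, out)
        summary["diffnet"][cond] = {
            "n_edges": comparison.n_edges,
            "density": comparison.density,
            "edge_jaccard": comparison.edge_jaccard,
            "ks_statistic": comparison.ks_statistic,
        }
        partition, big = _run_communities(config, net_treat, cond, out)
        summary["communities"][cond] = {
            "n_communities": partition.n_communities,
            "modularity": partition.q,
            "n_large": len(big),
            "large_sizes": [len(gs) for gs in big],
        }
        hub_table = _run_hubs(config, net_treat, partition, big, cond, out, warnings_log)
        summary["hubs"][cond] = {"n_selected": len(hub_table)}
        if len(hub_table) >= net_treat.number_of_nodes():
            warnings_log.append(f"{cond}: hub set spans the whole network; removal skipped")
        elif len(hub_table):
            report = _run_removal(config, net_treat, hub_table, cond, out)
            summary["removal"][cond] = {
                "before": report.before,
                "after": report.after,
                "baseline": report.baseline,
            }
        if annotation is not None:
            enrichment_rows.extend(
                _run_enrichment(annotation, de_sets[cond], big, cond, out)
            )

    if annotation is not None and enrichment_rows:
        enr = pd.concat(enrichment_rows, ignore_index=True)
        atomic_write_text(out / "enrichment.tsv", enr.to_csv(sep="\t", index=False))
        summary["enrichment"] = {"n_tests": len(enr)}

    summary["warnings"] = warnings_log
    write_json(out / "summary.json", summary)
    return out


@_stage("network")
def _build_networks(config, net_genes, expr, control_samples, treat_samples, cond, out):
    net_control, net_treat = matched_networks(
        net_genes,
        expr[control_samples],
        expr[treat_samples],
        fdr_max=config.net_fdr,
        rho_min=config.rho_min,
        use_abs=config.use_abs,
    )
    net_dir = out / "networks"
    for label, net in ((cond, net_treat), (f"control_{cond}", net_control)):
        write_edge_list(net_dir / f"{label}_edges.tsv", net)
        write_graphml(net_dir / f"{label}.graphml", net)
        if len(net) > 1:
            write_json(net_dir / f"{label}_summary.json", network_summary(net).to_dict())
    return net_control, net_treat


@_stage("diffnet")
def _run_diffnet(net_control, net_treat, cond, out):
    comparison = compare_networks(net_control, net_treat, labels=("control", cond))
    write_json(out / "diffnet" / f"{cond}.json", comparison.to_dict())
    return comparison


@_stage("communities")
def _run_communities(config, net, cond, out):
    tree = walktrap_dendrogram(net, steps=config.walktrap_t)
    partition = best_partition(tree)
    big = large_communities(partition, min_size=config.min_community)
    comm_dir = out / "communities"
    lines = ["gene_id\tcommunity"]
    for v in sorted(partition.labels, key=str):
        lines.append(f"{v}\t{partition.labels[v]}")
    atomic_write_text(comm_dir / f"{cond}.tsv", "\n".join(lines) + "\n")
    write_json(
        comm_dir / f"{cond}_dendrogram.json",
        {
            "merges": [list(mrg) for mrg in tree.merges],
            "q_profile": tree.q_profile,
        },
    )
    return partition, big


@_stage("hubs")
def _run_hubs(config, net, partition, big, cond, out, warnings_log):
    if net.number_of_edges() == 0:
        warnings_log.append(f"{cond}: no edges, hub selection skipped")
        return pd.DataFrame(columns=["gene_id", "community", "score", "rank"])
    cent = centralities(net)
    scores = hub_scores(cent)
    communities = big
    if not big:
        # fall back to communities at least hub_k strong (top-k of anything
        # smaller selects the whole community), else the single largest
        fallback = large_communities(partition, min_size=config.hub_k)
        if not fallback:
            fallback = large_communities(partition, min_size=1)[:1]
        communities = fallback
        warnings_log.append(
            f"{cond}: no community reached {config.min_community} nodes; "
            f"hubs selected from {len(fallback)} largest communities"
        )
    hub_table = select_hubs(partition, scores, k=config.hub_k, communities=communities)
    merged = hub_table.merge(
        scores.reset_index().rename(columns={"index": "gene_id"}), on="gene_id", how="left",
        suffixes=("", "_full"),
    )
    atomic_write_text(out / "hubs" / f"{cond}.tsv", merged.to_csv(sep="\t", index=False))
    return hub_table


@_stage("removal")
def _run_removal(config, net, hub_table, cond, out):
    report = removal_report(
        net,
        set(hub_table["gene_id"]),
        baseline_repeats=config.baseline_repeats,
        seed=config.seed + 1,
    )
    write_json(out / "removal" / f"{cond}.json", report.to_dict())
    return report


@_stage("enrichment")
def _run_enrichment(annotation, de_sets_cond, big, cond, out):
    rows = []
    studies = [(f"{cond}_up", de_sets_cond["up"]), (f"{cond}_down", de_sets_cond["down"])]
    studies += [(f"{cond}_{gs.label}", gs.genes) for gs in big]
    for label, genes in studies:
        if not genes:
            continue
        table = fisher_enrichment(genes, annotation)
        table.insert(0, "study", label)
        rows.append(table)
    return rows


def _versions() -> dict:
    import networkx
    import scipy

    return {
        "coexnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
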