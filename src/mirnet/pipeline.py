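"""Stage runners orchestrating the library end to end.

Each stage reads only files (plus the config), writes its artifacts with a
provenance header (package version, config hash, seed, active thresholds),
and is byte-deterministic: identical config + seed reproduce identical
output files. No timestamps are embedded anywhere.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .correlation import correlate_all, filter_inverse, read_edge_set
from .diffexp import diffexp_screen, normalize_log2, size_factors_median_of_ratios
from .enrichment import enrich, results_frame, top_table
from .io import (
    ExpressionMatrix,
    ValidationError,
    ValueKind,
    align_samples,
    filter_by_purity,
    read_expression_matrix,
    read_gene_sets_gmt,
    read_sample_annotations,
    write_expression_matrix,
    write_gene_sets_gmt,
    write_sample_annotations,
)
from .network import (
    build_bipartite,
    centralities,
    export_bipartite_graphml,
    export_projection_graphml,
    filter_core,
    find_hubs,
    mirna_degree,
    project_unipartite,
    summarize_network,
)
from .simulate import SimConfig, SyntheticTruth, simulate_cohort, simulate_expression, simulate_gene_sets
from .survival import survival_screen

log = logging.getLogger(__name__)

__all__ = [
    "run_simulate",
    "run_network",
    "run_enrich",
    "run_diffexp",
    "run_survive",
    "run_report",
]


def _provenance(config: PipelineConfig, **extra) -> str:
    parts = [f"mirnet {__version__}", f"config={config.config_hash()}", f"seed={config.seed}"]
    parts += [f"{k}={v}" for k, v in extra.items()]
    return " | ".join(parts)


def _write_tsv(frame: pd.DataFrame, path: Path, provenance: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}; run the '{stage}' stage first (looked in {path.parent})"
        )
    return path


def run_simulate(config: PipelineConfig, sim_config: SimConfig | None = None) -> Path:
    """Write a complete synthetic dataset (6 files) into ``config.data_dir``."""
    sim = sim_config or SimConfig()
    data_dir = Path(config.data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    mirna, mrna, truth = simulate_expression(sim, seed=config.seed)
    write_expression_matrix(mirna, data_dir / "mirna.tsv", header_comment=prov)
    write_expression_matrix(mrna, data_dir / "mrna.tsv", header_comment=prov)
    cohort_counts, annotations, _ = simulate_cohort(sim, seed=config.seed + 1)
    write_expression_matrix(cohort_counts, data_dir / "cohort_counts.tsv", header_comment=prov)
    write_sample_annotations(annotations, data_dir / "annotations.tsv")
    sets = simulate_gene_sets(truth, n_decoy_sets=49, seed=config.seed + 2)
    write_gene_sets_gmt(sets, data_dir / "gene_sets.gmt")
    truth.to_json(data_dir / "truth.json")
    log.info("simulate: wrote 6 files to %s", data_dir)
    return data_dir


def _input_path(config: PipelineConfig, attr: str, default_name: str) -> Path:
    explicit = getattr(config, attr)
    if explicit:
        return Path(explicit)
    return Path(config.data_dir) / default_name


def run_network(config: PipelineConfig) -> Path:
    """Correlation, edge filter, bipartite/core/projection, centralities, hubs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna = read_expression_matrix(
        _require(_input_path(config, "mirna_path", "mirna.tsv"), "simulate"), ValueKind.RPM
    )
    mrna = read_expression_matrix(
        _require(_input_path(config, "mrna_path", "mrna.tsv"), "simulate"), ValueKind.FPKM
    )
    mirna, mrna = align_samples(mirna, mrna)
    rho = correlate_all(mirna, mrna)
    edges = filter_inverse(rho, rho_max=config.rho_max)
    prov = _provenance(config, rho_max=config.rho_max, min_degree=config.min_degree)
    edges.write_tsv(out / "edges.tsv", header_comment=prov)

    network = build_bipartite(edges)
    degrees = mirna_degree(network)
    core = filter_core(network, config.min_degree, keep_equal=config.keep_equal_degree)
    projection = project_unipartite(core)
    table = centralities(projection, degrees)
    hubs = find_hubs(core)
    summary = summarize_network(network, core, hubs, table, top_k=config.top_k)
    summary["provenance"] = prov

    _write_tsv(table, out / "centralities.tsv", prov, index=True)
    _write_json(summary, out / "network_summary.json")
    export_bipartite_graphml(network, out / "bipartite.graphml", config.plot_min_degree)
    export_projection_graphml(projection, out / "projection.graphml", table)
    log.info(
        "network: %d edges, %d miRNAs, %d core, %d hubs",
        network.n_edges,
        len(network.mirna_nodes),
        len(core.mirna_nodes),
        len(hubs),
    )
    return out


def run_enrich(config: PipelineConfig) -> Path:
    """Per-hub over-representation of target genes in the GMT collection."""
    out = Path(config.out_dir)
    edges = read_edge_set(_require(out / "edges.tsv", "network"))
    summary = json.loads(_require(out / "network_summary.json", "network").read_text())
    collection = read_gene_sets_gmt(
        _require(_input_path(config, "gmt_path", "gene_sets.gmt"), "simulate")
    )
    mrna = read_expression_matrix(
        _require(_input_path(config, "mrna_path", "mrna.tsv"), "simulate"), ValueKind.FPKM
    )
    universe = sorted(set(mrna.feature_ids) & collection.all_genes())
    prov = _provenance(config, q_cutoff=config.q_cutoff, universe=len(universe))
    partners_by_mirna: dict[str, set[str]] = {}
    for e in edges.edges:
        partners_by_mirna.setdefault(e.mirna_id, set()).add(e.mrna_id)
    report = {}
    for i, hub in enumerate(summary["hubs"], start=1):
        genes = sorted(set().union(*(partners_by_mirna[m] for m in hub["members"])))
        genes = [g for g in genes if g in set(universe)]
        if not genes:
            log.warning("enrich: hub %d has no target genes inside the universe", i)
            continue
        results = enrich(genes, collection, universe)
        _write_tsv(results_frame(results), out / f"enrichment_hub{i}.tsv", prov)
        top = top_table(results, q_cutoff=config.q_cutoff, top_k=config.top_k)
        report[f"hub{i}"] = {
            "members": hub["members"],
            "n_target_genes": len(genes),
            "top_sets": top.to_dict(orient="records"),
        }
    _write_json({"provenance": prov, "hubs": report}, out / "enrichment_summary.json")
    return out


def _core_mirnas_in(matrix: ExpressionMatrix, out: Path) -> list[str]:
    """Core miRNAs from the network stage that exist in the cohort matrix."""
    summary_path = out / "network_summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        core = [m for h in summary["hubs"] for m in h["members"]]
        present = [m for m in core if m in matrix.feature_ids]
        if present:
            return present
    return list(matrix.feature_ids)


def run_diffexp(config: PipelineConfig) -> Path:
    """Differential expression of screened miRNAs between response groups."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_expression_matrix(
        _require(_input_path(config, "cohort_counts_path", "cohort_counts.tsv"), "simulate"),
        ValueKind.RAW_COUNTS,
    )
    annotations = read_sample_annotations(
        _require(_input_path(config, "annotation_path", "annotations.tsv"), "simulate")
    )
    mirnas = _core_mirnas_in(counts, out)
    frame = diffexp_screen(counts, annotations, mirnas)
    prov = _provenance(
        config, group_a=frame.attrs["group_a"], group_b=frame.attrs["group_b"]
    )
    _write_tsv(frame, out / "diffexp.tsv", prov)
    return out


def run_survive(config: PipelineConfig) -> Path:
    """Median-split survival screen of cohort miRNAs at the chosen endpoint."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_expression_matrix(
        _require(_input_path(config, "cohort_counts_path", "cohort_counts.tsv"), "simulate"),
        ValueKind.RAW_COUNTS,
    )
    annotations = read_sample_annotations(
        _require(_input_path(config, "annotation_path", "annotations.tsv"), "simulate")
    )
    factors = size_factors_median_of_ratios(counts)
    norm = normalize_log2(counts, factors)
    mirnas = _core_mirnas_in(counts, out)
    forest, curves = survival_screen(norm, annotations, mirnas, endpoint=config.endpoint)
    prov = _provenance(config, endpoint=config.endpoint)
    _write_tsv(forest, out / f"forest_{config.endpoint}.tsv", prov)
    km_dir = out / "km"
    km_dir.mkdir(exist_ok=True)
    for m, strata in curves.items():
        for stratum, curve in strata.items():
            frame = pd.DataFrame(
                {
                    "time": curve.event_times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                }
            )
            _write_tsv(frame, km_dir / f"{m}_{config.endpoint}_{stratum}.tsv", prov)
    return out


def run_report(config: PipelineConfig) -> Path:
    """Consolidated JSON + markdown report recomputed from stage files."""
    out = Path(config.out_dir)
    summary = json.loads(_require(out / "network_summary.json", "network").read_text())
    edges = read_edge_set(_require(out / "edges.tsv", "network"))
    if len(edges) != summary["total_edges"]:
        raise ValidationError(
            f"edge file ({len(edges)}) disagrees with network summary "
            f"({summary['total_edges']})"
        )
    enrichment = None
    enrich_path = out / "enrichment_summary.json"
    if enrich_path.exists():
        enrichment = json.loads(enrich_path.read_text())
    diffexp = None
    if (out / "diffexp.tsv").exists():
        diffexp = pd.read_csv(out / "diffexp.tsv", sep="\t", comment="#")
    forest = None
    forest_path = out / f"forest_{config.endpoint}.tsv"
    if forest_path.exists():
        forest = pd.read_csv(forest_path, sep="\t", comment="#")

    report = {
        "provenance": _provenance(config),
        "network": {
            "total_edges": summary["total_edges"],
            "total_mirnas": summary["total_mirnas"],
            "core_mirna_count": summary["core_mirna_count"],
            "core_edge_share_pct": summary["core_edge_share_pct"],
            "hubs": summary["hubs"],
        },
    }
    lines = [
        "# mirnet run report",
        "",
        f"Provenance: {report['provenance']}",
        "",
        "## Network",
        "",
        f"- {summary['total_edges']} miRNA-mRNA inverse-correlation edges "
        f"across {summary['total_mirnas']} miRNAs",
        f"- {summary['core_mirna_count']} core miRNAs carry "
        f"{summary['core_edge_share_pct']}% of all edges",
        f"- {len(summary['hubs'])} hubs (connected components of the core network):",
    ]
    for i, hub in enumerate(summary["hubs"], start=1):
        lines.append(
            f"  - hub {i}: {len(hub['members'])} miRNAs, {hub['edge_count']} edges "
            f"({100 * hub['edge_fraction']:.0f}% of core edges)"
        )
    if enrichment is not None:
        report["enrichment"] = enrichment["hubs"]
        lines += ["", "## Enrichment", ""]
        for hub_name, entry in enrichment["hubs"].items():
            tops = entry["top_sets"]
            best = tops[0]["set_name"] if tops else "(none below q cutoff)"
            lines.append(
                f"- {hub_name} ({len(entry['members'])} miRNAs, "
                f"{entry['n_target_genes']} target genes): top set {best}"
            )
    if diffexp is not None:
        report["diffexp"] = diffexp.to_dict(orient="records")
        n_sig = int((diffexp["q"] < config.q_cutoff).sum())
        lines += [
            "",
            "## Differential expression",
            "",
            f"- {len(diffexp)} miRNAs screened; {n_sig} with q < {config.q_cutoff}",
        ]
    if forest is not None:
        report["survival"] = forest.to_dict(orient="records")
        n_sig = int((forest["p_logrank"] < 0.05).sum())
        lines += [
            "",
            f"## Survival ({config.endpoint})",
            "",
            f"- {len(forest)} miRNAs screened; {n_sig} with log-rank p < 0.05",
        ]
    _write_json(report, out / "report.json")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return out
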