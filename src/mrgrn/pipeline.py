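"""End-to-end orchestration: DE per tissue -> contextualize per condition ->
MR inference -> optional enrichment and qPCR, with every intermediate
persisted before the report is assembled.

The run is fully deterministic: no stage draws random numbers, iteration
orders are sorted, and outputs carry no timestamps, so identical config
and inputs give byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .de import DeThresholds, run_de
from .enrich import overrepresentation_test, results_to_frame
from .io import (
    CountMatrix,
    read_count_matrix,
    read_edge_list,
    read_gene_sets,
    read_physical_pairs,
    read_qpcr_table,
    write_edge_list,
    write_network_graphml,
)
from .mr import (
    annotate_candidates,
    candidates_to_frame,
    iterative_core_pruning,
    select_master_regulators,
    trace_to_frame,
    upstream_neighborhood,
)
from .network import build_reference_network, contextualize, expression_status
from .qpcr import qpcr_gene_summary

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "write_report", "run_synthetic"]

CONDITIONS = ("control", "case")


class ConfigError(ValueError):
    """Raised when the pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``edge_lists`` is a list of (path, dialect) pairs; optional inputs
    (GMT annotation, physical pairs, qPCR Ct table) enable the
    corresponding stages when present.
    """

    counts: str
    meta: str
    edge_lists: list = field(default_factory=list)  # [(path, dialect), ...]
    gmt: str | None = None
    physical: str | None = None
    qpcr: str | None = None
    qpcr_housekeeping: str = "Gapdh"
    qpcr_targets: list = field(default_factory=list)
    alpha: float = 0.05
    fc_threshold: float = 0.0
    tau: float = 10.0
    tau_aggregate: str = "mean"
    min_term_size: int = 5
    max_term_size: int = 500
    skip_blockers: bool = False
    out_dir: str = "mrgrn_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        edge_lists = [
            (item["path"], item["dialect"]) for item in data.pop("edge_lists", [])
        ]
        return cls(edge_lists=edge_lists, **data)

    def validate(self) -> None:
        for name in ("counts", "meta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path does not exist: {p}")
        if not self.edge_lists:
            raise ConfigError("config field 'edge_lists': at least one edge list is required")
        for p, dialect in self.edge_lists:
            if not Path(p).exists():
                raise ConfigError(f"config field 'edge_lists': path does not exist: {p}")
        for name in ("gmt", "physical", "qpcr"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_de_table(det: pd.DataFrame, path: Path) -> None:
    out = det.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def _analyze_tissue(
    cm_tissue: CountMatrix,
    reference,
    config: PipelineConfig,
    physical,
    outdir: Path,
    tissue: str,
) -> dict:
    thresholds = DeThresholds(alpha=config.alpha, fc_threshold=config.fc_threshold)
    det, summary = run_de(cm_tissue, thresholds)
    _write_de_table(det, outdir / f"de_{tissue}.tsv")
    degs = set(det.index[det["status"].isin(["up", "down"])])

    result: dict = {"de_summary": summary, "conditions": {}}
    per_condition_de_mrs: dict[str, list] = {}
    case_survivors = None
    case_candidates = None
    for condition in CONDITIONS:
        status = expression_status(
            cm_tissue, condition, tau=config.tau, aggregate=config.tau_aggregate
        )
        ctx = contextualize(reference, status)
        write_edge_list(ctx.edge_records(), outdir / f"context_{tissue}_{condition}.edges.tsv")
        write_network_graphml(ctx, outdir / f"context_{tissue}_{condition}.graphml")
        cond_block: dict = {
            "contextualized_nodes": ctx.number_of_nodes(),
            "contextualized_edges": ctx.number_of_edges(),
        }
        degs_in = degs & set(ctx.nodes)
        if degs_in:
            neighborhood = upstream_neighborhood(ctx, degs_in)
            survivors, trace = iterative_core_pruning(
                neighborhood, skip_blockers=config.skip_blockers
            )
            trace_to_frame(trace).to_csv(
                outdir / f"trace_{tissue}_{condition}.tsv", sep="\t", index=False
            )
            candidates = annotate_candidates(survivors, det, physical)
            all_mrs, de_mrs = select_master_regulators(candidates)
            candidates_to_frame(candidates).to_csv(
                outdir / f"candidates_{tissue}_{condition}.tsv", sep="\t", index=False
            )
            node_attrs = {
                c.gene: {
                    "is_DE": c.is_de,
                    "direction": c.direction,
                    "is_master_regulator": True,
                }
                for c in candidates
            }
            write_network_graphml(
                survivors, outdir / f"survivors_{tissue}_{condition}.graphml", node_attrs
            )
            cond_block.update(
                {
                    "neighborhood_nodes": neighborhood.number_of_nodes(),
                    "n_survivors": survivors.number_of_nodes(),
                    "all_mrs": sorted(c.gene for c in all_mrs),
                    "de_mrs": [
                        {"gene": c.gene, "direction": c.direction} for c in de_mrs
                    ],
                }
            )
            per_condition_de_mrs[condition] = [c.gene for c in de_mrs]
            if condition == "case":
                case_survivors, case_candidates = survivors, candidates
        else:
            cond_block.update(
                {"neighborhood_nodes": 0, "n_survivors": 0, "all_mrs": [], "de_mrs": []}
            )
            per_condition_de_mrs[condition] = []
        result["conditions"][condition] = cond_block

    # headline set: the disease-context (case) candidates; both per-condition
    # sets and their intersection are reported alongside.
    result["de_mrs"] = result["conditions"]["case"]["de_mrs"]
    result["de_mrs_intersection"] = sorted(
        set(per_condition_de_mrs["control"]) & set(per_condition_de_mrs["case"])
    )
    if case_survivors is not None:
        node_attrs = {
            c.gene: {
                "is_DE": c.is_de,
                "direction": c.direction,
                "is_master_regulator": True,
            }
            for c in case_candidates
        }
        write_network_graphml(
            case_survivors, outdir / f"mr_network_{tissue}.graphml", node_attrs
        )

    if config.gmt is not None and degs:
        gene_sets = read_gene_sets(config.gmt)
        universe = set(det.index[det["p"].notna()])
        enr = overrepresentation_test(
            degs,
            gene_sets,
            universe,
            min_size=config.min_term_size,
            max_size=config.max_term_size,
        )
        frame = results_to_frame(enr)
        frame.to_csv(outdir / f"enrichment_{tissue}.tsv", sep="\t", index=False, float_format="%.10g")
        result["enrichment_top"] = frame.head(10).to_dict(orient="records")
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run report (a dict).

    Intermediates (DE tables, contextualized edge lists and GraphML,
    pruning traces, candidate tables, enrichment, qPCR summaries) are
    persisted under ``config.out_dir`` before the report is written.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cm = read_count_matrix(config.counts, config.meta)
    edge_lists = [read_edge_list(p, dialect) for p, dialect in config.edge_lists]
    reference = build_reference_network(edge_lists)
    physical = read_physical_pairs(config.physical) if config.physical else None

    report: dict = {
        "provenance": {
            "mrgrn_version": __version__,
            "config": {
                **{
                    k: v
                    for k, v in asdict(config).items()
                    if k not in ("edge_lists",)
                },
                "edge_lists": [
                    {"path": str(p), "dialect": d} for p, d in config.edge_lists
                ],
            },
            "input_checksums": {
                "counts": _sha256(config.counts),
                "meta": _sha256(config.meta),
                **{
                    f"edges_{i}": _sha256(p)
                    for i, (p, _) in enumerate(config.edge_lists)
                },
            },
        },
        "reference_network": {
            "nodes": reference.number_of_nodes(),
            "edges": reference.number_of_edges(),
        },
        "tissues": {},
    }

    tissues = sorted(set(cm.sample_meta["tissue"]))
    for tissue in tissues:
        cm_t = cm.subset_tissue(tissue)
        report["tissues"][tissue] = _analyze_tissue(
            cm_t, reference, config, physical, outdir, tissue
        )

    if config.qpcr is not None:
        table = read_qpcr_table(config.qpcr)
        targets = config.qpcr_targets or sorted(
            set(table["gene"]) - {config.qpcr_housekeeping}
        )
        per_animal, per_gene = qpcr_gene_summary(
            table, config.qpcr_housekeeping, targets
        )
        per_animal.to_csv(outdir / "qpcr_per_animal.tsv", sep="\t", index=False, float_format="%.10g")
        per_gene.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False, float_format="%.10g")
        report["qpcr"] = per_gene.to_dict(orient="records")

    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Persist the report as sorted JSON plus a human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [f"mrgrn {report['provenance']['mrgrn_version']} run report", ""]
    ref = report.get("reference_network", {})
    lines.append(
        f"reference network: {ref.get('nodes', 0)} nodes, {ref.get('edges', 0)} edges"
    )
    for tissue, block in sorted(report.get("tissues", {}).items()):
        s = block["de_summary"]
        lines.append("")
        lines.append(f"[{tissue}]")
        lines.append(
            f"  DEGs: {s['n_up']} up, {s['n_down']} down ({s['n_tested']} genes tested)"
        )
        for condition, cond in sorted(block["conditions"].items()):
            lines.append(
                f"  {condition}: contextualized network "
                f"{cond['contextualized_nodes']} nodes / {cond['contextualized_edges']} edges; "
                f"{cond['n_survivors']} pruning survivors; "
                f"{len(cond['all_mrs'])} MR candidates, {len(cond['de_mrs'])} DE"
            )
        de_mrs = ", ".join(
            f"{d['gene']}({d['direction']})" for d in block["de_mrs"]
        )
        lines.append(f"  DE master regulators (case context): {de_mrs or 'none'}")
    if "qpcr" in report:
        lines.append("")
        lines.append("[qPCR]")
        for row in report["qpcr"]:
            lines.append(
                f"  {row['gene']}: control rq {row['control_mean_rq']:.3f}, "
                f"case rq {row['case_mean_rq']:.3f}, p={row['p']:.4g}"
            )
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def run_synthetic(scenario, workdir: str | Path) -> dict:
    """Simulate one scenario to disk and run the full pipeline on it."""
    from .simulate import write_scenario_outputs

    workdir = Path(workdir)
    paths = write_scenario_outputs(scenario, workdir / "inputs")
    config = PipelineConfig(
        counts=paths["counts"],
        meta=paths["meta"],
        edge_lists=[(paths["edges"], "generic3col")],
        qpcr=paths["qpcr"],
        out_dir=str(workdir / "out"),
    )
    return run_pipeline(config)
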