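"""End-to-end pipeline: clean -> query -> project -> subtract -> merge ->
topology -> enrichment, driven by one config file.

Every stage writes its intermediate products under the configured output
directory and records row/node/edge counts in a machine-readable JSON
manifest, so the funnel from raw tables through queried networks to the
final merged interactome is auditable.  All randomness flows from the single
config seed; per-stage seeds are derived deterministically by salting the
seed with the stage name, so stages are independently reproducible.

Stage order is normative: each species network is queried first and the
extracted network is projected afterwards — projecting the full base network
first would give the same final edge set only if extraction commuted with
projection, which it need not under one-to-many orthology.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import yaml

from . import enrichment as enr
from . import interolog as ilog
from . import network_ops as nops
from . import ppi_io
from . import topology as topo
from .ppi_io import PathLike, SpeciesNetwork

logger = logging.getLogger(__name__)

STAGES = ("clean", "query", "project", "subtract", "merge", "topology", "enrich")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: config seed salted with the stage name."""
    return (seed ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class TopologySettings:
    n_reps: int = 300
    query_size: int | None = None  # default: length of the real query list


@dataclass
class EnrichmentSettings:
    annotation_file: str | Path | None = None
    annotation_format: str = "tsv"  # or "gaf"
    namespace: str = enr.BIOLOGICAL_PROCESS
    alpha: float = 0.05
    min_proteins: int = 8
    overlap_stat: str = "kappa"
    overlap_threshold: float = 0.4
    correction: str = "benjamini-hochberg"
    whole_annotation_background: bool = False


@dataclass
class PipelineConfig:
    """Everything one run needs; paths are resolved against ``base_dir``."""

    species_tables: dict[int, str | Path]
    ortholog_file: str | Path
    query_file: str | Path
    out_dir: str | Path
    seed: int
    dialects: dict[int, str] = field(default_factory=dict)  # "canonical"|"psimitab"
    target_taxid: int = 9606
    id_map_file: str | Path | None = None
    id_map_policy: str = "passthrough"
    query_key: str = "symbol"
    topology: TopologySettings = field(default_factory=TopologySettings)
    enrichment: EnrichmentSettings = field(default_factory=EnrichmentSettings)
    base_dir: Path = Path(".")

    def path(self, p: str | Path | None) -> Path | None:
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        topo_cfg = TopologySettings(**data.pop("topology", {}))
        enr_cfg = EnrichmentSettings(**data.pop("enrichment", {}))
        species = {int(t): p for t, p in data.pop("species_tables").items()}
        dialects = {int(t): d for t, d in data.pop("dialects", {}).items()}
        return cls(
            species_tables=species,
            dialects=dialects,
            topology=topo_cfg,
            enrichment=enr_cfg,
            base_dir=path.parent,
            **data,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    cleaned: dict[int, SpeciesNetwork] = field(default_factory=dict)
    queried: dict[int, SpeciesNetwork] = field(default_factory=dict)
    projected: dict[int, SpeciesNetwork] = field(default_factory=dict)
    subtracted: dict[int, SpeciesNetwork] = field(default_factory=dict)
    merged: nops.MergedNetwork | None = None
    measures: topo.GraphMeasures | None = None
    null: topo.NullDistribution | None = None
    comparison: "object" = None
    enrichment_results: list = field(default_factory=list)
    functional_map: enr.FunctionalMap | None = None
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _read_id_map(path: Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                continue
            out.setdefault(f[0].strip(), []).extend(
                s.strip() for s in f[1].split(";") if s.strip()
            )
    return out


def _read_query_list(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def run_pipeline(config: PipelineConfig, until: str = "enrich") -> PipelineResult:
    """Run the pipeline through ``until`` (a stage name; 'all' == 'enrich')."""
    if until == "all":
        until = "enrich"
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    last = STAGES.index(until)
    result = PipelineResult(config=config)
    manifest: dict = {"seed": config.seed, "stages": {}}
    result.manifest = manifest
    out_dir = config.path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- clean -----------------------------------------------------------
    id_map = None
    if config.id_map_file:
        id_map = _read_id_map(config.path(config.id_map_file))
    clean_counts: dict[str, dict] = {}
    for taxid, table in sorted(config.species_tables.items()):
        path = config.path(table)
        try:
            dialect = config.dialects.get(taxid, "canonical")
            if dialect == "psimitab":
                parsed = ppi_io.parse_psimitab(path)
            else:
                parsed = ppi_io.parse_interactions(path)
        except (OSError, ValueError) as exc:
            raise StageError("clean", f"{path}: {exc}") from exc
        records = ppi_io.filter_physical(parsed.records)
        n_physical = len(records)
        records = ppi_io.filter_intra_species(records)
        n_intra = len(records)
        n_dropped_ids = 0
        if id_map is not None:
            normed = ppi_io.normalize_ids(records, id_map, policy=config.id_map_policy)
            records = normed.records
            n_dropped_ids = normed.n_dropped
        net = ppi_io.build_species_network(records, taxid)
        result.cleaned[taxid] = net
        ppi_io.write_edge_table(net, out_dir / f"cleaned_{taxid}.tsv")
        clean_counts[str(taxid)] = {
            "rows": parsed.n_rows,
            "malformed_skipped": parsed.n_skipped,
            "after_physical_filter": n_physical,
            "after_intra_species_filter": n_intra,
            "dropped_unresolved_ids": n_dropped_ids,
            "nodes": net.n_nodes,
            "edges": net.n_edges,
            "self_interactions": len(net.self_interactions),
        }
    manifest["stages"]["clean"] = clean_counts
    manifest["base_totals"] = {
        "nodes": sum(n.n_nodes for n in result.cleaned.values()),
        "edges": sum(n.n_edges for n in result.cleaned.values()),
    }
    if config.target_taxid not in result.cleaned:
        raise StageError("clean", f"no table for target taxid {config.target_taxid}")
    if last == STAGES.index("clean"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- query -----------------------------------------------------------
    try:
        omap = ilog.parse_homologene(config.path(config.ortholog_file))
    except (OSError, ValueError) as exc:
        raise StageError("query", f"{config.ortholog_file}: {exc}") from exc
    queries = _read_query_list(config.path(config.query_file))
    query_counts: dict[str, dict] = {}
    for taxid, net in sorted(result.cleaned.items()):
        if taxid == config.target_taxid:
            species_queries = list(queries)
        else:
            species_queries = sorted(
                {s for q in queries for s in omap.orthologs_of(q, taxid)}
            )
        extracted = nops.extract_query_network(net, species_queries)
        result.queried[taxid] = extracted
        ppi_io.write_edge_table(extracted, out_dir / f"queried_{taxid}.tsv")
        query_counts[str(taxid)] = {
            "query_ids": len(species_queries),
            "unmatched_queries": len(extracted.unmatched_queries),
            "nodes": extracted.n_nodes,
            "edges": extracted.n_edges,
        }
    manifest["stages"]["query"] = query_counts
    manifest["queried_totals"] = {
        "nodes": sum(n.n_nodes for n in result.queried.values()),
        "edges": sum(n.n_edges for n in result.queried.values()),
    }
    if last == STAGES.index("query"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- project ---------------------------------------------------------
    project_counts: dict[str, dict] = {}
    for taxid, net in sorted(result.queried.items()):
        if taxid == config.target_taxid:
            continue
        projected = ilog.project_interologs(net, omap)
        result.projected[taxid] = projected
        ppi_io.write_edge_table(projected, out_dir / f"projected_{taxid}.tsv")
        project_counts[str(taxid)] = {"edges": projected.n_edges, **projected.stats}
    manifest["stages"]["project"] = project_counts
    if last == STAGES.index("project"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- subtract --------------------------------------------------------
    human_full = result.cleaned[config.target_taxid]
    subtract_counts: dict[str, dict] = {}
    for taxid, net in sorted(result.projected.items()):
        sub = ilog.subtract_known(net, human_full)
        result.subtracted[taxid] = sub
        ppi_io.write_edge_table(sub, out_dir / f"interolog_{taxid}.tsv")
        subtract_counts[str(taxid)] = {
            "edges": sub.n_edges,
            "removed_known_human": sub.stats.get("n_removed_known", 0),
        }
    manifest["stages"]["subtract"] = subtract_counts
    if last == STAGES.index("subtract"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- merge -----------------------------------------------------------
    nets = [result.queried[config.target_taxid]] + [
        result.subtracted[t] for t in sorted(result.subtracted)
    ]
    merged = nops.merge_networks(nets, queries, target_taxid=config.target_taxid)
    result.merged = merged
    nops.write_xgmml(merged, out_dir / "merged.xgmml", label="merged_interactome")
    nops.write_sif_with_attributes(merged, out_dir / "merged")
    ppi_io.write_edge_table(
        SpeciesNetwork(taxid=config.target_taxid, graph=merged.graph),
        out_dir / "merged.tsv",
    )
    manifest["stages"]["merge"] = {"nodes": merged.n_nodes, "edges": merged.n_edges}
    if last == STAGES.index("merge"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- topology --------------------------------------------------------
    if merged.n_nodes == 0:
        raise StageError("topology", "merged network is empty")
    result.measures = topo.compute_measures(merged)
    base = nx.Graph()
    for taxid, net in sorted(result.cleaned.items()):
        for a, b in net.graph.edges:
            base.add_edge(f"{taxid}:{a}", f"{taxid}:{b}")
        base.add_nodes_from(f"{taxid}:{n}" for n in net.graph.nodes)
    query_size = config.topology.query_size or len(queries)
    null = topo.sample_null(
        base,
        query_size=query_size,
        n_reps=config.topology.n_reps,
        seed=stage_seed(config.seed, "topology"),
    )
    result.null = null
    report = topo.compare_to_null(result.measures, null)
    result.comparison = report
    topo.write_comparison_tsv(report, out_dir / "topology_report.tsv")
    null.to_frame().to_csv(
        out_dir / "null_distribution.tsv", sep="\t", index=False, float_format="%.6g"
    )
    with open(out_dir / "degree_distribution.tsv", "w", encoding="utf-8") as fh:
        fh.write("degree\tcount\n")
        for d, c in topo.degree_distribution(merged).items():
            fh.write(f"{d}\t{c}\n")
    counts, edges = topo.clustering_distribution(merged)
    with open(out_dir / "clustering_distribution.tsv", "w", encoding="utf-8") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{left:.2f}\t{right:.2f}\t{c}\n")
    manifest["stages"]["topology"] = {
        "n_reps": null.n_reps,
        "query_size": query_size,
        "null_seed": stage_seed(config.seed, "topology"),
        "observed": {
            k: (v if v is None or isinstance(v, int) else round(float(v), 6))
            for k, v in result.measures.as_dict().items()
        },
    }
    if last == STAGES.index("topology"):
        _write_manifest(manifest, out_dir)
        return result

    # ---- enrich ----------------------------------------------------------
    settings = config.enrichment
    ann_path = config.path(settings.annotation_file)
    if ann_path is None:
        logger.info("no annotation file configured; skipping enrichment stage")
        manifest["stages"]["enrich"] = {"skipped": True}
        _write_manifest(manifest, out_dir)
        return result
    try:
        if settings.annotation_format == "gaf":
            ann = enr.AnnotationSet.from_gaf(ann_path, namespace=settings.namespace)
        else:
            ann = enr.AnnotationSet.from_tsv(ann_path, namespace=settings.namespace)
    except (OSError, ValueError) as exc:
        raise StageError("enrich", f"{ann_path}: {exc}") from exc
    if not settings.whole_annotation_background:
        # background = what the interaction data could have returned: every
        # human protein plus the human image of every non-human base protein
        universe = set(result.cleaned[config.target_taxid].graph.nodes)
        for taxid, net in result.cleaned.items():
            if taxid == config.target_taxid:
                continue
            for node in net.graph.nodes:
                universe |= omap.human_of(taxid, node)
        ann = ann.with_universe(universe)
    results = enr.enrich(merged.members, ann)
    results = enr.adjust(results, method=settings.correction)
    result.enrichment_results = results
    enr.write_enrichment_tsv(results, out_dir / "enrichment.tsv")
    fmap = enr.build_functional_map(
        results,
        ann,
        member_set=merged.members & ann.universe,
        min_proteins=settings.min_proteins,
        alpha=settings.alpha,
        overlap_stat=settings.overlap_stat,
        overlap_threshold=settings.overlap_threshold,
    )
    result.functional_map = fmap
    enr.write_functional_map(fmap, out_dir / "functional_map")
    manifest["stages"]["enrich"] = {
        "universe": len(ann.universe),
        "terms_tested": len(results),
        "terms_in_map": fmap.graph.number_of_nodes(),
        "map_edges": fmap.graph.number_of_edges(),
    }
    _write_manifest(manifest, out_dir)
    return result


def _write_manifest(manifest: Mapping, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
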