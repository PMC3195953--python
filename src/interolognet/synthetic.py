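"""Synthetic multi-species interaction fixtures with planted ground truth.

The generator emulates the statistical structure of the real inputs to the
interactome-construction workflow: several species-specific interaction
tables with partially overlapping interolog content, an ortholog-group table
with incomplete coverage, a query list whose proteins form a densely
connected "machine" together with a designated neighbor shell, and a GO
annotation table with one term planted into that machine.

Cross-species structure is generated by sampling a shared "ancestral" edge
set over the human namespace and copying it into each species through the
inverse ortholog map, then adding species-private Erdős–Rényi noise edges.
This makes interolog projection checkable against an explicit ancestral
truth: the bundle records the exact human-projected merged edge set the
pipeline must reproduce.  The truth record is computed here with plain
set arithmetic, independently of the pipeline modules.

The background model is Erdős–Rényi: the contracts exercised by the fixtures
(extraction, projection, null calibration) are degree-distribution-agnostic,
and ER gives closed-form expectations.  A preferential-attachment option
mimics heavy-tailed degree distributions qualitatively.

Emitted tables include deliberate chaff — purely genetic rows, cross-species
rows, self-interaction rows and randomly flipped edge orientations — that
the cleaning stages must remove or canonicalise; the truth record already
accounts for all of it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .ppi_io import CANONICAL_COLUMNS, PathLike

logger = logging.getLogger(__name__)

HUMAN_TAXID = 9606

_SOURCE_DBS = ("syndb-alpha", "syndb-beta", "syndb-curated")
_DETECTION = ("two hybrid", "affinity chromatography", "coimmunoprecipitation")
_NAMESPACE = "biological_process"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic bundle.

    Defaults emulate the scale of the real construction at desk size: seven
    species totalling 2000 base proteins (human largest), background edge
    density giving mean degree ~10 as in large aggregated interaction
    databases, a 39-protein query machine with a 100-protein neighbor shell
    whose internal edge probability makes the extracted machine as dense as
    a real chaperone-machine interactome, 80% ortholog coverage, and 30% of
    projected interologs already present in the human table.
    """

    species: tuple[tuple[int, int], ...] = (
        (9606, 800),
        (10090, 200),
        (4932, 200),
        (4896, 200),
        (6239, 200),
        (7227, 200),
        (3702, 200),
    )
    background_edge_p: float = 0.005
    query_size: int = 39
    shell_size: int = 100
    planted_p_in: float = 0.15
    ortholog_coverage: float = 0.8
    human_overlap_fraction: float = 0.3
    n_go_terms: int = 30
    go_background_rate: float = 0.05
    planted_term_effect: float = 0.6
    genetic_row_fraction: float = 0.03
    cross_species_row_fraction: float = 0.01
    degree_model: str = "erdos-renyi"  # or "preferential-attachment"
    seed: int = 0

    def __post_init__(self) -> None:
        taxids = [t for t, _n in self.species]
        if HUMAN_TAXID not in taxids:
            raise ValueError("species list must include the human taxon 9606")
        if len(set(taxids)) != len(taxids):
            raise ValueError("duplicate taxid in species list")
        if not (0.0 < self.background_edge_p <= self.planted_p_in <= 1.0):
            raise ValueError("need 0 < background_edge_p <= planted_p_in <= 1")
        if not (0.0 <= self.ortholog_coverage <= 1.0):
            raise ValueError("ortholog_coverage must lie in [0, 1]")
        if not (0.0 <= self.human_overlap_fraction <= 1.0):
            raise ValueError("human_overlap_fraction must lie in [0, 1]")
        n_h = dict(self.species)[HUMAN_TAXID]
        if self.query_size < 1 or self.query_size + self.shell_size > n_h:
            raise ValueError("query machine plus shell must fit in the human node set")
        if self.degree_model not in ("erdos-renyi", "preferential-attachment"):
            raise ValueError(f"unknown degree model {self.degree_model!r}")

    @property
    def n_human(self) -> int:
        return dict(self.species)[HUMAN_TAXID]

    @classmethod
    def from_mapping(cls, data: Mapping) -> "FixtureSpec":
        data = dict(data)
        if "species" in data:
            data["species"] = tuple((int(t), int(n)) for t, n in data["species"])
        return cls(**data)


@dataclass
class FixtureBundle:
    """In-memory fixture: tables, ortholog rows, queries, annotation, truth."""

    spec: FixtureSpec
    species_tables: dict[int, list[tuple[str, ...]]]
    homologene_rows: list[tuple[str, ...]]
    query_ids: list[str]
    annotation_rows: list[tuple[str, str, str, str]]
    truth: dict


def human_symbol(i: int) -> str:
    return f"H{i:04d}"


def species_symbol(taxid: int, i: int) -> str:
    return f"T{taxid}P{i:04d}"


def _pair_probabilities(
    n: int, block_size: int, p_background: float, p_in: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    p = np.where((iu < block_size) & (ju < block_size), p_in, p_background)
    return iu, ju, p


def _sample_pairs(
    rng: np.random.Generator, iu: np.ndarray, ju: np.ndarray, p
) -> set[tuple[int, int]]:
    mask = rng.random(iu.shape[0]) < p
    return set(zip(iu[mask].tolist(), ju[mask].tolist()))


def planted_base_graph(
    n_nodes: int = 2000,
    background_edge_p: float = 0.005,
    query_size: int = 30,
    shell_size: int = 100,
    planted_p_in: float = 0.15,
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Single-graph benchmark: ER background with a planted dense machine.

    Returns the base graph and the query node list (the machine minus its
    shell).  With ``planted_p_in == background_edge_p`` nothing is planted
    and the query set is statistically indistinguishable from a random draw,
    which is the null-calibration condition.
    """
    rng = np.random.default_rng(seed)
    iu, ju, p = _pair_probabilities(n_nodes, query_size + shell_size,
                                    background_edge_p, planted_p_in)
    pairs = _sample_pairs(rng, iu, ju, p)
    g = nx.Graph()
    g.add_nodes_from(f"N{i:04d}" for i in range(n_nodes))
    g.add_edges_from((f"N{i:04d}", f"N{j:04d}") for i, j in pairs)
    return g, [f"N{i:04d}" for i in range(query_size)]


def generate_annotation(
    universe: Sequence[str],
    machine: Sequence[str],
    n_terms: int,
    planted_term_effect: float,
    background_rate: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str, str]], str]:
    """Annotation rows with one term planted into the machine.

    Term 1 annotates a ``planted_term_effect`` fraction of the machine (and
    the background rate elsewhere); every other term annotates each protein
    at the background rate.  Returns ``(rows, planted_term_id)``.
    """
    machine_set = set(machine)
    rows: list[tuple[str, str, str, str]] = []
    planted_id = "GO:1000001"
    for t in range(1, n_terms + 1):
        term_id = f"GO:{1000000 + t:07d}"
        name = "planted machine process" if t == 1 else f"synthetic process {t}"
        for protein in universe:
            rate = (
                planted_term_effect
                if (t == 1 and protein in machine_set)
                else background_rate
            )
            if rng.random() < rate:
                rows.append((protein, term_id, name, _NAMESPACE))
    return rows, planted_id


def _extract(edges: set[tuple[str, str]], queries: Sequence[str]
             ) -> set[tuple[str, str]]:
    """Independent next-neighbor extraction on a plain edge set."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    matched = [q for q in queries if q in adj]
    selected = set(matched)
    for q in matched:
        selected |= adj[q]
    return {e for e in edges if e[0] in selected and e[1] in selected}


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate one fixture bundle, fully deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_h = spec.n_human
    block = spec.query_size + spec.shell_size
    hsyms = [human_symbol(i) for i in range(n_h)]
    queries = hsyms[: spec.query_size]
    machine = hsyms[:block]

    # shared "ancestral" edge set over the human namespace
    if spec.degree_model == "preferential-attachment":
        m_attach = max(1, int(round(spec.background_edge_p * (n_h - 1) / 2)))
        seed_ba = int(rng.integers(0, 2**31))
        base = nx.barabasi_albert_graph(n_h, m_attach, seed=seed_ba)
        ancestral = {(min(a, b), max(a, b)) for a, b in base.edges}
        iu, ju, _ = _pair_probabilities(n_h, block, 0.0, 0.0)
        in_block = (iu < block) & (ju < block)
        extra = rng.random(iu.shape[0]) < np.where(in_block, spec.planted_p_in, 0.0)
        ancestral |= set(zip(iu[extra].tolist(), ju[extra].tolist()))
    else:
        iu, ju, p = _pair_probabilities(n_h, block, spec.background_edge_p,
                                        spec.planted_p_in)
        ancestral = _sample_pairs(rng, iu, ju, p)
    ancestral_list = sorted(ancestral)

    # human table: overlap fraction of the ancestral set plus private noise
    keep = rng.random(len(ancestral_list)) < spec.human_overlap_fraction
    human_pairs = {e for e, k in zip(ancestral_list, keep) if k}
    iu_h, ju_h = np.triu_indices(n_h, k=1)
    human_pairs |= _sample_pairs(rng, iu_h, ju_h, spec.background_edge_p)
    human_edges = {(hsyms[i], hsyms[j]) for i, j in human_pairs}

    # per-species networks through the inverse ortholog map
    species_edges: dict[int, set[tuple[str, str]]] = {}
    sp_to_human: dict[int, dict[str, str]] = {}
    unmapped_extra_groups: dict[int, list[int]] = {}
    for taxid, n_s in spec.species:
        if taxid == HUMAN_TAXID:
            continue
        n_map = int(round(spec.ortholog_coverage * n_s))
        sp_idx = np.sort(rng.choice(n_s, size=n_map, replace=False))
        hum_idx = rng.choice(n_h, size=n_map, replace=False)
        hum_of_sp = dict(zip(sp_idx.tolist(), hum_idx.tolist()))
        sp_of_hum = {h: s for s, h in hum_of_sp.items()}
        shared = {
            (min(sp_of_hum[i], sp_of_hum[j]), max(sp_of_hum[i], sp_of_hum[j]))
            for i, j in ancestral_list
            if i in sp_of_hum and j in sp_of_hum
        }
        iu_s, ju_s = np.triu_indices(n_s, k=1)
        private = _sample_pairs(rng, iu_s, ju_s, spec.background_edge_p)
        edges = {
            (species_symbol(taxid, a), species_symbol(taxid, b))
            for a, b in shared | private
        }
        species_edges[taxid] = edges
        sp_to_human[taxid] = {
            species_symbol(taxid, s): hsyms[h] for s, h in hum_of_sp.items()
        }
        unmapped = [i for i in range(n_s) if i not in hum_of_sp]
        unmapped_extra_groups[taxid] = unmapped[:10]

    # ortholog flat file: one group per human gene + a few human-less groups
    homologene_rows: list[tuple[str, ...]] = []
    human_gene_id = lambda i: str(100000 + i)  # noqa: E731
    species_gene_id = lambda taxid, i: str(taxid * 1000000 + i)  # noqa: E731
    for i in range(n_h):
        homologene_rows.append(
            (str(i + 1), str(HUMAN_TAXID), human_gene_id(i), hsyms[i],
             str(500000 + i), f"NP_{100000 + i}")
        )
    for taxid, _n_s in spec.species:
        if taxid == HUMAN_TAXID:
            continue
        for sp_sym, h_sym in sorted(sp_to_human[taxid].items()):
            i = int(h_sym[1:])
            s = int(sp_sym.split("P")[-1])
            homologene_rows.append(
                (str(i + 1), str(taxid), species_gene_id(taxid, s), sp_sym,
                 str(taxid * 10 + s), f"XP_{taxid}{s:05d}")
            )
        for k, s in enumerate(unmapped_extra_groups[taxid]):
            homologene_rows.append(
                (f"9{taxid}{k:03d}", str(taxid), species_gene_id(taxid, s),
                 species_symbol(taxid, s), str(taxid * 10 + s), f"XP_{taxid}{s:05d}")
            )

    # interaction tables with provenance and chaff
    all_edges = dict(species_edges)
    all_edges[HUMAN_TAXID] = human_edges
    species_tables: dict[int, list[tuple[str, ...]]] = {}
    taxids = [t for t, _n in spec.species]
    for taxid, n_s in spec.species:
        rows: list[tuple[str, ...]] = []
        edges = sorted(all_edges[taxid])
        symbol = (
            (lambda i: human_symbol(i)) if taxid == HUMAN_TAXID
            else (lambda i: species_symbol(taxid, i))
        )
        for a, b in edges:
            if rng.random() < 0.5:
                a, b = b, a
            rows.append(
                (
                    a, b, str(taxid), str(taxid), "physical",
                    _SOURCE_DBS[int(rng.integers(len(_SOURCE_DBS)))],
                    _DETECTION[int(rng.integers(len(_DETECTION)))],
                    str(int(rng.integers(10_000_000, 99_999_999))),
                )
            )
        # self-interactions (homodimers): recorded, never graph edges
        for i in (0, 1):
            s = symbol(i)
            rows.append((s, s, str(taxid), str(taxid), "physical",
                         _SOURCE_DBS[0], _DETECTION[0], ""))
        n_genetic = max(1, int(round(spec.genetic_row_fraction * len(edges))))
        for _ in range(n_genetic):
            i, j = rng.integers(0, n_s, size=2)
            if i == j:
                j = (j + 1) % n_s
            rows.append((symbol(int(i)), symbol(int(j)), str(taxid), str(taxid),
                         "genetic", _SOURCE_DBS[1], "synthetic lethality", ""))
        n_cross = max(1, int(round(spec.cross_species_row_fraction * len(edges))))
        other = taxids[(taxids.index(taxid) + 1) % len(taxids)]
        other_symbol = (
            (lambda i: human_symbol(i)) if other == HUMAN_TAXID
            else (lambda i: species_symbol(other, i))
        )
        for _ in range(n_cross):
            i = int(rng.integers(0, n_s))
            j = int(rng.integers(0, dict(spec.species)[other]))
            rows.append((symbol(i), other_symbol(j), str(taxid), str(other),
                         "physical", _SOURCE_DBS[2], _DETECTION[1], ""))
        species_tables[taxid] = rows

    annotation_rows, planted_term = generate_annotation(
        hsyms, machine, spec.n_go_terms, spec.planted_term_effect,
        spec.go_background_rate, rng,
    )

    # ground truth: independent set-arithmetic rerun of the construction
    merged: set[tuple[str, str]] = set(_extract(human_edges, queries))
    per_species_queries: dict[int, list[str]] = {}
    for taxid, _n_s in spec.species:
        if taxid == HUMAN_TAXID:
            continue
        hum_of = sp_to_human[taxid]
        sp_of = {h: s for s, h in hum_of.items()}
        q_sp = sorted(sp_of[q] for q in queries if q in sp_of)
        per_species_queries[taxid] = q_sp
        extracted = _extract(species_edges[taxid], q_sp)
        for a, b in extracted:
            ha, hb = hum_of.get(a), hum_of.get(b)
            if ha is None or hb is None or ha == hb:
                continue
            pair = (ha, hb) if ha <= hb else (hb, ha)
            if pair in human_edges:
                continue
            merged.add(pair)

    truth = {
        "merged_edges": sorted(list(e) for e in merged),
        "machine_nodes": machine,
        "query_ids": queries,
        "planted_term_id": planted_term,
        "per_species_queries": {str(t): q for t, q in sorted(per_species_queries.items())},
        "n_human_edges": len(human_edges),
    }
    return FixtureBundle(
        spec=spec,
        species_tables=species_tables,
        homologene_rows=homologene_rows,
        query_ids=list(queries),
        annotation_rows=annotation_rows,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, out_dir: PathLike) -> dict[str, Path]:
    """Write the bundle as plain-text files plus a ready pipeline config.

    Byte-identical across runs with the same spec (fixed iteration orders,
    no timestamps).  Returns a name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for taxid, rows in sorted(bundle.species_tables.items()):
        path = out / f"species_{taxid}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[f"species_{taxid}"] = path
    path = out / "homologene.data"
    with open(path, "w", encoding="utf-8") as fh:
        for row in bundle.homologene_rows:
            fh.write("\t".join(row) + "\n")
    paths["ortholog_file"] = path
    path = out / "query.txt"
    with open(path, "w", encoding="utf-8") as fh:
        for q in bundle.query_ids:
            fh.write(q + "\n")
    paths["query_file"] = path
    path = out / "annotations.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tterm_id\tterm_name\tnamespace\n")
        for row in bundle.annotation_rows:
            fh.write("\t".join(row) + "\n")
    paths["annotation_file"] = path
    path = out / "truth.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = path
    config = {
        "species_tables": {
            int(taxid): f"species_{taxid}.tsv" for taxid in sorted(bundle.species_tables)
        },
        "target_taxid": HUMAN_TAXID,
        "ortholog_file": "homologene.data",
        "query_file": "query.txt",
        "out_dir": "results",
        "seed": bundle.spec.seed,
        "topology": {"n_reps": 300},
        "enrichment": {"annotation_file": "annotations.tsv"},
    }
    path = out / "config.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = path
    return paths


def spec_from_yaml(path: PathLike) -> FixtureSpec:
    """Load a FixtureSpec from a flat key-value YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return FixtureSpec.from_mapping(data)
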