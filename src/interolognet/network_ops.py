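"""Query-centred subnetwork extraction, merging, and Cytoscape formats.

The query network of a protein list is the subgraph induced on the query
proteins plus all of their first neighbors — including neighbor–neighbor
("second level") edges, so interactions among primary hits are retained.
Per-species query networks (the human one directly, the others after
interolog projection and subtraction of known human interactions) are merged
by node/edge union into the final human-projected interactome, with per-edge
origin sets recording whether an interaction is experimentally known in human
(``human``) or predicted (``interolog:<taxid>``), or both.

Exports target Cytoscape: XGMML with node/edge attributes, SIF with
attribute side tables, and the canonical edge table.  The XGMML reader
tolerates attribute-bearing nodes and edges and ignores layout graphics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union
from xml.etree import ElementTree as ET

import networkx as nx

from .ppi_io import PathLike, SpeciesNetwork, canonical_pair

logger = logging.getLogger(__name__)

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

NetworkLike = Union[SpeciesNetwork, nx.Graph]


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.graph


@dataclass
class MergedNetwork:
    """The human-projected query interactome.

    Nodes are human protein symbols flagged ``is_query``; every edge carries
    a non-empty origin set and union-merged provenance.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    query_ids: frozenset[str] = frozenset()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def members(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def query_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_query")}


def extract_query_network(
    net: NetworkLike, query_ids: Sequence[str]
) -> SpeciesNetwork:
    """Induced subgraph on the query proteins plus their first neighbors.

    The selected set is ``(query ∩ nodes) ∪ N(query)``; the output contains
    ALL edges of the input with both endpoints selected, so edges between two
    neighbors are kept.  Query ids absent from the network are ignored and
    reported via ``unmatched_queries``.  Matched query nodes are flagged
    ``is_query`` in the output.
    """
    graph = _as_graph(net)
    matched = [q for q in dict.fromkeys(query_ids) if q in graph]
    unmatched = tuple(sorted(set(query_ids) - set(matched)))
    selected: set[str] = set(matched)
    for q in matched:
        selected.update(graph.neighbors(q))
    sub = graph.subgraph(selected).copy()
    for q in matched:
        sub.nodes[q]["is_query"] = True
    taxid = net.taxid if isinstance(net, SpeciesNetwork) else None
    selfs = (
        [r for r in net.self_interactions if r.id_a in selected]
        if isinstance(net, SpeciesNetwork)
        else []
    )
    out = SpeciesNetwork(
        taxid=taxid,
        graph=sub,
        self_interactions=selfs,
        origin=net.origin if isinstance(net, SpeciesNetwork) else None,
        unmatched_queries=unmatched,
    )
    if unmatched:
        logger.info("%d query ids absent from taxid %s network", len(unmatched), taxid)
    return out


def merge_networks(
    nets: Sequence[NetworkLike],
    query_ids: Iterable[str] = (),
    target_taxid: int = 9606,
) -> MergedNetwork:
    """Union-merge per-species query networks into one interactome.

    Node and edge sets are unions under canonical keys; origin sets and
    provenance union-merge.  An edge arriving without explicit origins gets
    ``human`` if its network's taxon is the target species, otherwise
    ``interolog:<taxid>``; the same edge arriving through several routes
    keeps the union of its origins rather than conflicting.  ``is_query``
    flags are set from ``query_ids``.
    """
    query = set(query_ids)
    merged = MergedNetwork(query_ids=frozenset(query))
    g = merged.graph
    for net in nets:
        graph = _as_graph(net)
        taxid = net.taxid if isinstance(net, SpeciesNetwork) else target_taxid
        default_origin = (
            "human" if taxid == target_taxid and not getattr(net, "origin", None)
            else getattr(net, "origin", None) or f"interolog:{taxid}"
        )
        for node in graph.nodes:
            g.add_node(node)
        for a, b in graph.edges:
            data = graph.edges[a, b]
            origins = set(data.get("origins", ())) or {default_origin}
            a, b = canonical_pair(a, b)
            if g.has_edge(a, b):
                e = g.edges[a, b]
                e["origins"].update(origins)
                e["source_dbs"].update(data.get("source_dbs", ()))
                e["detection_methods"].update(data.get("detection_methods", ()))
                e["pubmed_ids"].update(data.get("pubmed_ids", ()))
            else:
                g.add_edge(
                    a,
                    b,
                    origins=set(origins),
                    source_dbs=set(data.get("source_dbs", ())),
                    detection_methods=set(data.get("detection_methods", ())),
                    pubmed_ids=set(data.get("pubmed_ids", ())),
                )
    for node in g.nodes:
        g.nodes[node]["is_query"] = node in query
    return merged


# ---------------------------------------------------------------------------
# Cytoscape-facing formats
# ---------------------------------------------------------------------------


def _att(parent: ET.Element, name: str, value: str, type_: str = "string") -> None:
    ET.SubElement(parent, "att", {"name": name, "value": value, "type": type_})


def write_xgmml(net: Union[MergedNetwork, SpeciesNetwork, nx.Graph], path: PathLike,
                label: str = "network") -> None:
    """Write a Cytoscape-importable XGMML file.

    Node attribute ``is_query`` and edge attributes ``origin``,
    ``source_dbs``, ``detection_methods`` and ``pubmed_ids`` are emitted
    (set-valued attributes ';'-joined, sorted).  No layout is written.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    root = ET.Element("graph", {"label": label, "directed": "0", "xmlns": XGMML_NS})
    node_ids = {node: str(i) for i, node in enumerate(sorted(graph.nodes))}
    for node in sorted(graph.nodes):
        el = ET.SubElement(root, "node", {"id": node_ids[node], "label": node})
        is_query = bool(graph.nodes[node].get("is_query"))
        _att(el, "is_query", "1" if is_query else "0", "boolean")
    for a, b in sorted(canonical_pair(a, b) for a, b in graph.edges):
        data = graph.edges[a, b]
        el = ET.SubElement(
            root,
            "edge",
            {"label": f"{a} (pp) {b}", "source": node_ids[a], "target": node_ids[b]},
        )
        _att(el, "origin", ";".join(sorted(data.get("origins", ()))))
        _att(el, "source_dbs", ";".join(sorted(data.get("source_dbs", ()))))
        _att(el, "detection_methods", ";".join(sorted(data.get("detection_methods", ()))))
        _att(el, "pubmed_ids", ";".join(sorted(data.get("pubmed_ids", ()))))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("\n")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _atts_of(el: ET.Element) -> dict[str, str]:
    out = {}
    for child in el:
        if _local(child.tag) == "att":
            name = child.get("name")
            if name is not None:
                out[name] = child.get("value", "")
    return out


_TRUE = {"1", "true", "yes"}


def read_xgmml(path: PathLike) -> MergedNetwork:
    """Load an XGMML network, tolerating attributes and ignoring graphics.

    Node labels are used as protein symbols when present (Cytoscape exports
    typically carry numeric ids plus a label), falling back to the id.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    if _local(root.tag) != "graph":
        raise ValueError(f"{path}: not an XGMML graph document")
    merged = MergedNetwork()
    g = merged.graph
    by_id: dict[str, str] = {}
    queries: set[str] = set()
    for el in root.iter():
        if _local(el.tag) != "node":
            continue
        node_id = el.get("id")
        name = el.get("label") or node_id
        if name is None:
            continue
        if node_id is not None:
            by_id[node_id] = name
        g.add_node(name)
        atts = _atts_of(el)
        is_query = atts.get("is_query", "0").strip().lower() in _TRUE
        g.nodes[name]["is_query"] = is_query
        if is_query:
            queries.add(name)
    for el in root.iter():
        if _local(el.tag) != "edge":
            continue
        src, tgt = el.get("source"), el.get("target")
        if src is None or tgt is None:
            continue
        a = by_id.get(src, src)
        b = by_id.get(tgt, tgt)
        if a == b:
            continue  # loop-free contract
        atts = _atts_of(el)

        def split(name: str) -> set[str]:
            return {s for s in atts.get(name, "").split(";") if s}

        a, b = canonical_pair(a, b)
        if g.has_edge(a, b):
            data = g.edges[a, b]
            data["origins"].update(split("origin"))
            data["source_dbs"].update(split("source_dbs"))
            data["detection_methods"].update(split("detection_methods"))
            data["pubmed_ids"].update(split("pubmed_ids"))
        else:
            g.add_edge(
                a,
                b,
                origins=split("origin"),
                source_dbs=split("source_dbs"),
                detection_methods=split("detection_methods"),
                pubmed_ids=split("pubmed_ids"),
            )
    merged.query_ids = frozenset(queries)
    return merged


def write_sif_with_attributes(net: MergedNetwork, prefix: PathLike) -> None:
    """Write ``<prefix>.sif`` plus node/edge attribute side tables."""
    prefix = str(prefix)
    g = net.graph
    with open(prefix + ".sif", "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edge_set()):
            fh.write(f"{a}\tpp\t{b}\n")
        for n in sorted(n for n in g.nodes if g.degree(n) == 0):
            fh.write(f"{n}\n")
    with open(prefix + ".node_attrs.tsv", "w", encoding="utf-8") as fh:
        fh.write("node\tis_query\n")
        for n in sorted(g.nodes):
            fh.write(f"{n}\t{int(bool(g.nodes[n].get('is_query')))}\n")
    with open(prefix + ".edge_attrs.tsv", "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\torigins\tsource_dbs\tpubmed_ids\n")
        for a, b in sorted(net.edge_set()):
            d = g.edges[a, b]
            fh.write(
                "\t".join(
                    (
                        a,
                        b,
                        ";".join(sorted(d.get("origins", ()))),
                        ";".join(sorted(d.get("source_dbs", ()))),
                        ";".join(sorted(d.get("pubmed_ids", ()))),
                    )
                )
                + "\n"
            )
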