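"""Ortholog-group mapping and interolog projection.

The interolog concept: if two proteins interact in one species, their
identifiable human orthologs are likely to interact as well.  Orthology is
taken from a HomoloGene-style flat file in which every gene of a group shares
the group id with all its orthologs.  Projection rewrites each non-human edge
through the group table into the human namespace, drops edges with an
unmapped endpoint, and tags every surviving edge with an
``interolog:<taxid>`` origin so the human/predicted distinction survives all
later merges.  Projected candidate interactions already described in humans
are removed by :func:`subtract_known`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ppi_io import PathLike, SpeciesNetwork, StreamLike, _open_lines, canonical_pair

logger = logging.getLogger(__name__)

HUMAN_TAXID = 9606


@dataclass
class OrthologMap:
    """Many-species -> ortholog-group -> human-gene mapping.

    Members are ``(taxid, gene_id, symbol)`` triples.  Lookups accept either
    the gene id or the symbol as key (which one anchors the join with an
    interaction table is a per-dataset choice).  A ``(taxid, gene_id)`` pair
    may belong to at most one group.
    """

    groups: dict[str, set[tuple[int, str, str]]] = field(default_factory=dict)
    _gene_group: dict[tuple[int, str], str] = field(default_factory=dict)
    _key_groups: dict[tuple[int, str], set[str]] = field(default_factory=dict)

    def add_member(self, group_id: str, taxid: int, gene_id: str, symbol: str) -> None:
        prev = self._gene_group.get((taxid, gene_id))
        if prev is not None and prev != group_id:
            raise ValueError(
                f"gene {gene_id} (taxid {taxid}) assigned to ortholog groups "
                f"{prev} and {group_id}"
            )
        self._gene_group[(taxid, gene_id)] = group_id
        self.groups.setdefault(group_id, set()).add((taxid, gene_id, symbol))
        for key in {gene_id, symbol}:
            if key:
                self._key_groups.setdefault((taxid, key), set()).add(group_id)

    def human_members(self, group_id: str) -> frozenset[str]:
        """Human gene symbols of one group (empty if the group has none)."""
        return frozenset(
            sym for taxid, _gid, sym in self.groups.get(group_id, ()) if taxid == HUMAN_TAXID
        )

    def human_of(self, taxid: int, key: str) -> frozenset[str]:
        """Human symbols orthologous to a gene, by gene id or symbol.

        Empty exactly when the gene is unmapped or its group has no human
        member.
        """
        out: set[str] = set()
        for gid in self._key_groups.get((taxid, key), ()):
            out |= self.human_members(gid)
        return frozenset(out)

    def orthologs_of(self, human_symbol: str, taxid: int) -> frozenset[str]:
        """Symbols in ``taxid`` sharing an ortholog group with a human gene."""
        out: set[str] = set()
        for gid in self._key_groups.get((HUMAN_TAXID, human_symbol), ()):
            out |= {sym for t, _gid, sym in self.groups.get(gid, ()) if t == taxid}
        return frozenset(out)


def parse_homologene(stream: StreamLike) -> OrthologMap:
    """Parse a HomoloGene flat file (6 tab-separated columns, no header).

    Columns: group id, taxid, gene id, gene symbol, protein gi, protein
    accession.  Malformed rows are skipped with a warning; a gene assigned to
    two different groups is a hard error (invariant violation).
    """
    omap = OrthologMap()
    lines, closer = _open_lines(stream)
    try:
        for n, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4 or not f[0].strip() or not f[2].strip():
                logger.warning("skipping malformed ortholog row %d", n)
                continue
            try:
                taxid = int(f[1])
            except ValueError:
                logger.warning("skipping ortholog row %d: bad taxid %r", n, f[1])
                continue
            omap.add_member(f[0].strip(), taxid, f[2].strip(), f[3].strip())
    finally:
        if closer is not None:
            closer.close()
    return omap


def project_interologs(net: SpeciesNetwork, omap: OrthologMap) -> SpeciesNetwork:
    """Project a non-human species network into a hypothetical human network.

    Every edge ``(a, b)`` maps to all pairs ``(h_a, h_b)`` of human orthologs
    of its endpoints (full cross product under one-to-many orthology: picking
    a single member would silently lose candidate interologs).  Edges with an
    endpoint lacking a human ortholog are dropped and counted — this is the
    step that eliminates interactions whose proteins have no identifiable
    human counterpart.  Projected pairs collapsing to a self-pair (two
    paralogs mapping onto one human gene) are dropped to keep the graph
    loop-free.  Retained edges carry origin ``interolog:<source taxid>`` and
    inherit source provenance.
    """
    if net.taxid == HUMAN_TAXID:
        raise ValueError("interolog projection applies to non-human networks only")
    tag = f"interolog:{net.taxid}"
    out = SpeciesNetwork(taxid=HUMAN_TAXID, origin=tag)
    n_unmapped = 0
    n_self = 0
    query_images: set[str] = set()
    for node, data in net.graph.nodes(data=True):
        if data.get("is_query"):
            query_images |= omap.human_of(net.taxid, node)
    for a, b in net.graph.edges:
        humans_a = omap.human_of(net.taxid, a)
        humans_b = omap.human_of(net.taxid, b)
        if not humans_a or not humans_b:
            n_unmapped += 1
            continue
        data = net.graph.edges[a, b]
        for ha in humans_a:
            for hb in humans_b:
                if ha == hb:
                    n_self += 1
                    continue
                out.add_edge(
                    ha,
                    hb,
                    source_dbs=data.get("source_dbs", ()),
                    detection_methods=data.get("detection_methods", ()),
                    pubmed_ids=data.get("pubmed_ids", ()),
                    origins={tag} | set(data.get("origins", ())),
                )
    for h in query_images:
        out.graph.add_node(h)
        out.graph.nodes[h]["is_query"] = True
    out.stats = {"n_dropped_unmapped": n_unmapped, "n_dropped_self_pairs": n_self}
    logger.info(
        "projected taxid %s: %d edges kept, %d unmapped, %d self-pairs dropped",
        net.taxid,
        out.n_edges,
        n_unmapped,
        n_self,
    )
    return out


def subtract_known(
    interolog_net: SpeciesNetwork, human_net: SpeciesNetwork
) -> SpeciesNetwork:
    """Remove projected edges already described in the human network.

    Both networks must be in the human identifier namespace.  The node set of
    the result is pruned to edge endpoints plus projected query nodes (nodes
    flagged ``is_query``), so the candidate-interolog network contains only
    what survives the subtraction.
    """
    known = human_net.edge_set()
    out = SpeciesNetwork(
        taxid=interolog_net.taxid,
        origin=interolog_net.origin,
        unmatched_queries=interolog_net.unmatched_queries,
    )
    n_removed = 0
    for a, b in interolog_net.graph.edges:
        if canonical_pair(a, b) in known:
            n_removed += 1
            continue
        data = interolog_net.graph.edges[a, b]
        out.add_edge(
            a,
            b,
            source_dbs=data.get("source_dbs", ()),
            detection_methods=data.get("detection_methods", ()),
            pubmed_ids=data.get("pubmed_ids", ()),
            origins=data.get("origins", ()),
        )
    for node, data in interolog_net.graph.nodes(data=True):
        if data.get("is_query"):
            out.graph.add_node(node)
            out.graph.nodes[node]["is_query"] = True
    out.stats = dict(interolog_net.stats, n_removed_known=n_removed)
    return out
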