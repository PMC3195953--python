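"""GO over-representation and functional-map construction.

Enrichment of a protein set is tested per term with the hypergeometric
upper tail: for a universe of N proteins of which K are annotated to a term,
and a member set of size n overlapping the term in k proteins,
``p = P(X >= k)`` for X ~ Hypergeometric(N, K, n).  Annotations are taken as
given flat sets — no parent-child propagation through the ontology graph is
performed here; propagate upstream when preparing the annotation table if
desired.

The functional map summarises the significant terms as a graph: one node per
term passing the significance and minimum-overlap filters, an edge between
two terms when their protein memberships agree above an overlap threshold
(Cohen's kappa on the binary membership vectors by default, Jaccard as an
alternative), and a group label per connected cluster taken from its most
significant term.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ppi_io import PathLike, StreamLike, _open_lines

logger = logging.getLogger(__name__)

BIOLOGICAL_PROCESS = "biological_process"

_GAF_ASPECTS = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}

_ADJUST_METHODS = {
    "benjamini-hochberg": "fdr_bh",
    "bh": "fdr_bh",
    "bonferroni": "bonferroni",
}


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    name: str
    namespace: str
    proteins: frozenset[str]


@dataclass
class AnnotationSet:
    """Flat term -> protein-set annotations over a background universe.

    Every annotated protein is a member of the universe; restricting the
    universe (e.g. to the proteins the interaction data could have returned)
    restricts the annotations accordingly.
    """

    terms: dict[str, TermAnnotation] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        annotated = set().union(*(t.proteins for t in self.terms.values())) if self.terms else set()
        if not annotated <= self.universe:
            self.universe = self.universe | annotated

    def with_universe(self, universe: Iterable[str]) -> "AnnotationSet":
        """Restrict background and annotations to ``universe``."""
        universe = set(universe)
        terms = {
            tid: replace(t, proteins=frozenset(t.proteins & universe))
            for tid, t in self.terms.items()
        }
        terms = {tid: t for tid, t in terms.items() if t.proteins}
        out = AnnotationSet(terms=terms, universe=universe)
        out.universe = universe
        return out

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, str]],
        namespace: str | None = None,
        universe: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Build from (protein, term_id, term_name, namespace) tuples."""
        proteins_by_term: dict[str, set[str]] = {}
        meta: dict[str, tuple[str, str]] = {}
        for protein, term_id, term_name, ns in records:
            if namespace and ns and ns != namespace:
                continue
            proteins_by_term.setdefault(term_id, set()).add(protein)
            meta.setdefault(term_id, (term_name, ns))
        terms = {
            tid: TermAnnotation(tid, meta[tid][0] or tid, meta[tid][1], frozenset(members))
            for tid, members in proteins_by_term.items()
        }
        return cls(terms=terms, universe=set(universe) if universe is not None else set())

    @classmethod
    def from_tsv(
        cls,
        stream: StreamLike,
        namespace: str | None = None,
        universe: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Read a simple annotation TSV: protein, term_id, term_name[, namespace].

        A header line starting with ``protein`` is tolerated; '#' comments
        are skipped.
        """
        lines, closer = _open_lines(stream)
        try:
            records = []
            for line in lines:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[0] == "protein":
                    continue
                if len(f) < 2:
                    continue
                records.append(
                    (
                        f[0].strip(),
                        f[1].strip(),
                        f[2].strip() if len(f) > 2 else "",
                        f[3].strip() if len(f) > 3 else "",
                    )
                )
        finally:
            if closer is not None:
                closer.close()
        return cls.from_records(records, namespace=namespace, universe=universe)

    @classmethod
    def from_gaf(
        cls,
        stream: StreamLike,
        namespace: str | None = BIOLOGICAL_PROCESS,
        universe: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Adapter for GAF 2.x: columns 3 (symbol), 5 (GO id), 9 (aspect).

        GAF carries no term names, so the term id doubles as the name.
        """
        lines, closer = _open_lines(stream)
        try:
            records = []
            for line in lines:
                if not line.strip() or line.startswith("!"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                ns = _GAF_ASPECTS.get(f[8].strip(), "")
                records.append((f[2].strip(), f[4].strip(), f[4].strip(), ns))
        finally:
            if closer is not None:
                closer.close()
        return cls.from_records(records, namespace=namespace, universe=universe)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one term in a member set."""

    term_id: str
    term_name: str
    k: int  # members annotated to the term
    n: int  # member-set size (within universe)
    K: int  # universe proteins annotated to the term
    N: int  # universe size
    p: float
    members: frozenset[str] = frozenset()
    p_adj: float | None = None


def enrich(member_set: Iterable[str], ann: AnnotationSet) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of every term overlapping members.

    Symbols outside the universe are dropped (and logged).  Terms with
    ``k = 0`` are absent from the output; results are sorted by ascending p
    (ties broken by term id).
    """
    if not ann.universe:
        raise ValueError("annotation universe is empty")
    members = set(member_set)
    outside = members - ann.universe
    if outside:
        logger.info("%d member symbols outside the annotation universe dropped", len(outside))
    members &= ann.universe
    N = len(ann.universe)
    n = len(members)
    results = []
    for term in ann.terms.values():
        annotated = term.proteins & ann.universe
        overlap = annotated & members
        k = len(overlap)
        if k == 0:
            continue
        K = len(annotated)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.name,
                k=k,
                n=n,
                K=K,
                N=N,
                p=min(p, 1.0),
                members=frozenset(overlap),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def adjust(
    results: Sequence[EnrichmentResult], method: str = "benjamini-hochberg"
) -> list[EnrichmentResult]:
    """Multiple-testing correction over all tested terms (order preserved)."""
    key = _ADJUST_METHODS.get(method.lower())
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    if not results:
        return []
    _rej, p_adj, *_ = multipletests([r.p for r in results], method=key)
    return [replace(r, p_adj=float(q)) for r, q in zip(results, p_adj)]


# ---------------------------------------------------------------------------
# functional map
# ---------------------------------------------------------------------------


def cohens_kappa(set_a: frozenset, set_b: frozenset, domain: frozenset) -> float:
    """Cohen's kappa between two binary membership vectors over ``domain``."""
    m = len(domain)
    if m == 0:
        return 0.0
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = m - a - b - c
    po = (a + d) / m
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (m * m)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def jaccard(set_a: frozenset, set_b: frozenset, domain: frozenset = frozenset()) -> float:
    union = set_a | set_b
    return len(set_a & set_b) / len(union) if union else 0.0


_OVERLAP_STATS = {"kappa": cohens_kappa, "jaccard": jaccard}


@dataclass
class FunctionalMap:
    """Term nodes with enrichment payloads, overlap edges, group labels."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node in sorted(self.graph.nodes):
            out.setdefault(self.graph.nodes[node]["group"], []).append(node)
        return out


def build_functional_map(
    results: Sequence[EnrichmentResult],
    ann: AnnotationSet | None = None,
    member_set: Iterable[str] | None = None,
    min_proteins: int = 8,
    alpha: float = 0.05,
    overlap_stat: str = "kappa",
    overlap_threshold: float = 0.4,
) -> FunctionalMap:
    """Build the functional map from adjusted enrichment results.

    Terms are kept when ``p_adj <= alpha`` and at least ``min_proteins`` of
    the member set carry the term (the overlap k, i.e. proteins from the
    interactome itself).  An edge joins two kept terms when their membership
    overlap statistic over the member set reaches ``overlap_threshold``.
    Connected clusters get a group label: the name of their most significant
    term.  The output is invariant to the input ordering of ``results``.
    """
    stat = _OVERLAP_STATS.get(overlap_stat)
    if stat is None:
        raise ValueError(f"unknown overlap statistic {overlap_stat!r}")
    missing = [r.term_id for r in results if r.p_adj is None]
    if missing:
        raise ValueError("results must carry p_adj; run adjust() first")
    kept = sorted(
        (r for r in results if r.p_adj <= alpha and r.k >= min_proteins),
        key=lambda r: (r.p_adj, r.p, r.term_id),
    )
    if member_set is not None:
        domain = frozenset(member_set)
    else:
        domain = frozenset().union(*(r.members for r in kept)) if kept else frozenset()
    fmap = FunctionalMap()
    g = fmap.graph
    for r in kept:
        g.add_node(r.term_id, result=r, term_name=r.term_name)
    for ra, rb in itertools.combinations(kept, 2):
        value = stat(ra.members, rb.members, domain)
        if value >= overlap_threshold:
            g.add_edge(ra.term_id, rb.term_id, overlap=float(value))
    for component in nx.connected_components(g):
        best = min(
            component,
            key=lambda t: (g.nodes[t]["result"].p_adj, g.nodes[t]["result"].p, t),
        )
        label = g.nodes[best]["result"].term_name
        for t in component:
            g.nodes[t]["group"] = label
    return fmap


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tk\tn\tK\tN\tp\tp_adj\tmembers\n")
        for r in results:
            p_adj = "" if r.p_adj is None else f"{r.p_adj:.6g}"
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p:.6g}\t{p_adj}\t{';'.join(sorted(r.members))}\n"
            )


def write_functional_map(fmap: FunctionalMap, prefix: PathLike) -> None:
    """Write ``<prefix>.sif`` and ``<prefix>.xgmml`` with term attributes."""
    from xml.etree import ElementTree as ET

    prefix = str(prefix)
    g = fmap.graph
    with open(prefix + ".sif", "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\tshares_proteins\t{b}\n")
        for t in sorted(t for t in g.nodes if g.degree(t) == 0):
            fh.write(f"{t}\n")
    root = ET.Element("graph", {"label": "functional_map", "directed": "0"})
    ids = {t: str(i) for i, t in enumerate(sorted(g.nodes))}
    for t in sorted(g.nodes):
        r: EnrichmentResult = g.nodes[t]["result"]
        el = ET.SubElement(root, "node", {"id": ids[t], "label": t})
        for name, value, type_ in (
            ("term_name", r.term_name, "string"),
            ("p_adj", f"{r.p_adj:.6g}", "real"),
            ("k", str(r.k), "integer"),
            ("group", g.nodes[t]["group"], "string"),
        ):
            ET.SubElement(el, "att", {"name": name, "value": value, "type": type_})
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        el = ET.SubElement(
            root, "edge", {"label": f"{a}-{b}", "source": ids[a], "target": ids[b]}
        )
        ET.SubElement(
            el,
            "att",
            {"name": "overlap", "value": f"{g.edges[a, b]['overlap']:.6g}", "type": "real"},
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(prefix + ".xgmml", encoding="unicode", xml_declaration=True)
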