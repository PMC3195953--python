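"""Parsing, normalisation and filtering of raw protein-interaction tables.

Public interaction databases (BioGRID, IntAct, HPRD, DIP, MINT, BIND, curated
literature tables) export protein-protein interactions in heterogeneous
tab-delimited dialects.  This module reduces them all to one canonical record
type (:class:`InteractionRecord`) and builds clean per-species simple graphs
(:class:`SpeciesNetwork`) from them.  The cleaning steps mirror the standard
curation funnel for interactome integration:

1. discard purely genetic interactions, keeping physical ones;
2. discard cross-species (inter-taxon) interactions;
3. split the pool into species-centred sets;
4. unify identifiers into a single namespace (HUGO-style symbols or UniProt
   accessions) through a user-supplied conversion map.

Self-interactions (homodimers) are retained as records and exported, but kept
out of the graph's edge set so that degree, clustering and assortativity keep
simple-graph semantics.  Edges are undirected and stored once under a
lexicographically sorted key; duplicate reports merge their provenance
(source databases, detection methods, PubMed ids) as set unions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

import networkx as nx

logger = logging.getLogger(__name__)

PHYSICAL = "physical"
GENETIC = "genetic"
CATEGORIES = (PHYSICAL, GENETIC)

#: Column order of the canonical 8-column interaction table.
CANONICAL_COLUMNS = (
    "id_a",
    "id_b",
    "taxid_a",
    "taxid_b",
    "category",
    "source_db",
    "detection_method",
    "pubmed_ids",
)

#: Columns that must be resolvable for a row to yield a record.
REQUIRED_COLUMNS = ("id_a", "id_b", "taxid_a", "taxid_b", "category", "source_db")

#: Column order of the canonical edge-table export.
EDGE_TABLE_COLUMNS = (
    "id_a",
    "id_b",
    "taxid",
    "source_dbs",
    "detection_methods",
    "pubmed_ids",
    "origins",
)

PathLike = Union[str, Path]
StreamLike = Union[PathLike, IO[str], Iterable[str]]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Undirected canonical edge key: the lexicographically sorted id pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One database or literature row: two interactors plus provenance."""

    id_a: str
    id_b: str
    taxid_a: int
    taxid_b: int
    category: str
    source_db: str = ""
    detection_method: str = ""
    pubmed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")

    @property
    def is_self(self) -> bool:
        return self.id_a == self.id_b

    @property
    def is_intra_species(self) -> bool:
        return self.taxid_a == self.taxid_b


@dataclass
class ParseResult:
    """Records parsed from a table plus the malformed-row count."""

    records: list[InteractionRecord]
    n_skipped: int = 0
    n_rows: int = 0

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class NormalizeResult:
    """Records after identifier unification plus the unresolved-drop count."""

    records: list[InteractionRecord]
    n_dropped: int = 0

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SpeciesNetwork:
    """Simple undirected interaction graph for one taxon.

    Edges carry merged provenance sets (``source_dbs``, ``detection_methods``,
    ``pubmed_ids``) and, after interolog projection, an ``origins`` set.
    Self-interactions live in :attr:`self_interactions`, never as graph loops.
    """

    taxid: int | None
    graph: nx.Graph = field(default_factory=nx.Graph)
    self_interactions: list[InteractionRecord] = field(default_factory=list)
    origin: str | None = None
    unmatched_queries: tuple[str, ...] = ()
    stats: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def add_edge(
        self,
        a: str,
        b: str,
        source_dbs: Iterable[str] = (),
        detection_methods: Iterable[str] = (),
        pubmed_ids: Iterable[str] = (),
        origins: Iterable[str] = (),
    ) -> None:
        """Insert or provenance-merge one undirected edge (no self-loops)."""
        if a == b:
            raise ValueError("self-loops are not stored as graph edges")
        a, b = canonical_pair(a, b)
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            data["source_dbs"].update(source_dbs)
            data["detection_methods"].update(detection_methods)
            data["pubmed_ids"].update(pubmed_ids)
            data["origins"].update(origins)
        else:
            self.graph.add_edge(
                a,
                b,
                source_dbs=set(source_dbs),
                detection_methods=set(detection_methods),
                pubmed_ids=set(pubmed_ids),
                origins=set(origins),
            )

    def copy(self) -> "SpeciesNetwork":
        return SpeciesNetwork(
            taxid=self.taxid,
            graph=self.graph.copy(),
            self_interactions=list(self.self_interactions),
            origin=self.origin,
            unmatched_queries=self.unmatched_queries,
            stats=dict(self.stats),
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _open_lines(stream: StreamLike):
    """Yield (lines, closer) for a path, file object or line iterable."""
    if isinstance(stream, (str, Path)):
        fh = open(stream, "r", encoding="utf-8")
        return fh, fh
    return stream, None


def _split_pubmed(raw: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in re.split(r"[;|,]", raw) if p.strip())


def parse_interactions(
    stream: StreamLike,
    column_map: Mapping[str, int | str] | None = None,
) -> ParseResult:
    """Parse a tab-delimited interaction table into canonical records.

    Parameters
    ----------
    stream
        Path, open text file, or iterable of lines.  ``#`` comment lines are
        ignored.  Without ``column_map`` the first non-comment line is taken
        as a header naming (at least) the required canonical columns.
    column_map
        Optional mapping from canonical column name to either a 0-based
        positional index (headerless file) or a header name.

    Returns
    -------
    ParseResult
        Parsed records plus the count of malformed rows, which are skipped
        with a logged warning rather than aborting the parse: real database
        dumps contain stray rows.

    Raises
    ------
    ValueError
        If a required column cannot be located (the offending column is
        named in the message).
    """
    lines, closer = _open_lines(stream)
    try:
        it = iter(lines)
        positional = column_map is not None and all(
            isinstance(v, int) for v in column_map.values()
        )
        if positional:
            index: dict[str, int] = dict(column_map)  # type: ignore[arg-type]
        else:
            header = None
            for line in it:
                if line.strip() and not line.startswith("#"):
                    header = line.rstrip("\n").split("\t")
                    break
            if header is None:
                return ParseResult([], 0, 0)
            names = {name: i for i, name in enumerate(header)}
            index = {}
            rename = dict(column_map or {})
            for col in CANONICAL_COLUMNS:
                source = rename.get(col, col)
                if source in names:
                    index[col] = names[source]
        for col in REQUIRED_COLUMNS:
            if col not in index:
                raise ValueError(f"required column {col!r} not found in interaction table")

        records: list[InteractionRecord] = []
        n_skipped = 0
        n_rows = 0
        for line in it:
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.rstrip("\n").split("\t")
            try:
                values = {
                    col: (fields[i].strip() if i < len(fields) else "")
                    for col, i in index.items()
                }
                category = values["category"].strip().lower()
                if category not in CATEGORIES:
                    raise ValueError(f"unknown interaction category {category!r}")
                rec = InteractionRecord(
                    id_a=values["id_a"],
                    id_b=values["id_b"],
                    taxid_a=int(values["taxid_a"]),
                    taxid_b=int(values["taxid_b"]),
                    category=category,
                    source_db=values.get("source_db", ""),
                    detection_method=values.get("detection_method", ""),
                    pubmed_ids=_split_pubmed(values.get("pubmed_ids", "")),
                )
            except (ValueError, IndexError) as exc:
                n_skipped += 1
                logger.warning("skipping malformed interaction row %d: %s", n_rows, exc)
                continue
            records.append(rec)
        return ParseResult(records, n_skipped, n_rows)
    finally:
        if closer is not None:
            closer.close()


# -- PSI-MI TAB 2.5 adapter --------------------------------------------------

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_PUBMED_RE = re.compile(r"pubmed:(\d+)")


_PAREN_RE = re.compile(r"\(([^)]+)\)")


def _mitab_first_value(cell: str) -> str:
    """``uniprotkb:P07900|...`` -> ``P07900``; ``psi-mi:"MI:0469"(IntAct)``
    -> ``IntAct`` (the parenthesised name is the human-readable term);
    ``-`` -> empty string."""
    cell = cell.strip()
    if not cell or cell == "-":
        return ""
    first = cell.split("|")[0]
    named = _PAREN_RE.search(first)
    if named:
        return named.group(1)
    if ":" in first:
        first = first.split(":", 1)[1]
    return first.strip('"')


def _mitab_taxid(cell: str) -> int | None:
    m = _TAXID_RE.search(cell)
    return int(m.group(1)) if m else None


def parse_psimitab(stream: StreamLike) -> ParseResult:
    """Convenience adapter: read PSI-MI TAB 2.5 into canonical records.

    Uses columns 1/2 (interactor ids), 7 (detection method), 9 (publication
    ids), 10/11 (taxids), 12 (interaction type -> category) and 13 (source
    database).  An interaction type naming a genetic interaction maps to the
    ``genetic`` category; everything else is treated as physical.
    """
    lines, closer = _open_lines(stream)
    try:
        records: list[InteractionRecord] = []
        n_skipped = 0
        n_rows = 0
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            f = line.rstrip("\n").split("\t")
            if len(f) < 13:
                n_skipped += 1
                logger.warning("skipping short PSI-MI TAB row %d", n_rows)
                continue
            id_a = _mitab_first_value(f[0])
            id_b = _mitab_first_value(f[1])
            taxid_a = _mitab_taxid(f[9])
            taxid_b = _mitab_taxid(f[10])
            if not id_a or not id_b or taxid_a is None or taxid_b is None:
                n_skipped += 1
                logger.warning("skipping unresolvable PSI-MI TAB row %d", n_rows)
                continue
            category = GENETIC if "genetic" in f[11].lower() else PHYSICAL
            records.append(
                InteractionRecord(
                    id_a=id_a,
                    id_b=id_b,
                    taxid_a=taxid_a,
                    taxid_b=taxid_b,
                    category=category,
                    source_db=_mitab_first_value(f[12]),
                    detection_method=_mitab_first_value(f[6]),
                    pubmed_ids=tuple(_PUBMED_RE.findall(f[8])),
                )
            )
        return ParseResult(records, n_skipped, n_rows)
    finally:
        if closer is not None:
            closer.close()


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_physical(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Keep physical interactions only; purely genetic ones are discarded."""
    return [r for r in records if r.category == PHYSICAL]


def filter_intra_species(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Drop interactions reported between proteins of different species."""
    return [r for r in records if r.is_intra_species]


def normalize_ids(
    records: Sequence[InteractionRecord],
    id_map: Mapping[str, Union[str, Sequence[str]]],
    policy: str = "passthrough",
) -> NormalizeResult:
    """Rewrite both interactor ids through a conversion map.

    A map value may be a single identifier or a sequence of identifiers; a
    one-to-many entry duplicates the record to every combination (curation
    choice for ambiguous isoforms, e.g. a report naming only "Hsp90" can be
    mapped to both cytosolic isoform symbols).

    policy
        ``"passthrough"`` keeps unmapped ids as-is; ``"strict"`` drops
        records containing an unmapped id and counts the drops.
    """
    if policy not in ("passthrough", "strict"):
        raise ValueError(f"unknown normalization policy {policy!r}")

    def targets(identifier: str) -> list[str] | None:
        if identifier in id_map:
            value = id_map[identifier]
            if isinstance(value, str):
                return [value]
            return list(value)
        if policy == "strict":
            return None
        return [identifier]

    out: list[InteractionRecord] = []
    n_dropped = 0
    for rec in records:
        ta = targets(rec.id_a)
        tb = targets(rec.id_b)
        if ta is None or tb is None:
            n_dropped += 1
            logger.warning("dropping record with unresolvable id: %s - %s", rec.id_a, rec.id_b)
            continue
        for a in ta:
            for b in tb:
                out.append(replace(rec, id_a=a, id_b=b))
    return NormalizeResult(out, n_dropped)


# ---------------------------------------------------------------------------
# network construction and round-trip formats
# ---------------------------------------------------------------------------


def build_species_network(
    records: Sequence[InteractionRecord], taxid: int
) -> SpeciesNetwork:
    """Collapse records of one taxon into a provenance-merged simple graph.

    Records are expected to be physical-only and intra-species already; rows
    whose taxids differ from ``taxid`` are ignored.  Both orientations of a
    pair collapse onto the canonical sorted key; self-pairs are diverted to
    the network's side list of self-interactions (their node is still added).
    """
    net = SpeciesNetwork(taxid=taxid)
    for rec in records:
        if rec.taxid_a != taxid or rec.taxid_b != taxid:
            continue
        if rec.is_self:
            net.self_interactions.append(rec)
            net.graph.add_node(rec.id_a)
            continue
        net.add_edge(
            rec.id_a,
            rec.id_b,
            source_dbs=[rec.source_db] if rec.source_db else [],
            detection_methods=[rec.detection_method] if rec.detection_method else [],
            pubmed_ids=rec.pubmed_ids,
        )
    return net


def _join(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def write_edge_table(net: SpeciesNetwork, path: PathLike) -> None:
    """Write the canonical tab-delimited edge table (sorted, round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for a, b in sorted(net.edge_set()):
            data = net.graph.edges[a, b]
            fh.write(
                "\t".join(
                    (
                        a,
                        b,
                        str(net.taxid if net.taxid is not None else ""),
                        _join(data.get("source_dbs", ())),
                        _join(data.get("detection_methods", ())),
                        _join(data.get("pubmed_ids", ())),
                        _join(data.get("origins", ())),
                    )
                )
                + "\n"
            )


def read_edge_table(path: PathLike) -> SpeciesNetwork:
    """Re-read a canonical edge table written by :func:`write_edge_table`."""
    net: SpeciesNetwork | None = None
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("id_a", "id_b", "taxid"):
            if name not in idx:
                raise ValueError(f"edge table missing column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def col(name: str) -> str:
                i = idx.get(name)
                return f[i] if i is not None and i < len(f) else ""

            taxid = int(col("taxid")) if col("taxid") else None
            if net is None:
                net = SpeciesNetwork(taxid=taxid)
            net.add_edge(
                col("id_a"),
                col("id_b"),
                source_dbs=[s for s in col("source_dbs").split(";") if s],
                detection_methods=[s for s in col("detection_methods").split(";") if s],
                pubmed_ids=[s for s in col("pubmed_ids").split(";") if s],
                origins=[s for s in col("origins").split(";") if s],
            )
    return net if net is not None else SpeciesNetwork(taxid=None)


def write_sif(net: SpeciesNetwork, path: PathLike, relation: str = "pp") -> None:
    """Simple interaction format: ``node<TAB>pp<TAB>node`` per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        for a, b in sorted(net.edge_set()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in isolated:
            fh.write(f"{n}\n")
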