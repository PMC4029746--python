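"""Interaction-network data model and readers.

Protein interaction networks are simple undirected graphs: nodes are
opaque protein identifiers, edges are physical interactions.  Self-loops
are dropped and duplicate reports of the same unordered pair are
collapsed into one edge, keeping the union of detection-method codes —
the usual distinction between *raw* and *non-redundant* interaction
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "EdgeRef",
    "ComplexRecord",
    "LoadSummary",
    "canonical_edge",
    "read_edge_list",
    "write_edge_list",
    "filter_by_method",
    "read_complexes",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (lexicographic) storage order for an unordered pair."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EdgeRef:
    """An unordered protein pair, stored with u < v."""

    u: str
    v: str

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError(f"self-interaction {self.u!r} is not a valid edge")
        if self.u > self.v:
            u, v = self.v, self.u
            object.__setattr__(self, "u", u)
            object.__setattr__(self, "v", v)

    def as_tuple(self) -> tuple[str, str]:
        return (self.u, self.v)


@dataclass
class LoadSummary:
    """Bookkeeping for an edge-list load: raw rows vs surviving edges."""

    raw: int = 0
    nonredundant: int = 0
    self_loops: int = 0
    duplicates: int = 0

    def conserved(self) -> bool:
        return self.raw == self.nonredundant + self.duplicates + self.self_loops


@dataclass
class ComplexRecord:
    complex_id: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"complex {self.complex_id!r} has no members")


class InteractionNetwork:
    """Simple undirected interaction network backed by a networkx Graph.

    Invariants: no self-loops, no duplicate edges, every edge endpoint in
    the node set.  Per-edge ``methods`` attributes hold the set of
    detection-method MI codes under which the interaction was reported.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in self.graph.edges()):
            raise ValueError("self-loops are not allowed")

    # -- container protocol -------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def add_edge(self, u: str, v: str, methods: set[str] | None = None) -> bool:
        """Add one interaction; returns False for self-loops (dropped).

        Re-adding an existing pair merges method attributes instead of
        creating a duplicate.
        """
        if u == v:
            return False
        if self.graph.has_edge(u, v):
            if methods:
                self.graph[u][v].setdefault("methods", set()).update(methods)
            return False
        self.graph.add_edge(u, v, methods=set(methods or ()))
        return True

    def edge_refs(self) -> list[EdgeRef]:
        return sorted(
            (EdgeRef(u, v) for u, v in self.graph.edges()),
            key=lambda e: e.as_tuple(),
        )

    def methods(self, u: str, v: str) -> set[str]:
        return self.graph[u][v].get("methods", set())


def _parse_mitab_id(raw_field: str) -> str:
    """First identifier of a PSI-MI TAB id column, without the db prefix."""
    first = raw_field.split("|")[0].strip()
    if ":" in first:
        return first.split(":", 1)[1].strip().strip('"')
    return first


def _parse_mitab_method(raw_field: str) -> str | None:
    """Extract the MI code from a column-7 entry like psi-mi:"MI:0018"(two hybrid)."""
    first = raw_field.split("|")[0].strip()
    if first in ("-", ""):
        return None
    if ":" in first:
        payload = first.split(":", 1)[1]
    else:
        payload = first
    payload = payload.split("(")[0].strip().strip('"')
    return payload or None


def read_edge_list(path, format: str = "tsv") -> tuple[InteractionNetwork, LoadSummary]:
    """Read an interaction network from a TSV edge list or PSI-MI TAB file.

    TSV rows need >= 2 tab-separated columns (extra columns ignored,
    ``#`` comment lines skipped).  MITAB rows need >= 15 columns;
    interactor ids come from columns 1-2 and the detection-method MI code
    from column 7 is kept as an edge attribute.

    Returns the simple network together with a :class:`LoadSummary`
    (raw = nonredundant + duplicates + self_loops).
    """
    if format not in ("tsv", "mitab"):
        raise ValueError(f"unknown edge-list format {format!r}")
    net = InteractionNetwork()
    summary = LoadSummary()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "tsv":
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected >=2 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                u, v = fields[0].strip(), fields[1].strip()
                methods: set[str] = set()
            else:
                if len(fields) < 15:
                    raise ValueError(
                        f"{path}: line {lineno}: PSI-MI TAB rows need >=15 "
                        f"columns, got {len(fields)}"
                    )
                u = _parse_mitab_id(fields[0])
                v = _parse_mitab_id(fields[1])
                mi = _parse_mitab_method(fields[6])
                methods = {mi} if mi else set()
            if not u or not v:
                raise ValueError(f"{path}: line {lineno}: empty interactor id")
            summary.raw += 1
            if u == v:
                summary.self_loops += 1
                continue
            if net.has_edge(u, v):
                summary.duplicates += 1
                net.add_edge(u, v, methods)  # merges method attributes
            else:
                net.add_edge(u, v, methods)
                summary.nonredundant += 1
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: no interactions found (empty network)")
    logger.info(
        "loaded %s: raw=%d nonredundant=%d duplicates=%d self_loops=%d",
        path, summary.raw, summary.nonredundant, summary.duplicates,
        summary.self_loops,
    )
    return net, summary


def write_edge_list(net: InteractionNetwork, path) -> None:
    """Write the canonicalized edge set as a 2-column TSV."""
    with open(path, "w") as fh:
        for e in net.edge_refs():
            fh.write(f"{e.u}\t{e.v}\n")


def filter_by_method(net: InteractionNetwork, keep: set[str]) -> InteractionNetwork:
    """Subnetwork of edges reported by at least one method code in *keep*.

    Nodes not covered by a surviving edge are pruned.  An empty result is
    allowed (logged as a warning) so callers can probe method codes.
    """
    if not keep:
        raise ValueError("keep must contain at least one MI method code")
    sub = InteractionNetwork()
    for u, v, data in net.graph.edges(data=True):
        methods = data.get("methods", set())
        if methods & keep:
            sub.add_edge(u, v, methods)
    if sub.number_of_edges() == 0:
        logger.warning("filter_by_method: no edge matches %s", sorted(keep))
    return sub


def read_complexes(path) -> list[ComplexRecord]:
    """Read a complex membership table.

    Format: TSV with ``complex_id<TAB>member;member;...``.  Members are
    deduplicated; duplicate complex ids are an error.
    """
    records: list[ComplexRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected complex_id<TAB>members"
                )
            cid = fields[0].strip()
            if cid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate complex id {cid!r}")
            seen.add(cid)
            members = {m.strip() for m in fields[1].split(";") if m.strip()}
            records.append(ComplexRecord(cid, members))
    return records
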