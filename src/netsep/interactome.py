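"""Interactome and gene-set handling.

The interactome is an undirected, simple (no self-loops, no parallel
edges) graph over opaque gene/protein identifiers, held as a
:class:`networkx.Graph`.  Gene sets arrive in GMT format; a set mapped
onto the interactome becomes a :class:`MappedModule`.  All distance
primitives are unweighted hop counts.

Identifier matching is exact, case-sensitive string equality: alias
resolution is upstream curation and deliberately not attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneSet",
    "MappedModule",
    "DistanceTable",
    "ShortestPaths",
    "load_interactome",
    "write_edgelist_tsv",
    "write_graphml",
    "restrict_to_lcc",
    "load_gene_sets",
    "write_gene_sets",
    "map_gene_set",
    "min_distances",
]


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (set semantics)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MappedModule:
    """A gene set intersected with the interactome's node set.

    ``mapped`` holds the members found in the network; ``unmapped_count``
    the members lost to interactome incompleteness, so that
    ``len(mapped) + unmapped_count`` equals the original set size.
    """

    name: str
    mapped: frozenset[str]
    unmapped_count: int = 0

    def __post_init__(self):
        if not self.mapped:
            raise ValueError(f"module {self.name!r}: no members in interactome")
        if self.unmapped_count < 0:
            raise ValueError("unmapped_count must be non-negative")

    def __len__(self) -> int:
        return len(self.mapped)


@dataclass(frozen=True)
class DistanceTable:
    """Per-source minimum hop distance to a target set."""

    sources: frozenset[str]
    targets: frozenset[str]
    distances: Mapping[str, int]


def _parse_edge_line(fields: Sequence[str], dialect: str, path, lineno: int):
    """Yield (u, v) pairs encoded by one line."""
    if dialect == "tsv-edgelist":
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        yield fields[0], fields[1]
    elif dialect == "sif":
        # SIF: source relation target [target ...]
        if len(fields) < 3:
            raise ParseError(path, lineno, f"SIF line needs >= 3 fields, got {len(fields)}")
        for tgt in fields[2:]:
            yield fields[0], tgt
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown dialect {dialect!r}")


def load_interactome(path, dialect: str = "tsv-edgelist") -> nx.Graph:
    """Load an undirected interactome from an edge-list or SIF file.

    Lines are split on any whitespace; lines starting with ``#`` and blank
    lines are skipped.  Self-loops and duplicate edges are dropped (with a
    logged count); the graph is simple and undirected.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv-edgelist"`` (two whitespace-separated columns) or ``"sif"``
        (``node relation node [node ...]``).

    Raises
    ------
    ParseError
        On a malformed line (names the line number).
    OSError
        If the file cannot be read.
    """
    if dialect not in ("tsv-edgelist", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    g = nx.Graph()
    self_loops = 0
    duplicates = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            for u, v in _parse_edge_line(stripped.split(), dialect, path, lineno):
                if u == v:
                    self_loops += 1
                    g.add_node(u)
                elif g.has_edge(u, v):
                    duplicates += 1
                else:
                    g.add_edge(u, v)
    if self_loops or duplicates:
        logger.info(
            "load_interactome(%s): dropped %d self-loops, %d duplicate edges",
            path, self_loops, duplicates,
        )
    logger.info(
        "load_interactome(%s): %d nodes, %d edges",
        path, g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def write_edgelist_tsv(g: nx.Graph, path) -> None:
    """Write the interactome as a sorted 2-column TSV (round-trips with
    :func:`load_interactome`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def write_graphml(g: nx.Graph, path) -> None:
    """Write the graph as GraphML with canonically ordered nodes/edges."""
    canon = nx.Graph()
    canon.add_nodes_from(sorted(g.nodes(), key=str))
    for u, v in sorted(tuple(sorted(e, key=str)) for e in g.edges()):
        canon.add_edge(u, v, **g.edges[u, v])
    for n in canon.nodes:
        canon.nodes[n].update(g.nodes[n])
    nx.write_graphml(canon, path)


def restrict_to_lcc(g: nx.Graph) -> nx.Graph:
    """Return the subgraph induced by the largest connected component.

    Ties between equal-size components are broken by the lexicographically
    smallest member identifier.  Idempotent.  All distance-based statistics
    downstream run on this subgraph so that every hop distance is finite.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take the LCC of an empty graph")
    comps = list(nx.connected_components(g))
    best = max(comps, key=lambda c: (len(c), _neg_lex(min(c, key=str))))
    if len(best) < g.number_of_nodes():
        logger.warning(
            "restrict_to_lcc: keeping %d of %d nodes (largest connected component)",
            len(best), g.number_of_nodes(),
        )
    return g.subgraph(best).copy()


class _neg_lex:
    """Ordering adaptor: greater when the wrapped string sorts smaller."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = str(s)

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def load_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file (``name<TAB>description<TAB>member...`` per line).

    Duplicate members within a line are collapsed with a warning; empty
    lines are skipped.  A line with fewer than three fields raises
    :class:`ParseError`.
    """
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"GMT line needs >= 3 tab-separated fields, got {len(fields)}")
            name = fields[0]
            members = fields[2:]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "load_gene_sets(%s): set %r has %d duplicate members (collapsed)",
                    path, name, len(members) - len(unique),
                )
            sets.append(GeneSet(name=name, members=unique))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path, descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets as GMT, members sorted for reproducibility."""
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            desc = descriptions.get(s.name, "na")
            fh.write("\t".join([s.name, desc, *sorted(s.members)]) + "\n")


def map_gene_set(g: nx.Graph, s: GeneSet) -> MappedModule:
    """Intersect a gene set with the interactome's node set.

    Members absent from the network (interactome incompleteness) are
    counted in ``unmapped_count`` and logged.  Raises ``ValueError`` when
    no member maps at all.
    """
    mapped = frozenset(m for m in s.members if m in g)
    unmapped = len(s.members) - len(mapped)
    if unmapped:
        logger.info("map_gene_set: %r: %d/%d members not in interactome",
                    s.name, unmapped, len(s.members))
    return MappedModule(name=s.name, mapped=mapped, unmapped_count=unmapped)


def min_distances(
    g: nx.Graph,
    sources: Iterable[str],
    targets: Iterable[str],
    exclude_self: bool = False,
) -> DistanceTable:
    """Minimum hop distance from each source node to the target set.

    Breadth-first (unweighted) semantics on a connected graph.  With
    ``exclude_self`` the minimum for a source ``a`` is taken over
    ``targets - {a}`` — the convention used for self-proximity, where a
    node must find its nearest *other* module member.

    Raises ``ValueError`` if some source is missing from the graph, or if
    ``exclude_self`` leaves a source with an empty target set.
    """
    src = frozenset(sources)
    tgt = frozenset(targets)
    missing = (src | tgt) - set(g.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)[:5]}")
    if not tgt:
        raise ValueError("empty target set")

    dist: dict[str, int] = {}
    if not exclude_self:
        # one multi-source BFS from the targets reaches every source
        lengths = nx.multi_source_dijkstra_path_length(g, tgt, weight=None)
        for a in src:
            dist[a] = int(lengths[a])
    else:
        for a in src:
            others = tgt - {a}
            if not others:
                raise ValueError(
                    f"exclude_self: node {a!r} has no other target (singleton self-comparison)"
                )
            lengths = nx.single_source_shortest_path_length(g, a)
            dist[a] = min(int(lengths[b]) for b in others)
    return DistanceTable(sources=src, targets=tgt, distances=dist)


class ShortestPaths:
    """All-pairs unweighted distance matrix with a label index.

    The heavy-duty backend for separation statistics: one BFS sweep over
    the (LCC-restricted) interactome, then every module pair and every
    permutation replicate reduces to array indexing.  Memory is
    ``8 n^2`` bytes, fine for networks up to a few tens of thousands of
    nodes.
    """

    def __init__(self, g: nx.Graph):
        if g.number_of_nodes() == 0:
            raise ValueError("empty graph")
        if not nx.is_connected(g):
            raise ValueError("graph must be connected; apply restrict_to_lcc first")
        self.nodes: list[str] = sorted(g.nodes(), key=str)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self.adjacency: csr_matrix = nx.to_scipy_sparse_array(g, nodelist=self.nodes, format="csr")
        self.dist: np.ndarray = shortest_path(self.adjacency, method="D", unweighted=True)
        self.degrees: np.ndarray = np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def __len__(self) -> int:
        return len(self.nodes)

    def idx(self, members: Iterable[str]) -> np.ndarray:
        """Sorted integer indices for a collection of node labels."""
        return np.array(sorted(self.index[m] for m in members), dtype=np.intp)
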