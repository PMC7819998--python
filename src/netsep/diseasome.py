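"""Disease-level aggregation: matrices, clustering, and the diseasome.

Pairwise separation results are collected into symmetric matrices of
s, p-value and the generalized measure s~.  Diseases are clustered by
complete-linkage agglomeration with s as the distance (shifted to be
non-negative; a uniform shift does not change complete-linkage merge
order).  The disease network links two diseases when the generalized
separation between them is strongly negative relative to each disease's
own distribution of negative s~ values: an edge (D, E) is admitted when
s~(D,E) lies below the 75th percentile of the negative s~ values of D
(or of E — union rule by default; an intersection variant is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._seeds import subseed
from .interactome import MappedModule, ShortestPaths, write_graphml
from .localization import build_degree_bins
from .separation import SeparationConfig, SeparationResult, separation_significance

__all__ = [
    "PairwiseMatrix",
    "ClusteringResult",
    "Diseasome",
    "pairwise_separation_matrix",
    "cluster_diseases",
    "build_shdn",
    "cross_collection_separation",
    "export_diseasome",
    "significance_stars",
]


@dataclass(frozen=True)
class PairwiseMatrix:
    """Square symmetric matrices of s, p and s~ over ordered disease labels.

    Diagonal convention: s = 0, s~ = 0, p = 1.
    """

    labels: tuple[str, ...]
    s: np.ndarray
    p: np.ndarray
    s_tilde: np.ndarray
    results: tuple[SeparationResult, ...] = ()

    def __post_init__(self):
        n = len(self.labels)
        for m in (self.s, self.p, self.s_tilde):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match labels")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError("matrix is not symmetric")
        if np.isnan(self.s).any():
            raise ValueError("matrix has missing entries")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClusteringResult:
    """Complete-linkage merge history plus a deterministic leaf order."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix on the shifted scale
    leaf_order: tuple[str, ...]
    shift: float  # added to s to make distances non-negative

    @property
    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge history as (cluster, cluster, height) with leaf labels."""
        n = len(self.labels)
        clusters: dict[int, frozenset] = {i: frozenset([l]) for i, l in enumerate(self.labels)}
        out = []
        for k, (i, j, h, _) in enumerate(self.linkage):
            a, b = clusters[int(i)], clusters[int(j)]
            out.append((a, b, float(h)))
            clusters[n + k] = a | b
        return out


@dataclass(frozen=True)
class Diseasome:
    """The disease network: nodes are diseases, edges pass the percentile rule."""

    graph: nx.Graph
    thresholds: dict[str, float]
    edge_rule: str


def pairwise_separation_matrix(
    g: nx.Graph | ShortestPaths,
    modules: Sequence[MappedModule],
    cfg: SeparationConfig | None = None,
) -> PairwiseMatrix:
    """Separation significance for every unordered module pair.

    Pairs are processed in sorted-label order and each pair draws its
    null from a sub-seed derived from the run seed and the two names, so
    the matrix is reproducible regardless of input order.
    """
    cfg = cfg or SeparationConfig()
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    by_name = {m.name: m for m in modules}
    if len(by_name) != len(modules):
        raise ValueError("duplicate module names")
    labels = tuple(sorted(by_name))

    from .separation import _prepare_paths  # shared LCC preparation
    sp = _prepare_paths(g)
    graph = nx.from_scipy_sparse_array(sp.adjacency)
    graph = nx.relabel_nodes(graph, dict(enumerate(sp.nodes)))
    bins = build_degree_bins(graph, min_occupancy=cfg.min_occupancy)

    n = len(labels)
    s = np.zeros((n, n))
    p = np.ones((n, n))
    st = np.zeros((n, n))
    results = []
    for i in range(n):
        for j in range(i + 1, n):
            pair_cfg = SeparationConfig(
                alpha=cfg.alpha, replicates=cfg.replicates, level=cfg.level,
                seed=subseed(cfg.seed, "pair", labels[i], labels[j]),
                min_occupancy=cfg.min_occupancy,
            )
            res = separation_significance(sp, by_name[labels[i]], by_name[labels[j]],
                                          cfg=pair_cfg, bins=bins)
            s[i, j] = s[j, i] = res.s
            p[i, j] = p[j, i] = res.p
            st[i, j] = st[j, i] = res.s_tilde
            results.append(res)
    return PairwiseMatrix(labels=labels, s=s, p=p, s_tilde=st, results=tuple(results))


def _leaf_order(Z: np.ndarray, labels: Sequence[str]) -> tuple[str, ...]:
    """Recursive smaller-cluster-first ordering; ties lexicographic by the
    smallest leaf label."""
    n = len(labels)

    def leaves(node: int) -> list[str]:
        if node < n:
            return [labels[node]]
        i, j = int(Z[node - n, 0]), int(Z[node - n, 1])
        a, b = leaves(i), leaves(j)
        if (len(a), min(a)) > (len(b), min(b)):
            a, b = b, a
        return a + b

    return tuple(leaves(n + len(Z) - 1))


def cluster_diseases(m: PairwiseMatrix) -> ClusteringResult:
    """Complete-linkage hierarchical clustering with s as the distance.

    s can be negative (overlapping modules); the condensed distances are
    shifted by −min(s) when needed, which preserves complete-linkage
    merge order.  Heights are reported on the shifted scale, with the
    shift recorded so callers can undo it.
    """
    condensed = squareform(m.s, checks=False)
    mn = float(condensed.min()) if len(condensed) else 0.0
    shift = -mn if mn < 0 else 0.0
    Z = linkage(condensed + shift, method="complete")
    return ClusteringResult(
        labels=m.labels,
        linkage=Z,
        leaf_order=_leaf_order(Z, m.labels),
        shift=shift,
    )


def negative_percentile_threshold(values: np.ndarray, q: float = 75.0) -> float | None:
    """The q-th percentile (linear interpolation) of the negative entries,
    or ``None`` when there are none."""
    neg = values[values < 0]
    if neg.size == 0:
        return None
    return float(np.percentile(neg, q, method="linear"))


def build_shdn(
    m: PairwiseMatrix,
    metadata: Mapping[str, Mapping] | None = None,
    edge_rule: str = "union",
    percentile: float = 75.0,
) -> Diseasome:
    """Build the disease network by the per-disease percentile rule.

    For disease D let N_D be the negative s~(D, .) values; its threshold
    t_D is the ``percentile``-th percentile of N_D (linear
    interpolation).  The candidate edge (D, E) is admitted from D's side
    when s~(D,E) <= t_D (the threshold itself is always negative).  With the
    ``union`` rule an edge exists when either endpoint admits it; with
    ``intersection``, only when both do.  Diseases with no negative s~
    admit no edges of their own.  Edge weight is s~.
    """
    if edge_rule not in ("union", "intersection"):
        raise ValueError("edge_rule must be 'union' or 'intersection'")
    if m.n < 2:
        raise ValueError("need at least 2 diseases")
    metadata = metadata or {}
    off = ~np.eye(m.n, dtype=bool)

    thresholds: dict[str, float] = {}
    admits: dict[str, set[str]] = {}
    for i, d in enumerate(m.labels):
        row = m.s_tilde[i][off[i]]
        t = negative_percentile_threshold(row, percentile)
        if t is None:
            admits[d] = set()
            continue
        thresholds[d] = t
        # <= not <: strongly overlapping pairs can saturate to numerically
        # identical s~ values, and an exact tie with the percentile still
        # means "at least as overlapping as the admission threshold"
        admits[d] = {
            m.labels[j] for j in range(m.n)
            if j != i and m.s_tilde[i, j] <= t
        }

    g = nx.Graph()
    for i, d in enumerate(m.labels):
        attrs = dict(metadata.get(d, {}))
        g.add_node(d, **attrs)
    for i in range(m.n):
        for j in range(i + 1, m.n):
            a, b = m.labels[i], m.labels[j]
            fwd, rev = b in admits[a], a in admits[b]
            admitted = (fwd or rev) if edge_rule == "union" else (fwd and rev)
            if admitted:
                g.add_edge(a, b, s_tilde=float(m.s_tilde[i, j]))
    return Diseasome(graph=g, thresholds=thresholds, edge_rule=edge_rule)


def significance_stars(p: float) -> str:
    """Conventional significance flags: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cross_collection_separation(
    g: nx.Graph | ShortestPaths,
    collection_a: Sequence[MappedModule],
    collection_b: Sequence[MappedModule],
    cfg: SeparationConfig | None = None,
) -> pd.DataFrame:
    """Separation of every cross pair (A x B) plus every within-B pair.

    Used to compare one module collection (e.g., expression-derived
    modules) against an externally curated one: the typical readout is
    whether cross-collection separations are smaller than the curated
    collection's internal ones.  Returns a long-format frame with
    significance stars.
    """
    cfg = cfg or SeparationConfig()
    if not collection_a or not collection_b:
        raise ValueError("both collections must be non-empty")
    from .separation import _prepare_paths
    sp = _prepare_paths(g)
    graph = nx.from_scipy_sparse_array(sp.adjacency)
    graph = nx.relabel_nodes(graph, dict(enumerate(sp.nodes)))
    bins = build_degree_bins(graph, min_occupancy=cfg.min_occupancy)

    rows = []

    def _run(x: MappedModule, y: MappedModule, kind: str):
        pair_cfg = SeparationConfig(
            alpha=cfg.alpha, replicates=cfg.replicates, level=cfg.level,
            seed=subseed(cfg.seed, "xcoll", kind, x.name, y.name),
            min_occupancy=cfg.min_occupancy,
        )
        r = separation_significance(sp, x, y, cfg=pair_cfg, bins=bins)
        rows.append({
            "module_a": x.name, "module_b": y.name, "kind": kind,
            "p_ab": r.p_ab, "p_aa": r.p_aa, "p_bb": r.p_bb,
            "s": r.s, "z": r.z, "p": r.p, "s_tilde": r.s_tilde,
            "label": r.label, "stars": significance_stars(r.p),
        })

    for x in sorted(collection_a, key=lambda m: m.name):
        for y in sorted(collection_b, key=lambda m: m.name):
            _run(x, y, "cross")
    sb = sorted(collection_b, key=lambda m: m.name)
    for i in range(len(sb)):
        for j in range(i + 1, len(sb)):
            _run(sb[i], sb[j], "within_b")
    return pd.DataFrame(rows)


def _newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string for a scipy linkage matrix; branch lengths are height
    differences, leaves ordered smaller-cluster-first."""
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{labels[node]}:{bl:.6g}"
        i, j = int(Z[node - n, 0]), int(Z[node - n, 1])
        kids = sorted(
            (i, j),
            key=lambda k: (len(_leaves(k)), min(_leaves(k))),
        )
        inner = ",".join(render(k, height(node)) for k in kids)
        return f"({inner}):{bl:.6g}"

    def _leaves(node: int) -> list[str]:
        if node < n:
            return [labels[node]]
        return _leaves(int(Z[node - n, 0])) + _leaves(int(Z[node - n, 1]))

    root = n + len(Z) - 1
    i, j = int(Z[root - n, 0]), int(Z[root - n, 1])
    kids = sorted((i, j), key=lambda k: (len(_leaves(k)), min(_leaves(k))))
    inner = ",".join(render(k, height(root)) for k in kids)
    return f"({inner});"


def export_diseasome(
    d: Diseasome,
    c: ClusteringResult,
    m: PairwiseMatrix,
    out_dir,
    manifest_extra: Mapping | None = None,
) -> dict[str, Path]:
    """Write the disease network (GraphML), matrices (TSV), dendrogram
    (Newick) and a JSON run manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": out / "diseasome.graphml",
        "s_matrix": out / "matrix_s.tsv",
        "p_matrix": out / "matrix_p.tsv",
        "s_tilde_matrix": out / "matrix_s_tilde.tsv",
        "newick": out / "dendrogram.nwk",
        "manifest": out / "manifest.json",
    }
    write_graphml(d.graph, paths["graphml"])
    for key, mat in (("s_matrix", m.s), ("p_matrix", m.p), ("s_tilde_matrix", m.s_tilde)):
        pd.DataFrame(mat, index=list(m.labels), columns=list(m.labels)).to_csv(
            paths[key], sep="\t", float_format="%.10g"
        )
    paths["newick"].write_text(_newick(c.linkage, c.labels) + "\n", encoding="utf-8")
    manifest = {
        "labels": list(m.labels),
        "leaf_order": list(c.leaf_order),
        "clustering_shift": c.shift,
        "edge_rule": d.edge_rule,
        "thresholds": {k: v for k, v in sorted(d.thresholds.items())},
        "n_edges": d.graph.number_of_edges(),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
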