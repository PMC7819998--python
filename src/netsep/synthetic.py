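"""Synthetic interactome benchmarks with planted ground truth.

Real inputs to this kind of analysis are a heavy-tailed protein
interaction network and per-disease gene sets that (a) agglomerate in
network neighborhoods and (b) overlap between related diseases.  The
generator emulates exactly those two properties so every downstream
statistic can be validated against a known truth without any download:

* the interactome is a preferential-attachment (Barabási–Albert) graph —
  connected by construction, with a heavy-tailed degree distribution
  that exercises degree binning non-trivially;
* a planted module grows a connected core by randomized breadth-first
  expansion (its *cohesion* is the fraction of members grown connected
  vs. sprinkled uniformly at random);
* a module family plants classes of modules in mutually distant
  neighborhoods with exact pairwise member-overlap counts, giving
  cognate (overlapping, co-located) and non-cognate (distant) pairs by
  construction.

What this does NOT emulate: the real interactome's exact degree
sequence, its clustering/motif structure, or expression-derived gene
set noise.  Passing benchmarks here validates the statistics'
implementation and calibration, not biological discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._seeds import rng_for, subseed
from .interactome import GeneSet, write_edgelist_tsv, write_gene_sets

__all__ = [
    "PlantedModuleSpec",
    "BenchmarkSpec",
    "BenchmarkTruth",
    "generate_interactome",
    "plant_module",
    "plant_module_family",
    "write_benchmark",
    "default_benchmark_spec",
]


@dataclass(frozen=True)
class PlantedModuleSpec:
    """One module to plant: size, cohesion in [0,1], and a class label
    (modules of the same class share a network neighborhood)."""

    name: str
    size: int
    cohesion: float = 1.0
    klass: str = "default"

    def __post_init__(self):
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        if not 0 <= self.cohesion <= 1:
            raise ValueError("cohesion must be in [0, 1]")


@dataclass(frozen=True)
class BenchmarkSpec:
    """A full benchmark: graph parameters, planted modules, pairwise
    member-overlap fractions, and the run seed."""

    n_nodes: int
    attachment: int
    modules: tuple[PlantedModuleSpec, ...]
    overlap: Mapping[frozenset, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")
        if self.modules:
            if self.n_nodes < 10 * max(m.size for m in self.modules):
                raise ValueError("n_nodes must be >= 10 x the largest module")
        for pair, frac in self.overlap.items():
            if not 0 <= frac <= 1:
                raise ValueError("overlap fractions must be in [0, 1]")
            if len(pair) != 2 or not set(pair) <= set(names):
                raise ValueError(f"overlap key {set(pair)} does not name two modules")

    def overlap_fraction(self, a: str, b: str) -> float:
        return float(self.overlap.get(frozenset((a, b)), 0.0))


@dataclass(frozen=True)
class BenchmarkTruth:
    """What was actually planted: members, realized pairwise overlap
    counts, and realized cohesion (fraction of members in the module's
    induced LCC)."""

    members: dict[str, tuple[str, ...]]
    overlap_counts: dict[str, dict[str, int]]
    cohesion: dict[str, float]
    classes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "members": {k: list(v) for k, v in sorted(self.members.items())},
                "overlap_counts": {k: dict(sorted(v.items())) for k, v in sorted(self.overlap_counts.items())},
                "cohesion": dict(sorted(self.cohesion.items())),
                "classes": dict(sorted(self.classes.items())),
            },
            indent=2, sort_keys=True,
        )


def _node_label(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def generate_interactome(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Preferential-attachment interactome: ``n`` nodes, each newcomer
    attaching to ``m`` existing nodes, hence ``m * (n - m)`` edges.

    Simple, connected, heavy-tailed; node labels are zero-padded strings
    so identifier ordering is stable.  Deterministic under ``seed``.
    """
    if m < 1 or n < m + 1:
        raise ValueError("need n >= m + 1 >= 2")
    rng = rng_for(seed, "interactome")
    g = nx.barabasi_albert_graph(n, m, seed=np.random.RandomState(rng.integers(2**31)))
    width = len(str(n - 1))
    return nx.relabel_nodes(g, {i: _node_label(i, width) for i in g.nodes()})


def _connected_growth(
    g: nx.Graph,
    rng: np.random.Generator,
    k: int,
    seeds: Sequence[str],
    forbidden: set[str],
) -> list[str]:
    """Grow ``k`` nodes by randomized breadth-first expansion from
    ``seeds``: each step picks a uniform random unclaimed neighbor of the
    region grown so far, so every added node attaches to the region."""
    region = list(seeds)
    chosen: list[str] = []
    frontier: set[str] = set()
    for s in region:
        frontier.update(g.neighbors(s))
    frontier -= forbidden
    frontier -= set(region)
    while len(chosen) < k:
        if not frontier:
            raise ValueError("connected growth exhausted the graph")
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.append(pick)
        region.append(pick)
        frontier.discard(pick)
        frontier.update(set(g.neighbors(pick)) - forbidden - set(region))
    return chosen


def plant_module(g: nx.Graph, size: int, cohesion: float, seed: int = 0, name: str = "planted") -> GeneSet:
    """Plant one module: ``ceil(cohesion * size)`` members grown as a
    connected subgraph from a random seed node, the rest drawn uniformly
    from the remaining nodes.

    With cohesion 1 the induced subgraph is connected by construction;
    with cohesion 0 the set is a uniform random sample.
    """
    if not 0 <= cohesion <= 1:
        raise ValueError("cohesion must be in [0, 1]")
    if size > g.number_of_nodes():
        raise ValueError("module larger than the graph")
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = rng_for(seed, "plant", name)
    nodes = sorted(g.nodes(), key=str)
    k_conn = int(np.ceil(cohesion * size))
    members: list[str] = []
    if k_conn > 0:
        start = nodes[rng.integers(len(nodes))]
        members = [start] + _connected_growth(g, rng, k_conn - 1, [start], set())
    rest = [n for n in nodes if n not in set(members)]
    k_rand = size - len(members)
    if k_rand > 0:
        picked = rng.choice(len(rest), size=k_rand, replace=False)
        members.extend(rest[i] for i in picked)
    return GeneSet(name=name, members=frozenset(members))


def _distant_anchors(g: nx.Graph, k: int, rng: np.random.Generator) -> list[str]:
    """Greedy farthest-point anchors: start from a random node's most
    eccentric partner, then repeatedly add the node maximizing the
    minimum BFS distance to the chosen anchors (ties lexicographic)."""
    nodes = sorted(g.nodes(), key=str)
    start = nodes[rng.integers(len(nodes))]
    d0 = nx.single_source_shortest_path_length(g, start)
    first = min((n for n in nodes), key=lambda n: (-d0[n], n))
    anchors = [first]
    mindist = nx.single_source_shortest_path_length(g, first)
    while len(anchors) < k:
        nxt = min(nodes, key=lambda n: (-mindist[n], n))
        anchors.append(nxt)
        dn = nx.single_source_shortest_path_length(g, nxt)
        mindist = {n: min(mindist[n], dn[n]) for n in nodes}
    return anchors


def _growth_within(
    g: nx.Graph,
    rng: np.random.Generator,
    k: int,
    seeds: Sequence[str],
    ball: set[str],
    claimed: set[str],
) -> list[str]:
    """Grow ``k`` unclaimed nodes connected to ``seeds``, restricted to
    the class ball.  When the connected frontier runs dry the growth
    falls back to any unclaimed ball node (degrading cohesion, which the
    truth record reports)."""
    region = list(seeds)
    chosen: list[str] = []
    frontier: set[str] = set()
    for s in region:
        frontier.update(g.neighbors(s))
    frontier &= ball
    frontier -= claimed
    frontier -= set(region)
    while len(chosen) < k:
        if frontier:
            pick = sorted(frontier)[rng.integers(len(frontier))]
        else:
            spare = sorted(ball - claimed - set(region))
            if not spare:
                raise ValueError("class neighborhood exhausted; increase n_nodes")
            pick = spare[rng.integers(len(spare))]
        chosen.append(pick)
        region.append(pick)
        claimed.add(pick)
        frontier.discard(pick)
        frontier.update((set(g.neighbors(pick)) & ball) - claimed - set(region))
    return chosen


def plant_module_family(g: nx.Graph, spec: BenchmarkSpec) -> tuple[list[GeneSet], BenchmarkTruth]:
    """Plant a family of modules with exact pairwise shared-member counts.

    Classes are seeded at mutually distant anchor nodes (greedy
    farthest-point selection) and each class claims a compact connected
    *ball* grown around its anchor; every member of the class's modules
    lives inside that ball, so same-class modules interleave in one
    network neighborhood while different classes stay far apart.  Shared
    members for an overlapping pair form a dedicated pool (pools of
    different pairs are disjoint, which realizes the requested pairwise
    counts exactly); each module's remaining members grow connected to
    the module inside the ball up to its cohesion, then uniformly at
    random from outside.

    Raises ``ValueError`` when a module's shared counts exceed its size
    or the requested structure cannot be embedded.
    """
    if not spec.modules:
        raise ValueError("no modules to plant")
    rng = rng_for(spec.seed, "family")
    names = [m.name for m in spec.modules]
    by_name = {m.name: m for m in spec.modules}

    # exact shared counts per pair; feasibility per module
    shared_count: dict[frozenset, int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            frac = spec.overlap_fraction(a, b)
            if frac > 0:
                pair = frozenset((a, b))
                cnt = int(round(frac * min(by_name[a].size, by_name[b].size)))
                if cnt:
                    shared_count[pair] = cnt
    for nm in names:
        total_shared = sum(c for p, c in shared_count.items() if nm in p)
        if total_shared > by_name[nm].size:
            raise ValueError(f"module {nm!r}: shared members ({total_shared}) exceed size")
    for pair in shared_count:
        a, b = sorted(pair)
        if by_name[a].klass != by_name[b].klass:
            raise ValueError(
                f"overlapping modules {a!r}/{b!r} must share a class "
                "(overlap means co-location)"
            )

    classes = sorted({m.klass for m in spec.modules})
    anchors = dict(zip(classes, _distant_anchors(g, len(classes), rng)))

    # one compact connected ball per class, with ~50% slack so modules
    # can interleave without deadlocking
    reserved: set[str] = set(anchors.values())
    balls: dict[str, set[str]] = {}
    for c in classes:
        union = sum(by_name[nm].size for nm in names if by_name[nm].klass == c)
        union -= sum(cnt for p, cnt in shared_count.items()
                     if by_name[sorted(p)[0]].klass == c)
        size = max(union + 5, int(np.ceil(1.5 * union)))
        grown = _connected_growth(g, rng, size - 1, [anchors[c]], reserved - {anchors[c]})
        balls[c] = {anchors[c], *grown}
        reserved.update(balls[c])

    assigned: dict[str, set[str]] = {nm: set() for nm in names}
    claimed: dict[str, set[str]] = {c: set() for c in classes}

    def _pick(cands: set[str]) -> str:
        ordered = sorted(cands)
        return ordered[rng.integers(len(ordered))]

    # shared pools, round-robin one node at a time: each new pool node
    # must (when possible) attach to a *different* pool of the class, so
    # pools interleave and every pool member sits adjacent to the partner
    # modules — cognate modules coalesce into one neighborhood
    pools_by_class: dict[str, list[frozenset]] = {c: [] for c in classes}
    for pair in sorted(shared_count, key=lambda p: tuple(sorted(p))):
        pools_by_class[by_name[sorted(pair)[0]].klass].append(pair)
    pool_nodes: dict[frozenset, list[str]] = {p: [] for p in shared_count}
    for klass in classes:
        ball = balls[klass]
        pairs = pools_by_class[klass]
        remaining = {p: shared_count[p] for p in pairs}
        while any(remaining.values()):
            for pair in pairs:
                if remaining[pair] == 0:
                    continue
                own = set(pool_nodes[pair])
                others = set()
                for q in pairs:
                    if q != pair:
                        others.update(pool_nodes[q])
                core = others | own
                cands = set()
                for v in others:
                    cands.update(g.neighbors(v))
                cands = (cands & ball) - claimed[klass]
                if own and cands:
                    # attaching to own pool too keeps the module connected
                    both = {v for v in cands if any(u in own for u in g.neighbors(v))}
                    if both:
                        cands = both
                if not cands:
                    for v in core:
                        cands.update(g.neighbors(v))
                    cands = (cands & ball) - claimed[klass]
                if not cands:
                    cands = ball - claimed[klass]
                    if not cands:
                        raise ValueError("class neighborhood exhausted; increase n_nodes")
                pick = _pick(cands)
                pool_nodes[pair].append(pick)
                claimed[klass].add(pick)
                remaining[pair] -= 1
    for pair, nodes in pool_nodes.items():
        a, b = sorted(pair)
        assigned[a].update(nodes)
        assigned[b].update(nodes)

    gene_sets: list[GeneSet] = []
    globally_used: set[str] = set().union(*claimed.values()) if claimed else set()
    members_of: dict[str, set[str]] = dict(assigned)
    for nm in names:
        ms = by_name[nm]
        ball = balls[ms.klass]
        members = set(assigned[nm])
        partners = [
            b for p in shared_count for b in sorted(p)
            if nm in p and b != nm
        ]
        k_conn_target = int(np.ceil(ms.cohesion * ms.size))
        need_conn = min(max(0, k_conn_target - len(members)), ms.size - len(members))
        if need_conn > 0 and not members:
            start = _pick(ball - claimed[ms.klass])
            members.add(start)
            claimed[ms.klass].add(start)
            need_conn -= 1
        # connected fill with a preference cascade: adjacent to every
        # partner module if possible, else to this module's shared pools,
        # else to any current member, else anywhere in the ball
        for _ in range(need_conn):
            pools = assigned[nm]
            shell_pools = set()
            for v in pools:
                shell_pools.update(g.neighbors(v))
            shell_pools = (shell_pools & ball) - claimed[ms.klass]
            best = shell_pools
            if partners and shell_pools:
                tight = {
                    v for v in shell_pools
                    if all(any(u in members_of[q] for u in g.neighbors(v)) for q in partners)
                }
                if tight:
                    best = tight
            if not best:
                shell_any = set()
                for v in members:
                    shell_any.update(g.neighbors(v))
                best = (shell_any & ball) - claimed[ms.klass]
            if not best:
                best = ball - claimed[ms.klass]
                if not best:
                    raise ValueError("class neighborhood exhausted; increase n_nodes")
            pick = _pick(best)
            members.add(pick)
            claimed[ms.klass].add(pick)
        need_rand = ms.size - len(members)
        if need_rand > 0:
            candidates = sorted(set(g.nodes()) - reserved - globally_used - members)
            picked = rng.choice(len(candidates), size=need_rand, replace=False)
            members.update(candidates[i] for i in picked)
        globally_used.update(members)
        members_of[nm] = members
        gene_sets.append(GeneSet(name=nm, members=frozenset(members)))

    # realized truth
    overlap_counts = {
        a: {b: len(set(ga.members) & set(gb.members)) for b, gb in zip(names, gene_sets) if b != a}
        for a, ga in zip(names, gene_sets)
    }
    cohesion = {}
    for gs in gene_sets:
        sub = g.subgraph(gs.members)
        lcc = max(nx.connected_components(sub), key=len)
        cohesion[gs.name] = len(lcc) / len(gs.members)
    truth = BenchmarkTruth(
        members={gs.name: tuple(sorted(gs.members)) for gs in gene_sets},
        overlap_counts=overlap_counts,
        cohesion=cohesion,
        classes={m.name: m.klass for m in spec.modules},
    )
    return gene_sets, truth


def default_benchmark_spec(
    seed: int = 0,
    n_nodes: int = 2000,
    attachment: int = 3,
    overlap: float = 0.4,
) -> BenchmarkSpec:
    """The stock benchmark: a three-module co-located class with pairwise
    member overlap (default 40%) plus one distant isolate, on a
    2,000-node attachment-3 graph — cognate within the class,
    non-cognate across."""
    mods = (
        PlantedModuleSpec("tumorA", size=30, cohesion=1.0, klass="tumor"),
        PlantedModuleSpec("tumorB", size=30, cohesion=1.0, klass="tumor"),
        PlantedModuleSpec("tumorC", size=30, cohesion=1.0, klass="tumor"),
        PlantedModuleSpec("isolate", size=30, cohesion=1.0, klass="lone"),
    )
    ov = {
        frozenset(("tumorA", "tumorB")): overlap,
        frozenset(("tumorA", "tumorC")): overlap,
        frozenset(("tumorB", "tumorC")): overlap,
    }
    return BenchmarkSpec(n_nodes=n_nodes, attachment=attachment, modules=mods,
                         overlap=ov, seed=seed)


def write_benchmark(spec: BenchmarkSpec, out_dir) -> dict[str, Path]:
    """Generate and write a benchmark: edge-list TSV, GMT of planted
    modules, truth JSON and a manifest.  Byte-identical for identical
    spec + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = generate_interactome(spec.n_nodes, spec.attachment, seed=spec.seed)
    gene_sets, truth = plant_module_family(g, spec)

    paths = {
        "edges": out / "interactome.tsv",
        "gmt": out / "modules.gmt",
        "truth": out / "truth.json",
        "manifest": out / "manifest.json",
    }
    write_edgelist_tsv(g, paths["edges"])
    write_gene_sets(
        gene_sets, paths["gmt"],
        descriptions={m.name: f"planted;class={m.klass};cohesion={m.cohesion}" for m in spec.modules},
    )
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    manifest = {
        "n_nodes": spec.n_nodes,
        "attachment": spec.attachment,
        "seed": spec.seed,
        "modules": [
            {"name": m.name, "size": m.size, "cohesion": m.cohesion, "class": m.klass}
            for m in spec.modules
        ],
        "overlap": {"|".join(sorted(p)): f for p, f in sorted(spec.overlap.items(), key=lambda kv: sorted(kv[0]))},
        "n_edges": g.number_of_edges(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths
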