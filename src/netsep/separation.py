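"""Module separation on the interactome.

For two modules A and B the proximity

    p(A,B) = [ sum_a min_b d(a,b) + sum_b min_a d(b,a) ] / (|A| + |B|)

is the mean nearest-neighbor hop distance between the sets, and the
separation

    s(A,B) = p_AB - (p_AA + p_BB) / 2

compares cross-set proximity with each set's internal proximity.
Negative s means the two modules live in the same network neighborhood
(overlapping, "cognate" modules); positive s means they are
topologically separated ("non-cognate").

Two conventions matter and are fixed here:

* self-proximity p_AA excludes the node itself in the inner minimum
  (otherwise p_AA would be identically zero and s could never be
  negative);
* distinct sets that share members let a shared node contribute
  distance 0, so member overlap pulls s negative.

Significance comes from a permutation null in which *both* sets are
replaced by independent degree-matched random sets, R times; s is
z-scored against that null and given a two-tailed normal p-value.
Effect size and significance are blended by the generalized measure

    s~ = 1 / (1 + exp(-alpha * s / pval)) - 0.5,

a sigmoid in s scaled by its p-value, bounded in (-0.5, 0.5): strongly
negative for significantly overlapping pairs, strongly positive for
significantly separated ones, and near zero when p is unimpressive.
The default smoothing alpha = 0.3 keeps |s~| below ~0.1 for
insignificant p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit
from scipy.stats import norm

from ._seeds import rng_for
from .interactome import MappedModule, ShortestPaths, restrict_to_lcc
from .localization import DegreeBinning, build_degree_bins, sample_degree_matched

__all__ = [
    "SeparationConfig",
    "SeparationResult",
    "proximity",
    "separation",
    "generalized_separation",
    "separation_significance",
]

#: Smallest p-value fed to the sigmoid; below this the exponent overflows
#: and the caller must opt into saturation.
PVAL_FLOOR = 1e-308

_HALF_INSIDE = float(np.nextafter(0.5, 0.0))


@dataclass(frozen=True)
class SeparationConfig:
    """Knobs of the separation analysis.

    alpha
        Smoothing parameter of the generalized measure (default 0.3).
    replicates
        Permutation replicates R for the null (default 1000).
    level
        Significance level for the cognate / non-cognate call (0.05).
    seed
        Run seed; every pair derives its own sub-seed from it.
    min_occupancy
        Minimum degree-bin occupancy for the null sampler.
    """

    alpha: float = 0.3
    replicates: int = 1000
    level: float = 0.05
    seed: int = 0
    min_occupancy: int = 100

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class SeparationResult:
    """Everything computed for one module pair."""

    name_a: str
    name_b: str
    p_ab: float
    p_aa: float
    p_bb: float
    s: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    s_tilde: float
    label: str  # cognate | non_cognate | uncertain
    replicates: int
    alpha: float
    seed: int
    degenerate: bool = False


def _prepare_paths(g: nx.Graph | ShortestPaths) -> ShortestPaths:
    if isinstance(g, ShortestPaths):
        return g
    if not nx.is_connected(g):
        g = restrict_to_lcc(g)
    return ShortestPaths(g)


def _members(m: MappedModule | frozenset | set) -> frozenset:
    return m.mapped if isinstance(m, MappedModule) else frozenset(m)


def _proximity_idx(dist: np.ndarray, ia: np.ndarray, ib: np.ndarray, same: bool) -> float:
    """Proximity from precomputed distances; ``same`` switches on
    self-exclusion (A compared with itself)."""
    sub = dist[np.ix_(ia, ib)]
    if same:
        if len(ia) < 2:
            raise ValueError("self-proximity needs at least 2 members")
        sub = sub.copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())
    # distinct sets: a shared node sits at distance 0 and contributes 0
    return float((sub.min(axis=1).sum() + sub.min(axis=0).sum()) / (len(ia) + len(ib)))


def proximity(
    g: nx.Graph | ShortestPaths,
    a: MappedModule | set,
    b: MappedModule | set,
) -> float:
    """Mean nearest-neighbor hop distance between two modules (p_AB).

    When ``a`` and ``b`` hold the same member set, the inner minimum
    excludes the node itself (self-proximity); a singleton module then
    raises ``ValueError``.
    """
    sp = _prepare_paths(g)
    ma, mb = _members(a), _members(b)
    dropped = (ma | mb) - set(sp.index)
    if dropped:
        raise ValueError(f"members outside the connected interactome: {sorted(dropped)[:5]}")
    if not ma or not mb:
        raise ValueError("modules must be non-empty")
    return _proximity_idx(sp.dist, sp.idx(ma), sp.idx(mb), same=(ma == mb))


def separation(
    g: nx.Graph | ShortestPaths,
    a: MappedModule | set,
    b: MappedModule | set,
) -> float:
    """Separation s(A,B) = p_AB − (p_AA + p_BB)/2; symmetric in (A, B)."""
    sp = _prepare_paths(g)
    ma, mb = _members(a), _members(b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("separation needs modules of size >= 2")
    p_ab = proximity(sp, ma, mb)
    p_aa = proximity(sp, ma, ma)
    p_bb = proximity(sp, mb, mb)
    return p_ab - (p_aa + p_bb) / 2.0


def generalized_separation(
    s: float,
    pval: float,
    alpha: float = 0.3,
    saturate: bool = False,
) -> float:
    """Significance-weighted separation s~ = sigmoid(alpha*s/pval) − 0.5.

    Strictly increasing in ``s`` for fixed ``pval``; bounded in the open
    interval (−0.5, 0.5) — float results that would round onto the
    boundary are nudged to the nearest representable interior value.
    ``pval`` below ``PVAL_FLOOR`` (or zero) is a domain error unless
    ``saturate`` is set, in which case the saturated value
    ±(0.5 − ulp) is returned.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not pval > PVAL_FLOOR:
        if not saturate:
            raise ValueError(
                f"p-value {pval!r} below floor {PVAL_FLOOR}; enable saturate=True "
                "to report the saturated value"
            )
        return math.copysign(_HALF_INSIDE, s) if s != 0 else 0.0
    if pval > 1:
        raise ValueError("p-value must be <= 1")
    val = float(expit(alpha * s / pval) - 0.5)
    if val >= 0.5:
        val = _HALF_INSIDE
    elif val <= -0.5:
        val = -_HALF_INSIDE
    return val


def _classify(s: float, p: float, level: float, degenerate: bool) -> str:
    if degenerate or p >= level or s == 0:
        return "uncertain"
    return "cognate" if s < 0 else "non_cognate"


def separation_significance(
    g: nx.Graph | ShortestPaths,
    a: MappedModule,
    b: MappedModule,
    cfg: SeparationConfig | None = None,
    bins: DegreeBinning | None = None,
    _graph_for_bins: nx.Graph | None = None,
) -> SeparationResult:
    """Separation of a module pair with its permutation significance.

    Each of R replicates replaces both modules with independent
    degree-matched random sets (same degree-bin histograms) and
    recomputes s; z = (s_obs − mean)/sd against that null, two-tailed
    normal p, then the generalized measure and the
    cognate / non-cognate / uncertain call at ``cfg.level``.
    A degenerate (zero-s.d.) null forces the label to ``uncertain``.
    """
    cfg = cfg or SeparationConfig()
    sp = _prepare_paths(g)
    if bins is None:
        graph = _graph_for_bins
        if graph is None:
            graph = nx.from_scipy_sparse_array(sp.adjacency)
            graph = nx.relabel_nodes(graph, dict(enumerate(sp.nodes)))
        bins = build_degree_bins(graph, min_occupancy=cfg.min_occupancy)

    ma = frozenset(m for m in a.mapped if m in sp.index)
    mb = frozenset(m for m in b.mapped if m in sp.index)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("separation needs >= 2 members inside the connected interactome")

    ia, ib = sp.idx(ma), sp.idx(mb)
    same = ma == mb
    p_ab = _proximity_idx(sp.dist, ia, ib, same=same)
    p_aa = _proximity_idx(sp.dist, ia, ia, same=True)
    p_bb = _proximity_idx(sp.dist, ib, ib, same=True)
    s_obs = p_ab - (p_aa + p_bb) / 2.0

    # degree-bin membership counts once; replicates only redraw per bin
    rng = rng_for(cfg.seed, "separation", *sorted([a.name, b.name]))
    null = np.empty(cfg.replicates)
    for r in range(cfg.replicates):
        ra = sp.idx(sample_degree_matched_idx(sp, bins, ma, rng))
        rb = sp.idx(sample_degree_matched_idx(sp, bins, mb, rng))
        n_ab = _proximity_idx(sp.dist, ra, rb, same=False)
        n_aa = _proximity_idx(sp.dist, ra, ra, same=True)
        n_bb = _proximity_idx(sp.dist, rb, rb, same=True)
        null[r] = n_ab - (n_aa + n_bb) / 2.0

    mu = float(null.mean())
    sd = float(null.std(ddof=0))
    if sd == 0.0:
        z, p, degenerate = float("nan"), 1.0, True
    else:
        z = float((s_obs - mu) / sd)
        p = float(2.0 * norm.sf(abs(z)))
        degenerate = False
    s_tilde = generalized_separation(s_obs, max(p, PVAL_FLOOR * 2), alpha=cfg.alpha)
    return SeparationResult(
        name_a=a.name, name_b=b.name,
        p_ab=p_ab, p_aa=p_aa, p_bb=p_bb, s=s_obs,
        null_mean=mu, null_sd=sd, z=z, p=p,
        s_tilde=s_tilde,
        label=_classify(s_obs, p, cfg.level, degenerate),
        replicates=cfg.replicates, alpha=cfg.alpha, seed=cfg.seed,
        degenerate=degenerate,
    )


def sample_degree_matched_idx(
    sp: ShortestPaths,
    bins: DegreeBinning,
    members: frozenset,
    rng: np.random.Generator,
) -> set:
    """Degree-matched sample drawn against a ShortestPaths index.

    Same contract as :func:`netsep.localization.sample_degree_matched`
    but reads degrees from the prepared index, avoiding a graph lookup
    per call in permutation loops.
    """
    counts: dict[int, int] = {}
    for m in members:
        k = bins.bin_of(int(sp.degrees[sp.index[m]]))
        counts[k] = counts.get(k, 0) + 1
    sample: set = set()
    for k in sorted(counts):  # fixed bin order keeps rng consumption reproducible
        need = counts[k]
        candidates = bins.bins[k]
        if need > len(candidates):
            raise ValueError(
                f"degree bin {bins.intervals[k]} has {len(candidates)} candidates, "
                f"{need} required; increase min_occupancy"
            )
        picked = rng.choice(len(candidates), size=need, replace=False)
        sample.update(candidates[i] for i in picked)
    return sample
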