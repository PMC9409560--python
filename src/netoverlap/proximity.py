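"""Network separation between two gene sets and its permutation significance.

The separation score of gene sets A and B on an interactome is

    S_AB = d_AB - (d_A + d_B) / 2

where d_A and d_B are the mean shortest distances within each set and d_AB the
mean shortest distance between them.  Negative S_AB means the two sets sit
closer to each other in the network than within themselves — their modules
overlap; positive S_AB means they are topologically separated.

Distances are unweighted hop counts on the largest connected component (LCC)
of the full interactome, so every pair of mapped nodes is reachable.  The
default ``nearest`` convention is the nearest-neighbour distance that defines
the separation score: each node contributes its distance to the closest
member of the other set (for d_A/d_B, the closest *other* member of its own
set), and d_AB averages the |A| + |B| node-level terms.  A gene shared by A
and B counts itself across sets at distance 0 — shared genes are what drives
S_AB negative — except in the degenerate case A = B, where the other-member
rule is applied symmetrically so that S_AA is exactly 0.  Pass
``self_distance_zero=False`` to exclude self-matches across sets always, or
``convention="all_pairs"`` for plain all-pairs means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from collections.abc import Iterable

import networkx as nx
import numpy as np
import scipy.sparse.csgraph as csgraph

from netoverlap.interactome import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["ProximityResult", "separation", "module_distance", "proximity_test"]


@dataclass(frozen=True)
class ProximityResult:
    """Separation score between two gene sets with its permutation p-value."""

    d_A: float
    d_B: float
    d_AB: float
    s_AB: float
    p_value: float
    n_permutations: int
    seed: int
    convention: str
    n_mapped_a: int = 0
    n_mapped_b: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def separation(d_A: float, d_B: float, d_AB: float) -> float:
    """S_AB = d_AB - (d_A + d_B)/2 (exact arithmetic; may be negative)."""
    for name, v in (("d_A", d_A), ("d_B", d_B), ("d_AB", d_AB)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return d_AB - (d_A + d_B) / 2


class _LccDistances:
    """All-pairs hop distances on the interactome's largest connected component."""

    def __init__(self, net: nx.Graph):
        lcc_nodes = max(nx.connected_components(net), key=len) if net.number_of_nodes() else set()
        self.nodes: list[str] = sorted(lcc_nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        lcc = net.subgraph(self.nodes)
        adj = nx.to_scipy_sparse_array(lcc, nodelist=self.nodes, format="csr")
        self.matrix = csgraph.shortest_path(adj, method="D", directed=False, unweighted=True)

    def map_set(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.index[g] for g in genes if g in self.index], dtype=int)


def _nearest_terms(D: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                   exclude_self: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-node nearest-member distances from idx_a into idx_b and vice versa."""
    sub = D[np.ix_(idx_a, idx_b)].copy()
    if exclude_self:
        same = idx_a[:, None] == idx_b[None, :]
        sub[same] = np.inf
    return sub.min(axis=1), sub.min(axis=0)


def _mean_dropping_inf(terms: np.ndarray, label: str) -> float:
    finite = terms[np.isfinite(terms)]
    if finite.size < terms.size:
        logger.warning("%s: %d node term(s) undefined (no eligible counterpart), dropped",
                       label, terms.size - finite.size)
    if finite.size == 0:
        return 0.0
    return float(finite.mean())


def _set_distances(D: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                   convention: str, self_distance_zero: bool) -> tuple[float, float, float]:
    """(d_A, d_B, d_AB) for index sets on a distance matrix."""
    # identical sets fall back to the symmetric other-member rule: S_AA = 0
    sets_equal = set(idx_a.tolist()) == set(idx_b.tolist())
    cross_exclude_self = (not self_distance_zero) or sets_equal
    if convention == "nearest":
        ta, _ = _nearest_terms(D, idx_a, idx_a, exclude_self=True)
        tb, _ = _nearest_terms(D, idx_b, idx_b, exclude_self=True)
        ca, cb = _nearest_terms(D, idx_a, idx_b, exclude_self=cross_exclude_self)
        d_a = _mean_dropping_inf(ta, "d_A")
        d_b = _mean_dropping_inf(tb, "d_B")
        d_ab = _mean_dropping_inf(np.concatenate([ca, cb]), "d_AB")
    elif convention == "all_pairs":
        sub_a = D[np.ix_(idx_a, idx_a)]
        sub_b = D[np.ix_(idx_b, idx_b)]
        iu_a = np.triu_indices(len(idx_a), k=1)
        iu_b = np.triu_indices(len(idx_b), k=1)
        d_a = float(sub_a[iu_a].mean()) if iu_a[0].size else 0.0
        d_b = float(sub_b[iu_b].mean()) if iu_b[0].size else 0.0
        cross = D[np.ix_(idx_a, idx_b)]
        if cross_exclude_self:
            cross = np.where(idx_a[:, None] == idx_b[None, :], np.nan, cross)
        d_ab = float(np.nanmean(cross)) if np.isfinite(np.nanmean(cross)) else 0.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return d_a, d_b, d_ab


def module_distance(
    net: nx.Graph,
    A: GeneSet | Iterable[str],
    B: GeneSet | Iterable[str],
    convention: str = "nearest",
    self_distance_zero: bool = True,
) -> float:
    """Mean shortest distance d_AB between two gene sets on the interactome LCC.

    Raises
    ------
    ValueError
        If either set has no member on the LCC.
    """
    dist = _LccDistances(net)
    idx_a, idx_b = dist.map_set(A), dist.map_set(B)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both gene sets must intersect the interactome's largest component")
    _, _, d_ab = _set_distances(dist.matrix, idx_a, idx_b, convention, self_distance_zero)
    return d_ab


def proximity_test(
    net: nx.Graph,
    A: GeneSet | Iterable[str],
    B: GeneSet | Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    convention: str = "nearest",
    self_distance_zero: bool = True,
) -> ProximityResult:
    """Observed S_AB plus a permutation p-value.

    Each replicate samples random node sets of sizes |A ∩ LCC| and |B ∩ LCC|
    uniformly (independently, so they may overlap) from the LCC and recomputes
    S_AB; p = fraction of replicates with random S_AB <= observed (one-sided:
    more negative separation = stronger overlap; ties inclusive).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dist = _LccDistances(net)
    idx_a, idx_b = dist.map_set(A), dist.map_set(B)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both gene sets must intersect the interactome's largest component")
    D = dist.matrix
    d_a, d_b, d_ab = _set_distances(D, idx_a, idx_b, convention, self_distance_zero)
    s_obs = separation(d_a, d_b, d_ab)

    n = len(dist.nodes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        ra = rng.choice(n, size=idx_a.size, replace=False)
        rb = rng.choice(n, size=idx_b.size, replace=False)
        xa, xb, xab = _set_distances(D, ra, rb, convention, self_distance_zero)
        if xab - (xa + xb) / 2 <= s_obs:
            hits += 1
    return ProximityResult(
        d_A=d_a,
        d_B=d_b,
        d_AB=d_ab,
        s_AB=s_obs,
        p_value=hits / n_perm,
        n_permutations=n_perm,
        seed=seed,
        convention=convention,
        n_mapped_a=int(idx_a.size),
        n_mapped_b=int(idx_b.size),
    )
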