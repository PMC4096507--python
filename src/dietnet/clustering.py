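"""Weighted clustering of the overlap network and dietary cluster extraction.

Clustering in an individual-based diet network means groups of individuals
whose diets overlap strongly within the group and weakly between groups.  Two
layers are provided:

* a population-level index C_ws: the deviation of the weighted clustering
  coefficient Cw of the overlap network from its diet-bootstrap null
  expectation, rescaled to [-1, +1] (positive = clustered diets, negative =
  overdispersed);
* cluster membership: connected components of the pairwise-significance
  graph, the binary graph joining pairs of individuals whose observed
  overlap exceeds the 95th percentile of that pair's null overlap.

Cw is the Onnela-type geometric-mean triangle intensity: the contribution of
a closed triangle (i, j, k) is (w_ij * w_ik * w_jk)^(1/3), averaged per node
over its neighbour pairs.  :func:`weighted_clustering_coefficient` evaluates
it on the complete overlap graph.  The C_ws test evaluates it on the
*pairwise-significance graph* (edges where the observed overlap beats that
pair's 95% null quantile), because on the complete graph the triangle
intensity tracks the mean overlap and therefore cannot separate clustered
from overdispersed arrangements: any diet segregation lowers it.  The null
distribution of Cw applies the identical per-pair thresholds to every
bootstrap replicate, so under the null each pair is significant ~5% of the
time and the null graphs are sparse.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .matrix import BinaryMatrix, DietMatrix
from .nulls import NullEnsemble, bootstrap_counts, pooled_proportions, pvalue, rng_from
from .specialization import _overlap_from_props, OverlapNetwork, diet_proportions

logger = logging.getLogger(__name__)

__all__ = [
    "CwsResult",
    "ClusterAssignment",
    "weighted_clustering_coefficient",
    "relative_clustering",
    "cws_index",
    "significant_overlap_graph",
    "extract_clusters",
]


@dataclass(frozen=True)
class CwsResult:
    """Relative clustering index with its two-tailed null summary."""

    C_ws: float
    Cw_obs: float
    null_mean: float
    null_lo: float  # 2.5% null quantile of Cw
    null_hi: float  # 97.5% null quantile of Cw
    p_value: float  # two-sided
    n_boot: int
    seed: int | None

    @property
    def verdict(self) -> str:
        if self.Cw_obs > self.null_hi:
            return "clustered"
        if self.Cw_obs < self.null_lo:
            return "overdispersed"
        return "neither"


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of individuals into dietary clusters."""

    labels: dict[str, int]
    n_clusters: int
    adjacency: BinaryMatrix

    def members(self, cluster: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == cluster)

    @property
    def sizes(self) -> list[int]:
        return [len(self.members(c)) for c in range(1, self.n_clusters + 1)]

    @property
    def non_singleton_clusters(self) -> int:
        return sum(1 for s in self.sizes if s > 1)


def _cw_stack(w: np.ndarray) -> np.ndarray:
    """Cw for a stack of weight matrices, shape (B, n, n) -> (B,)."""
    B, n, _ = w.shape
    if n < 3:
        raise ValueError("weighted clustering needs at least 3 nodes")
    c = np.cbrt(w)
    idx = np.arange(n)
    c = c.copy()
    c[:, idx, idx] = 0.0
    # sum over ordered (j, k), j != k, of c_ij c_ik c_jk per node i
    s = np.einsum("bij,bik,bjk->bi", c, c, c)
    # remove j == k terms: c_ij^2 * c_jj = 0 already (diagonal zeroed)
    per_node = s / ((n - 1) * (n - 2))  # mean over unordered pairs (double-counted)
    return per_node.mean(axis=1)


def weighted_clustering_coefficient(net: OverlapNetwork | np.ndarray) -> float:
    """Onnela geometric-mean weighted clustering of the complete graph."""
    w = net.weights if isinstance(net, OverlapNetwork) else np.asarray(net, dtype=float)
    return float(_cw_stack(w[None])[0])


def relative_clustering(cw_obs: float, null_mean: float) -> float:
    """Rescale the deviation of Cw from its null mean into [-1, +1].

    Positive deviations are normalised by the headroom (1 - null mean),
    negative ones by the null mean itself, so +1 means maximal clustering and
    -1 maximal overdispersion.
    """
    if cw_obs >= null_mean:
        denom = 1.0 - null_mean
    else:
        denom = null_mean
    if denom == 0:
        return 0.0
    return float(np.clip((cw_obs - null_mean) / denom, -1.0, 1.0))


def _null_overlap_stacks(
    m: DietMatrix, n_boot: int, rng: np.random.Generator, chunk: int = 500
):
    """Yield stacks of null overlap matrices (B, n, n) from the diet bootstrap."""
    pooled = pooled_proportions(m)
    totals = m.row_totals
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        counts = bootstrap_counts(totals, pooled, b, rng)
        props = counts / counts.sum(axis=2, keepdims=True)
        # |p_j - p_k| summed over taxa, for all pairs, vectorised per chunk
        diff = np.abs(props[:, :, None, :] - props[:, None, :, :]).sum(axis=3)
        w = 1.0 - 0.5 * diff
        n = w.shape[1]
        w[:, np.arange(n), np.arange(n)] = 1.0
        yield w
        done += b


def _cw_thresholded(w: np.ndarray, q95: np.ndarray) -> np.ndarray:
    """Onnela Cw of the thresholded graphs for a stack of weight matrices.

    w: (B, n, n) overlap matrices; q95: (n, n) per-pair significance
    thresholds.  Edge j-k exists iff w_jk > q95_jk; surviving edges keep
    their overlap weight.  Nodes with fewer than 2 neighbours contribute 0.
    """
    B, n, _ = w.shape
    adj = (w > q95[None]).astype(float)
    idx = np.arange(n)
    adj[:, idx, idx] = 0.0
    c = np.cbrt(w) * adj
    s = np.einsum("bij,bik,bjk->bi", c, c, c)  # 2x sum over closed triangles
    k = adj.sum(axis=2)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_node = np.where(denom > 0, s / denom, 0.0)
    return per_node.mean(axis=1)


def cws_index(m: DietMatrix, n_boot: int = 10000, seed=None) -> CwsResult:
    """C_ws relative clustering with its two-tailed diet-bootstrap test.

    Cw is evaluated on the pairwise-significance graph (see module
    docstring); the null Cw values come from applying the same per-pair
    thresholds to each bootstrap replicate.  The verdict is "clustered" when
    the observed Cw exceeds the 97.5% null quantile and "overdispersed" when
    it falls below the 2.5% quantile.
    """
    if m.n_individuals < 3:
        raise ValueError("C_ws needs at least 3 individuals")
    rng = rng_from(seed)
    obs_w = _overlap_from_props(diet_proportions(m))
    np.fill_diagonal(obs_w, 1.0)

    stacks = list(_null_overlap_stacks(m, n_boot, rng))
    null_w = np.concatenate(stacks, axis=0)
    idx = np.arange(m.n_individuals)
    null_w[:, idx, idx] = 0.0  # self-pairs carry no edges
    q95 = np.quantile(null_w, 0.95, axis=0)
    cw_obs = float(_cw_thresholded(obs_w[None], q95)[0])
    null = _cw_thresholded(null_w, q95)
    ens = NullEnsemble(
        "Cw", null, "diet_bootstrap", n_boot, seed if isinstance(seed, int) else None
    )
    return CwsResult(
        C_ws=relative_clustering(cw_obs, float(null.mean())),
        Cw_obs=cw_obs,
        null_mean=float(null.mean()),
        null_lo=ens.quantile(0.025),
        null_hi=ens.quantile(0.975),
        p_value=pvalue(cw_obs, ens, "two-sided"),
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
    )


def significant_overlap_graph(
    m: DietMatrix, n_boot: int = 10000, seed=None
) -> BinaryMatrix:
    """Binary graph of pairs whose overlap beats their own null distribution.

    Edge j-k = 1 iff the observed overlap w_jk exceeds the 95th percentile of
    the diet-bootstrap null overlaps for that pair.  Each pair is judged
    against its own null quantile because pairs differ in sample size.
    """
    rng = rng_from(seed)
    obs = _overlap_from_props(diet_proportions(m))
    n = m.n_individuals
    # per-pair 95th percentile of null overlap, accumulated chunk-wise
    stacks = [stack for stack in _null_overlap_stacks(m, n_boot, rng)]
    null = np.concatenate(stacks, axis=0)
    q95 = np.quantile(null, 0.95, axis=0)
    adj = (obs > q95).astype(np.int8)
    adj = np.triu(adj, k=1)
    adj = adj + adj.T
    return BinaryMatrix(adj, m.individual_ids, m.individual_ids, m.season)


def extract_clusters(adj: BinaryMatrix) -> ClusterAssignment:
    """Dietary clusters = connected components of the significance graph.

    Deterministic labelling: clusters are numbered 1..k by decreasing size,
    ties broken by the lexically smallest member id.  Singletons are allowed
    (an individual significantly overlapping no-one is its own cluster).
    """
    if not adj.is_square_symmetric:
        raise ValueError("adjacency must be square and symmetric")
    g = nx.Graph()
    g.add_nodes_from(adj.row_ids)
    for i, j in itertools.combinations(range(len(adj.row_ids)), 2):
        if adj.cells[i, j]:
            g.add_edge(adj.row_ids[i], adj.row_ids[j])
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    labels = {node: ci for ci, comp in enumerate(comps, start=1) for node in comp}
    return ClusterAssignment(labels=labels, n_clusters=len(comps), adjacency=adj)
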