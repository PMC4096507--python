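"""Pairwise diet overlap and the E index of inter-individual diet variation.

Each individual's diet is the vector of proportions p_ij (share of taxon i in
individual j's prey pool).  The overlap between two individuals is the
proportional similarity of their diet vectors,

    w_jk = 1 - 0.5 * sum_i |p_ij - p_ik|,

which is 1 for identical diets and 0 for disjoint ones.  The population-level
index of inter-individual variation is

    E = 1 - mean_{j<k} w_jk,

ranging from 0 (all diets identical) to 1 (maximal variation).  Significance
is assessed against the diet-bootstrap null model: every individual redraws
its prey multinomially from the pooled population diet, and the population is
called specialized when the observed E exceeds 95% of the null E values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import DietMatrix
from .nulls import NullEnsemble, bootstrap_counts, pooled_proportions, pvalue, rng_from

__all__ = [
    "OverlapNetwork",
    "EResult",
    "diet_proportions",
    "pairwise_overlap",
    "e_index",
    "null_e_values",
    "e_null_test",
]


@dataclass(frozen=True)
class OverlapNetwork:
    """Complete weighted graph on individuals; weight = diet overlap in [0,1]."""

    node_ids: tuple[str, ...]
    weights: np.ndarray  # symmetric, diagonal ignored

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("weight matrix shape does not match node ids")
        if not np.allclose(w, w.T):
            raise ValueError("overlap matrix must be symmetric")
        off = w[~np.eye(len(w), dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("overlap weights must lie in [0, 1]")
        w = np.clip(w, 0.0, 1.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def pair_weights(self) -> np.ndarray:
        """Upper-triangle weights as a flat vector (pdist order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.weights[iu]


@dataclass(frozen=True)
class EResult:
    """Observed E with its bootstrap null summary."""

    E: float
    null_mean: float
    null_q95: float
    p_value: float
    n_boot: int
    seed: int | None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        """Specialized iff observed E exceeds the 95% null quantile."""
        return (not self.degenerate) and self.E > self.null_q95


def diet_proportions(m: DietMatrix) -> np.ndarray:
    """Row-normalised counts; each row sums to 1."""
    totals = m.row_totals
    if np.any(totals == 0):
        raise ValueError("zero row total; filter the matrix first")
    return m.counts / totals[:, None]


def _overlap_from_props(props: np.ndarray) -> np.ndarray:
    # proportional similarity = 1 - half the L1 distance of proportion vectors
    return 1.0 - 0.5 * squareform(pdist(props, metric="cityblock"))


def pairwise_overlap(m: DietMatrix) -> OverlapNetwork:
    """Proportional-similarity overlap network among individuals."""
    if m.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    w = _overlap_from_props(diet_proportions(m))
    np.fill_diagonal(w, 1.0)
    return OverlapNetwork(m.individual_ids, w)


def e_index(net: OverlapNetwork) -> float:
    """E = 1 - mean pairwise overlap, in [0, 1]."""
    pw = net.pair_weights()
    if pw.size == 0:
        raise ValueError("need at least one pair of individuals")
    return float(1.0 - pw.mean())


def _e_from_counts(counts: np.ndarray) -> np.ndarray:
    """E for a stack of count matrices, shape (B, R, T) -> (B,)."""
    totals = counts.sum(axis=2, keepdims=True)
    props = counts / totals
    B, R, _ = props.shape
    acc = np.zeros(B)
    npairs = R * (R - 1) // 2
    for j in range(R):
        for k in range(j + 1, R):
            acc += 1.0 - 0.5 * np.abs(props[:, j] - props[:, k]).sum(axis=1)
    return 1.0 - acc / npairs


def null_e_values(
    m: DietMatrix, n_boot: int, seed=None, chunk: int = 2000
) -> NullEnsemble:
    """Diet-bootstrap null distribution of E (vectorised, chunked)."""
    rng = rng_from(seed)
    pooled = pooled_proportions(m)
    totals = m.row_totals
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        counts = bootstrap_counts(totals, pooled, b, rng)
        out[done : done + b] = _e_from_counts(counts)
        done += b
    return NullEnsemble(
        "E", out, "diet_bootstrap", n_boot, seed if isinstance(seed, int) else None
    )


def e_null_test(m: DietMatrix, n_boot: int = 10000, seed=None) -> EResult:
    """Observed E against the diet-bootstrap null.

    p = (1 + #{null E >= observed E}) / (n_boot + 1); the population is
    specialized when observed E exceeds the 95% null quantile.  A single-taxon
    matrix yields a null distribution degenerate at 0 and is flagged.
    """
    obs = e_index(pairwise_overlap(m))
    ens = null_e_values(m, n_boot, seed)
    degenerate = m.n_taxa < 2 or np.ptp(ens.values) == 0 and obs == ens.values[0]
    return EResult(
        E=obs,
        null_mean=float(ens.values.mean()),
        null_q95=ens.quantile(0.95),
        p_value=pvalue(obs, ens, "upper"),
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
        degenerate=bool(degenerate),
    )
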