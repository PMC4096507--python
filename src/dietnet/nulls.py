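"""Shared Monte-Carlo resampling machinery.

Three null schemes are used across the package:

* ``diet_bootstrap`` — every individual redraws its own number of prey items
  as a multinomial sample from the pooled population diet proportions (row
  totals preserved exactly).  Used for the E and C_ws tests and the
  pairwise-significance graph.
* ``CE`` — cell-probability null for binary matrices (see nestedness module).
* ``swap`` — fixed row/column total checkerboard swaps (see nestedness
  module).

Random streams: all randomness flows through numpy's PCG64 generator.  A
master seed is expanded with :func:`numpy.random.SeedSequence.spawn` so that
distinct statistics computed from the same analysis seed never share draws;
within one ensemble the replicates come from a single stream so draws can be
vectorised.  Given the same (scheme, seed, input) the ensemble is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import DietMatrix

__all__ = [
    "NullEnsemble",
    "rng_from",
    "spawn_rngs",
    "pooled_proportions",
    "bootstrap_diets",
    "bootstrap_counts",
    "pvalue",
]


@dataclass(frozen=True)
class NullEnsemble:
    """An ordered vector of null statistic values plus its provenance."""

    statistic: str
    values: np.ndarray
    scheme: str  # diet_bootstrap | CE | swap
    n: int
    seed: int | None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != self.n:
            raise ValueError("ensemble length must equal n")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


def rng_from(seed) -> np.random.Generator:
    """Normalise a seed-like (int, SeedSequence, Generator, None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """n independent generators derived from one master seed by counter."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def pooled_proportions(m: DietMatrix) -> np.ndarray:
    """Population diet: column totals normalised to sum 1."""
    totals = m.col_totals.astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("empty matrix has no pooled proportions")
    return totals / grand


def bootstrap_diets(m: DietMatrix, seed=None) -> DietMatrix:
    """One resampled diet matrix under the population-bootstrap null.

    Each individual keeps its observed number of prey items but redraws them
    multinomially from the pooled proportions (focal individual included in
    the pool).  Row totals are preserved exactly.
    """
    rng = rng_from(seed)
    counts = rng.multinomial(m.row_totals, pooled_proportions(m))
    return DietMatrix(counts, m.individual_ids, m.taxon_ids, m.season)


def bootstrap_counts(
    row_totals: np.ndarray, pooled: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised bootstrap: (n, n_individuals, n_taxa) count array."""
    row_totals = np.asarray(row_totals)
    return rng.multinomial(row_totals, pooled, size=(n, len(row_totals)))


def pvalue(observed: float, ensemble: NullEnsemble, tail: str = "upper") -> float:
    """Add-one Monte-Carlo p-value.

    upper: (1 + #{null >= observed}) / (n + 1); ties count as >=
    (conservative).  two-sided: 2 x min(upper, lower), capped at 1.  Never
    returns exactly 0.
    """
    null = ensemble.values
    n = ensemble.n
    upper = (1.0 + np.count_nonzero(null >= observed)) / (n + 1.0)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float((1.0 + np.count_nonzero(null <= observed)) / (n + 1.0))
    if tail == "two-sided":
        lower = (1.0 + np.count_nonzero(null <= observed)) / (n + 1.0)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown tail {tail!r}")
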