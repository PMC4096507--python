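"""Synthetic diet-matrix generators with known planted structure.

The generators emulate the scale of a single-season field study of a
provisioning predator: ~10-14 individuals, ~15-18 prey taxa, one dominant
taxon holding about half of all prey items, the rest of the pooled diet
decaying geometrically, and per-individual prey totals of at least 4 (the
study-design minimum for an individual to enter the analysis).

Four structures are available, mirroring the foraging models that predict
different network topologies:

* ``null`` — every individual samples multinomially from the pooled diet
  (the analysis null hypothesis; no structure).
* ``nested`` — niche breadth increases with a simulated body-mass covariate:
  individual j may only access the top b_j taxa of the global abundance
  ranking, so small individuals hold ordered subsets of the diets of large
  ones.
* ``competitive_refuge`` — clusters share the dominant prey but each cluster
  ranks a private block of alternative taxa in its own preference order.
* ``distinct_preferences`` — clusters have disjoint top-ranked taxa, each
  with its own dominant-plus-tail preference ranking.
* ``checkerboard`` — designated taxon pairs are mutually exclusive within an
  individual's prey pool, planting never-co-occurring pairs.

``strength`` is the fidelity of an individual's captures to its structured
preference ranking: a fraction ``strength`` of its prey items is allocated
deterministically in proportion to the structured diet (largest-remainder
rounding), and the remaining items are opportunistic multinomial draws from
the pooled diet.  Strength 1 is therefore noiseless (e.g. a perfectly
stepped binary matrix for the nested structure) and strength 0 reproduces
the null generator bit-for-bit under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import DietMatrix

__all__ = [
    "PopulationSpec",
    "pooled_proportions_for",
    "generate_null_population",
    "generate_nested_population",
    "generate_clustered_population",
    "generate_checkerboard_population",
    "generate_population",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic single-season population.

    totals_range is inclusive; the lower bound must be >= 4 to mirror the
    study's minimum-prey filter.  dominant_share is the pooled proportion of
    the single dominant taxon (~0.5 in provisioning-wasp prey spectra); the
    remaining mass decays geometrically across the other taxa.
    """

    n_individuals: int = 12
    n_taxa: int = 16
    totals_range: tuple[int, int] = (4, 30)
    dominant_share: float = 0.5
    geometric_ratio: float = 0.75
    structure: str = "null"
    strength: float = 0.0
    k_clusters: int = 3
    mass_mean_mg: float = 95.0
    mass_sd_mg: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_taxa < 2:
            raise ValueError("need at least 2 individuals and 2 taxa")
        lo, hi = self.totals_range
        if lo < 4 or hi < lo:
            raise ValueError("per-individual totals must be >= 4 (study filter)")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if not 0.0 < self.dominant_share < 1.0:
            raise ValueError("dominant_share must lie in (0, 1)")


def _ranked_shape(size: int, dominant_share: float, ratio: float) -> np.ndarray:
    """Dominant-plus-geometric-tail preference shape over `size` taxa."""
    if size == 1:
        return np.ones(1)
    tail = ratio ** np.arange(size - 1)
    tail = (1.0 - dominant_share) * tail / tail.sum()
    return np.concatenate([[dominant_share], tail])


def pooled_proportions_for(spec: PopulationSpec) -> np.ndarray:
    """Pooled diet: one dominant taxon, geometric tail, sums to 1."""
    return _ranked_shape(spec.n_taxa, spec.dominant_share, spec.geometric_ratio)


def _streams(seed) -> tuple[np.random.Generator, np.random.Generator]:
    # child 0 drives structure covariates, child 1 drives count draws, so
    # strength-0 populations are bit-identical across structures
    a, b = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(a), np.random.default_rng(b)


def _ids(spec: PopulationSpec) -> tuple[list[str], list[str]]:
    ind = [f"w{i + 1:02d}" for i in range(spec.n_individuals)]
    tax = [f"taxon{j + 1:02d}" for j in range(spec.n_taxa)]
    return ind, tax


def _largest_remainder(total: int, p: np.ndarray) -> np.ndarray:
    """Deterministic integer allocation of `total` items proportional to p."""
    target = total * p
    base = np.floor(target).astype(np.int64)
    short = total - base.sum()
    frac = target - base
    # ties broken toward the higher-ranked (lower-index) taxon
    order = np.lexsort((np.arange(len(p)), -frac))
    base[order[:short]] += 1
    return base


def _sample(
    spec: PopulationSpec,
    per_row_p: np.ndarray,
    rng_counts: np.random.Generator,
    strength: float,
    sampled_p: np.ndarray | None = None,
) -> DietMatrix:
    """Draw the population: per-individual faithful core + opportunistic rest.

    round(strength * total) items follow the individual's structured diet
    (per_row_p) deterministically; the remainder is multinomial from
    sampled_p (default: the pooled diet, identically for every row).
    """
    lo, hi = spec.totals_range
    pooled = pooled_proportions_for(spec)
    if sampled_p is None:
        sampled_p = np.tile(pooled, (spec.n_individuals, 1))
    totals = rng_counts.integers(lo, hi + 1, size=spec.n_individuals)
    faithful = np.rint(strength * totals).astype(np.int64)
    det = np.vstack(
        [_largest_remainder(f, p) for f, p in zip(faithful, per_row_p)]
    )
    noise = rng_counts.multinomial(totals - faithful, sampled_p)
    ind, tax = _ids(spec)
    return DietMatrix.validated(det + noise, ind, tax, season=spec.structure)


def generate_null_population(spec: PopulationSpec) -> DietMatrix:
    """Rows i.i.d. multinomial from the pooled proportions (no structure)."""
    _, rng_counts = _streams(spec.seed)
    pooled = pooled_proportions_for(spec)
    per_row = np.tile(pooled, (spec.n_individuals, 1))
    return _sample(spec, per_row, rng_counts, strength=0.0)


def generate_nested_population(
    spec: PopulationSpec,
) -> tuple[DietMatrix, pd.Series]:
    """Mass-ordered niche breadth: heavier individuals access more taxa.

    Individual j's structured diet is the pooled diet truncated to the top
    b_j taxa of the abundance ranking and renormalised, with b_j spanning
    1..n_taxa in mass-rank order, so light individuals hold ordered subsets
    of the diets of heavy ones.  Returns (matrix, mass covariate in mg).
    """
    rng_struct, rng_counts = _streams(spec.seed)
    pooled = pooled_proportions_for(spec)
    masses = rng_struct.normal(spec.mass_mean_mg, spec.mass_sd_mg, spec.n_individuals)
    masses = np.maximum(masses, 1.0)
    rank = np.argsort(np.argsort(masses))  # 0 = lightest
    n, t = spec.n_individuals, spec.n_taxa
    breadth = np.rint(1 + (t - 1) * rank / (n - 1)).astype(int)
    per_row = np.empty((n, t))
    for j in range(n):
        restricted = np.where(np.arange(t) < breadth[j], pooled, 0.0)
        per_row[j] = restricted / restricted.sum()
    ind, _ = _ids(spec)
    m = _sample(spec, per_row, rng_counts, spec.strength)
    return m, pd.Series(masses, index=ind, name="mass_mg")


def generate_clustered_population(
    spec: PopulationSpec,
) -> tuple[DietMatrix, dict[str, int]]:
    """Planted dietary clusters.  Returns (matrix, true labels 1..k).

    ``competitive_refuge`` (default unless structure is
    ``distinct_preferences``): all clusters share the dominant taxon at its
    pooled share, while each cluster's alternative diet mass follows the
    cluster's own preference ranking of a private block of the remaining
    taxa.  ``distinct_preferences``: clusters concentrate on disjoint blocks
    of all taxa, each with its own dominant-plus-tail ranking.
    """
    if spec.k_clusters < 2:
        raise ValueError("need k >= 2 clusters")
    if spec.k_clusters > spec.n_individuals:
        raise ValueError("more clusters than individuals")
    _, rng_counts = _streams(spec.seed)
    n, t, k = spec.n_individuals, spec.n_taxa, spec.k_clusters
    membership = np.arange(n) % k  # round-robin: cluster sizes differ by <= 1

    distinct = spec.structure == "distinct_preferences"
    if distinct:
        blocks = np.array_split(np.arange(t), k)
    else:
        blocks = np.array_split(np.arange(1, t), k)  # taxon 0 shared
    cluster_p = np.zeros((k, t))
    for c in range(k):
        shape = _ranked_shape(
            len(blocks[c]), spec.dominant_share, spec.geometric_ratio
        )
        if distinct:
            cluster_p[c, blocks[c]] = shape
        else:
            cluster_p[c, 0] = spec.dominant_share
            cluster_p[c, blocks[c]] = (1.0 - spec.dominant_share) * shape
    per_row = cluster_p[membership]
    ind, _ = _ids(spec)
    m = _sample(spec, per_row, rng_counts, spec.strength)
    return m, {w: int(c) + 1 for w, c in zip(ind, membership)}


def generate_checkerboard_population(spec: PopulationSpec) -> DietMatrix:
    """Mutually exclusive prey guilds planted across individuals.

    A fraction ``strength`` of the alternative (non-dominant) taxa — the
    most abundant ones first — is segregated into two guilds of interleaved
    abundance rank, as when prey species divide between two microhabitats
    and each forager hunts in only one of them.  Individuals alternate
    deterministically between the two sides; a side's diet excludes the
    other guild's segregated taxa entirely (a forager never encounters
    them), so every cross-guild pair of segregated taxa has zero
    co-occurrence by construction, at any strength.  Unsegregated taxa and
    the dominant taxon (shared by everyone, as in real prey spectra) remain
    available to all.  Diets are multinomial over the remaining spectrum:
    checkerboardedness is a property of diet support, not of allocation
    noise, so no deterministic item core is used.
    """
    _, rng_counts = _streams(spec.seed)
    pooled = pooled_proportions_for(spec)
    n, t = spec.n_individuals, spec.n_taxa
    alternatives = list(range(1, t)) if t >= 3 else [0, 1]
    n_seg = int(round(spec.strength * len(alternatives)))
    segregated = alternatives[:n_seg]
    guilds = (segregated[0::2], segregated[1::2])  # interleaved ranks
    per_row = np.empty((n, t))
    for i in range(n):
        restricted = pooled.copy()
        restricted[guilds[(i + 1) % 2]] = 0.0  # side i%2 keeps guilds[i%2]
        per_row[i] = restricted / restricted.sum()
    return _sample(spec, per_row, rng_counts, strength=0.0, sampled_p=per_row)


def generate_population(spec: PopulationSpec):
    """Dispatch on spec.structure; returns (matrix, truth) uniformly.

    truth is None (null, checkerboard), a mass Series (nested) or a label
    dict (clustered structures).
    """
    s = spec.structure
    if s == "null":
        return generate_null_population(spec), None
    if s == "nested":
        return generate_nested_population(spec)
    if s in ("competitive_refuge", "distinct_preferences", "clustered"):
        if s == "clustered":
            spec = replace(spec, structure="competitive_refuge")
        return generate_clustered_population(spec)
    if s == "checkerboard":
        return generate_checkerboard_population(spec), None
    raise ValueError(f"unknown structure {s!r}")
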