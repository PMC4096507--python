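"""Nestedness (NODF), checkerboardedness (C-score) and their null models.

A diet network is nested when the prey sets of narrow-diet individuals are
subsets of the prey sets of broad-diet individuals.  NODF scores this on the
presence/absence matrix: for every ordered pair of rows (and of columns) with
strictly decreasing marginal totals the paired overlap is

    100 * (shared presences) / (marginal total of the emptier line);

pairs with equal totals contribute 0, and NODF is the mean over all row pairs
and column pairs, so it ranges from 0 to 100.  Significance is judged against
the CE cell-probability null, in which cell (i, j) is occupied independently
with probability (row fill_i / n_cols + column fill_j / n_rows) / 2.

The opposite, checkerboard, signal is scored with the Stone-Roberts C-score
over prey-taxon pairs: with r_i occurrences of taxon i and S_ij shared
occurrences, the checkerboard unit count of a pair is
(r_i - S_ij)(r_j - S_ij).  The mean unit count is normalised by its
matrix-level maximum floor(R/2)*ceil(R/2) (R individuals), giving a value in
[0, 1]: 0 when every pair fully co-occurs, 1 for a perfect checkerboard.
(Normalising each pair by r_i*r_j instead is available as an option, but it
saturates at 1 for every never-co-occurring pair regardless of how little
data supports it, so rare taxa dominate the score.)  The null model
preserves all row and column totals exactly, via sequential random 2x2
checkerboard swaps (fixed-fixed null).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .matrix import BinaryMatrix
from .nulls import NullEnsemble, pvalue, rng_from

logger = logging.getLogger(__name__)

__all__ = [
    "NodfScore",
    "NodfResult",
    "CscoreResult",
    "nodf",
    "ce_probabilities",
    "ce_null_matrix",
    "nodf_test",
    "cscore",
    "checkerboard_units",
    "swap_null_matrices",
    "swap_null_test",
    "never_cooccurring_pairs",
]


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodfScore:
    nodf: float
    row_nodf: float
    col_nodf: float


@dataclass(frozen=True)
class NodfResult:
    observed: NodfScore
    null_mean: float
    null_q95: float
    p_value: float
    n_null: int
    seed: int | None

    @property
    def nodf(self) -> float:
        return self.observed.nodf

    @property
    def verdict(self) -> str:
        return "nested" if self.observed.nodf > self.null_q95 else "not nested"


def _pair_scores(cells: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap scores over ordered row pairs with decreasing fill."""
    totals = cells.sum(axis=1)
    shared = cells @ cells.T
    total_score = 0.0
    n = len(totals)
    for i, j in itertools.combinations(range(n), 2):
        hi, lo = (i, j) if totals[i] > totals[j] else (j, i)
        if totals[hi] == totals[lo] or totals[lo] == 0:
            continue  # equal (or empty) marginal totals score 0
        total_score += 100.0 * shared[hi, lo] / totals[lo]
    return total_score, n * (n - 1) // 2


def nodf(b: BinaryMatrix | np.ndarray) -> NodfScore:
    """Observed NODF with its row and column components.

    Invariant to the input row/column order (sorting by marginal totals is
    implicit in the decreasing-fill rule).
    """
    cells = b.cells if isinstance(b, BinaryMatrix) else np.asarray(b)
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    if np.any(cells.sum(axis=1) == 0) or np.any(cells.sum(axis=0) == 0):
        raise ValueError("NODF is undefined with empty rows or columns")
    row_sum, n_row_pairs = _pair_scores(cells)
    col_sum, n_col_pairs = _pair_scores(cells.T)
    return NodfScore(
        nodf=(row_sum + col_sum) / (n_row_pairs + n_col_pairs),
        row_nodf=row_sum / n_row_pairs,
        col_nodf=col_sum / n_col_pairs,
    )


def ce_probabilities(b: BinaryMatrix) -> np.ndarray:
    """CE cell probabilities: mean of row and column fill proportions."""
    nr, nc = b.cells.shape
    row_fill = b.row_totals / nc
    col_fill = b.col_totals / nr
    return (row_fill[:, None] + col_fill[None, :]) / 2.0


def ce_null_matrix(b: BinaryMatrix, seed=None, max_redraws: int = 1000) -> BinaryMatrix:
    """One CE-null binary matrix; matrices with empty rows/columns are redrawn."""
    rng = rng_from(seed)
    p = ce_probabilities(b)
    for attempt in range(max_redraws):
        cells = (rng.random(p.shape) < p).astype(np.int8)
        if cells.sum(axis=1).min() > 0 and cells.sum(axis=0).min() > 0:
            if attempt:
                logger.debug("CE redraws needed: %d", attempt)
            return BinaryMatrix(cells, b.row_ids, b.col_ids, b.season)
    raise RuntimeError("CE null could not produce a matrix without empty lines")


def nodf_test(b: BinaryMatrix, n_null: int = 10000, seed=None) -> NodfResult:
    """NODF against the CE null; nested iff observed beats 95% of null values."""
    rng = rng_from(seed)
    obs = nodf(b)
    p = ce_probabilities(b)
    null = np.empty(n_null)
    filled = 0
    redraws = 0
    # draw in vectorised batches, redrawing matrices with empty rows/columns
    while filled < n_null:
        batch = min(1000, 2 * (n_null - filled))
        draws = (rng.random((batch,) + p.shape) < p).astype(np.int8)
        ok = (draws.sum(axis=2).min(axis=1) > 0) & (draws.sum(axis=1).min(axis=1) > 0)
        redraws += int(batch - ok.sum())
        for cells in draws[ok]:
            if filled >= n_null:
                break
            null[filled] = nodf(cells).nodf
            filled += 1
    if redraws:
        logger.debug("CE null: %d redraws with empty rows/columns", redraws)
    ens = NullEnsemble(
        "NODF", null, "CE", n_null, seed if isinstance(seed, int) else None
    )
    return NodfResult(
        observed=obs,
        null_mean=float(null.mean()),
        null_q95=ens.quantile(0.95),
        p_value=pvalue(obs.nodf, ens, "upper"),
        n_null=n_null,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CscoreResult:
    C: float
    null_mean: float
    null_lo: float  # 2.5% null quantile
    null_hi: float  # 97.5% null quantile
    p_value: float  # two-sided
    checkerboard_pairs: int
    n_null: int
    seed: int | None
    degenerate: bool = False

    @property
    def verdict(self) -> str:
        if self.degenerate:
            return "degenerate"
        if self.C > self.null_hi:
            return "checkerboard"
        if self.C < self.null_lo:
            return "aggregated"
        return "neither"


def checkerboard_units(cells: np.ndarray) -> np.ndarray:
    """Raw checkerboard units (r_i - S)(r_j - S) per unordered taxon pair."""
    r = cells.sum(axis=0).astype(float)
    S = (cells.T @ cells).astype(float)
    cu = (r[:, None] - S) * (r[None, :] - S)
    iu = np.triu_indices(len(r), k=1)
    return cu[iu]


def cscore(b: BinaryMatrix | np.ndarray, normalization: str = "matrix") -> float:
    """Mean checkerboard units over prey-taxon pairs, normalised to [0, 1].

    normalization:
      "matrix" (default) — mean raw units / (floor(R/2) * ceil(R/2)), the
        maximum a pair can attain in a matrix with R individuals;
      "pair" — each pair's units divided by r_i * r_j before averaging;
      "none" — mean raw Stone-Roberts units (not bounded by 1).
    """
    cells = b.cells if isinstance(b, BinaryMatrix) else np.asarray(b)
    if cells.shape[1] < 2:
        raise ValueError("C-score needs at least 2 taxa")
    cu = checkerboard_units(cells)
    if normalization == "matrix":
        nrow = cells.shape[0]
        return float(cu.mean() / ((nrow // 2) * (nrow - nrow // 2)))
    if normalization == "pair":
        r = cells.sum(axis=0).astype(float)
        iu = np.triu_indices(len(r), k=1)
        rprod = (r[:, None] * r[None, :])[iu]
        return float((cu / rprod).mean())
    if normalization == "none":
        return float(cu.mean())
    raise ValueError(f"unknown normalization {normalization!r}")


def _trial_swaps(cells: np.ndarray, n_trials: int, rng: np.random.Generator) -> int:
    """Attempt n_trials random 2x2 checkerboard swaps in place; return #accepted.

    A trial picks two distinct rows and two distinct columns uniformly and
    swaps the 2x2 submatrix iff it is a checkerboard; this chain is symmetric
    and therefore uniform over the fixed-margin set at stationarity.
    """
    nr, nc = cells.shape
    rows = rng.integers(0, nr, size=(n_trials, 2))
    cols = rng.integers(0, nc, size=(n_trials, 2))
    accepted = 0
    for (r1, r2), (c1, c2) in zip(rows, cols):
        if r1 == r2 or c1 == c2:
            continue
        a, b_, c, d = cells[r1, c1], cells[r1, c2], cells[r2, c1], cells[r2, c2]
        if a == d and b_ == c and a != b_:
            cells[r1, c1] = b_
            cells[r1, c2] = a
            cells[r2, c1] = d
            cells[r2, c2] = c
            accepted += 1
    return accepted


def swap_null_matrices(
    b: BinaryMatrix,
    n_null: int,
    seed=None,
    burn_in_factor: int = 100,
    thin_factor: int = 10,
):
    """Yield n_null fixed-fixed null matrices by sequential checkerboard swaps.

    Burn-in of ``burn_in_factor * fill`` trial swaps, then ``thin_factor *
    fill`` trials between successive samples.  Trial counts (rather than
    accepted-swap counts) keep the chain's stationary distribution uniform
    over the fixed-margin set; the factors are sized so a typical acceptance
    rate of ~10% still yields several accepted swaps per retained sample.
    All row and column totals are preserved exactly by construction.
    """
    rng = rng_from(seed)
    cells = b.cells.astype(np.int8).copy()
    fill = max(int(cells.sum()), 1)
    _trial_swaps(cells, burn_in_factor * fill, rng)
    for _ in range(n_null):
        _trial_swaps(cells, thin_factor * fill, rng)
        yield cells.copy()


def _has_checkerboard_swap(cells: np.ndarray) -> bool:
    nr, nc = cells.shape
    for r1, r2 in itertools.combinations(range(nr), 2):
        d = cells[r1] - cells[r2]
        if (d == 1).any() and (d == -1).any():
            return True
    return False


def swap_null_test(b: BinaryMatrix, n_null: int = 10000, seed=None) -> CscoreResult:
    """C-score against the fixed-fixed swap null (two-tailed).

    Verdict "checkerboard" iff the observed C-score exceeds the 97.5% null
    quantile, "aggregated" iff it falls below the 2.5% quantile.  A matrix
    with no swappable 2x2 submatrix has a degenerate null and is flagged.
    """
    obs = cscore(b)
    never, _ = never_cooccurring_pairs(b)
    degenerate = not _has_checkerboard_swap(b.cells)
    null = np.fromiter(
        (cscore(cells) for cells in swap_null_matrices(b, n_null, seed)),
        dtype=float,
        count=n_null,
    )
    ens = NullEnsemble(
        "C-score", null, "swap", n_null, seed if isinstance(seed, int) else None
    )
    return CscoreResult(
        C=obs,
        null_mean=float(null.mean()),
        null_lo=ens.quantile(0.025),
        null_hi=ens.quantile(0.975),
        p_value=pvalue(obs, ens, "two-sided"),
        checkerboard_pairs=len(never),
        n_null=n_null,
        seed=seed if isinstance(seed, int) else None,
        degenerate=degenerate,
    )


def never_cooccurring_pairs(
    b: BinaryMatrix,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split taxon pairs into never-co-occurring and co-occurring lists.

    A pair never co-occurs when no individual captured both taxa (S_ij = 0);
    both taxa must occur at least once.  Returns (never, cooccurring).
    """
    cells = b.cells
    S = cells.T @ cells
    present = b.col_totals > 0
    never, co = [], []
    for i, j in itertools.combinations(range(cells.shape[1]), 2):
        if not (present[i] and present[j]):
            continue
        pair = (b.col_ids[i], b.col_ids[j])
        (never if S[i, j] == 0 else co).append(pair)
    return never, co
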