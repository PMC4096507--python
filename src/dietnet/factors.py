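"""Classical statistical tests for factors behind diet-network structure.

These wrap the standard numeric stack (scipy.stats, statsmodels) behind
stable contracts so the season pipeline can test, per year:

* whether the number of predators using a prey taxon tracks its environmental
  availability (Pearson correlation on ln-transformed availability);
* whether forager body mass predicts niche breadth (ordinary least squares on
  the percentage of the population's prey taxa an individual captures);
* whether dietary clusters differ in a covariate (one-way ANOVA with Tukey
  HSD post-hoc), e.g. body mass or mean capture-day score;
* whether mass variance differs among years (Levene's test, mean-centred);
* whether individuals shift diet within a season (paired t-test on the
  first-nest vs last-nest prey-species percentage);
* whether never-co-occurring prey pairs differ more in body mass than
  co-occurring pairs (two-sample t-test on |mass difference|);
* whether nests of same-cluster individuals sit closer together than nests of
  different-cluster individuals (two-sample t on square-root-transformed
  pairwise distances).

Transforms the study design prescribes (ln for availability, square root for
distances) are applied inside the operations and recorded in the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .clustering import ClusterAssignment
from .matrix import BinaryMatrix, DietMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FactorTestResult",
    "InsufficientDataError",
    "availability_correlation",
    "niche_breadth_pct",
    "mass_breadth_regression",
    "group_anova_tukey",
    "variance_homogeneity",
    "paired_shift_test",
    "cooccurrence_mass_test",
    "temporal_scores",
    "internest_distance_test",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class FactorTestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect: dict = field(default_factory=dict)
    transform: str = "none"  # none | ln | sqrt
    degenerate: bool = False

    def __str__(self) -> str:  # report-friendly one-liner
        dfs = ",".join(f"{d:g}" for d in self.df)
        return f"{self.name}: stat={self.statistic:.3f} df=({dfs}) p={self.p_value:.4g}"


def availability_correlation(
    predator_counts: Mapping[str, int], availability: Mapping[str, float]
) -> FactorTestResult:
    """Pearson correlation of per-taxon predator counts vs ln(availability).

    Taxa are matched by inner join; taxa with zero or missing availability
    are dropped (they cannot be ln-transformed).
    """
    taxa = sorted(
        t for t in predator_counts if availability.get(t, 0) > 0
    )
    if len(taxa) < 3:
        raise InsufficientDataError(
            f"need at least 3 matched taxa with availability > 0, got {len(taxa)}"
        )
    x = np.log([availability[t] for t in taxa])
    y = np.array([predator_counts[t] for t in taxa], dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return FactorTestResult(
            "availability_correlation", np.nan, (len(taxa) - 2,), np.nan,
            {"n": len(taxa)}, transform="ln", degenerate=True,
        )
    r, p = stats.pearsonr(x, y)
    return FactorTestResult(
        "availability_correlation",
        float(r),
        (len(taxa) - 2,),
        float(p),
        {"r": float(r), "n": len(taxa)},
        transform="ln",
    )


def niche_breadth_pct(m: DietMatrix) -> pd.Series:
    """Percent of the season's prey taxa captured by each individual."""
    captured = (m.counts > 0).sum(axis=1)
    return pd.Series(
        100.0 * captured / m.n_taxa, index=list(m.individual_ids), name="pct_species"
    )


def mass_breadth_regression(
    mass_mg: Mapping[str, float], pct_species: Mapping[str, float]
) -> FactorTestResult:
    """OLS of niche breadth (%) on body mass (mg); slope, R2adj, F, p."""
    import statsmodels.api as sm

    ids = sorted(set(mass_mg) & set(pct_species))
    if len(ids) < 3:
        raise InsufficientDataError("need at least 3 individuals with mass and breadth")
    x = np.array([mass_mg[i] for i in ids], dtype=float)
    y = np.array([pct_species[i] for i in ids], dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in mass")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits emit df warnings
        fit = sm.OLS(y, sm.add_constant(x)).fit()
    return FactorTestResult(
        "mass_breadth_regression",
        float(fit.fvalue),
        (float(fit.df_model), float(fit.df_resid)),
        float(fit.f_pvalue),
        {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r2_adj": float(fit.rsquared_adj),
            "n": len(ids),
        },
    )


def group_anova_tukey(
    values: Mapping[str, float], groups: ClusterAssignment | Mapping[str, int]
) -> FactorTestResult:
    """One-way ANOVA across clusters with Tukey HSD pairwise comparisons."""
    labels = groups.labels if isinstance(groups, ClusterAssignment) else dict(groups)
    ids = sorted(set(values) & set(labels))
    by_group: dict[int, list[float]] = {}
    for i in ids:
        by_group.setdefault(labels[i], []).append(float(values[i]))
    samples = [np.asarray(v) for v in by_group.values() if len(v) > 0]
    if len(samples) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    n = sum(len(s) for s in samples)
    k = len(samples)
    flat = np.concatenate(samples)
    if np.ptp(flat) == 0:
        return FactorTestResult(
            "group_anova", 0.0, (k - 1, n - k), 1.0,
            {"group_means": {g: float(np.mean(v)) for g, v in by_group.items()}},
            degenerate=True,
        )
    f, p = stats.f_oneway(*samples)
    effect: dict = {
        "group_means": {g: float(np.mean(v)) for g, v in by_group.items()},
        "n": n,
    }
    if all(len(s) >= 2 for s in samples):
        grp = np.concatenate([[g] * len(v) for g, v in by_group.items()])
        tukey = pairwise_tukeyhsd(flat, grp)
        effect["tukey"] = {
            f"{row[0]}-{row[1]}": float(pv)
            for row, pv in zip(tukey.summary().data[1:], tukey.pvalues)
        }
    return FactorTestResult("group_anova", float(f), (k - 1, n - k), float(p), effect)


def variance_homogeneity(
    values: Sequence[float], grouping: Sequence
) -> FactorTestResult:
    """Levene's test (mean-centred) for equal variance across groups + CVs."""
    s = pd.Series(values, dtype=float)
    g = pd.Series(grouping)
    samples = [grp.to_numpy() for _, grp in s.groupby(g.values)]
    if len(samples) < 2:
        raise InsufficientDataError("Levene needs at least 2 groups")
    f, p = stats.levene(*samples, center="mean")
    cv = {
        str(name): float(grp.std(ddof=1) / grp.mean())
        for name, grp in s.groupby(g.values)
    }
    n, k = len(s), len(samples)
    return FactorTestResult(
        "variance_homogeneity", float(f), (k - 1, n - k), float(p), {"cv": cv}
    )


def paired_shift_test(
    first_nest_pct: Sequence[float], last_nest_pct: Sequence[float]
) -> FactorTestResult:
    """Paired t-test for a within-season shift in niche breadth."""
    x = np.asarray(first_nest_pct, dtype=float)
    y = np.asarray(last_nest_pct, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise InsufficientDataError("need >= 2 matched pairs")
    d = y - x
    if np.ptp(d) == 0:
        return FactorTestResult(
            "paired_shift", 0.0 if d[0] == 0 else np.inf, (len(x) - 1,),
            1.0 if d[0] == 0 else 0.0, {"mean_shift": float(d.mean())},
            degenerate=True,
        )
    t, p = stats.ttest_rel(x, y)
    return FactorTestResult(
        "paired_shift", float(t), (len(x) - 1,), float(p),
        {"mean_shift": float(d.mean()), "n": len(x)},
    )


def cooccurrence_mass_test(
    never_pairs: Sequence[tuple[str, str]],
    cooccurring_pairs: Sequence[tuple[str, str]],
    species_mean_masses: Mapping[str, float],
) -> FactorTestResult:
    """Two-sample t: |mass difference| of never- vs ever-co-occurring pairs."""
    missing = sorted(
        {t for pair in list(never_pairs) + list(cooccurring_pairs) for t in pair}
        - set(species_mean_masses)
    )
    if missing:
        raise InsufficientDataError(f"no mean mass for taxa: {missing}")

    def diffs(pairs):
        return np.array(
            [abs(species_mean_masses[a] - species_mean_masses[b]) for a, b in pairs]
        )

    d_never, d_co = diffs(never_pairs), diffs(cooccurring_pairs)
    if len(d_never) < 2 or len(d_co) < 2:
        raise InsufficientDataError("need >= 2 pairs in each class")
    df = len(d_never) + len(d_co) - 2
    if np.ptp(np.concatenate([d_never, d_co])) == 0:
        return FactorTestResult(
            "cooccurrence_mass", 0.0, (df,), 1.0, {}, degenerate=True
        )
    t, p = stats.ttest_ind(d_never, d_co)
    return FactorTestResult(
        "cooccurrence_mass", float(t), (df,), float(p),
        {"mean_never": float(d_never.mean()), "mean_co": float(d_co.mean())},
    )


def temporal_scores(capture_days: Mapping[str, Sequence[int]]) -> pd.Series:
    """Mean capture-day score (1..17) per female; unscored females excluded."""
    means = {}
    for female, days in capture_days.items():
        if len(days) == 0:
            logger.warning("female %s has no scored prey; excluded", female)
            continue
        means[female] = float(np.mean(days))
    return pd.Series(means, name="mean_day_score")


def internest_distance_test(
    coords: Mapping[str, tuple[float, float]],
    assignment: ClusterAssignment | Mapping[str, int],
) -> FactorTestResult:
    """Within- vs between-cluster nest distances (sqrt-transformed, t-test)."""
    labels = (
        assignment.labels
        if isinstance(assignment, ClusterAssignment)
        else dict(assignment)
    )
    ids = sorted(set(coords) & set(labels))
    within, between = [], []
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            d = float(np.hypot(
                coords[a][0] - coords[b][0], coords[a][1] - coords[b][1]
            ))
            (within if labels[a] == labels[b] else between).append(d)
    if len(within) < 2 or len(between) < 2:
        raise InsufficientDataError(
            "need >= 2 nest pairs in each class (clusters with < 2 nests "
            "contribute no within pairs)"
        )
    w = np.sqrt(within)
    b = np.sqrt(between)
    df = len(w) + len(b) - 2
    if np.ptp(np.concatenate([w, b])) == 0:
        return FactorTestResult(
            "internest_distance", 0.0, (df,), 1.0, {}, transform="sqrt",
            degenerate=True,
        )
    t, p = stats.ttest_ind(w, b)
    return FactorTestResult(
        "internest_distance", float(t), (df,), float(p),
        {
            "mean_within_cm": float(np.mean(within)),
            "mean_between_cm": float(np.mean(between)),
            "n_within": len(within),
            "n_between": len(between),
        },
        transform="sqrt",
    )
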