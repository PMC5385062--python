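"""Environmental niche statistics for OTU groups.

For each group (clade) and environmental variable the niche-narrowness
criterion compares the occurrence-weighted spread of the group's sites to
the spread across all sampled sites (the null distribution): the niche is
called significantly narrow iff the null standard deviation exceeds the
group's more than two-fold *and* a Levene test for homogeneity of
variances rejects at alpha (star grades * p<0.05, ** p<0.01, *** p<0.001).
Categorical (biome/region) bias is tested with a G-statistic against
site-frequency-proportional expectations and a 999-permutation null.
Predictability is quantified by repeated k-fold cross-validated R2 around
any fit/predict-style regressor.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    NotDeterminedError,
    NUMERIC_SITE_COLUMNS,
    OccurrenceMatrix,
    ValidationError,
)

__all__ = [
    "NicheResult",
    "BiasResult",
    "CvR2Result",
    "group_occurrence_weights",
    "group_env_sample",
    "null_env_sample",
    "weighted_sd",
    "levene_test",
    "niche_narrowness",
    "categorical_bias_test",
    "cv_r2",
    "niche_histogram",
]


@dataclass(frozen=True)
class NicheResult:
    group_id: str
    variable: str
    sd_null: float
    sd_group: float
    sd_ratio: float
    levene_W: float
    levene_p: float
    significant: bool
    grade: str


@dataclass(frozen=True)
class BiasResult:
    group_id: str
    factor: str
    statistic: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class CvR2Result:
    mean: float
    sd: float
    per_repeat: tuple[float, ...]


def group_occurrence_weights(
    group_members: Sequence[str], matrix: OccurrenceMatrix
) -> pd.Series:
    """Per-site summed occurrences of the group's member OTUs."""
    missing = [m for m in group_members if m not in matrix.table.columns]
    if missing:
        raise ValidationError(f"OTUs absent from occurrence matrix: {missing}")
    return matrix.table[list(group_members)].sum(axis=1)


def group_env_sample(
    group_members: Sequence[str],
    matrix: OccurrenceMatrix,
    metadata: pd.DataFrame,
    variable: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Environmental values at the group's sites, with occurrence weights.

    Sites with a missing value of ``variable`` are dropped.  Raises
    :class:`NotDeterminedError` ('nd') when the group never occurs.
    """
    if variable not in metadata.columns:
        raise ValidationError(f"variable {variable!r} not in site metadata")
    weights = group_occurrence_weights(group_members, matrix)
    weights = weights.reindex(metadata.index).fillna(0.0)
    values = metadata[variable].astype(float)
    keep = (weights > 0) & values.notna()
    if not keep.any():
        raise NotDeterminedError(
            f"group has no occurrences with non-missing {variable!r} (nd)"
        )
    return values[keep].to_numpy(), weights[keep].to_numpy()


def null_env_sample(metadata: pd.DataFrame, variable: str) -> np.ndarray:
    """All non-missing site values of ``variable`` (unweighted)."""
    if variable not in metadata.columns:
        raise ValidationError(f"variable {variable!r} not in site metadata")
    values = metadata[variable].astype(float).dropna().to_numpy()
    if values.size < 2:
        raise ValidationError(
            f"need >= 2 non-missing values of {variable!r}, got {values.size}"
        )
    return values


def weighted_sd(values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Frequency-weighted population SD (weights act as repeat counts)."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValidationError("weighted_sd: weights sum to 0")
    mean = float(np.sum(weights * values) / total)
    var = float(np.sum(weights * (values - mean) ** 2) / total)
    return math.sqrt(max(var, 0.0))


def _expand(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Expand integer-count weights into a repeated multiset."""
    counts = np.rint(weights).astype(int)
    if not np.allclose(counts, weights):
        raise ValidationError("weights must be (near-)integer repeat counts to expand")
    return np.repeat(values, counts)


def levene_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    center: str = "mean",
) -> tuple[float, float]:
    """Classic two-sample Levene test on absolute deviations from the center.

    ``center='median'`` gives the Brown-Forsythe variant.  Returns (W, p)
    with p from F(1, nA + nB - 2).  If neither sample deviates from its
    center at all, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("levene_test: each sample needs >= 2 values")
    if center not in ("mean", "median"):
        raise ValidationError(f"unknown center {center!r}")
    center_fn = np.mean if center == "mean" else np.median
    if not (np.abs(a - center_fn(a)).sum() or np.abs(b - center_fn(b)).sum()):
        return 0.0, 1.0
    w, p = stats.levene(a, b, center=center)
    return float(w), float(p)


def _star_grade(p: float, alpha: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def niche_narrowness(
    group_id: str,
    group_members: Sequence[str],
    matrix: OccurrenceMatrix,
    metadata: pd.DataFrame,
    variable: str,
    alpha: float = 0.05,
    sd_ratio_threshold: float = 2.0,
    center: str = "mean",
) -> NicheResult:
    """Apply the two-part narrowness criterion to one group and variable.

    Significant iff sd_null/sd_group > ``sd_ratio_threshold`` and the
    Levene test (group sample expanded by its occurrence weights vs. the
    null sample) has p < alpha.
    """
    values, weights = group_env_sample(group_members, matrix, metadata, variable)
    null_values = null_env_sample(metadata, variable)
    sd_group = weighted_sd(values, weights)
    sd_null = weighted_sd(null_values)
    sd_ratio = sd_null / sd_group if sd_group > 0 else math.inf
    expanded = _expand(values, weights)
    if expanded.size < 2:
        w_stat, p = 0.0, 1.0
    else:
        w_stat, p = levene_test(expanded, null_values, center=center)
    significant = (sd_ratio > sd_ratio_threshold) and (p < alpha)
    grade = _star_grade(p, alpha) if significant else ""
    return NicheResult(
        group_id=group_id,
        variable=variable,
        sd_null=sd_null,
        sd_group=sd_group,
        sd_ratio=sd_ratio,
        levene_W=w_stat,
        levene_p=p,
        significant=significant,
        grade=grade,
    )


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def categorical_bias_test(
    group_id: str,
    group_members: Sequence[str],
    matrix: OccurrenceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> BiasResult:
    """Permutation G-test for bias of group occurrences across categories.

    Observed counts are the group's summed occurrences per category of
    ``factor``; expectations are proportional to the number of sites per
    category.  The null is built by permuting the site-to-category labels
    ``n_perm`` times; p = (1 + #{G_perm >= G_obs}) / (n_perm + 1).
    """
    if factor not in ("biome", "region"):
        raise ValidationError(f"factor must be 'biome' or 'region', got {factor!r}")
    weights = group_occurrence_weights(group_members, matrix)
    weights = weights.reindex(metadata.index).fillna(0.0)
    categories = metadata[factor]
    keep = categories.notna()
    weights = weights[keep].to_numpy(dtype=float)
    codes, uniques = pd.factorize(categories[keep])
    if weights.sum() <= 0:
        raise NotDeterminedError(f"group has no occurrences (nd)")
    n_categories = len(uniques)
    if n_categories < 2:
        return BiasResult(group_id, factor, 0.0, 1.0, n_perm)
    site_counts = np.bincount(codes, minlength=n_categories).astype(float)
    total = weights.sum()
    expected = total * site_counts / site_counts.sum()
    observed = np.bincount(codes, weights=weights, minlength=n_categories)
    g_obs = _g_statistic(observed, expected)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        perm_obs = np.bincount(perm_codes, weights=weights, minlength=n_categories)
        if _g_statistic(perm_obs, expected) >= g_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return BiasResult(group_id, factor, g_obs, p, n_perm)


def _clone(predictor):
    try:
        from sklearn.base import clone

        return clone(predictor)
    except Exception:
        return copy.deepcopy(predictor)


def cv_r2(
    predictor,
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    k: int = 10,
    repeats: int = 100,
    seed: int | None = None,
) -> CvR2Result:
    """Repeated k-fold cross-validated R2 around a fit/predict regressor.

    Per repeat, sites are randomly partitioned into ``k`` folds; each fold
    is predicted by a model trained on the others, and R2 is computed on
    the pooled out-of-fold predictions (1 - SSE/SST about the overall
    mean).  Returns the mean and SD over repeats.  Seed-reproducible.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(X) != n:
        raise ValidationError("X and y length mismatch")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of observations n={n}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValidationError("cv_r2: response has zero variance")
    scores = []
    for _ in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        pooled = np.empty(n, dtype=float)
        for fold in folds:
            train = np.setdiff1d(order, fold)
            model = _clone(predictor)
            model.fit(X.iloc[train], y[train])
            pooled[fold] = np.asarray(model.predict(X.iloc[fold]), dtype=float)
        scores.append(1.0 - float(np.sum((y - pooled) ** 2)) / sst)
    scores = np.asarray(scores)
    return CvR2Result(
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)) if repeats > 1 else 0.0,
        per_repeat=tuple(float(s) for s in scores),
    )


def predictor_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """The default six-predictor table (MAT, MAP, pH, soil C, soil P, fire)."""
    return metadata.loc[:, list(NUMERIC_SITE_COLUMNS)].astype(float)


def niche_histogram(
    group_members: Sequence[str],
    matrix: OccurrenceMatrix,
    metadata: pd.DataFrame,
    variable: str,
    bins: int | Sequence[float] = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Occurrence-weighted group histogram vs. unweighted null histogram.

    Returns ``(group_counts, null_counts, bin_edges)`` with shared edges;
    the group histogram sums to the group's total occurrence weight and the
    null histogram to the number of non-missing sites.
    """
    if not isinstance(bins, int) and len(np.atleast_1d(bins)) < 3:
        raise ValidationError("need at least 2 bins")
    if isinstance(bins, int) and bins < 2:
        raise ValidationError("need at least 2 bins")
    null_values = null_env_sample(metadata, variable)
    values, weights = group_env_sample(group_members, matrix, metadata, variable)
    edges = np.histogram_bin_edges(null_values, bins=bins)
    null_counts, _ = np.histogram(null_values, bins=edges)
    group_counts, _ = np.histogram(values, bins=edges, weights=weights)
    return group_counts, null_counts, edges
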