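"""Derived statistics: interdependence, plant importance, regressions.

* **Interdependence** ``I`` — correlation, across random extinction
  sequences, between the robustness of the two animal species sets.  High
  I means the plants that matter for one animal set also matter for the
  other; low I means conservation gains for one set need not propagate.
* **Plant importance** — a plant is important when robustness is lower in
  sequences where it is lost earlier, i.e. its sequence position correlates
  *negatively* with robustness.  Ranks go by ascending correlation (most
  negative = rank 1).
* **Driver classification** — ``S_set``, the squared correlation between a
  per-animal-set importance ranking and the whole-community ranking,
  classifies networks as driven (one layer explains > 90% of the ranking
  variance), mixed, or emergent (neither explains 50%).
* **Composition fit** — no-intercept least squares ``R ~ a*R_L + b*R_S``
  expressing whole-community robustness from the two bipartite networks.
* **Feature regression** — exhaustive-subset OLS of a response on z-scored
  structural features, selected by minimum AIC.
* **Group comparison** — pairwise Welch t-tests between network classes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, DomainError
from .extinction import EnsembleResult

FEATURE_NAMES = ("heterogeneity", "C", "H_C", "PC_C")


@dataclass(frozen=True)
class InterdependenceResult:
    """Correlation of the two animal sets' per-sequence robustness."""

    I: Optional[float]
    n_sequences: int
    method: str
    defined: bool
    set_names: tuple[str, str]


@dataclass(frozen=True)
class ImportanceResult:
    """Per-plant importance scores and ranks for one robustness scope."""

    scope: str
    scores: Mapping[str, float]  # plant -> correlation(position, robustness)
    ranks: Mapping[str, int]     # rank 1 = most important (most negative)

    def ranking(self) -> list[str]:
        """Plants from most to least important."""
        return sorted(self.ranks, key=lambda p: self.ranks[p])


@dataclass(frozen=True)
class DriverClassification:
    """How much each animal set's ranking explains the whole-community one."""

    S: Mapping[str, float]
    category: str  # driven / mixed / emergent
    negative_correlation: tuple[str, ...]  # sets whose rank correlation was negative


@dataclass(frozen=True)
class CompositionFit:
    """No-intercept fit R ~ a*R_L + b*R_S across networks."""

    a: float
    b: float
    r_squared: float
    fitted: tuple[float, ...]


@dataclass(frozen=True)
class RegressionResult:
    """Minimum-AIC subset regression on standardized features."""

    predictors: tuple[str, ...]
    coefficients: Mapping[str, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    aic: float
    all_aic: Mapping[tuple[str, ...], float]


@dataclass(frozen=True)
class GroupComparison:
    """Welch t-test between two groups of per-network values."""

    group_a: str
    group_b: str
    t: float
    p: float
    stars: str


# ---------------------------------------------------------------------- #


def _pair_series(ensemble: EnsembleResult) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
    names = sorted({k for rec in ensemble.records for k in rec.R_per_set})
    if len(names) != 2:
        raise DomainError(
            f"interdependence needs exactly two non-basal sets, found {names}"
        )
    a = ensemble.series(names[0])
    b = ensemble.series(names[1])
    return (names[0], names[1]), a, b


def interdependence(
    ensemble: EnsembleResult, method: str = "pearson"
) -> InterdependenceResult:
    """I: correlation of the paired per-sequence (R_setA, R_setB) values.

    Flagged undefined (``I=None``) when either series has zero variance —
    a constant robustness carries no information about co-variation.
    """
    names, a, b = _pair_series(ensemble)
    if np.std(a) == 0 or np.std(b) == 0:
        return InterdependenceResult(
            I=None, n_sequences=len(a), method=method, defined=False, set_names=names
        )
    if method == "pearson":
        r = stats.pearsonr(a, b).statistic
    elif method == "spearman":
        r = stats.spearmanr(a, b).statistic
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    return InterdependenceResult(
        I=float(r), n_sequences=len(a), method=method, defined=True, set_names=names
    )


def plant_importance(ensemble: EnsembleResult, scope: str = "whole") -> ImportanceResult:
    """Correlation of each plant's sequence position with robustness.

    The importance of a plant cannot be read off the extinctions its own
    removal causes (a plant lost last causes few); instead, sequences where
    an important plant falls early have low robustness.  The score is the
    Pearson correlation between the plant's removal position and the
    community damage ``1 - R``: an important plant lost early (small
    position) drives damage up, so its score is strongly negative.  Ranks
    ascend with the score (most negative = rank 1), ties broken by id.
    """
    if ensemble.n_sequences < 2:
        raise DomainError("importance needs at least two sequences")
    plants = sorted(ensemble.sequences[0].order)
    if len(plants) < 2:
        raise DomainError("importance needs at least two plants")
    r_values = ensemble.series(scope)
    if np.std(r_values) == 0:
        raise DomainError(f"robustness ({scope}) has zero variance across sequences")
    positions = {p: np.empty(ensemble.n_sequences) for p in plants}
    for i, seq in enumerate(ensemble.sequences):
        for pos, p in enumerate(seq.order, start=1):
            positions[p][i] = pos
    scores: dict[str, float] = {}
    for p in plants:
        pos = positions[p]
        if np.std(pos) == 0:
            scores[p] = 0.0  # plant never changes position; uninformative
        else:
            scores[p] = float(stats.pearsonr(pos, 1.0 - r_values).statistic)
    ordered = sorted(plants, key=lambda p: (scores[p], p))
    ranks = {p: i + 1 for i, p in enumerate(ordered)}
    return ImportanceResult(scope=scope, scores=scores, ranks=ranks)


def driver_classification(
    importance_whole: ImportanceResult,
    importance_per_set: Mapping[str, ImportanceResult],
) -> DriverClassification:
    """S_set per animal set and the driven / mixed / emergent category.

    ``S_set`` is the squared correlation between rank vectors (equivalently
    the squared Spearman correlation of the importance scores): driven when
    any S exceeds 0.9, emergent when all fall below 0.5, mixed otherwise
    (boundary values 0.5 and 0.9 count as mixed).  S is direction-blind;
    sets whose underlying rank correlation is negative are flagged.
    """
    plants = sorted(importance_whole.ranks)
    whole = np.array([importance_whole.ranks[p] for p in plants], dtype=float)
    S: dict[str, float] = {}
    negative: list[str] = []
    for set_name, imp in importance_per_set.items():
        if sorted(imp.ranks) != plants:
            raise DomainError(
                f"ranking for {set_name!r} covers different plants than the whole ranking"
            )
        r_set = np.array([imp.ranks[p] for p in plants], dtype=float)
        r = float(stats.pearsonr(whole, r_set).statistic)
        S[set_name] = r * r
        if r < 0:
            negative.append(set_name)
    s_max = max(S.values())
    if s_max > 0.9:
        category = "driven"
    elif s_max < 0.5:
        category = "emergent"
    else:
        category = "mixed"
    return DriverClassification(
        S=S, category=category, negative_correlation=tuple(sorted(negative))
    )


def composition_fit(records: pd.DataFrame) -> CompositionFit:
    """Fit R = a*R_L + b*R_S (no intercept) across networks.

    ``records`` needs columns ``R``, ``R_L``, ``R_S``; rows with undefined
    bipartite robustness (chain/AA networks) are excluded beforehand by the
    caller or dropped here.
    """
    df = records.dropna(subset=["R", "R_L", "R_S"])
    if len(df) < 3:
        raise DomainError(
            f"composition fit needs >= 3 networks with defined R_L and R_S, got {len(df)}"
        )
    X = df[["R_L", "R_S"]].to_numpy(dtype=float)
    y = df["R"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < 2:
        raise DomainError("R_L and R_S are collinear; fit is not identifiable")
    model = sm.OLS(y, X).fit()
    return CompositionFit(
        a=float(model.params[0]),
        b=float(model.params[1]),
        r_squared=float(model.rsquared),
        fitted=tuple(float(v) for v in model.fittedvalues),
    )


def single_layer_fits(records: pd.DataFrame) -> dict[str, CompositionFit]:
    """One-predictor variants (R ~ a*R_L and R ~ b*R_S) for comparison."""
    df = records.dropna(subset=["R", "R_L", "R_S"])
    out: dict[str, CompositionFit] = {}
    for col in ("R_L", "R_S"):
        X = df[[col]].to_numpy(dtype=float)
        y = df["R"].to_numpy(dtype=float)
        model = sm.OLS(y, X).fit()
        coef = float(model.params[0])
        out[col] = CompositionFit(
            a=coef if col == "R_L" else 0.0,
            b=coef if col == "R_S" else 0.0,
            r_squared=float(model.rsquared),
            fitted=tuple(float(v) for v in model.fittedvalues),
        )
    return out


def _aic(rss: float, n: int, k: int) -> float:
    # n*ln(RSS/n) + 2*(k+1); +1 counts the residual variance
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2.0 * (k + 1)


def feature_regression(
    features: pd.DataFrame,
    response: Sequence[float],
    candidates: Sequence[str] = FEATURE_NAMES,
) -> RegressionResult:
    """Exhaustive-subset OLS on z-scored features, selected by minimum AIC.

    All 2^k - 1 non-empty predictor subsets are evaluated (k <= 4 here, 15
    models), deterministic given the data.  Predictors are standardized so
    coefficient magnitudes are comparable across features (effect per SD of
    the feature); the response keeps its own units.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    usable: list[str] = []
    for c in candidates:
        col = features[c].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"dropping constant predictor {c!r}", stacklevel=2)
        else:
            usable.append(c)
    if not usable:
        raise DomainError("no non-constant predictors")
    if n < len(usable) + 2:
        raise DomainError(
            f"need at least {len(usable) + 2} rows for {len(usable)} predictors, got {n}"
        )
    Z = {c: stats.zscore(features[c].to_numpy(dtype=float), ddof=0) for c in usable}
    if np.std(y) == 0:
        raise DomainError("response is constant")

    all_aic: dict[tuple[str, ...], float] = {}
    best: Optional[tuple[float, tuple[str, ...]]] = None
    for r in range(1, len(usable) + 1):
        for subset in itertools.combinations(usable, r):
            X = sm.add_constant(np.column_stack([Z[c] for c in subset]))
            fit = sm.OLS(y, X).fit()
            aic = _aic(float(fit.ssr), n, len(subset))
            all_aic[subset] = aic
            if best is None or aic < best[0]:
                best = (aic, subset)
    assert best is not None
    aic, subset = best
    X = sm.add_constant(np.column_stack([Z[c] for c in subset]))
    fit = sm.OLS(y, X).fit()
    coefs = {c: float(fit.params[i + 1]) for i, c in enumerate(subset)}
    return RegressionResult(
        predictors=subset,
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        aic=aic,
        all_aic=all_aic,
    )


_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def compare_groups(
    values: Mapping[str, Sequence[float]], equal_var: bool = False
) -> list[GroupComparison]:
    """Pairwise independent t-tests (Welch by default) between classes.

    Groups with fewer than two values are skipped with a warning.  The
    usual significance stars annotate each pair.
    """
    usable = {}
    for name, vals in values.items():
        vals = list(vals)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has < 2 values; skipped", stacklevel=2)
        else:
            usable[name] = vals
    out = []
    for a, b in itertools.combinations(sorted(usable), 2):
        res = stats.ttest_ind(usable[a], usable[b], equal_var=equal_var)
        stars = "ns"
        for cutoff, symbol in _STARS:
            if res.pvalue < cutoff:
                stars = symbol
                break
        out.append(
            GroupComparison(
                group_a=a, group_b=b, t=float(res.statistic), p=float(res.pvalue), stars=stars
            )
        )
    return out
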