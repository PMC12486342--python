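"""Group-comparison statistics and bootstrap internal validation.

The Mann-Whitney U statistic is computed by tie-aware pair counting (so that
U / (n_x * n_y) is exactly the pair-counting AUC with the second sample as
the "diseased" class).  Two-sided p-values are exact by enumeration of label
assignments when both samples have at most 8 observations, otherwise a
normal approximation with tie and continuity corrections is used.

Internal validation is a stratified nonparametric bootstrap: subjects are
resampled with replacement within each outcome class (class sizes
preserved), the metric — including any cutoff derivation it involves — is
recomputed inside every resample, and a percentile confidence interval is
reported.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence, Union

import numpy as np
from scipy import stats as sps

from .errors import (
    BootstrapFailureError,
    InvalidInputError,
    InvalidTableError,
)
from .metrics import ALLERGIC, TOLERANT, _is_missing, confusion_from_threshold, summarize
from .roc import auc_pair_oracle, build_roc, derive_cutoffs
from .triage import triage_summary

EXACT_MAX_N = 8  # both samples at or below this size => exact enumeration


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    method: str  # "exact" or "normal_approx"


def _pair_count_u(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(x_i, y_j): y_j > x_i} + ½ #ties, via sorted search."""
    xs = np.sort(x)
    greater = np.searchsorted(xs, y, side="left").sum()
    ties = (np.searchsorted(xs, y, side="right") - np.searchsorted(xs, y, side="left")).sum()
    return float(greater) + 0.5 * float(ties)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U counts pairs where y exceeds x."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u = _pair_count_u(x, y)
    mean_u = nx * ny / 2.0
    if nx <= EXACT_MAX_N and ny <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        n = nx + ny
        obs_dev = abs(u - mean_u)
        count = total = 0
        for idx in combinations(range(n), ny):
            yy = pooled[list(idx)]
            mask = np.ones(n, dtype=bool)
            mask[list(idx)] = False
            xx = pooled[mask]
            total += 1
            if abs(_pair_count_u(xx, yy) - mean_u) >= obs_dev - 1e-12:
                count += 1
        return MannWhitneyResult(U=u, p_value=count / total, method="exact")
    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([x, y])
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return MannWhitneyResult(U=u, p_value=1.0, method="normal_approx")
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2 * float(sps.norm.sf(z)))
    return MannWhitneyResult(U=u, p_value=p, method="normal_approx")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  A zero
    margin makes every permissible table identical: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if t.shape == (2, 2) and np.allclose(t, np.round(t)) and (t >= 0).all():
            t = np.round(t).astype(int)
        else:
            raise InvalidTableError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; Fisher p = 1 by convention")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p for an r x c table.

    Warns when any expected cell count falls below 5 (the conventional
    trigger for preferring Fisher's exact test).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise InvalidTableError("table must be a 2-D array of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InvalidTableError("chi-square requires all margins > 0")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; consider Fisher's exact test")
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, p


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles at positions p(n+1) with linear interpolation."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InvalidInputError("values must be non-empty")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="weibull")
    return float(med), float(q1), float(q3)


def format_p(p: float) -> str:
    """Clinical-table p formatting: below 0.0005 prints as "< 0.001"."""
    if p < 0.0005:
        return "< 0.001"
    return f"{p:.3f}"


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_a: str
    summary_b: str
    test: str
    statistic: float
    p_value: float

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_value)


def compare_groups(
    frame,
    group_col: str,
    variables: Sequence[str],
    categorical: Sequence[str] = (),
) -> list[GroupComparison]:
    """Two-group descriptive table: median (q1; q3) + Mann-Whitney for
    continuous variables, count (%) + chi-square/Fisher for categorical.

    ``frame`` is a DataFrame whose ``group_col`` has exactly two levels
    after dropping missing values.
    """
    sub = frame.dropna(subset=[group_col])
    levels = sorted(sub[group_col].unique())
    if len(levels) != 2:
        raise InvalidInputError(f"expected two group levels, got {levels}")
    a_mask = sub[group_col] == levels[0]
    results = []
    for var in variables:
        col = sub[var]
        ok = col.notna()
        xa = col[ok & a_mask].to_numpy(dtype=float) if var not in categorical else None
        xb = col[ok & ~a_mask].to_numpy(dtype=float) if var not in categorical else None
        if var in categorical:
            tab = (
                sub.loc[ok]
                .groupby([group_col, var], observed=True)
                .size()
                .unstack(fill_value=0)
                .to_numpy()
            )
            row = sub.loc[ok & a_mask, var]
            other = sub.loc[ok & ~a_mask, var]
            summ_a = f"n={len(row)}"
            summ_b = f"n={len(other)}"
            expected_small = False
            if tab.shape == (2, 2):
                rowsum = tab.sum(axis=1, keepdims=True)
                colsum = tab.sum(axis=0, keepdims=True)
                if tab.sum() > 0:
                    expected_small = (rowsum @ colsum / tab.sum() < 5).any()
            if tab.shape == (2, 2) and expected_small:
                p = fisher_exact_2x2(tab.astype(int))
                results.append(
                    GroupComparison(var, summ_a, summ_b, "fisher_exact", math.nan, p)
                )
            else:
                stat, p = chi_square(tab)
                results.append(
                    GroupComparison(var, summ_a, summ_b, "chi_square", stat, p)
                )
        else:
            if xa.size == 0 or xb.size == 0:
                continue
            ma, q1a, q3a = median_iqr(xa)
            mb, q1b, q3b = median_iqr(xb)
            res = mann_whitney(xa, xb)
            results.append(
                GroupComparison(
                    var,
                    f"{ma:.2f} ({q1a:.2f}; {q3a:.2f})",
                    f"{mb:.2f} ({q1b:.2f}; {q3b:.2f})",
                    "mann_whitney",
                    res.U,
                    res.p_value,
                )
            )
    return results


# Bootstrap --------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapReport:
    metric_name: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int
    n_failed: int = 0
    method: str = "stratified percentile"


def metric_auc(values, outcomes) -> float:
    return float(auc_pair_oracle(values, outcomes))


def metric_youden_accuracy(values, outcomes, resolution: float = 0.01) -> float:
    """Accuracy at the Youden-optimal cutoff re-derived on the given data."""
    roc = build_roc(values, outcomes, resolution=resolution)
    cuts = derive_cutoffs(roc, values, outcomes, resolution=resolution)
    cm = confusion_from_threshold(values, outcomes, cuts.optimal)
    return float(summarize(cm).accuracy)


def metric_optimal_cutoff(values, outcomes, resolution: float = 0.01) -> float:
    roc = build_roc(values, outcomes, resolution=resolution)
    return derive_cutoffs(roc, values, outcomes, resolution=resolution).optimal


def metric_ofc_fraction(values, outcomes, resolution: float = 0.01) -> float:
    """Equivocal-zone fraction under in-resample se100/sp100 cutoffs."""
    roc = build_roc(values, outcomes, resolution=resolution)
    cuts = derive_cutoffs(roc, values, outcomes, resolution=resolution)
    res = triage_summary(values, outcomes, cuts.se100, cuts.sp100)
    return float(res.pct_ofc)


METRICS: dict[str, Callable] = {
    "auc": metric_auc,
    "youden_accuracy": metric_youden_accuracy,
    "optimal_cutoff": metric_optimal_cutoff,
    "ofc_fraction": metric_ofc_fraction,
}


def bootstrap_validate(
    values: Sequence,
    outcomes: Sequence,
    metric: Union[str, Callable],
    n_resamples: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> BootstrapReport:
    """Stratified percentile bootstrap of a diagnostic metric.

    Resamples with replacement within each outcome class so every resample
    keeps the observed class sizes; the metric (cutoff derivation included)
    is recomputed per resample.  Fails if the metric is undefined on more
    than half of the resamples.
    """
    if n_resamples < 1:
        raise InvalidInputError("n_resamples must be >= 1")
    if isinstance(metric, str):
        metric_name = metric
        metric_fn = METRICS[metric]
    else:
        metric_name = getattr(metric, "__name__", "metric")
        metric_fn = metric
    pairs = [(float(v), o) for v, o in zip(values, outcomes) if not _is_missing(v)]
    vals = np.array([p[0] for p in pairs])
    outs = np.array([p[1] for p in pairs])
    point = float(metric_fn(vals, outs))
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(outs == c) for c in (ALLERGIC, TOLERANT)]
    idx_by_class = [ix for ix in idx_by_class if ix.size]
    estimates = []
    failed = 0
    for _ in range(n_resamples):
        take = np.concatenate(
            [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_class]
        )
        try:
            estimates.append(float(metric_fn(vals[take], outs[take])))
        except Exception:
            failed += 1
    if failed > n_resamples / 2:
        raise BootstrapFailureError(
            f"metric {metric_name!r} undefined on {failed}/{n_resamples} resamples"
        )
    alpha = (1 - confidence) / 2
    lo, hi = np.quantile(estimates, [alpha, 1 - alpha])
    return BootstrapReport(
        metric_name=metric_name,
        point_estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        seed=seed,
        n_failed=failed,
    )


def bootstrap_validate_subjects(
    subjects,
    marker: str,
    outcome_field: str,
    metric: Union[str, Callable],
    n_resamples: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> BootstrapReport:
    """Subject-level convenience wrapper around :func:`bootstrap_validate`."""
    values, outcomes = [], []
    for s in subjects:
        o = getattr(s, outcome_field)
        if o in (ALLERGIC, TOLERANT):
            values.append(s.marker(marker))
            outcomes.append(o)
    return bootstrap_validate(
        values, outcomes, metric, n_resamples=n_resamples, seed=seed, confidence=confidence
    )
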