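"""Empirical ROC curves and derivation of the three clinical cutoffs.

Candidate thresholds are the observed marker values plus one sentinel above
the maximum (so that a "nobody positive" operating point always exists under
the ``value >= threshold`` positivity convention).  The area under the curve
is the exact trapezoidal integral over (1-Sp, Se), computed in integer
arithmetic; it coincides with the tie-aware pair-counting probability
(Mann-Whitney statistic scaled to [0, 1]), which :func:`auc_pair_oracle`
computes independently.

Three cutoffs are derived per marker:

* ``optimal`` — maximizes the Youden index J = Se + Sp - 1;
* ``se100``  — the highest threshold retaining 100% sensitivity, i.e. the
  minimum diseased value (rule-out / "negative" cutoff);
* ``sp100``  — the lowest threshold achieving 100% specificity, i.e. the
  smallest observed value strictly above every non-diseased value, or a
  sentinel one resolution unit above the maximum when none qualifies
  (rule-in / "positive" cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateRocError, EmptyAnalysisError, InvalidInputError
from .metrics import (
    ALLERGIC,
    TOLERANT,
    ConfusionMatrix,
    DiagnosticSummary,
    _is_missing,
    confusion_from_threshold,
    summarize,
)

POSITIVITY_CONVENTION = "positive iff value >= threshold"


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: Fraction
    specificity: Fraction


@dataclass(frozen=True)
class RocCurve:
    points: tuple  # of RocPoint, thresholds strictly increasing
    auc: Fraction
    n_diseased: int
    n_nondiseased: int

    def as_arrays(self):
        """(thresholds, sensitivity, specificity) as float arrays."""
        t = np.array([p.threshold for p in self.points], dtype=float)
        se = np.array([float(p.sensitivity) for p in self.points])
        sp = np.array([float(p.specificity) for p in self.points])
        return t, se, sp


@dataclass(frozen=True)
class CutoffSet:
    optimal: float
    se100: float
    sp100: Optional[float]
    youden_at_optimal: Fraction
    convention: str = field(default=POSITIVITY_CONVENTION)

    def as_list(self) -> list:
        out = [("optimal", self.optimal), ("se100", self.se100)]
        if self.sp100 is not None:
            out.append(("sp100", self.sp100))
        return out


def _split_classes(values: Sequence, outcomes: Sequence):
    if len(values) != len(outcomes):
        raise InvalidInputError("values and outcomes must be aligned")
    diseased, nondiseased = [], []
    for v, o in zip(values, outcomes):
        if _is_missing(v):
            continue
        if o == ALLERGIC:
            diseased.append(float(v))
        elif o == TOLERANT:
            nondiseased.append(float(v))
        else:
            raise InvalidInputError(f"unexpected outcome label {o!r}")
    if not diseased and not nondiseased:
        raise EmptyAnalysisError("no non-missing (value, outcome) pairs")
    if not diseased:
        raise DegenerateRocError(ALLERGIC)
    if not nondiseased:
        raise DegenerateRocError(TOLERANT)
    return np.sort(diseased), np.sort(nondiseased)


def build_roc(values: Sequence, outcomes: Sequence, resolution: float = 0.01) -> RocCurve:
    """Empirical ROC over observed thresholds plus a top sentinel.

    ``resolution`` is the marker's reporting resolution (1 mm for skin prick
    wheals, 0.01 for sIgE and BAT indices); it only positions the sentinel.
    """
    d, h = _split_classes(values, outcomes)
    nd, nh = len(d), len(h)
    cands = np.unique(np.concatenate([d, h]))
    thresholds = np.append(cands, cands[-1] + resolution)
    # count of class members >= t, exact integers via sorted search
    tp = nd - np.searchsorted(d, thresholds, side="left")
    fp = nh - np.searchsorted(h, thresholds, side="left")
    points = tuple(
        RocPoint(float(t), Fraction(int(a), nd), Fraction(nh - int(b), nh))
        for t, a, b in zip(thresholds, tp, fp)
    )
    # trapezoid over (x, y) = (fp/nh, tp/nd), walked in threshold order
    num = 0
    for i in range(len(thresholds) - 1):
        num += (int(fp[i]) - int(fp[i + 1])) * (int(tp[i]) + int(tp[i + 1]))
    auc = Fraction(num, 2 * nd * nh)
    return RocCurve(points=points, auc=auc, n_diseased=nd, n_nondiseased=nh)


def auc_pair_oracle(values: Sequence, outcomes: Sequence) -> Fraction:
    """Tie-aware pair-counting AUC: P(diseased > non-diseased) + ½P(tie).

    Independent of :func:`build_roc`; the two must agree exactly.
    """
    d, h = _split_classes(values, outcomes)
    greater = int(np.searchsorted(h, d, side="left").sum())
    ties = int((np.searchsorted(h, d, side="right") - np.searchsorted(h, d, side="left")).sum())
    return Fraction(2 * greater + ties, 2 * len(d) * len(h))


def derive_cutoffs(
    roc: RocCurve,
    values: Sequence,
    outcomes: Sequence,
    resolution: float = 0.01,
) -> CutoffSet:
    """Youden-optimal, 100%-sensitivity and 100%-specificity cutoffs.

    Youden ties break toward higher specificity, then the lower threshold
    (fewer challenge referrals at equal J).
    """
    d, h = _split_classes(values, outcomes)
    best = None
    for p in roc.points:
        j = p.sensitivity + p.specificity - 1
        if best is None or j > best[0] or (j == best[0] and p.specificity > best[1]):
            best = (j, p.specificity, p.threshold)
    se100 = float(d[0])  # minimum diseased value: Se = 1 and maximal threshold
    hmax = float(h[-1])
    above = np.concatenate([d, h])
    above = np.unique(above[above > hmax])
    if above.size:
        sp100 = float(above[0])
    else:
        sp100 = float(max(d[-1], hmax) + resolution)
    return CutoffSet(
        optimal=best[2], se100=se100, sp100=sp100, youden_at_optimal=best[0]
    )


def evaluate_at_cutoffs(
    values: Sequence, outcomes: Sequence, cutoffs: Sequence[float]
) -> list[tuple[float, ConfusionMatrix, DiagnosticSummary]]:
    """One (cutoff, confusion matrix, summary) row per requested cutoff."""
    if len(cutoffs) == 0:
        raise InvalidInputError("cutoffs must be non-empty")
    rows = []
    for c in cutoffs:
        cm = confusion_from_threshold(values, outcomes, c)
        rows.append((c, cm, summarize(cm)))
    return rows
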