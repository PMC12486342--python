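"""Confusion matrices and the Se/Sp/PPV/NPV/accuracy bundle.

All ratios are kept as exact :class:`fractions.Fraction` objects built from
integer cell counts, so summaries are reproducible bit-for-bit and a zero
denominator is represented by the explicit sentinel ``None`` ("undefined"),
never by ``nan`` or a silent zero.  Percent formatting rounds half-up, the
convention used in clinical diagnostic-accuracy tables, and renders the
undefined sentinel as an em-dash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .errors import (
    EmptyAnalysisError,
    InvalidInputError,
    InvalidOutcomeError,
    InvalidProportionError,
)

ALLERGIC = "allergic"
TOLERANT = "tolerant"

#: Sentinel rendered as an em-dash: a metric whose denominator is zero.
UNDEFINED = None

Proportion = Optional[Fraction]


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts against the oral-food-challenge reference standard.

    ``tp`` counts allergic subjects with a positive index test, ``tn``
    tolerant subjects with a negative one.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def nondiseased(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Exact diagnostic proportions; ``None`` marks an undefined cell."""

    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion
    balanced_accuracy: Proportion

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _ratio(num: int, den: int) -> Proportion:
    return Fraction(num, den) if den else UNDEFINED


def summarize(cm: ConfusionMatrix) -> DiagnosticSummary:
    """Se, Sp, PPV, NPV, accuracy and balanced accuracy from 2x2 counts.

    Any ratio with a zero denominator is the undefined sentinel; balanced
    accuracy — the mean of Se and Sp, which numerically coincides with the
    AUC of the dichotomized test — is undefined if either input is.
    """
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.tn + cm.fp)
    bal = (se + sp) / 2 if se is not None and sp is not None else UNDEFINED
    return DiagnosticSummary(
        sensitivity=se,
        specificity=sp,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        balanced_accuracy=bal,
    )


def confusion_from_threshold(
    values: Sequence, outcomes: Sequence, threshold: float
) -> ConfusionMatrix:
    """Dichotomize marker values at ``threshold`` against challenge outcomes.

    Positivity convention: positive iff ``value >= threshold``.  Missing
    values (``None``/NaN) are excluded pairwise together with their outcome.
    """
    if len(values) != len(outcomes):
        raise InvalidInputError("values and outcomes must be aligned")
    tp = fp = tn = fn = 0
    seen = 0
    for v, o in zip(values, outcomes):
        if _is_missing(v):
            continue
        if o not in (ALLERGIC, TOLERANT):
            raise InvalidOutcomeError(
                f"outcome must be {ALLERGIC!r} or {TOLERANT!r}, got {o!r}"
            )
        seen += 1
        positive = float(v) >= threshold
        if o == ALLERGIC:
            if positive:
                tp += 1
            else:
                fn += 1
        else:
            if positive:
                fp += 1
            else:
                tn += 1
    if seen == 0:
        raise EmptyAnalysisError("no non-missing (value, outcome) pairs")
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(x)  # exact for ints and binary floats


def _round_half_up_scaled(x: Fraction, scale: int) -> int:
    """floor(x*scale + 1/2) — exact half-up rounding of a rational."""
    return math.floor(x * scale + Fraction(1, 2))


def percent(x, decimals: int = 0) -> str:
    """Format a proportion (or the undefined sentinel) as e.g. ``"88%"``.

    Rounds half-up at the requested number of decimals: 7/8 -> "88%".
    """
    if x is UNDEFINED:
        return "—"
    f = _as_fraction(x)
    if not 0 <= f <= 1:
        raise InvalidProportionError(f"proportion outside [0, 1]: {x!r}")
    n = _round_half_up_scaled(f, 100 * 10**decimals)
    if decimals == 0:
        return f"{n}%"
    intpart, frac = divmod(n, 10**decimals)
    return f"{intpart}.{frac:0{decimals}d}%"


def format_proportion(x, decimals: int = 2) -> str:
    """Format a proportion as a bare decimal, e.g. ``"0.85"``; "—" if undefined."""
    if x is UNDEFINED:
        return "—"
    f = _as_fraction(x)
    if not 0 <= f <= 1:
        raise InvalidProportionError(f"proportion outside [0, 1]: {x!r}")
    n = _round_half_up_scaled(f, 10**decimals)
    intpart, frac = divmod(n, 10**decimals)
    return f"{intpart}.{frac:0{decimals}d}"
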