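"""Two-cutoff triage: rule out below the 100%-sensitivity cutoff, rule in
at/above the 100%-specificity cutoff, refer the equivocal zone to an oral
food challenge (OFC).

Zone semantics follow the ``value >= threshold`` positivity convention: the
tolerant zone is *strictly below* the rule-out cutoff (a subject exactly at
it is test-positive, hence equivocal), and the allergic zone starts *at* the
rule-in cutoff.  With cutoffs derived in-sample this guarantees zero false
negatives in the tolerant zone and zero false positives in the allergic
zone, so resolving the equivocal zone by OFC yields 100% diagnostic
accuracy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .errors import EmptyAnalysisError, InvalidCutoffPairError, InvalidInputError
from .metrics import ALLERGIC, TOLERANT, _is_missing
from .roc import build_roc, derive_cutoffs

TOLERANT_ZONE = "tolerant"
EQUIVOCAL_ZONE = "equivocal"
ALLERGIC_ZONE = "allergic"


@dataclass(frozen=True)
class TriageResult:
    n_total: int
    n_tolerant_zone: int
    n_equivocal: int
    n_allergic_zone: int
    ofc_negative: int          # true tolerant within the equivocal zone
    ofc_positive: int          # true allergic within the equivocal zone
    false_negatives_in_tolerant_zone: int
    false_positives_in_allergic_zone: int

    @property
    def pct_ofc(self) -> Fraction:
        return Fraction(self.n_equivocal, self.n_total)

    @property
    def pct_ofc_positive(self) -> Optional[Fraction]:
        if self.n_equivocal == 0:
            return None
        return Fraction(self.ofc_positive, self.n_equivocal)

    @property
    def pct_reduction(self) -> Fraction:
        return 1 - self.pct_ofc

    @property
    def strategy_accuracy(self) -> Fraction:
        """Equivocal subjects count as correct: the OFC resolves them."""
        correct = (
            (self.n_tolerant_zone - self.false_negatives_in_tolerant_zone)
            + (self.n_allergic_zone - self.false_positives_in_allergic_zone)
            + self.n_equivocal
        )
        return Fraction(correct, self.n_total)

    @property
    def accuracy_excluding_equivocal(self) -> Optional[Fraction]:
        """Accuracy over the confidently-labelled zones only (transparency)."""
        n = self.n_tolerant_zone + self.n_allergic_zone
        if n == 0:
            return None
        correct = (
            (self.n_tolerant_zone - self.false_negatives_in_tolerant_zone)
            + (self.n_allergic_zone - self.false_positives_in_allergic_zone)
        )
        return Fraction(correct, n)


def stratify(value: float, neg_cutoff: float, sp_cutoff: float) -> str:
    """Assign one marker value to the tolerant/equivocal/allergic zone."""
    if neg_cutoff > sp_cutoff:
        raise InvalidCutoffPairError(
            f"rule-out cutoff {neg_cutoff} exceeds rule-in cutoff {sp_cutoff}"
        )
    if value < neg_cutoff:
        return TOLERANT_ZONE
    if value >= sp_cutoff:
        return ALLERGIC_ZONE
    return EQUIVOCAL_ZONE


def triage_summary(
    values: Sequence,
    outcomes: Sequence,
    neg_cutoff: float,
    sp_cutoff: float,
) -> TriageResult:
    """Tally triage zones and equivocal-zone OFC outcomes."""
    if len(values) != len(outcomes):
        raise InvalidInputError("values and outcomes must be aligned")
    n = n_tol = n_eq = n_all = ofc_neg = ofc_pos = fn_tol = fp_all = 0
    for v, o in zip(values, outcomes):
        if _is_missing(v):
            continue
        if o not in (ALLERGIC, TOLERANT):
            raise InvalidInputError(f"unexpected outcome label {o!r}")
        n += 1
        zone = stratify(float(v), neg_cutoff, sp_cutoff)
        if zone == TOLERANT_ZONE:
            n_tol += 1
            if o == ALLERGIC:
                fn_tol += 1
        elif zone == ALLERGIC_ZONE:
            n_all += 1
            if o == TOLERANT:
                fp_all += 1
        else:
            n_eq += 1
            if o == ALLERGIC:
                ofc_pos += 1
            else:
                ofc_neg += 1
    if n == 0:
        raise EmptyAnalysisError("no non-missing (value, outcome) pairs")
    return TriageResult(
        n_total=n,
        n_tolerant_zone=n_tol,
        n_equivocal=n_eq,
        n_allergic_zone=n_all,
        ofc_negative=ofc_neg,
        ofc_positive=ofc_pos,
        false_negatives_in_tolerant_zone=fn_tol,
        false_positives_in_allergic_zone=fp_all,
    )


def ofc_reduction(result: TriageResult) -> Fraction:
    """Fraction of challenges avoided: 1 - n_equivocal / n_total."""
    return result.pct_reduction


def strategy_accuracy_check(
    values: Sequence, outcomes: Sequence, resolution: float = 0.01
) -> Fraction:
    """Derive se100/sp100 in-sample, triage with them, return the accuracy.

    Equals 1 by construction when cutoffs are derived and applied on the
    same data.
    """
    roc = build_roc(values, outcomes, resolution=resolution)
    cuts = derive_cutoffs(roc, values, outcomes, resolution=resolution)
    res = triage_summary(values, outcomes, cuts.se100, cuts.sp100)
    return res.strategy_accuracy
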