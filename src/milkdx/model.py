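"""Model/Results interface over the diagnostic-accuracy machinery.

:class:`DiagnosticCutoffModel` is built from per-subject marker values and
challenge outcomes (or directly from a cohort DataFrame / record list);
``fit()`` returns a :class:`DiagnosticCutoffResults` carrying the empirical
ROC, the three clinical cutoffs, the per-cutoff diagnostic table, the
two-cutoff triage result and a printable summary.  Bootstrap uncertainty
and plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ALLERGIC, MARKER_RESOLUTION, SubjectRecord, TOLERANT
from .errors import InvalidInputError
from .metrics import _is_missing, format_proportion, percent
from .roc import CutoffSet, RocCurve, build_roc, derive_cutoffs, evaluate_at_cutoffs
from .stats import BootstrapReport, bootstrap_validate
from .triage import TriageResult, triage_summary


class DiagnosticCutoffModel:
    """Diagnostic accuracy of one marker against one challenge outcome.

    Parameters
    ----------
    values, outcomes
        Aligned per-subject marker values (missing allowed) and outcomes
        (``"allergic"`` / ``"tolerant"``; others must be excluded upstream).
    marker_name
        Label used in reports; also selects the default reporting
        resolution (1 mm for skin-prick wheals, 0.01 otherwise).
    resolution
        Overrides the marker resolution used for ROC sentinels.
    """

    def __init__(
        self,
        values: Sequence,
        outcomes: Sequence,
        marker_name: str = "marker",
        resolution: Optional[float] = None,
    ):
        if len(values) != len(outcomes):
            raise InvalidInputError("values and outcomes must be aligned")
        keep = [
            (float(v), o)
            for v, o in zip(values, outcomes)
            if not _is_missing(v) and o in (ALLERGIC, TOLERANT)
        ]
        self.values = np.array([k[0] for k in keep])
        self.outcomes = np.array([k[1] for k in keep])
        self.marker_name = marker_name
        self.resolution = (
            resolution if resolution is not None else MARKER_RESOLUTION.get(marker_name, 0.01)
        )
        self.n_excluded = len(values) - len(keep)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        marker: str,
        outcome: str = "bm_outcome",
        resolution: Optional[float] = None,
    ) -> "DiagnosticCutoffModel":
        if marker not in frame.columns:
            raise InvalidInputError(f"marker column {marker!r} not in frame")
        if outcome not in frame.columns:
            raise InvalidInputError(f"outcome column {outcome!r} not in frame")
        return cls(
            frame[marker].tolist(),
            frame[outcome].tolist(),
            marker_name=marker,
            resolution=resolution,
        )

    @classmethod
    def from_cohort(
        cls,
        subjects: Sequence[SubjectRecord],
        marker: str,
        endpoint: str = "bm",
        population: str = "all_ages",
        nonresponder_policy: str = "include",
        resolution: Optional[float] = None,
    ) -> "DiagnosticCutoffModel":
        """Build from subject records, applying population and basophil
        non-responder filters.

        ``endpoint``: "bm" or "fm"; fresh-milk analyses are automatically
        restricted to subjects with a defined FM outcome.
        ``nonresponder_policy``: "include" keeps flagged subjects,
        "exclude" drops them (the basophil test is uninformative for them).
        """
        field = {"bm": "bm_outcome", "fm": "fm_outcome"}[endpoint]
        values, outcomes = [], []
        for s in subjects:
            if population == "under2" and s.age_group != "under2":
                continue
            if nonresponder_policy == "exclude" and s.basophil_nonresponder:
                continue
            o = getattr(s, field)
            if o not in (ALLERGIC, TOLERANT):
                continue
            values.append(s.marker(marker))
            outcomes.append(o)
        return cls(values, outcomes, marker_name=marker, resolution=resolution)

    @property
    def n(self) -> int:
        return len(self.values)

    def fit(self) -> "DiagnosticCutoffResults":
        roc = build_roc(self.values, self.outcomes, resolution=self.resolution)
        cutoffs = derive_cutoffs(roc, self.values, self.outcomes, resolution=self.resolution)
        rows = evaluate_at_cutoffs(
            self.values,
            self.outcomes,
            [cutoffs.optimal, cutoffs.se100, cutoffs.sp100],
        )
        labels = ["optimal", "se100", "sp100"]
        table = pd.DataFrame(
            [
                {
                    "cutoff_type": label,
                    "cutoff": c,
                    "balanced_accuracy": format_proportion(s.balanced_accuracy),
                    "sensitivity": percent(s.sensitivity),
                    "specificity": percent(s.specificity),
                    "ppv": percent(s.ppv),
                    "npv": percent(s.npv),
                    "accuracy": percent(s.accuracy),
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                    "n": cm.total,
                }
                for label, (c, cm, s) in zip(labels, rows)
            ]
        )
        triage = triage_summary(self.values, self.outcomes, cutoffs.se100, cutoffs.sp100)
        return DiagnosticCutoffResults(
            model=self, roc=roc, cutoffs=cutoffs, table=table, triage=triage
        )


@dataclass
class DiagnosticCutoffResults:
    """Fitted diagnostic-accuracy results for one marker/outcome pair."""

    model: DiagnosticCutoffModel
    roc: RocCurve
    cutoffs: CutoffSet
    table: pd.DataFrame
    triage: TriageResult

    @property
    def auc(self) -> float:
        return float(self.roc.auc)

    def bootstrap(
        self, metric: str = "auc", n_resamples: int = 2000, seed: int = 0
    ) -> BootstrapReport:
        return bootstrap_validate(
            self.model.values,
            self.model.outcomes,
            metric,
            n_resamples=n_resamples,
            seed=seed,
        )

    def triage_row(self) -> dict:
        """One report row in clinical column order."""
        t = self.triage
        return {
            "marker": self.model.marker_name,
            "tolerant": t.n_tolerant_zone,
            "equivocal": t.n_equivocal,
            "allergic": t.n_allergic_zone,
            "ofc_negative": t.ofc_negative,
            "ofc_positive": t.ofc_positive,
            "pct_ofc": percent(t.pct_ofc),
            "pct_ofc_positive": percent(t.pct_ofc_positive),
        }

    def summary(self) -> str:
        m = self.model
        lines = [
            "Diagnostic cutoff analysis",
            "=" * 60,
            f"Marker:            {m.marker_name}",
            f"N (analysed):      {m.n}"
            + (f"  [{m.n_excluded} excluded: missing value or outcome]" if m.n_excluded else ""),
            f"Allergic / Tolerant: {self.roc.n_diseased} / {self.roc.n_nondiseased}",
            f"AUC (trapezoidal): {float(self.roc.auc):.3f}",
            f"Positivity:        {self.cutoffs.convention}",
            "",
            f"Youden-optimal cutoff: {self.cutoffs.optimal:g}"
            f"   (J = {float(self.cutoffs.youden_at_optimal):.3f})",
            f"100%-sensitivity (rule-out) cutoff: {self.cutoffs.se100:g}",
            f"100%-specificity (rule-in) cutoff:  {self.cutoffs.sp100:g}",
            "",
            self.table.to_string(index=False),
            "",
            "Two-cutoff triage (rule out / OFC / rule in):",
            f"  tolerant zone {self.triage.n_tolerant_zone}"
            f" | equivocal {self.triage.n_equivocal}"
            f" | allergic zone {self.triage.n_allergic_zone}",
            f"  OFC needed: {percent(self.triage.pct_ofc)}"
            f" (positive OFC among them: {percent(self.triage.pct_ofc_positive)})",
            f"  OFC reduction: {percent(self.triage.pct_reduction)}",
            f"  strategy accuracy (OFC resolves equivocal): {percent(self.triage.strategy_accuracy)}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the empirical ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        _, se, sp = self.roc.as_arrays()
        ax.plot(1 - sp, se, drawstyle="steps-post", label=self.model.marker_name)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("Sensitivity")
        ax.set_title(f"AUC = {float(self.roc.auc):.3f}")
        ax.legend()
        return ax
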