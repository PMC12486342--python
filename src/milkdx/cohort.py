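"""Synthetic milk-allergy cohort generator and cohort-level filters.

The generator emulates the statistical structure of a pediatric cow's-milk
diagnostic cohort in which every child has a baked-milk (BM) oral food
challenge and only BM-tolerant children go on to a fresh-milk (FM)
challenge.  Three latent phenotypes drive both outcomes and the biomarker
panel:

* ``allergic_all`` — reacts to baked and fresh milk;
* ``bm_tolerant_fm_allergic`` — tolerates baked but reacts to fresh milk;
* ``tolerant_all`` — tolerates both.

Markers (skin-prick wheals, specific IgE, basophil activation readouts) are
drawn from left-censored log-normal distributions calibrated per phenotype
to published median (q1; q3) summaries; skin-prick wheals are additionally
rounded to whole millimetres.  A small fraction of subjects carry
non-responder basophils (%CD63+ below 5% to both anti-IgE and allergen), by
default drawn from the fully tolerant phenotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    ConfigurationError,
    InvalidInputError,
    SchemaError,
    UnsupportedCaseError,
)

# Outcome / phenotype labels -------------------------------------------------

ALLERGIC = "allergic"
TOLERANT = "tolerant"
INCONCLUSIVE = "inconclusive"
MISSING = "missing"

ALLERGIC_ALL = "allergic_all"
BM_TOL_FM_ALLERGIC = "bm_tolerant_fm_allergic"
TOLERANT_ALL = "tolerant_all"
PHENOTYPES = (ALLERGIC_ALL, BM_TOL_FM_ALLERGIC, TOLERANT_ALL)

#: Marker panel, in the fixed order used by the sampling stream.
MARKER_NAMES = (
    "spt_milk_extract_mm",
    "spt_fresh_milk_mm",
    "spt_baked_milk_mm",
    "sige_cows_milk",
    "sige_boiled_milk",
    "sige_bosd4",
    "sige_bosd5",
    "sige_bosd8",
    "bat_me_cd63_pct",
    "bat_me_si_cd203c",
    "bat_bm_cd63_pct",
    "bat_bm_si_cd203c",
    "bat_antiige_cd63_pct",
)

SPT_MARKERS = tuple(m for m in MARKER_NAMES if m.startswith("spt_"))
CD63_PCT_MARKERS = ("bat_me_cd63_pct", "bat_bm_cd63_pct")

#: Reporting resolution per marker: 1 mm for wheals, 0.01 otherwise.
MARKER_RESOLUTION = {m: (1.0 if m in SPT_MARKERS else 0.01) for m in MARKER_NAMES}

Z75 = float(norm.ppf(0.75))  # 0.6744897...


# Domain types ----------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One child: challenge outcomes, age, marker panel, basophil status."""

    subject_id: str
    age_years: float
    bm_outcome: str
    fm_outcome: str
    phenotype: Optional[str]
    markers: dict
    basophil_nonresponder: bool = False

    @property
    def age_group(self) -> str:
        return "under2" if self.age_years < 2 else "ge2"

    def marker(self, name: str):
        return self.markers.get(name)


@dataclass(frozen=True)
class MarkerDistribution:
    """Left-censored log-normal with optional extra point mass at the floor.

    ``mu``/``sigma`` are on the natural-log scale; ``floor`` is the
    censoring value (0 mm for wheals, 0.01 kU_A/L for sIgE); ``zero_mass``
    adds a point mass at the floor on top of censoring; ``rounding``
    ("none" or "integer") models the instrument's reporting grid.
    """

    mu: float
    sigma: float
    floor: float = 0.0
    zero_mass: float = 0.0
    rounding: str = "none"
    family: str = "lognormal_censored"
    upper: Optional[float] = None  # hard cap, e.g. 100 for %CD63

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")
        if not 0 <= self.zero_mass <= 1:
            raise InvalidInputError("zero_mass must be in [0, 1]")
        if self.rounding not in ("none", "integer"):
            raise InvalidInputError(f"unknown rounding {self.rounding!r}")

    def sample(self, u_zero: float, z: float) -> float:
        """One draw from two uniform/normal variates (stream-stable)."""
        if u_zero < self.zero_mass:
            x = self.floor
        else:
            x = math.exp(self.mu + self.sigma * z)
            x = max(x, self.floor)
        if self.upper is not None:
            x = min(x, self.upper)
        if self.rounding == "integer":
            x = float(round(x))
        else:
            x = round(x, 3)  # instrument reporting grid; keeps CSV round-trips exact
        return x

    def quantile(self, p: float) -> float:
        """Analytic quantile of the censored (pre-rounding) distribution."""
        if p < self.zero_mass:
            q = self.floor
        else:
            pc = (p - self.zero_mass) / (1 - self.zero_mass)
            q = max(math.exp(self.mu + self.sigma * norm.ppf(pc)), self.floor)
        if self.upper is not None:
            q = min(q, self.upper)
        return q

    def floor_mass(self) -> float:
        """Total probability at the floor (zero mass plus censoring)."""
        if self.sigma == 0:
            cens = 1.0 if math.exp(self.mu) <= self.floor else 0.0
        elif self.floor <= 0:
            cens = 0.0
        else:
            cens = float(norm.cdf((math.log(self.floor) - self.mu) / self.sigma))
        return self.zero_mass + (1 - self.zero_mass) * cens


def lognormal_params_from_quartiles(median: float, q1: float, q3: float):
    """(mu, sigma) of a log-normal from its median and quartiles.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_0.75).  The median is
    matched exactly and the quartiles are matched in ratio (log-symmetric
    approximation).
    """
    if not (0 < q1 <= median <= q3):
        raise InvalidInputError(
            f"quartiles must satisfy 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    return math.log(median), math.log(q3 / q1) / (2 * Z75)


def dist_from_summary(
    median: float,
    q1: float,
    q3: float,
    floor: float = 0.0,
    rounding: str = "none",
    upper: Optional[float] = None,
    zero_mass_when_floored: float = 0.26,
) -> MarkerDistribution:
    """Calibrate a :class:`MarkerDistribution` to a printed median (q1; q3).

    When the printed q1 sits at the floor (e.g. "0.85 (0; 3.42)"), a point
    mass ``zero_mass_when_floored`` (just above a quartile) is placed at the
    floor and (mu, sigma) solve the remaining two quantile equations for the
    continuous part exactly.
    """
    if q1 > floor:
        mu, sigma = lognormal_params_from_quartiles(median, q1, q3)
        return MarkerDistribution(
            mu=mu, sigma=sigma, floor=floor, rounding=rounding, upper=upper
        )
    if not (floor < median <= q3):
        raise InvalidInputError(
            f"need floor < median <= q3 for floored calibration, got ({median}, {q1}, {q3})"
        )
    w = zero_mass_when_floored
    z_med = norm.ppf((0.5 - w) / (1 - w))
    z_q3 = norm.ppf((0.75 - w) / (1 - w))
    if median == q3:
        sigma = 0.0
    else:
        sigma = math.log(q3 / median) / (z_q3 - z_med)
    mu = math.log(median) - sigma * z_med
    return MarkerDistribution(
        mu=mu, sigma=sigma, floor=floor, zero_mass=w, rounding=rounding, upper=upper
    )


def analytic_auc_lognormal(d0: MarkerDistribution, d1: MarkerDistribution) -> float:
    """P(draw from d1 > draw from d0) for two pure log-normals.

    Closed form Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2)); valid only
    without point masses or rounding (use Monte Carlo otherwise).
    """
    for d in (d0, d1):
        if d.zero_mass > 0 or d.rounding != "none":
            raise UnsupportedCaseError(
                "closed-form AUC requires zero_mass = 0 and no rounding"
            )
    s = math.hypot(d0.sigma, d1.sigma)
    if s == 0:
        if d1.mu == d0.mu:
            return 0.5
        return 1.0 if d1.mu > d0.mu else 0.0
    return float(norm.cdf((d1.mu - d0.mu) / s))


# Default calibration ---------------------------------------------------------

_SIGE_FLOOR = 0.01

# (median, q1, q3) per marker and phenotype. The allergic_all column comes
# from the BM-allergic group summaries, tolerant_all from the FM-tolerant
# group, and the intermediate phenotype from the FM-allergic group (a
# documented approximation: that group is a mixture dominated by the
# intermediate phenotype).
_TABLE_SUMMARIES = {
    "spt_milk_extract_mm": {
        ALLERGIC_ALL: (4, 3, 5),
        BM_TOL_FM_ALLERGIC: (4, 3, 5),
        TOLERANT_ALL: (1, 0, 3),
    },
    "spt_fresh_milk_mm": {
        ALLERGIC_ALL: (8, 5, 9),
        BM_TOL_FM_ALLERGIC: (7, 5, 9),
        TOLERANT_ALL: (4, 0, 5),
    },
    "spt_baked_milk_mm": {
        ALLERGIC_ALL: (5, 3, 6),
        BM_TOL_FM_ALLERGIC: (1, 0, 3),
        TOLERANT_ALL: (1, 0, 3),
    },
    "sige_cows_milk": {
        ALLERGIC_ALL: (6.29, 1.47, 14.73),
        BM_TOL_FM_ALLERGIC: (1.55, 0.41, 8.26),
        TOLERANT_ALL: (0.35, 0.12, 0.74),
    },
    "sige_boiled_milk": {
        ALLERGIC_ALL: (5.53, 1.14, 14.18),
        BM_TOL_FM_ALLERGIC: (1.21, 0.27, 5.42),
        TOLERANT_ALL: (0.16, 0.03, 0.51),
    },
    "sige_bosd4": {
        ALLERGIC_ALL: (0.70, 0.09, 3.57),
        BM_TOL_FM_ALLERGIC: (0.33, 0.02, 2.89),
        TOLERANT_ALL: (0.07, 0.01, 0.17),
    },
    "sige_bosd5": {
        ALLERGIC_ALL: (0.62, 0.05, 2.38),
        BM_TOL_FM_ALLERGIC: (0.28, 0.08, 0.82),
        TOLERANT_ALL: (0.13, 0.03, 0.36),
    },
    "sige_bosd8": {
        ALLERGIC_ALL: (3.09, 1.12, 13.15),
        BM_TOL_FM_ALLERGIC: (0.68, 0.14, 3.30),
        TOLERANT_ALL: (0.11, 0.01, 0.28),
    },
    "bat_me_cd63_pct": {
        ALLERGIC_ALL: (24.99, 16.70, 36.28),
        BM_TOL_FM_ALLERGIC: (9.45, 2.80, 28.72),
        TOLERANT_ALL: (1.17, 0.16, 3.65),
    },
    "bat_me_si_cd203c": {
        ALLERGIC_ALL: (3.48, 2.58, 4.66),
        BM_TOL_FM_ALLERGIC: (1.97, 1.30, 3.54),
        TOLERANT_ALL: (1.07, 1.00, 1.30),
    },
    "bat_bm_cd63_pct": {
        ALLERGIC_ALL: (18.01, 9.43, 29.24),
        BM_TOL_FM_ALLERGIC: (4.69, 0.84, 20.41),
        TOLERANT_ALL: (0.20, 0.0, 1.32),
    },
    "bat_bm_si_cd203c": {
        ALLERGIC_ALL: (3.54, 2.06, 4.54),
        BM_TOL_FM_ALLERGIC: (1.51, 1.13, 3.55),
        TOLERANT_ALL: (1.04, 0.97, 1.11),
    },
    # Anti-IgE positive control: not phenotype-dependent; a typical
    # responder distribution well above the 5% non-responder threshold.
    "bat_antiige_cd63_pct": {
        ALLERGIC_ALL: (35.0, 20.0, 55.0),
        BM_TOL_FM_ALLERGIC: (35.0, 20.0, 55.0),
        TOLERANT_ALL: (35.0, 20.0, 55.0),
    },
}


def _marker_floor(marker: str) -> float:
    if marker in SPT_MARKERS:
        return 0.0
    if marker.startswith("sige_"):
        return _SIGE_FLOOR
    if marker.endswith("_cd63_pct"):
        return 0.0
    return 0.0  # stimulation indices: strictly positive log-normal, no censoring


def default_marker_dists() -> dict:
    """Default (phenotype, marker) -> MarkerDistribution calibration."""
    dists = {}
    for marker, per_phen in _TABLE_SUMMARIES.items():
        floor = _marker_floor(marker)
        rounding = "integer" if marker in SPT_MARKERS else "none"
        upper = 100.0 if marker.endswith("_cd63_pct") else None
        for phen, (m, q1, q3) in per_phen.items():
            # printed q1 at (or below) the floor => floored calibration path;
            # for integer-rounded wheals a printed q1 of 0 means sub-0.5 mm
            eff_q1 = q1 if q1 > floor and not (rounding == "integer" and q1 == 0) else floor
            dists[(phen, marker)] = dist_from_summary(
                m, eff_q1, q3, floor=floor, rounding=rounding, upper=upper
            )
    return dists


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults reproduce the study-scale cohort:

    ~15% allergic to all milk, 85% BM-tolerant of whom ~56% also tolerate
    FM, ~17% under two years of age, ~4.7% basophil non-responders, and an
    FM-challenge completion rate of 113/127 among BM-tolerant children.
    """

    n: int = 150
    prop_allergic_all: float = 0.15
    prop_bm_tolerant_fm_allergic: float = 0.37
    prop_tolerant_all: float = 0.48
    prop_under2: float = 0.17
    nonresponder_rate: float = 0.047
    fm_completion_rate: float = 113 / 127
    marker_missing_rate: float = 0.0
    seed: int = 0
    marker_dists: dict = field(default_factory=default_marker_dists)
    #: optional per-age-group overrides, keyed (phenotype, marker)
    under2_marker_dists: dict = field(default_factory=dict)
    #: phenotypes eligible for the non-responder flag
    nonresponder_phenotypes: tuple = (TOLERANT_ALL,)

    def __post_init__(self):
        props = (
            self.prop_allergic_all,
            self.prop_bm_tolerant_fm_allergic,
            self.prop_tolerant_all,
        )
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(f"phenotype proportions must sum to 1, got {props}")
        for name in (
            "prop_allergic_all",
            "prop_bm_tolerant_fm_allergic",
            "prop_tolerant_all",
            "prop_under2",
            "nonresponder_rate",
            "fm_completion_rate",
            "marker_missing_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")

    def dist_for(self, phenotype: str, marker: str, under2: bool) -> MarkerDistribution:
        if under2 and (phenotype, marker) in self.under2_marker_dists:
            return self.under2_marker_dists[(phenotype, marker)]
        try:
            return self.marker_dists[(phenotype, marker)]
        except KeyError:
            raise ConfigurationError(
                f"no marker distribution configured for ({phenotype!r}, {marker!r})"
            ) from None


# Generation ------------------------------------------------------------------

# Age model for the >= 2 / < 2 split: a single log-normal (median 4 y,
# quartiles ~2.3/7.6 y) truncated on each side of 2 years via inverse-CDF.
_AGE_MU = math.log(4.0)
_AGE_SIGMA = math.log(7.6 / 2.3) / (2 * Z75)
_AGE_F2 = float(norm.cdf((math.log(2.0) - _AGE_MU) / _AGE_SIGMA))


def _sample_age(u: float, under2: bool) -> float:
    if under2:
        p = u * _AGE_F2
    else:
        p = _AGE_F2 + u * (1 - _AGE_F2)
    p = min(max(p, 1e-12), 1 - 1e-12)
    age = math.exp(_AGE_MU + _AGE_SIGMA * norm.ppf(p))
    return float(min(max(age, 0.5), 15.0))


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw ``config.n`` subjects; identical seeds give identical cohorts.

    The sampling stream is strictly sequential per subject in documented
    order: phenotype, age group, age, FM completion, non-responder flag,
    then per marker (missingness, floor mass, log-normal variate), and
    finally non-responder marker overrides.
    """
    rng = np.random.default_rng(config.seed)
    # per-subject probability so that the *cohort-level* non-responder rate
    # matches nonresponder_rate while only eligible phenotypes are flagged
    prop_eligible = 0.0
    for phen, prop in zip(
        PHENOTYPES,
        (
            config.prop_allergic_all,
            config.prop_bm_tolerant_fm_allergic,
            config.prop_tolerant_all,
        ),
    ):
        if phen in config.nonresponder_phenotypes:
            prop_eligible += prop
    nr_prob = config.nonresponder_rate / prop_eligible if prop_eligible > 0 else 0.0
    if nr_prob > 1:
        raise ConfigurationError(
            "nonresponder_rate exceeds the mass of eligible phenotypes"
        )

    cum = np.cumsum(
        [config.prop_allergic_all, config.prop_bm_tolerant_fm_allergic, config.prop_tolerant_all]
    )
    subjects = []
    for i in range(config.n):
        u_phen = rng.random()
        phenotype = PHENOTYPES[int(np.searchsorted(cum, u_phen, side="right").clip(0, 2))]
        under2 = rng.random() < config.prop_under2
        age = _sample_age(rng.random(), under2)
        u_fm = rng.random()
        u_nr = rng.random()

        bm_outcome = ALLERGIC if phenotype == ALLERGIC_ALL else TOLERANT
        if bm_outcome == TOLERANT and u_fm < config.fm_completion_rate:
            fm_outcome = ALLERGIC if phenotype == BM_TOL_FM_ALLERGIC else TOLERANT
        else:
            fm_outcome = MISSING
        nonresponder = (
            phenotype in config.nonresponder_phenotypes and u_nr < nr_prob
        )

        markers = {}
        for marker in MARKER_NAMES:
            u_miss = rng.random()
            u_zero = rng.random()
            z = rng.standard_normal()
            if u_miss < config.marker_missing_rate:
                markers[marker] = None
                continue
            dist = config.dist_for(phenotype, marker, under2)
            markers[marker] = dist.sample(u_zero, z)

        if nonresponder:
            # basophils unresponsive: %CD63 below the 5% threshold for
            # anti-IgE and allergen, stimulation indices near background
            for marker in ("bat_antiige_cd63_pct", *CD63_PCT_MARKERS):
                val = rng.uniform(0.0, 4.5)
                if markers.get(marker) is not None:
                    markers[marker] = round(val, 2)
            for marker in ("bat_me_si_cd203c", "bat_bm_si_cd203c"):
                val = rng.uniform(0.9, 1.15)
                if markers.get(marker) is not None:
                    markers[marker] = round(val, 2)

        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:05d}",
                age_years=round(age, 2),
                bm_outcome=bm_outcome,
                fm_outcome=fm_outcome,
                phenotype=phenotype,
                markers=markers,
                basophil_nonresponder=nonresponder,
            )
        )
    return subjects


# Cohort filters and derived quantities ---------------------------------------


def flag_nonresponders(
    subjects: Sequence[SubjectRecord],
    threshold_pct: float = 5.0,
    warnings_out: Optional[list] = None,
) -> list[SubjectRecord]:
    """Re-derive the non-responder flag from measured BAT values.

    A subject is a non-responder iff %CD63+ to anti-IgE is below
    ``threshold_pct`` AND every present allergen %CD63+ marker is below it.
    Subjects with all relevant markers missing keep their flag unchanged and
    are listed in ``warnings_out`` if given.
    """
    out = []
    for s in subjects:
        anti = s.marker("bat_antiige_cd63_pct")
        allergen = [s.marker(m) for m in CD63_PCT_MARKERS]
        allergen = [a for a in allergen if a is not None]
        if anti is None and not allergen:
            if warnings_out is not None:
                warnings_out.append(s.subject_id)
            out.append(s)
            continue
        flag = (anti is not None and anti < threshold_pct) and all(
            a < threshold_pct for a in allergen
        )
        out.append(replace(s, basophil_nonresponder=bool(flag)))
    return out


def derived_spt_markers(subject: SubjectRecord):
    """(fresh-milk minus extract wheal, extract/fresh-milk wheal ratio).

    The ratio is ``None`` when the fresh-milk wheal is 0 mm; both are
    ``None`` when either wheal is missing.
    """
    cme = subject.marker("spt_milk_extract_mm")
    fm = subject.marker("spt_fresh_milk_mm")
    if cme is None or fm is None:
        return None, None
    diff = fm - cme
    ratio = cme / fm if fm != 0 else None
    return diff, ratio


# I/O --------------------------------------------------------------------------

_CSV_COLUMNS = (
    "subject_id",
    "age_years",
    "age_group",
    "bm_outcome",
    "fm_outcome",
    "phenotype",
    "basophil_nonresponder",
    *MARKER_NAMES,
)

MANDATORY_COLUMNS = ("subject_id", "bm_outcome")


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age_years": s.age_years,
            "age_group": s.age_group,
            "bm_outcome": s.bm_outcome,
            "fm_outcome": s.fm_outcome,
            "phenotype": s.phenotype,
            "basophil_nonresponder": s.basophil_nonresponder,
        }
        for m in MARKER_NAMES:
            row[m] = s.markers.get(m)
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort(subjects: Sequence[SubjectRecord], path) -> None:
    """Write the cohort as a UTF-8 CSV; missing values as empty cells."""
    df = cohort_to_frame(subjects)
    df["basophil_nonresponder"] = df["basophil_nonresponder"].map(
        {True: "true", False: "false"}
    )
    df.to_csv(path, index=False, encoding="utf-8")


def _parse_outcome(raw, row_no: int, col: str) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return MISSING
    val = str(raw).strip().lower()
    if val in (ALLERGIC, TOLERANT, INCONCLUSIVE, MISSING):
        return val
    raise SchemaError(f"row {row_no}: invalid {col} value {raw!r}")


def read_cohort(path) -> list[SubjectRecord]:
    """Read a cohort CSV back into records, validating structure.

    Empty outcome cells are *missing* (never tolerant); an FM outcome on a
    subject who is not BM-tolerant violates the challenge-sequence rule (FM
    challenges are only offered after a passed BM challenge) and raises
    :class:`SchemaError`.  Malformed numeric cells are reported with their
    row number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    absent = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if absent:
        raise SchemaError(f"missing mandatory columns: {absent}")
    subjects = []
    problems = []
    for idx, row in df.iterrows():
        row_no = idx + 2  # header is line 1
        bm = _parse_outcome(row.get("bm_outcome"), row_no, "bm_outcome")
        fm = _parse_outcome(row.get("fm_outcome"), row_no, "fm_outcome")
        if fm in (ALLERGIC, TOLERANT) and bm != TOLERANT:
            raise SchemaError(
                f"row {row_no}: fm_outcome={fm!r} but bm_outcome={bm!r}; a fresh-milk "
                "challenge outcome requires a tolerated baked-milk challenge"
            )
        markers = {}
        for m in MARKER_NAMES:
            if m not in df.columns:
                continue
            raw = row[m]
            if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
                markers[m] = None
                continue
            try:
                markers[m] = float(raw)
            except (TypeError, ValueError):
                problems.append(f"row {row_no}: malformed numeric cell {m}={raw!r}")
                markers[m] = None
        age_raw = row.get("age_years", math.nan)
        try:
            age = float(age_raw)
        except (TypeError, ValueError):
            problems.append(f"row {row_no}: malformed age_years={age_raw!r}")
            age = math.nan
        nr_raw = str(row.get("basophil_nonresponder", "false")).strip().lower()
        phen = row.get("phenotype")
        if phen is not None and (not isinstance(phen, str) or phen == ""):
            phen = None
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age_years=age,
                bm_outcome=bm,
                fm_outcome=fm,
                phenotype=phen if phen in PHENOTYPES else None,
                markers=markers,
                basophil_nonresponder=nr_raw in ("true", "1", "yes"),
            )
        )
    if problems:
        raise SchemaError("; ".join(problems))
    return subjects


# Config (de)serialization -----------------------------------------------------


def _dist_to_dict(d: MarkerDistribution) -> dict:
    return {
        "mu": d.mu,
        "sigma": d.sigma,
        "floor": d.floor,
        "zero_mass": d.zero_mass,
        "rounding": d.rounding,
        "upper": d.upper,
    }


def config_to_dict(config: CohortConfig) -> dict:
    out = {
        "n": config.n,
        "prop_allergic_all": config.prop_allergic_all,
        "prop_bm_tolerant_fm_allergic": config.prop_bm_tolerant_fm_allergic,
        "prop_tolerant_all": config.prop_tolerant_all,
        "prop_under2": config.prop_under2,
        "nonresponder_rate": config.nonresponder_rate,
        "fm_completion_rate": config.fm_completion_rate,
        "marker_missing_rate": config.marker_missing_rate,
        "seed": config.seed,
        "nonresponder_phenotypes": list(config.nonresponder_phenotypes),
        "marker_dists": {
            f"{phen}/{marker}": _dist_to_dict(d)
            for (phen, marker), d in sorted(config.marker_dists.items())
        },
        "under2_marker_dists": {
            f"{phen}/{marker}": _dist_to_dict(d)
            for (phen, marker), d in sorted(config.under2_marker_dists.items())
        },
    }
    return out


def _dists_from_dict(d: dict) -> dict:
    out = {}
    for key, dd in d.items():
        phen, marker = key.split("/", 1)
        out[(phen, marker)] = MarkerDistribution(**dd)
    return out


def config_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    if "marker_dists" in data:
        data["marker_dists"] = _dists_from_dict(data["marker_dists"])
    if "under2_marker_dists" in data:
        data["under2_marker_dists"] = _dists_from_dict(data["under2_marker_dists"])
    if "nonresponder_phenotypes" in data:
        data["nonresponder_phenotypes"] = tuple(data["nonresponder_phenotypes"])
    return CohortConfig(**data)


def load_config(path) -> CohortConfig:
    """Load a CohortConfig from a JSON or YAML key-value file."""
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return config_from_dict(data)


def save_config(config: CohortConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)
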