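# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, the numerical conventions, and the design choices made where the
problem left the design genuinely open.

## Diagnostic-accuracy model

All analyses compare a continuous marker X against a binary reference
outcome D ∈ {allergic, tolerant} determined by oral food challenge (OFC).
A subject is test-positive iff X ≥ c. This "≥" convention is forced by the
behaviour of published accuracy tables at a 0 mm skin-prick cutoff
(Se 100%, Sp 0%: every wheal, including 0 mm, is positive) and is carried
consistently through ROC construction, cutoff derivation and triage.

**ROC and AUC.** Candidate thresholds are the sorted unique observed values
plus a sentinel one reporting-resolution unit above the maximum (1 mm for
wheals, 0.01 for sIgE and BAT indices), so the curve always contains the
everyone-positive point (Se 1, Sp 0) and the nobody-positive point
(Se 0, Sp 1). Sensitivity and specificity at each threshold are exact
fractions of integer counts; the AUC is the trapezoidal integral over
(1 − Sp, Se) accumulated in integer arithmetic and reduced once, so it is
an exact rational. With observed-value thresholds the trapezoid rule is
algebraically identical to the tie-aware pair-counting probability
P(X_D > X_T) + ½ P(X_D = X_T); the package implements both routes
independently and the test suite asserts exact equality on randomized
inputs.

**Cutoffs.** Three operating points are derived per marker:

* *Youden-optimal*: the candidate threshold maximizing J = Se + Sp − 1.
  Ties break toward higher specificity and then the lower threshold —
  at equal J this prefers the operating point with fewer challenge
  referrals. The tie-break matters only on tied data and is documented
  rather than load-bearing.
* *100% sensitivity (rule-out)*: the largest threshold with Se = 1, which
  under the ≥ convention is exactly the minimum diseased value.
* *100% specificity (rule-in)*: the smallest observed value strictly above
  every non-diseased value; when no observed value qualifies (complete
  overlap at the top), the sentinel max + 1 resolution unit is used, which
  yields Se 0 / Sp 1 — matching the printed convention of rule-in rows
  with TP/FP = 0/0 at a cutoff above all observations.

**Summaries.** Se, Sp, PPV, NPV, accuracy and balanced accuracy
(Se + Sp)/2 are exact `Fraction`s. A metric whose denominator is zero is
the explicit sentinel "undefined", propagated through balanced accuracy and
rendered as an em-dash; it is never silently 0 or NaN. Percent formatting
rounds half-up (7/8 → 88%), which is the convention required to reproduce
published table cells. The balanced-accuracy column corresponds numerically
to the "AUC" column that accuracy tables print per dichotomized cutoff; the
package names it for what it computes rather than asserting the original
formula. Missing marker values are deleted pairwise and the effective n is
reported alongside every table.

**Two-cutoff triage.** Given a rule-out cutoff c⁻ and rule-in cutoff c⁺
(c⁻ ≤ c⁺): X < c⁻ → tolerant zone, X ≥ c⁺ → allergic zone, otherwise
equivocal → refer to OFC. A subject exactly at c⁻ is equivocal, because the
≥ convention makes the minimum diseased value test-positive. Strategy
accuracy counts equivocal subjects as correctly classified (the OFC
resolves them); with in-sample c⁻ = se100 and c⁺ = sp100 the tolerant zone
contains no allergic subject and the allergic zone no tolerant one, so the
strategy accuracy is 100% by construction. Because that result is
definitional, the package also reports the accuracy restricted to the
confidently-labelled zones and, for out-of-sample cutoffs, the counts of
false negatives in the tolerant zone and false positives in the allergic
zone — the clinically critical errors — explicitly.

## Group comparisons and internal validation

Continuous variables are compared with a Mann–Whitney U test: U is computed
by tie-aware pair counting (which makes U/(n₁n₀) exactly the pair-counting
AUC, an identity the tests assert), with an exact two-sided p by full
enumeration of label assignments when both groups have ≤ 8 observations and
a normal approximation with tie and continuity corrections otherwise.
Categorical variables use Pearson chi-square (no continuity correction),
with Fisher's exact test for 2×2 tables when an expected cell is below 5; a
zero margin returns p = 1 with a warning. Fisher p-values are delegated to
scipy's hypergeometric implementation; the test suite verifies them against
direct enumeration of all tables with fixed margins. Quantiles use the
weighted-average-at-p(n+1) definition throughout. No multiplicity
adjustment is applied.

Internal validation is a stratified nonparametric bootstrap: resampling
with replacement within each outcome class (class sizes preserved),
B = 2000 resamples by default, percentile 95% CIs, fully determined by one
seed. Any metric that involves cutoff selection re-derives the cutoffs
inside each resample, so the resampled distribution reflects the whole
selection procedure rather than a frozen cutoff (no leakage). If the metric
is undefined on more than half of the resamples the report fails loudly
with the failure count. The published description of the resampling scheme
is not specific enough to pin an algorithm, so this standard scheme is a
documented package choice. The test suite checks, in a 200-replicate
simulation at cohort size 150, that the percentile CI for the AUC covers
the generator's analytic AUC at approximately the nominal 95% rate.

## Synthetic-cohort generator

The generator emulates a pediatric milk-allergy diagnostic cohort in which
every child has a baked-milk (BM) OFC and only BM-tolerant children are
offered a fresh-milk (FM) OFC. It exists so that every downstream stage is
testable without patient-level data; it defines the study conditions for
all stochastic tests.

**Phenotypes and outcomes.** A latent phenotype drives everything:
allergic-to-all (15%), BM-tolerant/FM-allergic (37%), tolerant-to-all
(48%). These defaults reproduce a cohort in which 85% tolerate BM and ~56%
of those also tolerate FM. The BM outcome is allergic iff the phenotype is
allergic-to-all; the FM outcome is defined only for BM-tolerant subjects
and only with probability 113/127 (the observed FM-challenge completion
rate), otherwise missing. 17% of subjects are under two years of age; age
is drawn from one log-normal (median 4 y, quartiles 2.3/7.6 y) truncated on
either side of 2 years by inverse-CDF so the split costs a single draw.

**Markers.** Each (phenotype, marker) pair has a left-censored log-normal
distribution calibrated to a printed "median (q1; q3)" summary:
μ = ln(median), σ = ln(q3/q1)/(2·z₀.₇₅). This matches the median exactly
and the quartile ratio by construction; printed summaries that are
asymmetric on the log scale are therefore matched approximately — the
log-normal family is the simplest one consistent with strictly positive,
right-skewed clinical summaries, and no two-parameter family can match all
three numbers of an asymmetric triple. When the printed q1 sits at the
reporting floor (e.g. "0.85 (0; 3.42)"), a point mass of 0.26 (just above
one quartile) is placed at the floor and μ, σ solve the median and q3
equations of the censored mixture exactly. Floors: 0 mm for wheals
(rounded to integer millimetres), 0.01 kU_A/L for sIgE, 0 for %CD63 (also
capped at 100); stimulation indices are uncensored. Continuous markers are
reported on a 0.001 grid, which keeps CSV round-trips exact. The
intermediate phenotype borrows the FM-allergic group's summaries — a
documented approximation, since that printed group is a mixture dominated
by the intermediate phenotype. The anti-IgE positive control (median 35%
CD63+, quartiles 20/55) is phenotype-independent and invented, chosen well
above the 5% non-responder threshold.

**Non-responders.** A configurable cohort-level fraction (default 4.7%)
has non-responder basophils: %CD63+ below 5% to both anti-IgE and allergen,
stimulation indices near background. By default they are drawn only from
the tolerant-to-all phenotype (matching the observation that all
non-responders in the reference cohort were BM-tolerant); the per-subject
flag probability is scaled by the eligible phenotype mass so the cohort
rate matches the configured one. `flag_nonresponders` re-derives the flag
from measured values (below-threshold anti-IgE *and* all present allergen
%CD63 markers) and lists subjects with no relevant markers in a warnings
report without touching their flag.

**Determinism.** All sampling flows from one `numpy` Generator seeded with
the single config seed, strictly sequentially per subject in documented
field order (phenotype, age group, age, FM completion, non-responder flag,
then per marker: missingness, floor mass, normal variate, then
non-responder overrides). Equal seeds give identical cohorts byte-for-byte.

**What the generator does not emulate.** Between-marker correlation within
a subject (markers are drawn independently given the phenotype), age
dependence of marker levels (available as per-age-group overrides but off
by default), assay drift between the BM and FM visits, and any relation
between marker missingness and severity. Consequently, passing tests
demonstrate the correctness of the *analysis machinery* and the
calibration of the marginal distributions — not the joint behaviour of
real biomarker panels; multi-marker results on synthetic cohorts should
not be read as clinical estimates.

## Problem sizes used by the test suite

Deterministic identities are tested exhaustively on small randomized inputs
(samples up to 100 per class for the AUC identity; enumeration regimes up
to n = 8 per group). Stochastic checks use cohorts of 10000 per phenotype
for calibration recovery, 20000 for the closed-form AUC comparison
(Φ((μ₁−μ₀)/√(σ₀²+σ₁²)) for two log-normals), 100 cohorts of 60 for the
strategy-accuracy property, and 200 replicates of 150 subjects with 300
bootstrap resamples for CI coverage. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping a full run in
well under a minute per module.

## Known limitations

* The log-normal calibration cannot reproduce log-asymmetric printed
  quartile triples exactly (see above); calibration-recovery tests compare
  against the configured distribution's own quantiles.
* Exact Mann–Whitney enumeration is limited to both groups ≤ 8; beyond
  that the corrected normal approximation is used (tie-corrected,
  continuity-corrected), as in standard statistical software.
* Fisher's exact test is 2×2 only; larger categorical tables fall back to
  chi-square.
* The single-marker Model/Results interface analyses one marker and one
  endpoint at a time; combining markers (e.g. sequential testing) is out
  of scope.
* Confidence intervals come only from the bootstrap; no asymptotic CIs
  for AUC or predictive values are provided, and predictive values are not
  prevalence-adjusted.
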