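import math

import numpy as np
import pytest
from scipy.stats import norm

from milkdx import (
    CohortConfig,
    MarkerDistribution,
    SubjectRecord,
    analytic_auc_lognormal,
    auc_pair_oracle,
    default_marker_dists,
    derived_spt_markers,
    dist_from_summary,
    flag_nonresponders,
    generate_cohort,
    lognormal_params_from_quartiles,
    read_cohort,
    write_cohort,
)
from milkdx.cohort import ALLERGIC_ALL, MARKER_NAMES, TOLERANT_ALL
from milkdx.errors import (
    ConfigurationError,
    InvalidInputError,
    SchemaError,
    UnsupportedCaseError,
)


class TestLognormalCalibration:
    def test_degenerate_quartiles(self):
        mu, sigma = lognormal_params_from_quartiles(3.0, 3.0, 3.0)
        assert mu == pytest.approx(math.log(3.0))
        assert sigma == 0

    def test_log_symmetric_quartiles(self):
        mu, sigma = lognormal_params_from_quartiles(1.0, 1 / math.e, math.e)
        assert mu == pytest.approx(0.0)
        assert sigma == pytest.approx(2 / 1.34898, rel=1e-4)

    def test_roundtrip_against_fitted_quantiles(self):
        # activation summary 24.99 (16.70; 36.28): median is matched exactly
        # and the quartile ratio is preserved by construction
        mu, sigma = lognormal_params_from_quartiles(24.99, 16.70, 36.28)
        assert mu == pytest.approx(3.2185, abs=1e-4)
        assert sigma == pytest.approx(0.5752, abs=1e-3)
        z = norm.ppf(0.75)
        assert math.exp(mu) == pytest.approx(24.99)
        q1, q3 = math.exp(mu - sigma * z), math.exp(mu + sigma * z)
        assert q3 / q1 == pytest.approx(36.28 / 16.70)

    def test_invalid_quartiles_rejected(self):
        with pytest.raises(InvalidInputError):
            lognormal_params_from_quartiles(1.0, 2.0, 3.0)
        with pytest.raises(InvalidInputError):
            lognormal_params_from_quartiles(1.0, 0.0, 3.0)

    def test_floored_summary_reproduces_median_and_q3(self):
        # printed q1 at the floor: remaining two quantiles solved exactly
        d = dist_from_summary(0.85, 0.0, 3.42, floor=0.0)
        assert d.zero_mass > 0.25
        assert d.quantile(0.5) == pytest.approx(0.85, rel=1e-9)
        assert d.quantile(0.75) == pytest.approx(3.42, rel=1e-9)
        assert d.quantile(0.25) == 0.0


class TestAnalyticAuc:
    def test_identical_distributions(self):
        d = MarkerDistribution(mu=1.0, sigma=0.5)
        assert analytic_auc_lognormal(d, d) == 0.5

    def test_standard_normal_shift(self):
        d0 = MarkerDistribution(mu=0.0, sigma=1.0)
        d1 = MarkerDistribution(mu=math.sqrt(2), sigma=1.0)
        assert analytic_auc_lognormal(d0, d1) == pytest.approx(norm.cdf(1.0))

    def test_infinite_separation_limit(self):
        d0 = MarkerDistribution(mu=0.0, sigma=1.0)
        d1 = MarkerDistribution(mu=60.0, sigma=1.0)
        assert analytic_auc_lognormal(d0, d1) == pytest.approx(1.0)

    def test_point_mass_unsupported(self):
        d0 = MarkerDistribution(mu=0.0, sigma=1.0, zero_mass=0.2)
        with pytest.raises(UnsupportedCaseError):
            analytic_auc_lognormal(d0, d0)


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n=0, seed=1)) == []

    def test_seed_determinism(self):
        cfg = CohortConfig(n=50, seed=42)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n=50, seed=1))
        b = generate_cohort(CohortConfig(n=50, seed=2))
        assert a != b

    def test_outcome_proportions_at_large_n(self):
        subs = generate_cohort(CohortConfig(n=20000, seed=5))
        bm_tol = np.mean([s.bm_outcome == "tolerant" for s in subs])
        assert abs(bm_tol - 0.85) < 0.015
        fm = [s.fm_outcome for s in subs if s.fm_outcome in ("allergic", "tolerant")]
        fm_tol = np.mean([o == "tolerant" for o in fm])
        assert abs(fm_tol - 0.48 / 0.85) < 0.015

    def test_structural_invariants(self, default_cohort):
        for s in default_cohort:
            if s.fm_outcome in ("allergic", "tolerant"):
                assert s.bm_outcome == "tolerant"
            for m in ("spt_milk_extract_mm", "spt_fresh_milk_mm", "spt_baked_milk_mm"):
                v = s.marker(m)
                assert v is None or (v >= 0 and v == int(v))
            for m in ("bat_me_cd63_pct", "bat_bm_cd63_pct", "bat_antiige_cd63_pct"):
                v = s.marker(m)
                assert v is None or 0 <= v <= 100
            for m in ("bat_me_si_cd203c", "bat_bm_si_cd203c"):
                v = s.marker(m)
                assert v is None or v > 0

    def test_nonresponders_only_in_tolerant_phenotype(self, default_cohort):
        for s in default_cohort:
            if s.basophil_nonresponder:
                assert s.phenotype == TOLERANT_ALL
                assert s.marker("bat_antiige_cd63_pct") < 5

    def test_missing_distribution_names_pair(self):
        dists = default_marker_dists()
        del dists[(ALLERGIC_ALL, "sige_bosd5")]
        cfg = CohortConfig(n=30, seed=1, marker_dists=dists)
        with pytest.raises(ConfigurationError, match="sige_bosd5"):
            generate_cohort(cfg)

    def test_phenotype_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(prop_allergic_all=0.5, prop_bm_tolerant_fm_allergic=0.5,
                         prop_tolerant_all=0.5)

    def test_marker_missingness_rate_applied(self):
        subs = generate_cohort(CohortConfig(n=2000, seed=9, marker_missing_rate=0.1))
        miss = np.mean([s.marker("sige_cows_milk") is None for s in subs])
        assert 0.07 < miss < 0.13


class TestCalibrationRecovery:
    def test_empirical_auc_matches_closed_form_at_20000(self):
        """Generated marker draws reproduce the analytic log-normal AUC."""
        cfg = CohortConfig(
            n=20000,
            seed=13,
            prop_allergic_all=0.15,
            prop_bm_tolerant_fm_allergic=0.0,
            prop_tolerant_all=0.85,
            nonresponder_rate=0.0,
        )
        subs = generate_cohort(cfg)
        marker = "bat_bm_si_cd203c"
        vals = [s.marker(marker) for s in subs]
        outs = [s.bm_outcome for s in subs]
        expected = analytic_auc_lognormal(
            cfg.marker_dists[(TOLERANT_ALL, marker)],
            cfg.marker_dists[(ALLERGIC_ALL, marker)],
        )
        assert abs(float(auc_pair_oracle(vals, outs)) - expected) < 0.02

    def test_sample_quartiles_recover_configured_distribution(self):
        """With 10000 subjects per phenotype, sample median/quartiles of
        smooth markers land within 10% of the configured distribution's
        analytic quantiles (heavily floored or integer-rounded markers are
        dominated by their point mass and are checked structurally instead)."""
        from milkdx.stats import median_iqr

        dists = default_marker_dists()
        checked = 0
        for i, phen in enumerate((ALLERGIC_ALL, "bm_tolerant_fm_allergic", TOLERANT_ALL)):
            cfg = CohortConfig(
                n=10000,
                seed=100 + i,
                prop_allergic_all=1.0 if phen == ALLERGIC_ALL else 0.0,
                prop_bm_tolerant_fm_allergic=1.0 if phen == "bm_tolerant_fm_allergic" else 0.0,
                prop_tolerant_all=1.0 if phen == TOLERANT_ALL else 0.0,
                nonresponder_rate=0.0,
            )
            subs = generate_cohort(cfg)
            for marker in MARKER_NAMES:
                d = dists[(phen, marker)]
                if d.rounding != "none" or d.floor_mass() > 0.25:
                    continue
                vals = [s.marker(marker) for s in subs if s.marker(marker) is not None]
                med, q1, q3 = median_iqr(vals)
                for got, p in ((med, 0.5), (q1, 0.25), (q3, 0.75)):
                    want = d.quantile(p)
                    assert got == pytest.approx(want, rel=0.10), (phen, marker, p)
                checked += 1
        assert checked >= 10

    def test_nonresponder_rate_within_99pct_binomial_interval(self, large_cohort):
        from scipy.stats import binom

        n = len(large_cohort)
        k = sum(s.basophil_nonresponder for s in large_cohort)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.047)
        assert lo <= k <= hi


class TestFlagNonresponders:
    def _subject(self, anti, me, bm, flag=False):
        markers = {
            "bat_antiige_cd63_pct": anti,
            "bat_me_cd63_pct": me,
            "bat_bm_cd63_pct": bm,
        }
        return SubjectRecord(
            subject_id="X", age_years=4.0, bm_outcome="tolerant",
            fm_outcome="missing", phenotype=None, markers=markers,
            basophil_nonresponder=flag,
        )

    def test_low_everywhere_is_nonresponder(self):
        out = flag_nonresponders([self._subject(3.0, 2.0, 1.0)])
        assert out[0].basophil_nonresponder

    def test_responsive_anti_ige_is_responder(self):
        out = flag_nonresponders([self._subject(30.0, 2.0, 1.0)])
        assert not out[0].basophil_nonresponder

    def test_any_allergen_response_is_responder(self):
        out = flag_nonresponders([self._subject(3.0, 2.0, 8.0)])
        assert not out[0].basophil_nonresponder

    def test_all_markers_missing_keeps_flag_and_warns(self):
        warn = []
        out = flag_nonresponders(
            [self._subject(None, None, None, flag=True)], warnings_out=warn
        )
        assert out[0].basophil_nonresponder
        assert warn == ["X"]

    def test_engineered_rate_rounds_to_five_percent(self):
        subjects = [self._subject(3.0, 2.0, 1.0)] * 7 + [self._subject(40.0, 2.0, 1.0)] * 142
        out = flag_nonresponders(subjects)
        rate = sum(s.basophil_nonresponder for s in out) / len(out)
        assert round(100 * rate) == 5


class TestDerivedSptMarkers:
    def _subject(self, cme, fm):
        return SubjectRecord(
            subject_id="Y", age_years=4.0, bm_outcome="tolerant",
            fm_outcome="missing", phenotype=None,
            markers={"spt_milk_extract_mm": cme, "spt_fresh_milk_mm": fm},
        )

    @pytest.mark.parametrize(
        "cme, fm, diff, ratio",
        [(2, 4, 2, 0.5), (3, 3, 0, 1.0), (3, 0, -3, None)],
    )
    def test_examples(self, cme, fm, diff, ratio):
        assert derived_spt_markers(self._subject(cme, fm)) == (diff, ratio)

    def test_missing_marker_gives_missing_results(self):
        assert derived_spt_markers(self._subject(None, 4)) == (None, None)


class TestCohortIO:
    def test_roundtrip_identity(self, tmp_path, default_cohort):
        path = tmp_path / "cohort.csv"
        subjects = default_cohort[:100]
        write_cohort(subjects, path)
        back = read_cohort(path)
        assert back == list(subjects)

    def test_empty_fm_outcome_is_missing(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("subject_id,bm_outcome,fm_outcome\nS1,tolerant,\n")
        subs = read_cohort(path)
        assert subs[0].fm_outcome == "missing"

    def test_fm_outcome_without_bm_tolerance_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("subject_id,bm_outcome,fm_outcome\nS1,allergic,tolerant\n")
        with pytest.raises(SchemaError, match="fresh-milk"):
            read_cohort(path)

    def test_missing_mandatory_columns_listed(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("age_years\n4\n")
        with pytest.raises(SchemaError, match="subject_id"):
            read_cohort(path)

    def test_malformed_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "subject_id,bm_outcome,sige_cows_milk\nS1,tolerant,1.5\nS2,tolerant,oops\n"
        )
        with pytest.raises(SchemaError, match="row 3"):
            read_cohort(path)

    def test_config_roundtrip(self, tmp_path):
        from milkdx.cohort import load_config, save_config

        cfg = CohortConfig(n=25, seed=99, marker_missing_rate=0.05)
        path = tmp_path / "cfg.json"
        save_config(cfg, path)
        back = load_config(path)
        assert back == cfg
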