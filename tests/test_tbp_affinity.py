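"""The three-stage TBP binding model: terms, estimates and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tatascan import (
    CalibrationError,
    ModelCoefficients,
    PromoterSequence,
    TataPwm,
    bend_term,
    calibrate_coefficients,
    default_calibration,
    default_pwm,
    estimate_affinity,
    pwm_site_score,
    slide_term,
    worked_examples,
)
from tatascan.tbp_affinity import _bend_table, _slide_table, best_site

BASES = "ACGT"

REFERENCE_COEF = ModelCoefficients(
    intercept=16.13, w_slide=-1.0, w_stop=0.25, w_bend=0.5
)


class TestPwm:
    def test_consensus_scores_maximum(self):
        pwm = default_pwm()
        assert pwm_site_score(pwm.consensus, pwm) == pytest.approx(pwm.max_score)

    @given(st.text(alphabet=BASES, min_size=15, max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_score_equals_naive_per_position_sum(self, window):
        pwm = default_pwm()
        naive = sum(
            pwm.weights[i][BASES.index(b)] for i, b in enumerate(window)
        )
        assert pwm_site_score(window, pwm) == pytest.approx(naive)

    def test_width_mismatch_and_bad_base(self):
        pwm = default_pwm()
        with pytest.raises(ValueError):
            pwm_site_score("ACGT", pwm)
        with pytest.raises(ValueError):
            pwm_site_score("N" * pwm.width, pwm)

    def test_degenerate_row_rejected(self):
        weights = np.zeros((15, 4))
        weights[0] = [1, 2, 3, 4]  # all other rows degenerate
        with pytest.raises(ValueError, match="degenerate"):
            TataPwm(weights=weights)


class TestTerms:
    def test_terms_are_pure_functions(self):
        seq = "TGCTTTGGATATAAATCCAGG"
        assert slide_term(seq) == slide_term(seq)
        assert bend_term(seq[:15]) == bend_term(seq[:15])

    def test_ta_rich_window_bends_more_than_gc_rich(self):
        assert bend_term("TATATATATATATAT") > bend_term("GCGCGCGCGCGCGCG")

    @given(st.text(alphabet=BASES, min_size=2, max_size=90))
    @settings(max_examples=100, deadline=None)
    def test_terms_equal_naive_table_lookup(self, seq):
        slide_tab, bend_tab = _slide_table(), _bend_table()
        steps = [seq[i : i + 2] for i in range(len(seq) - 1)]
        assert slide_term(seq) == pytest.approx(-np.mean([slide_tab[s] for s in steps]))
        assert bend_term(seq) == pytest.approx(sum(bend_tab[s] for s in steps))

    def test_too_short(self):
        with pytest.raises(ValueError):
            slide_term("A")


class TestEstimate:
    def test_consensus_box_beats_homopolymer(self):
        pwm = default_pwm()
        n = 90
        boxed = "G" * 40 + pwm.consensus + "G" * (n - 40 - pwm.width)
        est_box = estimate_affinity(
            PromoterSequence("G", "T1", boxed), coef=REFERENCE_COEF
        )
        est_gg = estimate_affinity(
            PromoterSequence("G", "T2", "G" * n), coef=REFERENCE_COEF
        )
        assert est_box.kd_nM < est_gg.kd_nM

    def test_kd_and_minus_ln_kd_consistent(self, crp_promoter):
        est = estimate_affinity(crp_promoter)
        assert abs(est.minus_ln_kd + math.log(est.kd_nM * 1e-9)) < 1e-9

    def test_best_site_inside_promoter(self, crp_promoter):
        est = estimate_affinity(crp_promoter)
        assert -crp_promoter.length <= est.best_site_start <= -default_pwm().width
        assert est.best_site_sequence in crp_promoter.sequence

    def test_promoter_shorter_than_pwm(self):
        with pytest.raises(ValueError):
            estimate_affinity(PromoterSequence("G", "T", "ACGTACGT"))

    def test_relative_se_in_published_band(self, crp_promoter, ser_promoter):
        """The default relative-SE setting must land in the SE/Kd band of
        the six published estimates (0.07..0.11)."""
        published = [(2.26, 0.23), (7.64, 0.76), (6.19, 0.62),
                     (10.21, 0.92), (7.27, 0.51), (8.53, 0.77)]
        for kd, se in published:
            assert 0.07 <= se / kd <= 0.11
        for p in (crp_promoter, ser_promoter):
            est = estimate_affinity(p)
            assert 0.07 <= est.se_nM / est.kd_nM <= 0.11

    @given(st.text(alphabet=BASES, min_size=20, max_size=90), st.data())
    @settings(max_examples=60, deadline=None)
    def test_best_site_is_global_max(self, seq, data):
        """The reported estimate corresponds to the minimal-Kd window: no
        other window achieves a larger combined site value."""
        from tatascan.tbp_affinity import window_profiles

        p = PromoterSequence("G", "T", seq)
        pwm = default_pwm()
        best, score, bend = best_site(p, pwm, REFERENCE_COEF)
        scores, bends, valid = window_profiles(p, pwm)
        values = REFERENCE_COEF.w_stop * scores + REFERENCE_COEF.w_bend * bends
        i = data.draw(st.integers(0, len(values) - 1))
        assert values[best] >= values[i] - 1e-12

    def test_substitution_away_from_best_site_leaves_it_unchanged(self):
        """Lowering the score of a remote window never moves the best site."""
        pwm = default_pwm()
        seq = "G" * 30 + pwm.consensus + "G" * 30 + "TATAA" + "G" * 10
        p = PromoterSequence("G", "T", seq)
        before = estimate_affinity(p, coef=REFERENCE_COEF)
        # degrade the remote TATAA remnant, far downstream of the best site
        mutated = seq[:78] + "C" + seq[79:]
        after = estimate_affinity(PromoterSequence("G", "T", mutated), coef=REFERENCE_COEF)
        assert after.best_site_start == before.best_site_start

    def test_fixed_site_mode(self):
        """Pinning the evaluation to the scan's own best window reproduces
        the scan; pinning to any other window cannot yield a lower Kd."""
        pwm = default_pwm()
        seq = "G" * 30 + pwm.consensus + "G" * 45
        p = PromoterSequence("G", "T", seq)
        scanned = estimate_affinity(p, coef=REFERENCE_COEF)
        pinned = estimate_affinity(
            p, coef=REFERENCE_COEF, fixed_site=scanned.best_site_start
        )
        assert pinned.kd_nM == pytest.approx(scanned.kd_nM)
        elsewhere = estimate_affinity(p, coef=REFERENCE_COEF, fixed_site=-90)
        assert elsewhere.kd_nM >= scanned.kd_nM
        with pytest.raises(ValueError):
            estimate_affinity(p, coef=REFERENCE_COEF, fixed_site=-5)

    def test_monotone_in_stop_score(self):
        """Holding slide and bend fixed, a higher best-window score never
        increases Kd (w_stop >= 0 by construction)."""
        coef = default_calibration().coefficients
        assert coef.w_stop >= 0 and coef.w_bend >= 0
        base = dict(intercept=coef.intercept, w_slide=coef.w_slide,
                    w_stop=coef.w_stop, w_bend=coef.w_bend)
        lo = base["intercept"] + base["w_slide"] * 1.3 + base["w_stop"] * 2.0 + base["w_bend"] * 6.0
        hi = base["intercept"] + base["w_slide"] * 1.3 + base["w_stop"] * 5.0 + base["w_bend"] * 6.0
        assert math.exp(-hi) <= math.exp(-lo)


class TestCalibration:
    def test_recovers_known_coefficients_from_synthetic_truth(self):
        """Examples generated under known coefficients are fitted back to
        those coefficients (self-consistency)."""
        rng = np.random.default_rng(5)
        pwm = default_pwm()
        seqs = []
        for k in range(8):
            seq = "".join(rng.choice(list(BASES), size=60))
            if k % 2:  # vary site strength so the design has full rank
                i = int(rng.integers(0, 60 - pwm.width))
                seq = seq[:i] + pwm.consensus + seq[i + pwm.width :]
            seqs.append(seq)
        examples = []
        for seq in seqs:
            est = estimate_affinity(
                PromoterSequence("G", "T", seq), coef=REFERENCE_COEF
            )
            examples.append((seq, est.kd_nM))
        fit = calibrate_coefficients(examples)
        assert fit.coefficients.intercept == pytest.approx(REFERENCE_COEF.intercept, abs=1e-6)
        assert fit.coefficients.w_slide == pytest.approx(REFERENCE_COEF.w_slide, abs=1e-6)
        assert fit.coefficients.w_stop == pytest.approx(REFERENCE_COEF.w_stop, abs=1e-6)
        assert fit.coefficients.w_bend == pytest.approx(REFERENCE_COEF.w_bend, abs=1e-6)
        assert np.max(np.abs(fit.residuals_ln)) < 1e-8

    def test_two_examples_is_underdetermined(self):
        with pytest.raises(CalibrationError):
            calibrate_coefficients([("A" * 30, 5.0), ("C" * 30, 6.0)])

    def test_unvaried_examples_are_rank_deficient(self):
        with pytest.raises(CalibrationError, match="rank-deficient"):
            calibrate_coefficients([("ACGT" * 8, 5.0)] * 5)

    def test_default_calibration_runs_on_worked_examples(self):
        """The shipped worked-example table calibrates without error and the
        fit reproduces the observed affinity ordering within each promoter
        (ancestral CRP strongest; ancestral SERPINF1 weakest)."""
        cal = default_calibration()
        df = worked_examples()
        assert len(df) == 6
        kd = list(cal.fitted_kd_nM)
        assert kd[0] < kd[1] and kd[0] < kd[2]  # CRP ancestral binds tightest
        assert kd[3] > kd[4] and kd[3] > kd[5]  # SERPINF1 ancestral weakest
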