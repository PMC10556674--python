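"""Two-point DLW engine: arithmetic oracles and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietval import dlw_engine as de
from dietval import synthetic_cohort as sc
from dietval.errors import DomainError, ValidationError


class TestEliminationConstant:
    @pytest.mark.parametrize("e0, e1, days, expected", [
        (500.0, 250.0, 7.0, math.log(2) / 7.0),   # half-life case
        (600.0, 600.0, 7.0, 0.0),                 # no elimination
        (600.0, 230.9, 7.0, math.log(600.0 / 230.9) / 7.0),
    ])
    def test_known_values(self, e0, e1, days, expected):
        assert de.elimination_constant(e0, e1, days) == pytest.approx(expected)

    def test_hand_value(self):
        assert de.elimination_constant(600.0, 230.9, 7.0) == pytest.approx(0.13642, abs=1e-5)

    def test_below_background_rejected(self):
        with pytest.raises(DomainError):
            de.elimination_constant(-5.0, 250.0, 7.0)

    def test_rising_enrichment_gives_negative_rate(self):
        # protocol violation is surfaced as a negative rate, not an exception
        assert de.elimination_constant(100.0, 200.0, 7.0) < 0


class TestDilutionSpace:
    def test_ratio_definition(self):
        assert de.dilution_space(1.0, 100_000.0, 0.0, 50.0, 0.0) == pytest.approx(2000.0)

    def test_linearity_in_dose(self):
        one = de.dilution_space(1.0, 100_000.0, 0.0, 50.0, 0.0)
        two = de.dilution_space(2.0, 100_000.0, 0.0, 50.0, 0.0)
        assert two == pytest.approx(2 * one)

    def test_unit_conversion_to_kg(self):
        n_mol = de.dilution_space(0.5, 4000.0, 0.0, 1.0, 0.0)
        assert n_mol == pytest.approx(2000.0)
        assert n_mol * 18.02 / 1000.0 == pytest.approx(36.04)

    def test_no_enrichment_rejected(self):
        with pytest.raises(DomainError):
            de.dilution_space(1.0, 100_000.0, 0.0, 5.0, 5.0)


class TestBodyWater:
    def test_exact_inversion(self):
        x = 33.0
        assert de.tbw_from_spaces(1.041 * x, 1.007 * x) == pytest.approx(x)

    def test_hand_value(self):
        assert de.tbw_from_spaces(37.0, 36.2) == pytest.approx(35.7456, abs=1e-3)

    @given(st.floats(20.0, 50.0), st.floats(20.0, 50.0), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_space(self, nd, no, eps):
        base = de.tbw_from_spaces(nd, no)
        assert de.tbw_from_spaces(nd + eps, no) > base
        assert de.tbw_from_spaces(nd, no + eps) > base

    def test_body_composition_hand_value(self):
        comp = de.body_composition(35.7456, 57.8)
        assert comp.ffm_kg == pytest.approx(48.833, abs=1e-3)
        assert comp.fm_kg == pytest.approx(8.967, abs=1e-3)
        assert comp.ffm_kg + comp.fm_kg == pytest.approx(57.8, abs=1e-9)

    def test_zero_fat_boundary(self):
        comp = de.body_composition(0.732 * 60.0, 60.0)
        assert comp.fm_kg == pytest.approx(0.0, abs=1e-9)
        assert not comp.flags

    def test_impossible_hydration_flagged(self):
        comp = de.body_composition(50.0, 55.0)  # FFM = 68.3 > weight
        assert comp.fm_kg < 0
        assert "ffm_exceeds_body_weight" in comp.flags


class TestQC:
    def _kin(self, n_d, n_o, k_o, k_d):
        return de.IsotopeKinetics(k_O=k_o, k_d=k_d, N_O=n_o, N_d=n_d,
                                  N=(n_o + n_d) / 2, elapsed_days=7.0)

    def test_within_observed_ranges(self):
        qc = de.qc_ratios(self._kin(37.0, 36.2, 0.12, 0.10))
        assert qc.dilution_space_ratio == pytest.approx(1.0221, abs=1e-4)
        assert qc.elimination_rate_ratio == pytest.approx(1.2)
        assert qc.passed

    def test_low_dsr_flagged(self):
        qc = de.qc_ratios(self._kin(0.995 * 36.2, 36.2, 0.12, 0.10))
        assert "dsr_below_low" in qc.flags

    @given(st.floats(0.9, 1.2), st.floats(1.0, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_flags_monotone_in_range_width(self, dsr, err):
        """Widening any configured QC range never adds a flag."""
        kin = self._kin(dsr * 36.0, 36.0, err * 0.1, 0.1)
        narrow = de.qc_ratios(kin, de.DLWConfig())
        wide = de.qc_ratios(kin, de.DLWConfig(dsr_low=0.5, dsr_high=2.0,
                                              err_low=0.5, err_high=3.0))
        assert set(wide.flags) <= set(narrow.flags)


class TestEnergyChain:
    def test_rco2_hand_value(self):
        rco2, flags = de.rco2_speakman(1998.0, 0.12, 0.10)
        assert rco2 == pytest.approx(0.4554 * 1998 * (1.007 * 0.12 - 1.043 * 0.10) * 22.26)
        assert rco2 == pytest.approx(335.0, abs=0.1)
        assert not flags

    def test_rco2_zero_crossing_and_linearity(self):
        k_d = 0.10
        k_o = 1.043 * k_d / 1.007
        rco2, _ = de.rco2_speakman(2000.0, k_o, k_d)
        assert rco2 == pytest.approx(0.0, abs=1e-9)
        a, _ = de.rco2_speakman(1000.0, 0.12, 0.10)
        b, _ = de.rco2_speakman(2000.0, 0.12, 0.10)
        assert b == pytest.approx(2 * a)

    def test_negative_rco2_flagged_not_clipped(self):
        rco2, flags = de.rco2_speakman(2000.0, 0.09, 0.10)
        assert rco2 < 0 and "negative_rco2" in flags

    @pytest.mark.parametrize("rco2, rq, expected", [
        (335.0, 0.85, 335.0 * (1.106 + 3.94 / 0.85)),
        (0.0, 0.9, 0.0),
        (100.0, 1.0, 504.6),
    ])
    def test_weir_values(self, rco2, rq, expected):
        assert de.tdee_weir(rco2, rq) == pytest.approx(expected, abs=0.05)

    def test_weir_hand_value(self):
        assert de.tdee_weir(335.0, 0.85) == pytest.approx(1923.3, abs=0.1)

    def test_weir_decreasing_in_rq(self):
        assert de.tdee_weir(300.0, 0.80) > de.tdee_weir(300.0, 0.90)

    def test_weir_rejects_bad_rq(self):
        with pytest.raises(DomainError):
            de.tdee_weir(300.0, 0.0)
        with pytest.raises(DomainError):
            de.tdee_weir(300.0, 1.5)


class TestTwoPoint:
    def test_noise_free_round_trip(self, study, sim_config):
        """With zero measurement noise the engine recovers the generator's truth."""
        cfg = de.DLWConfig(rq=sim_config.rq)
        weights = {p.id: p.weight_start_kg for p in study.participants}
        for truth, row in zip(study.truths, study.isotopes):
            res = de.run_two_point(row, weights[truth.participant_id], cfg)
            assert res.tdee_kcal == pytest.approx(truth.true_tdee, rel=1e-6)
            assert res.body_composition.tbw_kg == pytest.approx(truth.true_tbw_kg, rel=1e-6)
            assert res.qc.dilution_space_ratio == pytest.approx(truth.dsr, rel=1e-9)
            assert res.kinetics.k_O / res.kinetics.k_d == pytest.approx(truth.err, rel=1e-9)
            # unit coherence: TBW(kg) vs the mean pool in mol
            n_kg = (res.kinetics.N_O + res.kinetics.N_d) / 2 * 18.02 / 1000.0
            assert n_kg == pytest.approx(res.kinetics.N * 18.02 / 1000.0, abs=1e-9)

    def test_cohort_tdee_all_positive(self, dlw_results):
        assert len(dlw_results) == 30
        assert all(r.tdee_kcal > 0 for r in dlw_results)
        assert all(r.qc.passed for r in dlw_results)

    def test_missing_sample_named(self, study):
        row = study.isotopes[0]
        row = de.IsotopeSampleRow(**{**row.__dict__, "E_final_d2": float("nan")})
        with pytest.raises(ValidationError, match="E_final_d2"):
            de.run_two_point(row, 60.0)

    def test_plateau_mean_of_same_day_samples(self, study):
        """A two-sample plateau equals its scalar mean."""
        row = study.isotopes[0]
        val = float(row.E_post_o18)
        split = de.IsotopeSampleRow(**{**row.__dict__,
                                       "E_post_o18": [val - 2.0, val + 2.0]})
        w = 60.0
        assert de.run_two_point(split, w).tdee_kcal == pytest.approx(
            de.run_two_point(row, w).tdee_kcal, rel=1e-9)

    def test_tdee_monotone_in_rates(self):
        """TDEE rises with k_O and falls with k_d for a fixed pool."""
        base, _ = de.rco2_speakman(1800.0, 0.12, 0.10)
        up, _ = de.rco2_speakman(1800.0, 0.13, 0.10)
        down, _ = de.rco2_speakman(1800.0, 0.12, 0.11)
        assert up > base > down

    def test_enrichment_noise_keeps_tdee_unbiased(self):
        """2% enrichment noise: recovered cohort TDEE unbiased within 1%."""
        rel_errs = []
        for rep in range(40):
            cfg = sc.SimulationConfig(seed=900 + rep, n_participants=15,
                                      enrichment_noise=0.02)
            _, truths = sc.simulate_cohort(cfg)
            dlw_cfg = de.DLWConfig(rq=cfg.rq)
            for t in truths:
                row = sc.simulate_isotope_kinetics(t, cfg)
                res = de.run_two_point(row, t.true_ffm_kg + t.true_fm_kg, dlw_cfg)
                rel_errs.append(res.tdee_kcal / t.true_tdee - 1.0)
        assert abs(np.mean(rel_errs)) < 0.01
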