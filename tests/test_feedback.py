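"""Golgi feedback: sigmoid, drive terms, fixed point, trials, calibration."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grcsim
from grcsim.feedback import (
    basal_tail_probability,
    calibrate_gain,
    field_drive,
    golgi_active_inputs,
    run_beam_regulation,
    run_trials,
    summarize_trials,
    veto_from_inputs,
)


def hypergeom_tail_oracle(x, contacts, minimum, y):
    """P(>= minimum active) among `contacts` drawn from y fibers, x active.

    Direct summation of the hypergeometric mass function with math.comb.
    """
    total = 0.0
    for j in range(minimum, contacts + 1):
        if j > x or contacts - j > y - x:
            continue
        total += math.comb(x, j) * math.comb(y - x, contacts - j) / math.comb(y, contacts)
    return total


class TestGolgiActiveInputs:
    def test_values(self, anatomy):
        assert golgi_active_inputs(0, anatomy) == 0.0
        assert golgi_active_inputs(1200, anatomy) == pytest.approx(1600 * 1200 / 350000)
        assert golgi_active_inputs(350000, anatomy) == pytest.approx(1600.0)

    def test_negative_rejected(self, anatomy):
        with pytest.raises(ValueError):
            golgi_active_inputs(-1.0, anatomy)


class TestVetoSigmoid:
    def test_floor_saturation_midpoint(self, anatomy, feedback_params):
        fb = feedback_params
        assert veto_from_inputs(3.9, fb, anatomy) == 0.0
        assert veto_from_inputs(0.0, fb, anatomy) == 0.0
        assert veto_from_inputs(16.0, fb, anatomy) == pytest.approx(fb.veto_max)
        assert veto_from_inputs(40.0, fb, anatomy) == pytest.approx(fb.veto_max)
        assert veto_from_inputs(fb.sigmoid_midpoint, fb, anatomy) == pytest.approx(
            fb.veto_max / 2, abs=1e-9
        )

    @given(a=st.floats(min_value=0, max_value=30), b=st.floats(min_value=0, max_value=30))
    def test_monotone(self, a, b):
        anatomy = grcsim.AnatomyParams()
        fb = grcsim.GolgiFeedbackParams()
        lo, hi = sorted((a, b))
        assert veto_from_inputs(lo, fb, anatomy) <= veto_from_inputs(hi, fb, anatomy)


def test_basal_tail_matches_direct_summation(anatomy, feedback_params):
    for x in (0, 3, 4, 12, 30, 80):
        oracle = hypergeom_tail_oracle(
            x, feedback_params.basal_contacts, anatomy.basal_mf_min, anatomy.n_mf_per_field
        )
        assert basal_tail_probability(x, feedback_params, anatomy) == pytest.approx(
            oracle, abs=1e-12
        )


class TestFieldDrive:
    def test_zero_grid(self, anatomy, feedback_params):
        counts = np.zeros((5, 20))
        x = np.zeros((5, 20), dtype=int)  # x < basal_mf_min: basal term vanishes
        assert field_drive(counts, x, 2, 0, feedback_params, anatomy) == 0.0

    def test_degenerate_weights_give_beam_total(self, anatomy, feedback_params, rng):
        fb = feedback_params.model_copy(
            update={"local_weight": 1.0, "neighbor_weight": 0.0, "basal_boost": 0.0}
        )
        counts = rng.uniform(0, 300, size=(5, 20))
        x = rng.integers(3, 31, size=(5, 20))
        for b in (0, 2, 4):
            assert field_drive(counts, x, b, 7, fb, anatomy) == pytest.approx(
                counts[b].sum()
            )

    def test_index_out_of_range(self, anatomy, feedback_params):
        counts = np.zeros((5, 20))
        with pytest.raises(IndexError):
            field_drive(counts, counts.astype(int), 5, 0, feedback_params, anatomy)


class TestBeamRegulation:
    def test_veto_disabled_equals_unregulated(self, anatomy, feedback_params):
        fb = feedback_params.model_copy(update={"veto_max": 0.0})
        x = np.full((5, 20), 18)
        res = run_beam_regulation(x, fb, anatomy)
        np.testing.assert_allclose(res.count_firing, res.count_threshold)
        assert res.converged

    def test_regulated_below_unregulated(self, anatomy, feedback_params, rng):
        x = rng.integers(3, 31, size=(5, 20))
        res = run_beam_regulation(x, feedback_params, anatomy)
        assert np.all(res.count_firing <= res.count_threshold + 1e-9)
        assert res.middle_beam_total <= res.unregulated_totals[res.middle_beam]

    def test_expectation_mode_bit_identical(self, anatomy, feedback_params):
        x = np.full((5, 20), 15)
        a = run_beam_regulation(x, feedback_params, anatomy)
        b = run_beam_regulation(x, feedback_params, anatomy)
        assert np.array_equal(a.count_firing, b.count_firing)
        assert np.array_equal(a.p_veto, b.p_veto)
        assert a.iterations == b.iterations

    @pytest.mark.parametrize("x_range", [(3, 30), (5, 25), (15, 30), (20, 30)])
    def test_converges_on_default_matrix(self, anatomy, feedback_params, x_range):
        table = run_trials(10, feedback_params, anatomy, seed=21, x_range=x_range)
        assert table["converged"].all()
        assert (table["iterations"] <= feedback_params.max_iter).all()

    def test_realization_mode_runs_and_bounds_hold(self, anatomy, feedback_params):
        fb = feedback_params.model_copy(update={"mode": "realization", "max_iter": 15})
        rng = np.random.default_rng(5)
        x = rng.integers(3, 31, size=(5, 20))
        res = run_beam_regulation(x, fb, anatomy, rng=rng)
        assert np.all(res.count_firing >= 0)
        assert np.all(res.count_firing <= anatomy.n_grc_per_field)

    def test_bad_grid_shape(self, anatomy, feedback_params):
        with pytest.raises(ValueError, match="x_grid"):
            run_beam_regulation(np.zeros((2, 2), dtype=int), feedback_params, anatomy)


class TestRunTrials:
    def test_zero_input_range(self, anatomy, feedback_params):
        table = run_trials(1, feedback_params, anatomy, seed=0, x_range=(0, 0))
        assert (table["count_firing"] == 0).all()
        assert (table["count_threshold"] == 0).all()

    def test_tidy_keying(self, anatomy, feedback_params):
        table = run_trials(3, feedback_params, anatomy, seed=1)
        assert len(table) == 3 * anatomy.n_beams * anatomy.fields_per_beam
        assert not table.duplicated(subset=["trial", "beam", "field"]).any()

    def test_unregulated_mean_matches_analytic_expectation(self, anatomy, feedback_params):
        """Mean threshold population agrees with the closed-form expectation.

        With m=3 of n=4 dendrites and no veto, P(fire) = 4p^3 - 3p^4 at
        p = x/100, so the expected beam total is 20 * 8750 * E_x[4p^3 - 3p^4]
        over x ~ U{3..30} (~4305 granule cells).
        """
        xs = np.arange(3, 31)
        p = xs / 100
        expected = 20 * 8750 * np.mean(4 * p**3 - 3 * p**4)
        fb = feedback_params.model_copy(update={"veto_max": 0.0})
        summary = summarize_trials(run_trials(100, fb, anatomy, seed=2), anatomy)
        se = summary["unregulated_total"].std(ddof=1) / 10
        assert abs(summary["unregulated_total"].mean() - expected) < 3 * se

    def test_threshold_two_mean_matches_analytic_expectation(self, anatomy, feedback_params):
        """m=2 threshold population: P(fire) = 1 - (1-p)^4 - 4p(1-p)^3."""
        anatomy2 = anatomy.model_copy(update={"input_threshold": 2})
        fb = feedback_params.model_copy(update={"veto_max": 0.0})
        xs = np.arange(3, 31)
        p = xs / 100
        expected = 20 * 8750 * np.mean(1 - (1 - p) ** 4 - 4 * p * (1 - p) ** 3)
        summary = summarize_trials(run_trials(100, fb, anatomy2, seed=2), anatomy2)
        se = summary["unregulated_total"].std(ddof=1) / 10
        assert abs(summary["unregulated_total"].mean() - expected) < 3 * se


class TestCalibrateGain:
    def test_single_candidate_returned_unchanged(self, anatomy, feedback_params):
        res = calibrate_gain(
            feedback_params,
            anatomy,
            [(5, 25), (15, 30)],
            seed=4,
            veto_max_grid=(feedback_params.veto_max,),
            steepness_grid=(feedback_params.sigmoid_steepness,),
            n_trials=3,
        )
        assert res.params == feedback_params

    def test_beats_weak_feedback(self, anatomy, feedback_params):
        res = calibrate_gain(
            feedback_params,
            anatomy,
            [(5, 25), (15, 30)],
            seed=4,
            veto_max_grid=(0.1, feedback_params.veto_max),
            steepness_grid=(feedback_params.sigmoid_steepness,),
            n_trials=5,
        )
        weak = res.table.loc[res.table["veto_max"] == 0.1, "spread"].iloc[0]
        assert res.params.veto_max != 0.1
        assert res.spread < weak

    def test_empty_grid_rejected(self, anatomy, feedback_params):
        with pytest.raises(ValueError, match="grid"):
            calibrate_gain(
                feedback_params, anatomy, [(5, 25), (15, 30)], seed=0, veto_max_grid=()
            )
        with pytest.raises(ValueError, match="ranges"):
            calibrate_gain(feedback_params, anatomy, [(5, 25)], seed=0)

    def test_high_range_falls_below_mid_range(self, anatomy, feedback_params):
        """Direct basal drive depresses the regulated total at high input."""
        mid = summarize_trials(
            run_trials(40, feedback_params, anatomy, seed=6, x_range=(15, 30)), anatomy
        )["regulated_total"].mean()
        high = summarize_trials(
            run_trials(40, feedback_params, anatomy, seed=6, x_range=(20, 30)), anatomy
        )["regulated_total"].mean()
        assert high < mid
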