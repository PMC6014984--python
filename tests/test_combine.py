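"""Combination rules: worked knockdown examples, ordering and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsensor.combine import (AlignedCurves, SensorInput,
                               align_on_shared_grid, combine,
                               combine_additive, combine_antagonistic,
                               combine_synergistic, fraction_affected,
                               predict_ant_syn, prediction_errors)

GRID = np.array([1.0, 10.0, 100.0])
NEG = np.array([10.0, 100.0, 1000.0])


def curves_from_fa(fas, utrs=None):
    """Build AlignedCurves where input i has constant fraction affected."""
    utrs = utrs or ["three_prime"] * len(fas)
    inputs = tuple(SensorInput(f"in{i}", utr, (1.0 - fa) * NEG)
                   for i, (fa, utr) in enumerate(zip(fas, utrs)))
    return AlignedCurves(GRID, NEG, inputs)


def knockdown(result):
    return 1.0 - result.output / NEG


class TestFractionAffected:
    def test_basic_values(self):
        np.testing.assert_allclose(fraction_affected(NEG, NEG), 0.0)
        np.testing.assert_allclose(fraction_affected(NEG / 2, NEG), 0.5)

    def test_noise_above_control_clamps_to_zero(self):
        np.testing.assert_allclose(fraction_affected(NEG * 1.2, NEG), 0.0)

    def test_near_total_knockdown_clamped(self):
        fa = fraction_affected(NEG * 1e-12, NEG)
        assert np.all(fa <= 1.0 - 1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fraction_affected(NEG[:2], NEG)


class TestWorkedExamples:
    """The two-miRNAs-at-50%-knockdown example and its k-input extensions."""

    def test_two_halves_additive_gives_67_percent(self):
        res = combine_additive(curves_from_fa([0.5, 0.5]))
        np.testing.assert_allclose(knockdown(res), 2.0 / 3.0, rtol=1e-12)

    def test_two_halves_synergistic_gives_75_percent(self):
        res = combine_synergistic(curves_from_fa([0.5, 0.5]))
        np.testing.assert_allclose(knockdown(res), 0.75, rtol=1e-12)

    def test_two_halves_antagonistic_gives_50_percent(self):
        res = combine_antagonistic(curves_from_fa([0.5, 0.5]))
        np.testing.assert_allclose(knockdown(res), 0.5, rtol=1e-12)

    def test_three_halves_additive_gives_75_percent(self):
        res = combine_additive(curves_from_fa([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(knockdown(res), 0.75, rtol=1e-12)

    def test_synergy_of_90_and_50_gives_95_percent(self):
        res = combine_synergistic(curves_from_fa([0.9, 0.5]))
        np.testing.assert_allclose(knockdown(res), 0.95, rtol=1e-12)

    def test_ant_syn_two_per_utr(self):
        # per-UTR minimum fu {0.5, 0.8} -> 0.5 and {0.4, 0.9} -> 0.4
        res = predict_ant_syn(curves_from_fa(
            [0.5, 0.2, 0.6, 0.1],
            utrs=["five_prime", "five_prime", "three_prime", "three_prime"]))
        np.testing.assert_allclose(res.output / NEG, 0.5 * 0.4, rtol=1e-12)


class TestDegeneracies:
    @pytest.mark.parametrize("rule", ["antagonistic", "additive",
                                      "synergistic", "ant_syn"])
    def test_single_input_idempotence(self, rule):
        curves = curves_from_fa([0.37])
        np.testing.assert_allclose(combine(curves, rule).output,
                                   curves.inputs[0].output, rtol=1e-9)

    def test_zero_inputs(self):
        empty = AlignedCurves(GRID, NEG, ())
        np.testing.assert_allclose(combine_antagonistic(empty).output, NEG)
        np.testing.assert_allclose(combine_synergistic(empty).output, NEG)
        np.testing.assert_allclose(combine_additive(empty).output, NEG)

    def test_ant_syn_single_utr_equals_antagonistic(self):
        curves = curves_from_fa([0.3, 0.6, 0.1])
        np.testing.assert_allclose(predict_ant_syn(curves).output,
                                   combine_antagonistic(curves).output)

    def test_ant_syn_one_per_utr_equals_synergistic(self):
        curves = curves_from_fa([0.3, 0.6], utrs=["five_prime", "three_prime"])
        np.testing.assert_allclose(predict_ant_syn(curves).output,
                                   combine_synergistic(curves).output)

    def test_crossing_curves_antagonism_traces_minimum(self):
        a = np.array([2.0, 40.0, 800.0])   # stronger at low bins
        b = np.array([8.0, 40.0, 200.0])   # stronger at high bins
        curves = AlignedCurves(GRID, NEG,
                               (SensorInput("a", "three_prime", a),
                                SensorInput("b", "three_prime", b)))
        np.testing.assert_allclose(combine_antagonistic(curves).output,
                                   np.minimum(a, b))


@st.composite
def random_curve_sets(draw):
    k = draw(st.integers(2, 5))
    fas = [draw(st.lists(st.floats(0.0, 0.99), min_size=3, max_size=3))
           for _ in range(k)]
    utrs = [draw(st.sampled_from(["five_prime", "three_prime"]))
            for _ in range(k)]
    inputs = tuple(SensorInput(f"in{i}", utr,
                               np.clip((1.0 - np.array(fa)) * NEG, 1e-9, None))
                   for i, (fa, utr) in enumerate(zip(fas, utrs)))
    return AlignedCurves(GRID, NEG, inputs)


class TestOrderingInvariants:
    @settings(max_examples=200, deadline=None)
    @given(curves=random_curve_sets())
    def test_rule_ordering_and_bracketing(self, curves):
        ant = combine_antagonistic(curves).output
        add = combine_additive(curves).output
        syn = combine_synergistic(curves).output
        mix = predict_ant_syn(curves).output
        tol = 1e-9 * NEG
        assert np.all(syn <= add + tol)
        assert np.all(add <= ant + tol)
        assert np.all(ant <= NEG + tol)
        assert np.all(syn <= mix + tol)
        assert np.all(mix <= ant + tol)

    @settings(max_examples=50, deadline=None)
    @given(curves=random_curve_sets(), data=st.data())
    def test_permutation_invariance(self, curves, data):
        perm = data.draw(st.permutations(range(len(curves.inputs))))
        shuffled = AlignedCurves(curves.grid, curves.neg,
                                 tuple(curves.inputs[i] for i in perm))
        for rule in ("antagonistic", "additive", "synergistic", "ant_syn"):
            np.testing.assert_allclose(combine(curves, rule).output,
                                       combine(shuffled, rule).output)

    @settings(max_examples=50, deadline=None)
    @given(curves=random_curve_sets(),
           fa_new=st.floats(0.0, 0.99),
           utr_new=st.sampled_from(["five_prime", "three_prime"]))
    def test_adding_input_never_increases_output(self, curves, fa_new,
                                                 utr_new):
        extra = SensorInput("extra", utr_new,
                            np.clip((1.0 - fa_new) * NEG, 1e-9, None))
        grown = AlignedCurves(curves.grid, curves.neg,
                              curves.inputs + (extra,))
        for rule in ("antagonistic", "additive", "synergistic", "ant_syn"):
            before = combine(curves, rule).output
            after = combine(grown, rule).output
            assert np.all(after <= before + 1e-9 * before)


class TestPredictionErrors:
    def test_perfect_prediction(self):
        assert prediction_errors(NEG, NEG) == (1.0, 0.0)

    def test_uniform_factor_two(self):
        mfe, _ = prediction_errors(2.0 * NEG, NEG)
        assert mfe == pytest.approx(2.0)

    def test_max_of_log_ratios(self):
        pred = NEG * np.array([1.0, 2.0, 0.25])
        mfe, mse = prediction_errors(pred, NEG)
        assert mfe == pytest.approx(4.0)
        assert mse == pytest.approx(np.mean(np.log10([1.0, 2.0, 0.25]) ** 2))

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError):
            prediction_errors(NEG[:2], NEG)
        with pytest.raises(ValueError):
            prediction_errors(np.array([]), np.array([]))


class TestGridAlignment:
    def test_intersection_with_warning(self):
        ga = np.array([1.0, 2.0, 4.0, 8.0])
        gb = np.array([2.0, 4.0, 8.0, 16.0])
        with pytest.warns(UserWarning):
            grid, a, b = align_on_shared_grid(ga, ga * 10, gb, gb * 100)
        np.testing.assert_allclose(grid, [2.0, 4.0, 8.0])
        np.testing.assert_allclose(a, [20.0, 40.0, 80.0])
        np.testing.assert_allclose(b, [200.0, 400.0, 800.0])

    def test_disjoint_grids_error(self):
        with pytest.raises(ValueError):
            align_on_shared_grid(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                                 np.array([5.0, 7.0]), np.array([5.0, 7.0]))
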