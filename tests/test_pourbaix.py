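"""Pourbaix curve construction: constant- and variable-slope transforms."""

import numpy as np
import pytest

import phredox as px
from conftest import random_ladder

S = px.nernst_slope_at(298.15)


def _couple(nh_ox=4, np_=2, n=2, q_ox=0):
    ox = px.SpeciesState("ox", n_hydrogens=nh_ox, charge=q_ox)
    red = px.SpeciesState(
        "red", n_hydrogens=nh_ox + np_, charge=q_ox + np_ - n
    )
    return px.RedoxCouple(ox, red)


def dense_g_recurrence(g0, nh0, ladder, c, step=0.01):
    """Independent oracle: the midpoint-hydrogen recurrence applied
    point-by-point on a dense pH grid instead of on breakpoints only.

    The recurrence's grid by definition contains the pKas, so they are
    merged into the uniform 0.01 steps; without them a step straddling a
    pKa would use a single slope where the true curve bends."""
    phs = np.arange(0.0, 14.0 + step / 2, step)
    phs = np.unique(np.concatenate([phs, np.asarray(ladder.in_range())]))
    values = [g0]
    for lo, hi in zip(phs[:-1], phs[1:]):
        nh = px.hydrogens_at_ph(nh0, ladder, 0.5 * (lo + hi))
        values.append(values[-1] + nh * c.nernst_slope * (hi - lo))
    return phs, np.array(values)


class TestGConstantSlope:
    def test_no_hydrogens_no_shift(self, constants):
        assert px.g_constant_slope(-250.0, 0, 7.0, constants) == -250.0

    def test_one_nernst_unit(self, constants):
        assert px.g_constant_slope(0.0, 1, 1.0, constants) == pytest.approx(
            0.0591597, abs=1e-6
        )

    def test_direct_evaluation(self, constants):
        assert px.g_constant_slope(-250.0, 6, 14.0, constants) == pytest.approx(
            -250.0 + 6 * 14 * S, abs=1e-9
        )
        assert px.g_constant_slope(-250.0, 6, 14.0, constants) == pytest.approx(
            -245.0306, abs=1e-4
        )

    def test_out_of_window_ph_rejected(self, constants):
        with pytest.raises(px.PhredoxError):
            px.g_constant_slope(0.0, 1, -0.5, constants)


class TestGVariableSlope:
    def test_no_pkas_degenerates_to_constant_slope(self, constants):
        curve = px.g_variable_slope(-250.0, 6, px.PKaLadder("s"), constants)
        for ph in curve.ph:
            assert curve(ph) == pytest.approx(
                px.g_constant_slope(-250.0, 6, ph, constants), abs=1e-12
            )

    def test_hand_recurrence_single_pka(self, constants):
        # slope 2 H below the pKa at 10, 1 H above it
        curve = px.g_variable_slope(0.0, 2, px.PKaLadder("s", (10.0,)), constants)
        assert curve(10.0) == pytest.approx(2 * 10 * S, abs=1e-9)
        assert curve(14.0) == pytest.approx(2 * 10 * S + 1 * 4 * S, abs=1e-9)
        assert curve(10.0) == pytest.approx(1.1832, abs=1e-4)
        assert curve(14.0) == pytest.approx(1.4198, abs=1e-4)

    def test_flat_after_full_deprotonation(self, constants):
        curve = px.g_variable_slope(0.0, 1, px.PKaLadder("s", (7.0,)), constants)
        assert curve(7.0) == pytest.approx(curve(14.0), abs=1e-12)

    def test_inconsistent_ladder_rejected(self, constants):
        with pytest.raises(px.PhredoxError):
            px.g_variable_slope(0.0, 1, px.PKaLadder("s", (3.0, 5.0)), constants)

    def test_dense_grid_oracle_random_fixtures(self, constants, rng):
        """Breakpoint construction vs the 0.01-pH-step pointwise recurrence."""
        for _ in range(20):
            nh0 = int(rng.integers(1, 9))
            ladder = random_ladder(rng, "s", nh0)
            g0 = float(rng.uniform(-260, -240))
            curve = px.g_variable_slope(g0, nh0, ladder, constants)
            phs, dense = dense_g_recurrence(g0, nh0, ladder, constants)
            assert np.max(np.abs(curve(phs) - dense)) < 1e-9

    def test_concave_for_deprotonation_only_ladders(self, constants, rng):
        """Slopes nh*s are non-increasing in pH, so G is concave piecewise
        linear whenever protons are only ever lost as pH rises."""
        for _ in range(20):
            nh0 = int(rng.integers(1, 9))
            ladder = random_ladder(rng, "s", nh0)
            curve = px.g_variable_slope(0.0, nh0, ladder, constants)
            slopes = np.diff(curve.values) / np.diff(curve.ph)
            assert np.all(np.diff(slopes) < 1e-12)


class TestUCurve:
    def test_nernst_line_constant_mode(self, constants):
        couple = _couple()
        g_ox, g_red = -250.0, -237.56  # U0 = 0.730 V
        for mode in ("constant", "variable"):
            curve = px.u_curve(
                couple, g_ox, g_red, px.PKaLadder("ox"), px.PKaLadder("red"),
                constants, mode=mode,
            )
            assert curve(0.0) == pytest.approx(0.730, abs=1e-9)
            assert curve(7.0) == pytest.approx(0.730 - 7 * S, abs=1e-9)
            assert curve(7.0) == pytest.approx(0.3159, abs=1e-4)

    def test_red_deprotonation_halves_the_slope(self, constants):
        """2e-/2H+ couple with one Red pKa at 10: below it the slope is -s,
        above it -(1/2)s."""
        couple = _couple()
        curve = px.u_curve(
            couple, -250.0, -237.56, px.PKaLadder("ox"),
            px.PKaLadder("red", (10.0,)), constants, mode="variable",
        )
        assert curve(10.0) == pytest.approx(0.730 - 10 * S, abs=1e-9)
        assert curve(13.0) == pytest.approx(0.730 - 10 * S - 3 * 0.5 * S, abs=1e-9)
        assert curve(10.0) == pytest.approx(0.1384, abs=1e-4)
        assert curve(13.0) == pytest.approx(0.0497, abs=1e-4)

    def test_pure_electron_transfer_is_flat(self, constants):
        couple = _couple(nh_ox=4, np_=0, n=1)
        curve = px.u_curve(
            couple, -250.0, -245.0, px.PKaLadder("ox"), px.PKaLadder("red"),
            constants, mode="variable",
        )
        assert np.ptp(curve.values) < 1e-12

    def test_segment_slopes_match_midpoint_hydrogen_formula(self, constants, rng):
        """Each U segment's slope is -(NH_red - NH_ox)(mid) * s / n; every
        Red deprotonation makes the slope less negative by s/n, every Ox
        deprotonation more negative by s/n."""
        for _ in range(20):
            np_ = int(rng.integers(0, 3))
            n = int(rng.integers(max(1, np_), np_ + 2))
            nh_ox = int(rng.integers(2, 7))
            couple = _couple(nh_ox=nh_ox, np_=np_, n=n)
            lad_ox = random_ladder(rng, "ox", nh_ox, max_count=2)
            lad_red = random_ladder(rng, "red", nh_ox + np_, max_count=3)
            g_ox = -250.0
            # invert the potential expressions so U0 = 0.5 V
            g_red = -n * (0.5 + constants.U_SHE) - np_ * constants.dG_solv_proton + g_ox
            curve = px.u_curve(
                couple, g_ox, g_red, lad_ox, lad_red, constants, mode="variable"
            )
            for i, (lo, hi) in enumerate(zip(curve.ph[:-1], curve.ph[1:])):
                slope = (curve.values[i + 1] - curve.values[i]) / (hi - lo)
                d_nh = px.midpoint_hydrogens(
                    nh_ox + np_, lad_red, lo, hi
                ) - px.midpoint_hydrogens(nh_ox, lad_ox, lo, hi)
                assert slope == pytest.approx(
                    -d_nh * constants.nernst_slope / n, abs=1e-12
                )

    def test_curves_are_continuous(self, constants, rng):
        """Approaching any interior breakpoint from both sides gives the
        breakpoint value (continuity of the piecewise construction)."""
        couple = _couple()
        lad_red = px.PKaLadder("red", (4.0, 9.0, 11.5))
        curve = px.u_curve(
            couple, -250.0, -237.56, px.PKaLadder("ox"), lad_red, constants
        )
        for p, v in zip(curve.ph[1:-1], curve.values[1:-1]):
            assert curve(p - 1e-9) == pytest.approx(v, abs=1e-6)
            assert curve(p + 1e-9) == pytest.approx(v, abs=1e-6)

    def test_unknown_mode_rejected(self, constants):
        with pytest.raises(px.PhredoxError):
            px.u_curve(
                _couple(), -1.0, -1.0, px.PKaLadder("ox"), px.PKaLadder("red"),
                constants, mode="spline",
            )


class TestEvaluate:
    def test_interpolation_and_breakpoints(self):
        curve = px.PiecewiseLinearCurve(np.array([0.0, 14.0]), np.array([0.0, 14.0]))
        assert px.evaluate(curve, 7.0) == 7.0
        assert px.evaluate(curve, 14.0) == 14.0

    def test_no_extrapolation(self):
        curve = px.PiecewiseLinearCurve(np.array([0.0, 14.0]), np.array([0.0, 1.0]))
        with pytest.raises(px.PhredoxError):
            px.evaluate(curve, -1.0)
        with pytest.raises(px.PhredoxError):
            px.evaluate(curve, 14.5)

    def test_vectorized_evaluation(self):
        curve = px.PiecewiseLinearCurve(np.array([0.0, 10.0]), np.array([0.0, 5.0]))
        np.testing.assert_allclose(curve(np.array([0.0, 2.0, 10.0])), [0.0, 1.0, 5.0])

    def test_malformed_breakpoints_rejected(self):
        with pytest.raises(px.PhredoxError):
            px.PiecewiseLinearCurve(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
        with pytest.raises(px.PhredoxError):
            px.PiecewiseLinearCurve(np.array([0.0]), np.array([1.0]))


class TestSegmentTable:
    def test_columns_and_slopes(self, constants):
        couple = _couple()
        df = px.segment_table(
            "c1", couple, -250.0, -237.56, px.PKaLadder("ox"),
            px.PKaLadder("red", (10.0,)), constants,
        )
        assert list(df["ph_lo"]) == [0.0, 10.0]
        assert df["slope_v_per_ph"].iloc[0] == pytest.approx(-S, abs=1e-12)
        assert df["slope_v_per_ph"].iloc[1] == pytest.approx(-S / 2, abs=1e-12)
        assert list(df["nh_red_mid"]) == [6, 5]
        assert list(df["nh_ox_mid"]) == [4, 4]
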