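"""Curvature, canopy, smoothing, VCI and VAI contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcdmorph import (
    AverageBeat,
    BilateralPair,
    Exam,
    EnvelopeRecording,
    beat_canopy,
    curvature,
    extract_features,
    smooth_beat,
    synth,
    vai,
    vci_pair,
    vci_single,
)
from tcdmorph.errors import DegenerateBeatError, ValidationError

FS = 125.0


def _beat(x, hemi="left", sid="s1", depth=50.0):
    return AverageBeat(sid, hemi, depth, FS, np.asarray(x, float), 20)


def _pair(left_x, right_x, sid="s1"):
    return BilateralPair(sid, _beat(left_x, "left", sid), _beat(right_x, "right", sid))


TEMPLATE = synth.make_beat_template(synth.NORMAL_MORPHOLOGY, 100)


class TestSmoothBeat:
    def test_constant_unchanged(self):
        x = np.full(20, 7.0)
        np.testing.assert_allclose(smooth_beat(x, FS), x, atol=1e-12)

    def test_linear_ramp_unchanged_in_interior(self):
        x = 2.0 + 0.5 * np.arange(30)
        s = smooth_beat(x, FS)
        np.testing.assert_allclose(s[1:-1], x[1:-1], atol=1e-12)

    def test_impulse_reproduces_kernel_taps(self):
        x = np.zeros(11)
        x[5] = 1.0
        s = smooth_beat(x, FS)  # 3 taps at 125 Hz
        np.testing.assert_allclose(s[4:7], [0.25, 0.5, 0.25], atol=1e-12)

    def test_kernel_widens_with_sampling_rate(self):
        x = np.zeros(41)
        x[20] = 1.0
        s = smooth_beat(x, 1000.0)  # 9 ms at 1 kHz -> 9 taps
        assert (np.abs(s) > 1e-15).sum() == 9

    def test_non_positive_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth_beat(np.zeros(10), FS, window_ms=0.0)


class TestCurvature:
    def test_affine_is_zero(self):
        x = 3.0 + 0.7 * np.arange(25)
        np.testing.assert_allclose(curvature(x), 0.0, atol=1e-12)

    def test_step_example_hand_values(self):
        k = curvature(np.array([0.0, 0.0, 1.0, 1.0]))
        assert k[0] == 0.0 and k[3] == 0.0
        assert k[1] == pytest.approx(1.0, abs=1e-15)
        assert k[2] == pytest.approx(2.0 ** -1.5, abs=1e-15)

    def test_discretized_parabola_closed_form(self):
        c = 0.01
        i = np.arange(30, dtype=float)
        k = curvature(c * i ** 2)
        interior = np.arange(1, 29)
        expected = 2 * c / (1 + (c * (2 * interior - 1)) ** 2) ** 1.5
        np.testing.assert_allclose(k[1:-1], expected, rtol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            curvature(np.array([1.0, 2.0]))

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40))
    def test_nonnegative_and_translation_invariant(self, xs):
        x = np.asarray(xs)
        k = curvature(x)
        assert np.all(k >= 0)
        np.testing.assert_allclose(curvature(x + 17.3), k, atol=1e-9)


class TestBeatCanopy:
    def test_quarter_range_example(self):
        x = np.array([0.0, 1.0, 4.0, 2.0, 0.0])
        assert beat_canopy(x, 0, 2).tolist() == [1, 2, 3]

    def test_spike_only(self):
        x = np.full(10, 5.0)
        x[4] = 25.0
        assert beat_canopy(x, 0, 4).tolist() == [4]

    def test_offset_invariant(self):
        x = TEMPLATE
        c0 = beat_canopy(x, int(np.argmin(x)), int(np.argmax(x)))
        c1 = beat_canopy(x + 100.0, int(np.argmin(x)), int(np.argmax(x)))
        np.testing.assert_array_equal(c0, c1)

    def test_flat_beat_is_degenerate(self):
        with pytest.raises(DegenerateBeatError):
            beat_canopy(np.full(5, 3.0), 0, 1)


class TestVci:
    def test_translation_invariance(self):
        b0 = _beat(TEMPLATE)
        b1 = _beat(TEMPLATE + 23.0)
        assert vci_single(b1) == pytest.approx(vci_single(b0), rel=1e-12)

    def test_positive_on_pulsatile_beat(self):
        assert vci_single(_beat(TEMPLATE)) > 0

    def test_amplitude_scaling_monotone(self):
        base = TEMPLATE - TEMPLATE.min()
        values = [
            vci_single(_beat(30.0 + a * base)) for a in (1.0, 0.5, 0.25)
        ]
        assert values[0] > values[1] > values[2]

    def test_affine_beat_is_degenerate(self):
        with pytest.raises(DegenerateBeatError):
            vci_single(_beat(np.linspace(30, 30, 50)))

    def test_matches_independent_reference_on_toy_beat(self):
        # straight-line reimplementation of smooth->curvature->canopy->sum
        x = np.array([10.0, 12, 40, 55, 48, 30, 20, 14, 11, 10])
        width = 9.0 * FS / 1000.0
        n = max(3, 2 * int(round((width - 1.0) / 2.0)) + 1)
        win = np.hanning(n + 2)[1:-1]
        win = win / win.sum()
        half = n // 2
        xp = np.concatenate([x[1: 1 + half][::-1], x, x[-1 - half: -1][::-1]])
        s = np.array(
            [sum(win[m] * xp[i + m] for m in range(n)) for i in range(len(x))]
        )
        td, ts = int(np.argmin(s)), int(np.argmax(s))
        thr = s[td] + (s[ts] - s[td]) / 4.0
        ref = 0.0
        for i in range(1, len(s) - 1):
            if s[i] >= thr:
                d1 = s[i] - s[i - 1]
                d2 = s[i + 1] - 2 * s[i] + s[i - 1]
                ref += abs(d2) / (1 + d1 * d1) ** 1.5
        assert vci_single(_beat(x)) == pytest.approx(ref, abs=1e-12)
        assert ref == pytest.approx(0.1216482514566443, abs=1e-12)

    def test_pair_takes_minimum_side(self):
        blunted = synth.make_beat_template(synth.BLUNTED_MORPHOLOGY, 100)
        v, v_l, v_r = vci_pair(_pair(blunted, TEMPLATE))
        assert v == min(v_l, v_r) == v_l
        assert v_r > v_l


def _pulse_with_exact_mean(mean):
    """A non-flat beat whose sample mean is exactly ``mean`` in floats."""
    return np.array([mean - 1.0, mean + 1.0, mean, mean, mean, mean])


class TestVai:
    def test_equal_means_give_one(self):
        v, _, _ = vai(_pair(TEMPLATE, TEMPLATE.copy()))
        assert v == 1.0

    def test_65_over_100_is_exact(self):
        v, mu_l, mu_r = vai(
            _pair(_pulse_with_exact_mean(65.0), _pulse_with_exact_mean(100.0))
        )
        assert (mu_l, mu_r) == (65.0, 100.0)
        assert v == 0.65

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValidationError):
            vai(_pair(TEMPLATE - 100.0, TEMPLATE))

    @given(
        st.floats(2.0, 200.0),
        st.floats(2.0, 200.0),
    )
    def test_bounds_and_symmetry(self, a, b):
        v_ab, _, _ = vai(_pair(_pulse_with_exact_mean(a), _pulse_with_exact_mean(b)))
        v_ba, _, _ = vai(_pair(_pulse_with_exact_mean(b), _pulse_with_exact_mean(a)))
        assert 0.0 < v_ab <= 1.0
        assert v_ab == v_ba
        assert (v_ab == 1.0) == (a == b)


class TestExtractFeatures:
    def test_complete_cohort_yields_row_per_subject(self, cohort_features):
        rows, skips = cohort_features
        assert len(rows) + len(skips) == 66
        assert len(rows) >= 60

    def test_missing_hemisphere_becomes_skip_entry(self):
        rec = EnvelopeRecording(
            "only_left",
            "left",
            50.0,
            np.tile(TEMPLATE, 30),
            FS,
        )
        exam = Exam("only_left", recordings=[rec], label="IHC")
        rows, skips = extract_features([exam])
        assert rows == []
        assert skips[0][0] == "only_left"

    def test_planted_effect_orders_group_means(self, cohort_features):
        rows, _ = cohort_features
        vci_lvo = np.mean([r.vci for r in rows if r.label == "LVO"])
        vci_ihc = np.mean([r.vci for r in rows if r.label == "IHC"])
        assert vci_ihc > vci_lvo
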