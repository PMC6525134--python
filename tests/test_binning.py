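"""Cycle division, mid-inspiration/mid-expiration anchoring and bin labels."""

import numpy as np
import pytest

from respigate.binning import (
    CycleSet,
    amplitude_anchors,
    analytic_signal,
    assign_bins,
    cardiac_membership,
    cycle_divisions,
    phase_anchors,
    respiratory_membership,
)
from respigate.selfgate_projection import RespiratorySignal


def _sig(t, v, amplitude_valid=True):
    return RespiratorySignal(t=t, value=v, amplitude_valid=amplitude_valid)


class TestAnalyticSignal:
    def test_cosine_phase_advances_linearly(self):
        f = 0.25
        t = np.arange(0, 80, 0.0625)
        a = analytic_signal(_sig(t, np.cos(2 * np.pi * f * t)))
        phase = np.unwrap(np.angle(a))
        core = slice(100, -100)
        slope = np.polyfit(t[core], phase[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_envelope_recovers_amplitude(self):
        t = np.arange(0, 80, 0.0625)
        a = analytic_signal(_sig(t, 3.0 * np.cos(2 * np.pi * 0.25 * t)))
        core = slice(200, -200)
        assert np.median(np.abs(a[core])) == pytest.approx(3.0, rel=0.02)

    def test_sign_flip_shifts_phase_by_pi(self):
        t = np.arange(0, 40, 0.0625)
        v = np.cos(2 * np.pi * 0.25 * t)
        p1 = np.angle(analytic_signal(_sig(t, v)))
        p2 = np.angle(analytic_signal(_sig(t, -v)))
        d = np.angle(np.exp(1j * (p2 - p1)))
        core = slice(100, -100)
        np.testing.assert_allclose(np.abs(d[core]), np.pi, atol=0.05)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(_sig(np.arange(10.0), np.ones(10)))


class TestCycleDivisions:
    def test_sinusoid_divisions_at_period(self):
        T = 4.0
        t = np.arange(0, 10 * T, 0.0625)
        cyc = cycle_divisions(_sig(t, np.sin(2 * np.pi * t / T)))
        assert 8 <= cyc.n_cycles <= 10
        np.testing.assert_allclose(cyc.durations, T, atol=0.1)

    def test_division_count_for_50s_record(self):
        t = np.arange(0, 50, 0.0625)
        cyc = cycle_divisions(_sig(t, np.sin(2 * np.pi * 0.25 * t)))
        assert 10 <= cyc.n_cycles <= 13

    def test_outlier_cycles_discarded(self):
        t = np.arange(0, 100, 0.0625)
        v = np.sin(2 * np.pi * 0.25 * t)
        v[t > 80] = np.sin(2 * np.pi * 2.5 * t[t > 80])  # 0.4 s cycles
        cyc = cycle_divisions(_sig(t, v))
        assert np.all(cyc.durations >= 1.0)

    def test_variable_breathing_count_matches_truth(self, small_acq):
        from respigate.selfgate_projection import extract_projection_selfgating

        sig = extract_projection_selfgating(small_acq)
        cyc = cycle_divisions(sig)
        assert abs(cyc.n_cycles - small_acq.truth.resp.n_cycles) <= 1


class TestAmplitudeAnchors:
    def test_triangle_wave_quarter_points(self):
        T = 8.0
        t = np.arange(0, 10 * T, 0.01)
        tri = 1 - 2 * np.abs(((t / T) % 1.0) - 0.5)  # min at cycle start
        cycles = CycleSet(
            start=np.arange(0, 9) * T + 0.0, end=np.arange(1, 10) * T + 0.0
        )
        out = amplitude_anchors(_sig(t, tri), cycles)
        frac_mi = (out.anchor_mi - out.start) / out.durations
        frac_me = (out.anchor_me - out.start) / out.durations
        np.testing.assert_allclose(frac_mi, 0.25, atol=0.01)
        np.testing.assert_allclose(frac_me, 0.75, atol=0.01)

    def test_negative_cosine_anchors(self):
        T = 4.0
        t = np.arange(0, 40, 0.005)
        v = -np.cos(2 * np.pi * t / T)
        cycles = CycleSet(start=np.arange(0, 9) * T, end=np.arange(1, 10) * T)
        out = amplitude_anchors(_sig(t, v), cycles)
        np.testing.assert_allclose(out.anchor_mi - out.start, T / 4, atol=0.02)
        np.testing.assert_allclose(out.anchor_me - out.start, 3 * T / 4, atol=0.02)

    def test_sawtooth_fast_rise(self):
        T = 10.0
        t = np.arange(0, 30, 0.001)
        u = (t / T) % 1.0
        v = np.where(u < 0.2, u / 0.2, 1 - (u - 0.2) / 0.8)
        cycles = CycleSet(start=np.array([0.0, T]), end=np.array([T, 2 * T]))
        out = amplitude_anchors(_sig(t, v), cycles)
        np.testing.assert_allclose(
            (out.anchor_mi - out.start) / T, 0.10, atol=0.01
        )

    def test_phase_only_signal_rejected(self):
        t = np.arange(0, 40, 0.0625)
        sig = _sig(t, np.sin(t), amplitude_valid=False)
        cycles = CycleSet(start=np.array([0.0]), end=np.array([6.28]))
        with pytest.raises(ValueError):
            amplitude_anchors(sig, cycles)


class TestPhaseAnchors:
    def test_four_second_cycle(self):
        cycles = CycleSet(start=np.array([0.0]), end=np.array([4.0]))
        out = phase_anchors(cycles)
        assert out.anchor_mi[0] == pytest.approx(1.12)
        assert out.anchor_me[0] == pytest.approx(3.52)

    def test_zero_fraction_is_cycle_start(self):
        cycles = CycleSet(start=np.array([2.0]), end=np.array([6.0]))
        out = phase_anchors(cycles, mi_frac=0.0)
        assert out.anchor_mi[0] == 2.0

    def test_uniform_cycles_equally_spaced(self):
        cycles = CycleSet(start=np.arange(5.0) * 3, end=np.arange(1, 6.0) * 3)
        out = phase_anchors(cycles)
        np.testing.assert_allclose(np.diff(out.anchor_mi), 3.0)


class TestMembership:
    def _cycles(self):
        return CycleSet(
            start=np.array([0.0]),
            end=np.array([4.0]),
            anchor_mi=np.array([1.0]),
            anchor_me=np.array([3.0]),
        )

    def test_window_is_15pct_of_cycle(self):
        c = self._cycles()
        t = np.array([0.69, 0.7, 1.0, 1.3, 1.31])
        labels = respiratory_membership(t, c)
        np.testing.assert_array_equal(labels, [0, 1, 1, 1, 0])

    def test_spoke_just_outside_excluded(self):
        c = self._cycles()
        assert respiratory_membership(np.array([1.0 + 0.08 * 4.0]), c)[0] == 0

    def test_labels_mutually_exclusive_and_partition(self, small_acq):
        truth = small_acq.truth.resp
        cycles = CycleSet(
            start=truth.starts, end=truth.ends,
            anchor_mi=truth.anchor_mi, anchor_me=truth.anchor_me,
        )
        t = small_acq.spoke_table.timestamps
        labels = respiratory_membership(t, cycles)
        assert set(np.unique(labels)) <= {0, 1, 2}
        n = (labels == 0).sum() + (labels == 1).sum() + (labels == 2).sum()
        assert n == len(t)

    def test_window_width_adapts_to_cycle_duration(self):
        cycles = CycleSet(
            start=np.array([0.0, 4.0]),
            end=np.array([4.0, 12.0]),  # second cycle twice as long
            anchor_mi=np.array([1.0, 6.0]),
            anchor_me=np.array([3.0, 10.0]),
        )
        t = np.arange(0, 12, 0.001)
        labels = respiratory_membership(t, cycles)
        w1 = ((labels == 1) & (t < 4)).sum()
        w2 = ((labels == 1) & (t >= 4)).sum()
        assert w2 == pytest.approx(2 * w1, rel=0.01)

    def test_overlapping_windows_resolved_to_nearer_anchor(self):
        cycles = CycleSet(
            start=np.array([0.0]), end=np.array([4.0]),
            anchor_mi=np.array([1.9]), anchor_me=np.array([2.1]),
        )
        labels = respiratory_membership(np.array([1.95, 2.05]), cycles)
        np.testing.assert_array_equal(labels, [1, 2])


class TestCardiacMembership:
    def test_window_boundaries(self):
        rpeaks = np.arange(0.0, 10.0, 1.0)
        t = np.array([0.75, 0.85, 0.70, 0.8249, 0.825])
        lab = cardiac_membership(t, rpeaks)
        np.testing.assert_array_equal(lab, [True, False, True, True, False])

    def test_spokes_outside_rr_coverage_excluded(self):
        rpeaks = np.array([1.0, 2.0, 3.0])
        lab = cardiac_membership(np.array([0.5, 3.5, 1.75]), rpeaks)
        np.testing.assert_array_equal(lab, [False, False, True])

    def test_needs_two_rpeaks(self):
        with pytest.raises(ValueError):
            cardiac_membership(np.array([0.5]), np.array([1.0]))


class TestAssignBins:
    def test_truth_anchor_binning_is_pure(self, small_acq):
        from respigate.selfgate_projection import extract_projection_selfgating

        truth = small_acq.truth.resp
        cycles = CycleSet(
            start=truth.starts, end=truth.ends,
            anchor_mi=truth.anchor_mi, anchor_me=truth.anchor_me,
        )
        sig = extract_projection_selfgating(small_acq)
        ba = assign_bins(small_acq, sig, cycles=cycles)
        t = small_acq.spoke_table.timestamps
        ref = respiratory_membership(t, cycles)
        for b in (1, 2):
            sp = ba.spokes(b)
            assert len(sp) > 0
            assert np.all(ref[sp] == b)

    def test_si_spokes_never_reconstructed(self, small_acq):
        from respigate.selfgate_projection import extract_projection_selfgating

        sig = extract_projection_selfgating(small_acq)
        ba = assign_bins(small_acq, sig)
        assert not np.any(ba.in_bin & small_acq.spoke_table.is_si)

    def test_counts_reported(self, small_acq):
        from respigate.selfgate_projection import extract_projection_selfgating

        sig = extract_projection_selfgating(small_acq)
        ba = assign_bins(small_acq, sig)
        assert ba.counts["total_spokes"] == small_acq.spoke_table.n_spokes
        assert ba.counts["mid_inspiration"] == len(ba.spokes(1))

    def test_amplitude_and_phase_anchors_disagree_on_asymmetric_cycles(
        self, small_acq
    ):
        # the sin^4 cycle shape is asymmetric: half-amplitude anchors and the
        # fixed 28%/88% fractions must differ systematically
        from respigate.selfgate_projection import extract_projection_selfgating

        sig = extract_projection_selfgating(small_acq)
        cyc = cycle_divisions(sig)
        amp = amplitude_anchors(sig, cyc)
        pha = phase_anchors(CycleSet(start=amp.start, end=amp.end))
        d_mi = np.abs(amp.anchor_mi - pha.anchor_mi) / amp.durations
        d_me = np.abs(amp.anchor_me - pha.anchor_me) / amp.durations
        assert np.concatenate([d_mi, d_me]).mean() > 0.05
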