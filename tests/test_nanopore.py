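"""Nanopore event detection, ECD integration and MW calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from habrush import nanopore as npore
from habrush import synthetic as syn
from habrush.errors import CalibrationError, DegenerateNoiseError, DomainError, InvalidSpecError

from helpers import naive_detect_events, recall_precision

SEED = 0
FS = 200e3


def make_trace(samples, fs=FS):
    return npore.NanoporeTrace(np.asarray(samples, dtype=float), fs)


class TestBaseline:
    def test_constant_trace(self):
        trace = make_trace(np.full(10000, 4000.0))
        baseline, sigma = npore.estimate_baseline(trace, 0.01)
        assert np.allclose(baseline, 4000.0) and sigma == 0.0

    def test_gaussian_noise_sigma_within_five_percent(self, rng):
        trace = make_trace(4000.0 + rng.normal(0, 10.0, 400000))
        _, sigma = npore.estimate_baseline(trace, 0.05)
        assert sigma == pytest.approx(10.0, rel=0.05)

    def test_baseline_robust_to_ten_percent_event_occupancy(self, rng):
        x = 4000.0 + rng.normal(0, 10.0, 200000)
        for s in range(0, 200000, 20000):  # 2000 of every 20000 samples blocked
            x[s : s + 2000] -= 300.0
        baseline, sigma = npore.estimate_baseline(make_trace(x), 0.05)
        assert np.median(np.abs(baseline - 4000.0)) < sigma

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(InvalidSpecError):
            npore.estimate_baseline(make_trace(np.zeros(100)), 1.0)


class TestLowpass:
    def test_constant_trace_unchanged(self):
        out = npore.lowpass_filter(make_trace(np.full(5000, 123.0)))
        assert np.allclose(out.samples_pa, 123.0)

    def test_tone_above_cutoff_attenuated_20db(self):
        t = np.arange(100000) / FS
        out = npore.lowpass_filter(make_trace(np.sin(2 * np.pi * 50e3 * t)), 5000.0)
        mid = out.samples_pa[20000:80000]
        assert np.abs(mid).max() < 0.1  # > 20 dB down

    def test_tone_below_cutoff_within_one_percent(self):
        t = np.arange(100000) / FS
        out = npore.lowpass_filter(make_trace(np.sin(2 * np.pi * 200.0 * t)), 5000.0)
        mid = out.samples_pa[20000:80000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(InvalidSpecError):
            npore.lowpass_filter(make_trace(np.zeros(100)), FS / 2)


def rect_pulse_trace(depth, n_samples, start=5000, total=20000, baseline=4000.0, noise=None, rng=None):
    x = np.full(total, baseline)
    x[start : start + n_samples] -= depth
    if noise:
        x += rng.normal(0, noise, total)
    return make_trace(x)


class TestDetection:
    def test_single_rect_pulse_boundaries(self):
        trace = rect_pulse_trace(100.0, 200)  # 10 sigma pulse, 1 ms, noise floor 10 pA
        accepted, rejected = npore.detect_events(trace, 4000.0, 10.0)
        assert len(accepted) == 1 and not rejected
        ev = accepted[0]
        assert abs(ev.start - 5000) <= 2 and abs(ev.end - 5200) <= 2
        assert ev.mean_amplitude_pa == pytest.approx(100.0)

    def test_three_sigma_pulse_not_detected(self):
        trace = rect_pulse_trace(30.0, 200)  # depth 3 sigma for a 10 pA noise floor
        accepted, _ = npore.detect_events(trace, 4000.0, 10.0)
        assert accepted == []

    def test_ten_microsecond_pulse_rejected_too_short(self):
        trace = rect_pulse_trace(100.0, 2)  # 2 samples at 200 kHz = 10 us
        accepted, rejected = npore.detect_events(trace, 4000.0, 1.0)
        assert accepted == []
        assert len(rejected) == 1 and rejected[0].flags == ("too-short",)

    def test_duration_gate_inclusive_at_both_ends(self):
        fs = 80e3
        dmin_n = int(25e-6 * fs)  # 2 samples
        dmax_n = int(2.5 * fs)
        x = np.full(dmax_n + 20000, 1000.0)
        x[1000 : 1000 + dmin_n] -= 50.0
        x[5000 : 5000 + dmax_n] -= 50.0
        accepted, rejected = npore.detect_events(make_trace(x, fs), 1000.0, 1.0)
        assert len(accepted) == 2 and not rejected

    def test_zero_sigma_on_nonconstant_trace_is_degenerate(self):
        trace = rect_pulse_trace(100.0, 100)
        with pytest.raises(DegenerateNoiseError):
            npore.detect_events(trace, 4000.0, 0.0)

    def test_detection_invariant_to_baseline_shift(self, rng):
        noise = rng.normal(0, 10.0, 50000)
        x = np.full(50000, 4000.0) + noise
        x[10000:10400] -= 150.0
        a1, _ = npore.detect_events(make_trace(x), 4000.0, 10.0)
        a2, _ = npore.detect_events(make_trace(x + 500.0), 4500.0, 10.0)
        assert [(e.start, e.end) for e in a1] == [(e.start, e.end) for e in a2]

    def test_matches_brute_force_oracle_on_random_traces(self):
        """Spot-check oracle equivalence (the full 100-trace sweep is in acceptance)."""
        rng = np.random.default_rng(SEED)
        for _ in range(10):
            n = int(rng.integers(20000, 60000))
            x = 2000.0 + rng.normal(0, 8.0, n)
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, n - 600))
                x[s : s + int(rng.integers(2, 600))] -= rng.uniform(20, 200)
            trace = make_trace(x)
            accepted, _ = npore.detect_events(trace, 2000.0, 8.0)
            oracle = naive_detect_events(x, 2000.0, 8.0, FS)
            assert [(e.start, e.end) for e in accepted] == oracle


class TestECD:
    def test_rectangle_area_exact(self):
        trace = rect_pulse_trace(100.0, 200)  # 100 pA for 1 ms
        ecd = npore.event_charge_deficit((5000, 5200), trace, 4000.0)
        assert ecd == pytest.approx(0.1e-3 * 1000, rel=1e-12)  # 0.1 pA s

    @given(st.floats(0.1, 10.0))
    def test_linearity_in_depth(self, c):
        trace1 = rect_pulse_trace(50.0, 100)
        trace2 = rect_pulse_trace(50.0 * c, 100)
        e1 = npore.event_charge_deficit((5000, 5100), trace1, 4000.0)
        e2 = npore.event_charge_deficit((5000, 5100), trace2, 4000.0)
        assert e2 == pytest.approx(c * e1, rel=1e-9)

    def test_triangle_area_matches_analytic(self):
        n = 200
        x = np.full(20000, 4000.0)
        ramp = 100.0 * (1.0 - np.abs(np.arange(n + 1) - n // 2) / (n / 2))
        x[5000 : 5000 + n + 1] -= ramp
        trace = make_trace(x)
        ecd = npore.event_charge_deficit((5000, 5201), trace, 4000.0)
        assert ecd == pytest.approx(0.05, rel=1e-3)  # 100 pA * 1 ms / 2

    def test_additive_under_event_splitting(self, rng):
        x = 4000.0 + rng.normal(0, 5.0, 10000)
        x[2000:4000] -= 80.0
        trace = make_trace(x)
        whole = npore.event_charge_deficit((1500, 4500), trace, 4000.0)
        for split in (1600, 2500, 3999, 4400):
            left = np.sum(4000.0 - trace.samples_pa[1500:split]) * trace.dt
            right = np.sum(4000.0 - trace.samples_pa[split:4500]) * trace.dt
            assert left + right == pytest.approx(
                np.sum(4000.0 - trace.samples_pa[1500:4500]) * trace.dt, rel=1e-12
            )
        assert whole >= 0.0

    def test_inverted_boundaries_rejected(self):
        trace = rect_pulse_trace(10.0, 10)
        with pytest.raises(DomainError):
            npore.event_charge_deficit((500, 400), trace, 4000.0)


class TestCalibration:
    def test_exact_power_law_recovered_to_machine_precision(self):
        ecd = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        mw = 3.0e9 * ecd**1.2
        cal = npore.fit_ecd_calibration(np.column_stack([ecd, mw]))
        assert cal.exponent == pytest.approx(1.2, rel=1e-12)
        pred, extra = cal.predict(ecd)
        assert np.allclose(pred, mw)
        assert not extra.any()

    def test_single_standard_underdetermined(self):
        with pytest.raises(CalibrationError):
            npore.fit_ecd_calibration([[1e-3, 1e6]])

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(CalibrationError):
            npore.fit_ecd_calibration([[1e-3, 2e6], [2e-3, 1e6], [4e-3, 3e6]])

    def test_noisy_fit_matches_closed_form_regression(self, rng):
        ecd = np.geomspace(1e-4, 1e-1, 12)
        mw = 2.5e9 * ecd**1.1 * np.exp(rng.normal(0, 0.05, ecd.size))
        cal = npore.fit_ecd_calibration(np.column_stack([ecd, mw]))
        # independent closed-form least squares on logs
        lx, ly = np.log(ecd), np.log(mw)
        b = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum((lx - lx.mean()) ** 2)
        a = ly.mean() - b * lx.mean()
        assert cal.exponent == pytest.approx(b, rel=1e-9)
        assert cal.log_intercept == pytest.approx(a, rel=1e-9)

    def test_extrapolation_flagged(self):
        cal = npore.fit_ecd_calibration([[1e-3, 1e6], [1e-2, 1e7]])
        _, extra = cal.predict([1e-5, 5e-3, 1.0])
        assert extra.tolist() == [True, False, True]


class TestMWStats:
    def test_single_species(self):
        mn, mw, pdi = npore.mw_distribution_stats([2e6])
        assert mn == mw == 2e6 and pdi == 1.0

    def test_two_species_direct_summation(self):
        mn, mw, pdi = npore.mw_distribution_stats([1e6, 3e6])
        assert mn == pytest.approx(2e6)
        assert mw == pytest.approx(2.5e6)
        assert pdi == pytest.approx(1.25)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            npore.mw_distribution_stats([])

    @given(st.lists(st.floats(1e3, 1e8), min_size=1, max_size=30))
    def test_mw_at_least_mn(self, weights):
        mn, mw, pdi = npore.mw_distribution_stats(weights)
        assert mw >= mn * (1 - 1e-12)
        assert pdi >= 1 - 1e-12

    def test_equality_iff_monodisperse(self):
        mn, mw, _ = npore.mw_distribution_stats([5e6] * 10)
        assert mw == pytest.approx(mn, rel=1e-15)
        mn2, mw2, _ = npore.mw_distribution_stats([5e6] * 9 + [6e6])
        assert mw2 > mn2


class TestEndToEnd:
    def _calibration(self, spec):
        standards = [[spec.ecd_pas(m), m] for m in (0.2e6, 1e6, 5e6, 20e6)]
        return npore.fit_ecd_calibration(standards)

    def test_recovers_sample_moments_within_five_percent(self):
        mw = syn.sample_mw_distribution(
            syn.MWGeneratorSpec(n=100, mn_da=2.42e6, mw_da=6.76e6, seed=SEED)
        )
        spec = syn.SyntheticTraceSpec(seed=SEED)
        trace, truth = syn.generate_nanopore_trace(mw, spec)
        res = npore.end_to_end_mw_pipeline(trace, self._calibration(spec))
        recall, precision = recall_precision(
            [(e.start, e.end) for e in res.events], [(e.start, e.end) for e in truth]
        )
        assert recall == precision == 1.0
        assert res.distribution.mn_da == pytest.approx(mw.mn_da, rel=0.05)
        assert res.distribution.mw_da == pytest.approx(mw.mw_da, rel=0.05)

    def test_event_free_trace_yields_empty_distribution(self):
        spec = syn.SyntheticTraceSpec(seed=SEED, pad_s=2.0)
        trace, _ = syn.generate_nanopore_trace(None, spec)
        res = npore.end_to_end_mw_pipeline(trace, self._calibration(spec))
        assert len(res.distribution) == 0
        with pytest.raises(DomainError):
            res.distribution.mn_da
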