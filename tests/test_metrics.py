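"""Bleach correction, event metrics, tau fitting and synchrony tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calmech import (
    MovieStack,
    SimConfig,
    compute_bleach_ratios,
    compute_frequency,
    detect_synchrony,
    extract_events,
    fit_decay_tau,
    generate_ground_truth,
    render_movie,
    synchrony_case_fraction,
)
from calmech.metrics import (
    CalciumEvent,
    analyze_movie,
    apply_bleach_correction,
    coincidence_fraction,
)
from calmech.simulate import transient_kernel


class TestBleachRatios:
    def test_constant_background_unit_ratios(self):
        stack = MovieStack(np.full((20, 8, 8), 500.0), 30.0)
        ratios = compute_bleach_ratios(stack, [np.zeros((8, 8), bool)])
        np.testing.assert_allclose(ratios.ratios, 1.0)

    def test_exponential_background_closed_form(self):
        lam = 0.02
        t = np.arange(100) / 30.0
        data = np.broadcast_to(
            (800 * np.exp(-lam * t))[:, None, None], (100, 8, 8)
        ).copy()
        ratios = compute_bleach_ratios(MovieStack(data, 30.0),
                                       [np.zeros((8, 8), bool)])
        np.testing.assert_allclose(ratios.ratios, np.exp(lam * t), rtol=1e-12)

    def test_no_background_raises(self):
        stack = MovieStack(np.ones((5, 4, 4)), 30.0)
        with pytest.raises(ValueError, match="background"):
            compute_bleach_ratios(stack, [np.ones((4, 4), bool)])

    def test_corrected_amplitudes_near_truth(self):
        cfg = SimConfig(frame_count=600, height=48, width=48, n_cells=3,
                        soma_radius=3, event_rate=0.25, tau_true=1.4,
                        amp_true=0.06, bleach_fraction=0.2, noise_sd=0.0,
                        seed=11)
        truth = generate_ground_truth(cfg)
        stack = render_movie(truth, cfg)
        ratios = compute_bleach_ratios(stack, list(truth.footprint_masks))
        for mask, times in zip(truth.footprint_masks, truth.event_times):
            trace = apply_bleach_correction(stack.data[:, mask].mean(axis=1),
                                            ratios)
            for t_e in times:
                i = int(np.ceil(t_e * cfg.frame_rate))
                if i >= cfg.frame_count:
                    continue
                local_amp = (trace[i] - cfg.baseline) / cfg.baseline
                # includes tails of earlier events, so >= amp_true - 5%
                assert local_amp >= cfg.amp_true * 0.95


class TestExtractEvents:
    def _trace(self, events, amp=0.06, tau=1.4, n=600, rate=30.0):
        t = np.arange(n) / rate
        return 1000.0 * (1 + amp * transient_kernel(t, np.asarray(events), tau))

    def test_single_transient_amplitude(self):
        events = extract_events(self._trace([5.0]), 30.0)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(6.0, abs=0.05)
        assert events[0].peak_time == pytest.approx(5.0, abs=0.05)

    def test_two_transients_ordered(self):
        events = extract_events(self._trace([4.0, 12.0]), 30.0)
        assert len(events) == 2
        assert events[0].peak_time < events[1].peak_time

    def test_flat_trace_no_events(self):
        assert extract_events(np.full(200, 7.0), 30.0) == []

    def test_subthreshold_amplitude_rejected(self):
        events = extract_events(self._trace([5.0], amp=0.03), 30.0)
        assert events == []

    def test_monte_carlo_amplitude_recovery(self):
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(40):
            n_ev = rng.poisson(0.3 * 20)
            times = np.sort(rng.uniform(0, 20, n_ev))
            trace = self._trace(times) + rng.normal(0, 1.5, 600)
            amps += [e.amplitude for e in
                     extract_events(trace, 30.0, tau_guess=1.4)]
        assert np.mean(amps) == pytest.approx(6.0, rel=0.10)


class TestFrequency:
    @pytest.mark.parametrize("n_events,duration,expected", [
        (6, 20.0, 0.30), (0, 20.0, 0.0), (5, 10.0, 0.5),
    ])
    def test_arithmetic(self, n_events, duration, expected):
        events = [CalciumEvent(peak_time=i, peak_index=i, amplitude=5.0)
                  for i in range(n_events)]
        assert compute_frequency(events, duration) == pytest.approx(expected)

    def test_requires_positive_duration(self):
        with pytest.raises(ValueError):
            compute_frequency([], 0.0)


class TestFitDecayTau:
    def test_noiseless_exponential_exact(self):
        t = np.arange(100) / 30.0
        tau, err, flag = fit_decay_tau(np.exp(-t / 1.5), 30.0)
        assert not flag
        assert tau == pytest.approx(1.5, abs=1e-6)
        assert err < 1e-12

    def test_constant_segment_flagged(self):
        tau, _, flag = fit_decay_tau(np.full(50, 3.0), 30.0)
        assert flag and tau is None

    def test_short_segment_flagged(self):
        tau, _, flag = fit_decay_tau(np.exp(-np.arange(5)), 30.0)
        assert flag and tau is None

    def test_non_exponential_segment_fails_quality_gate(self):
        # a triangular bump cannot be fitted by a single exponential to
        # within 0.05% mean squared relative error
        seg = np.concatenate([np.linspace(1.0, 0.5, 40),
                              np.linspace(0.5, 1.0, 40)])
        tau, err, flag = fit_decay_tau(seg, 30.0)
        assert flag and tau is None
        assert err > 5e-4

    def test_monte_carlo_tau_recovery(self):
        # segments in fluorescence units: amplitude 60 counts on a 1000-count
        # baseline, amplitude SNR 20, so the 0.05% quality gate stays open
        rng = np.random.default_rng(1)
        t = np.arange(90) / 30.0
        taus = []
        for _ in range(100):
            y = 1000.0 + 60.0 * np.exp(-t / 1.22) + rng.normal(0, 3.0, len(t))
            tau, _, flag = fit_decay_tau(y, 30.0)
            if not flag:
                taus.append(tau)
        assert len(taus) >= 90
        assert np.median(taus) == pytest.approx(1.22, rel=0.05)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        t = np.arange(80) / 30.0
        y = 2.0 * np.exp(-t / 0.8) + 0.3
        tau_ref, _, _ = fit_decay_tau(y, 30.0)
        tau_scaled, _, _ = fit_decay_tau(c * y, 30.0)
        assert tau_scaled == pytest.approx(tau_ref, rel=1e-6)


class TestSynchrony:
    def test_identical_trains_synchronized(self):
        t = np.array([1.0, 5.0, 9.0])
        summary = detect_synchrony([t, t.copy()])
        assert summary.synchronized_pair
        assert not summary.synchronized_triple

    def test_triple_clique_flag(self):
        t = np.array([2.0, 6.0, 11.0])
        summary = detect_synchrony([t, t + 0.01, t - 0.01])
        assert summary.synchronized_triple and summary.synchronized_pair

    def test_disjoint_trains_not_synchronized(self):
        a = np.array([1.0, 5.0, 9.0])
        summary = detect_synchrony([a, a + 2.0])
        assert not summary.synchronized_pair

    def test_needs_two_neurons(self):
        with pytest.raises(ValueError):
            detect_synchrony([np.array([1.0])])

    def test_coincidence_fraction_matches_analytic(self):
        # single interior event vs a Poisson train at rate r: the partner
        # probability is 1 - exp(-2 w r)
        rng = np.random.default_rng(2)
        r, w, T = 0.5, 0.3, 200.0
        hits = [
            coincidence_fraction(
                np.array([rng.uniform(w, T - w)]),
                np.sort(rng.uniform(0, T, rng.poisson(r * T))), w)
            for _ in range(3000)
        ]
        expected = 1 - np.exp(-2 * w * r)
        se = np.sqrt(expected * (1 - expected) / 3000)
        assert np.mean(hits) == pytest.approx(expected, abs=4 * se)

    def test_case_fraction_bookkeeping(self):
        t = np.array([1.0, 4.0, 7.0])
        synced = detect_synchrony([t, t + 0.02, t - 0.02])
        lone = detect_synchrony([t, t + 1.0, t + 2.0])
        summaries = [synced] * 15 + [lone] * 25
        assert synchrony_case_fraction(summaries, "triple") == pytest.approx(37.5)


class TestPipeline:
    def test_bleach_invariance_of_amplitudes(self):
        base = dict(frame_count=600, height=48, width=48, n_cells=3,
                    soma_radius=3, event_rate=0.25, tau_true=1.4,
                    amp_true=0.06, noise_sd=2.0, seed=21)
        cfg_b = SimConfig(bleach_fraction=0.15, **base)
        cfg_u = SimConfig(bleach_fraction=0.0, **base)
        truth = generate_ground_truth(cfg_b)
        amps = {}
        for key, cfg in (("b", cfg_b), ("u", cfg_u)):
            stack = render_movie(truth, cfg)
            signals, _ = analyze_movie(stack, tau_guess=1.4)
            cell_amp = {}
            for s in signals:
                ov = [np.logical_and(s.roi_mask, m).sum()
                      for m in truth.footprint_masks]
                cell_amp[int(np.argmax(ov))] = s.mean_amplitude
            amps[key] = cell_amp
        assert set(amps["b"]) == set(amps["u"])
        for c in amps["b"]:
            assert amps["b"][c] == pytest.approx(amps["u"][c], rel=0.05)

    def test_frequency_amplitude_tau_recovered(self):
        cfg = SimConfig(frame_count=600, height=64, width=64, n_cells=4,
                        soma_radius=3, event_rate=0.3, tau_true=1.5,
                        amp_true=0.08, bleach_fraction=0.1, noise_sd=4.0,
                        seed=31)
        truth = generate_ground_truth(cfg)
        stack = render_movie(truth, cfg)
        signals, summary = analyze_movie(stack, tau_guess=1.5)
        matched = {}
        for s in signals:
            ov = [np.logical_and(s.roi_mask, m).sum()
                  for m in truth.footprint_masks]
            assert max(ov) > 0  # no background false positives
            c = int(np.argmax(ov))
            if c not in matched or s.n_pixels > matched[c].n_pixels:
                matched[c] = s
        for c, s in matched.items():
            true_f = len(truth.event_times[c]) / cfg.duration
            if true_f > 0:
                assert s.frequency == pytest.approx(true_f, rel=0.25)
                assert s.mean_amplitude == pytest.approx(8.0, rel=0.2)
        assert summary is not None
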