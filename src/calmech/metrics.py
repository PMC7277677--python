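"""Bleach correction and per-neuron functional metrics.

The simple-ratio photobleaching correction rescales each frame by
``b(0)/b(t)``, where ``b(t)`` is the mean intensity of the region outside
all detected ROIs.  On corrected traces the module extracts Ca2+ events
(peaks passing the same dual threshold as detection), computes the event
frequency, the relative amplitude dF/F in percent, the exponential decay
constant tau of each transient, and flags cross-neuron synchrony by a
windowed coincidence criterion.

Baseline F0 for dF/F is estimated in two passes: a provisional low-percentile
baseline locates events, then F0 is the time mean of the corrected trace
with windows of +/- 3 tau around each event excluded.  At the event rates
typical of these recordings the exclusion windows can cover essentially the
whole 20 s trace; the estimator then falls back to the low percentile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from calmech.detect import (
    NeuronSignal,
    find_trace_peaks,
    merge_detections,
    detect_active_pixels,
    pixel_statistics,
    smooth_trace,
)
from calmech.simulate import MovieStack

__all__ = [
    "BleachRatios",
    "CalciumEvent",
    "RecordingSummary",
    "compute_bleach_ratios",
    "apply_bleach_correction",
    "extract_events",
    "compute_frequency",
    "fit_decay_tau",
    "coincidence_fraction",
    "detect_synchrony",
    "synchrony_case_fraction",
    "analyze_movie",
]

#: Upper bound on the mean squared relative fit residual (0.05% of signal
#: scale) above which a tau fit is flagged and the constant withheld.
TAU_FIT_ERROR_BOUND = 5e-4

#: Percentile of the trace used for the provisional (pass-1) baseline and
#: as the fallback when the event-exclusion windows cover the whole trace.
BASELINE_PERCENTILE = 10.0


@dataclass
class BleachRatios:
    """Per-frame simple-ratio correction factors, referenced to frame 0."""

    ratios: np.ndarray              # T, ratio[0] == 1
    background_mask: np.ndarray     # H x W bool, pixels used for b(t)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if not np.isclose(self.ratios[0], 1.0):
            raise ValueError("correction factor at frame 0 must be 1")
        if np.any(self.ratios <= 0):
            raise ValueError("correction factors must be positive")


@dataclass
class CalciumEvent:
    """One detected Ca2+ transient on a corrected trace."""

    peak_time: float                # s
    peak_index: int
    amplitude: float                # dF/F, percent
    decay_tau: float | None = None  # s, absent when the fit is rejected
    fit_error: float | None = None  # mean squared relative residual
    tau_flag: bool = False          # True when the fit failed the quality gate


@dataclass
class RecordingSummary:
    """Per-recording functional summary across neurons."""

    frequencies: list[float]                    # Hz, per neuron
    mean_amplitudes: list[float]                # dF/F %, per neuron
    taus: list[float | None]                    # s, per neuron (median over events)
    synchronized_pair: bool = False
    synchronized_triple: bool = False
    n_synchronized_pairs: int = 0
    sync_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.synchronized_triple and not self.synchronized_pair:
            raise ValueError("a synchronized triple implies a synchronized pair")


def compute_bleach_ratios(stack: MovieStack,
                          roi_masks: np.ndarray | list[np.ndarray],
                          min_background_fraction: float = 0.01
                          ) -> BleachRatios:
    """Simple-ratio correction factors from the non-ROI background.

    ``ratio(t) = b(0) / b(t)`` with ``b(t)`` the spatial mean over pixels
    outside every ROI; multiplying a trace by ``ratio(t)`` compensates the
    photobleaching decay.
    """
    H, W = stack.data.shape[1:]
    union = np.zeros((H, W), dtype=bool)
    for mask in roi_masks:
        union |= mask
    background = ~union
    if background.sum() < min_background_fraction * H * W or background.sum() == 0:
        raise ValueError("not enough background pixels outside the ROIs")
    b = stack.data[:, background].mean(axis=1)
    if np.any(b <= 0):
        raise ValueError("non-positive background mean; cannot form ratios")
    return BleachRatios(ratios=b[0] / b, background_mask=background)


def apply_bleach_correction(trace: np.ndarray,
                            ratios: BleachRatios) -> np.ndarray:
    """Multiply a trace by the per-frame correction factors."""
    return np.asarray(trace, dtype=float) * ratios.ratios


def _exp_decay(t: np.ndarray, A: float, tau: float, C: float) -> np.ndarray:
    return A * np.exp(-t / tau) + C


def fit_decay_tau(segment: np.ndarray, frame_rate: float,
                  baseline_hint: float | None = None
                  ) -> tuple[float | None, float, bool]:
    """Fit ``A exp(-t/tau) + C`` to a post-peak segment.

    Returns ``(tau_s, fit_error, flag)``.  ``fit_error`` is the mean squared
    residual relative to the segment's peak value; fits exceeding the 0.05%
    bound, non-convergent fits and degenerate segments are flagged and tau
    is withheld (``None``).  When ``baseline_hint`` is given the offset C is
    bounded to within one segment amplitude of it.
    """
    y = np.asarray(segment, dtype=float)
    if len(y) < 10:
        return None, np.inf, True
    if np.ptp(y) == 0:
        return None, np.inf, True
    t = np.arange(len(y)) / frame_rate
    span = y[0] - y[-1]
    A0 = span if span != 0 else np.ptp(y)
    tau0 = max(t[-1] / 3.0, 1.0 / frame_rate)
    C0 = y[-1]
    scale = max(abs(y).max(), np.finfo(float).tiny)
    if baseline_hint is not None:
        amp = max(abs(A0), 1e-12 * scale)
        bounds = ([-np.inf, 1e-9, baseline_hint - amp],
                  [np.inf, np.inf, baseline_hint + amp])
        C0 = float(np.clip(C0, *[b[2] for b in bounds]))
    else:
        bounds = ([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(
            _exp_decay, t, y, p0=[A0, tau0, C0], bounds=bounds, maxfev=10000
        )
    except (RuntimeError, ValueError):
        return None, np.inf, True
    tau = float(popt[1])
    residual = (y - _exp_decay(t, *popt)) / scale
    fit_error = float(np.mean(residual**2))
    # a decay constant far beyond the observation window is unidentifiable
    # (the fit degenerates to a straight line)
    if fit_error > TAU_FIT_ERROR_BOUND or tau <= 0 or tau > 10.0 * t[-1]:
        return None, fit_error, True
    return tau, fit_error, False


def _masked_baseline(trace: np.ndarray, peak_indices: np.ndarray,
                     frame_rate: float, tau_guess: float,
                     max_masked_fraction: float = 0.8) -> float:
    """Event-masked time mean; falls back to a low percentile when the
    +/- 3 tau exclusion windows cover most of the trace."""
    mask = np.zeros(len(trace), dtype=bool)
    half = int(round(3.0 * tau_guess * frame_rate))
    for p in peak_indices:
        mask[max(p - half, 0): p + half + 1] = True
    if mask.mean() > max_masked_fraction:
        return float(np.percentile(trace, BASELINE_PERCENTILE))
    return float(trace[~mask].mean())


def extract_events(trace: np.ndarray, frame_rate: float,
                   rel_thresh: float = 0.05, sd_floor: float = 0.0,
                   sd_factor: float = 4.0, smooth_window: int = 3,
                   tau_guess: float = 1.5, min_separation_s: float = 0.1,
                   amplitude_mode: str = "step",
                   fit_tau: bool = True) -> list[CalciumEvent]:
    """Detect Ca2+ transients on a (bleach-corrected) trace.

    Candidate peaks are local maxima of the smoothed trace, refined to the
    raw maximum within one frame; a peak counts as an event when its raw
    height above the baseline F0 exceeds both ``rel_thresh * F0`` and
    ``sd_factor * sd_floor``.  F0 is estimated in two passes (provisional
    low percentile, then event-masked mean).

    Amplitude is reported as dF/F in percent.  In the default ``"step"``
    mode dF is the rise step at the event (peak minus the median pre-onset
    level), which stays unbiased when a transient rides on the decay tail
    of an earlier one; ``"above_f0"`` uses peak minus F0.  Each event's
    decay constant is fitted on the segment up to the next event onset.
    """
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) == 0:
        return []
    if amplitude_mode not in ("step", "above_f0"):
        raise ValueError("amplitude_mode must be 'step' or 'above_f0'")
    n = len(trace)

    def refine(p: int) -> int:
        lo, hi = max(p - 1, 0), min(p + 2, n)
        return lo + int(np.argmax(trace[lo:hi]))

    # robust per-trace noise scale from first differences; used to reject
    # noise ripples on a decay tail that pass the height criterion but have
    # no genuine rise of their own
    diffs = np.abs(np.diff(trace))
    noise_scale = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)

    def pre_onset(p: int) -> float:
        # raw samples ending 2 frames before the peak are uncontaminated for
        # either alignment of the refined peak relative to the event frame
        if p < 3:
            return trace[0]
        return float(np.median(trace[max(p - 4, 0): p - 1]))

    def rise_step(p: int) -> float:
        return trace[p] - pre_onset(p)

    def qualifying_peaks(f0: float) -> np.ndarray:
        peaks = find_trace_peaks(trace, smooth_window)
        if len(peaks) == 0:
            return peaks
        peaks = np.unique([refine(p) for p in peaks])
        height = trace[peaks] - f0
        ok = height > rel_thresh * f0
        if sd_floor > 0:
            ok &= height > sd_factor * sd_floor
        if noise_scale > 0:
            ok &= np.array([rise_step(p) for p in peaks]) > 5.0 * noise_scale
        return peaks[ok]

    f0 = float(np.percentile(trace, BASELINE_PERCENTILE))
    peaks = qualifying_peaks(f0)
    f0 = _masked_baseline(trace, peaks, frame_rate, tau_guess)
    peaks = qualifying_peaks(f0)
    peaks = _deduplicate_peaks(
        trace, peaks, max(int(round(min_separation_s * frame_rate)), 1)
    )

    events: list[CalciumEvent] = []
    for i, p in enumerate(peaks):
        stop = peaks[i + 1] - 1 if i + 1 < len(peaks) else n
        if amplitude_mode == "step":
            amplitude = 100.0 * (trace[p] - max(pre_onset(p), f0)) / f0
        else:
            amplitude = 100.0 * (trace[p] - f0) / f0
        tau, err, flag = (None, np.inf, True)
        if fit_tau:
            tau, err, flag = fit_decay_tau(trace[p:stop], frame_rate,
                                           baseline_hint=f0)
        events.append(CalciumEvent(
            peak_time=p / frame_rate, peak_index=int(p),
            amplitude=float(amplitude), decay_tau=tau,
            fit_error=None if np.isinf(err) else err, tau_flag=flag,
        ))
    return events


def _deduplicate_peaks(trace: np.ndarray, peaks: np.ndarray,
                       min_separation: int) -> np.ndarray:
    """Collapse qualifying peaks closer than ``min_separation`` frames,
    keeping the tallest of each run."""
    if len(peaks) <= 1:
        return peaks
    kept: list[int] = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] < min_separation:
            if trace[p] > trace[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.array(kept, dtype=int)


def compute_frequency(events: list[CalciumEvent], duration_s: float) -> float:
    """Event rate in Hz: count / duration."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(events) / duration_s


def coincidence_fraction(times_a: np.ndarray, times_b: np.ndarray,
                         window_s: float) -> float:
    """Fraction of the smaller train's events with a partner in the other
    train within ``+/- window_s``.  Returns 0 when either train is empty."""
    a = np.sort(np.asarray(times_a, dtype=float))
    b = np.sort(np.asarray(times_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        return 0.0
    small, big = (a, b) if len(a) <= len(b) else (b, a)
    idx = np.searchsorted(big, small)
    left = np.abs(small - big[np.clip(idx - 1, 0, len(big) - 1)])
    right = np.abs(big[np.clip(idx, 0, len(big) - 1)] - small)
    return float(np.mean(np.minimum(left, right) <= window_s))


def detect_synchrony(event_times: list[np.ndarray], window_s: float = 0.1,
                     min_coincidence: float = 0.5) -> RecordingSummary:
    """Flag synchronized activity across neurons.

    Two neurons are synchronized when at least ``min_coincidence`` of the
    smaller neuron's events have a partner event in the other within
    ``+/- window_s``; three or more neurons are synchronized when a clique
    of at least three pairwise-synchronized neurons exists.
    """
    n = len(event_times)
    if n < 2:
        raise ValueError("synchrony needs at least 2 neurons")
    sync = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        if len(event_times[i]) and len(event_times[j]):
            frac = coincidence_fraction(event_times[i], event_times[j], window_s)
            sync[i, j] = sync[j, i] = frac >= min_coincidence
    n_pairs = int(sync[np.triu_indices(n, 1)].sum())
    triple = any(
        sync[i, j] and sync[i, k] and sync[j, k]
        for i, j, k in itertools.combinations(range(n), 3)
    ) if n >= 3 else False
    return RecordingSummary(
        frequencies=[], mean_amplitudes=[], taus=[],
        synchronized_pair=n_pairs > 0,
        synchronized_triple=triple,
        n_synchronized_pairs=n_pairs,
        sync_matrix=sync,
    )


def synchrony_case_fraction(summaries: list[RecordingSummary],
                            kind: str = "triple") -> float:
    """Percent of recordings whose synchrony flag of the given kind is set.

    ``kind`` is ``"pair"`` (two or more synchronized neurons) or
    ``"triple"`` (three or more).
    """
    if not summaries:
        raise ValueError("no recordings")
    if kind == "pair":
        flags = [s.synchronized_pair for s in summaries]
    elif kind == "triple":
        flags = [s.synchronized_triple for s in summaries]
    else:
        raise ValueError("kind must be 'pair' or 'triple'")
    return 100.0 * sum(flags) / len(flags)


def analyze_movie(stack: MovieStack, rel_thresh: float = 0.05,
                  sd_factor: float = 4.0, max_extent: int = 20,
                  sync_window_s: float = 0.1,
                  precorrect_for_detection: bool = True,
                  tau_guess: float = 1.5
                  ) -> tuple[list[NeuronSignal], RecordingSummary | None]:
    """Full pipeline: detect ROIs, bleach-correct, quantify, flag synchrony.

    When ``precorrect_for_detection`` is set (default), the detection stage
    runs on a provisionally de-bleached copy of the stack (each frame scaled
    by the global-frame simple ratio) so that the monotone bleaching trend
    is not mistaken for signal excursions around the time mean; the final
    trace correction always uses the background outside the detected ROIs.
    """
    if precorrect_for_detection:
        frame_means = stack.data.mean(axis=(1, 2))
        if np.any(frame_means <= 0):
            raise ValueError("non-positive frame mean")
        det_stack = MovieStack(
            data=stack.data * (frame_means[0] / frame_means)[:, None, None],
            frame_rate=stack.frame_rate,
        )
    else:
        det_stack = stack

    mask = detect_active_pixels(det_stack, rel_thresh=rel_thresh,
                                sd_factor=sd_factor)
    signals = merge_detections(mask, stack, max_extent=max_extent)
    if not signals:
        return [], None

    ratios = compute_bleach_ratios(stack, [s.roi_mask for s in signals])
    sd_floor = pixel_statistics(det_stack).sd_floor
    duration = stack.data.shape[0] / stack.frame_rate
    for s in signals:
        corrected = apply_bleach_correction(s.trace, ratios)
        s.trace = corrected
        s.events = extract_events(corrected, stack.frame_rate,
                                  rel_thresh=rel_thresh, sd_floor=sd_floor,
                                  sd_factor=sd_factor, tau_guess=tau_guess)
        s.frequency = compute_frequency(s.events, duration)
        amps = [e.amplitude for e in s.events]
        s.mean_amplitude = float(np.mean(amps)) if amps else 0.0
        taus = [e.decay_tau for e in s.events if e.decay_tau is not None]
        s.tau = float(np.median(taus)) if taus else None

    summary = None
    if len(signals) >= 2:
        summary = detect_synchrony(
            [np.array([e.peak_time for e in s.events]) for s in signals],
            window_s=sync_window_s,
        )
        summary.frequencies = [s.frequency for s in signals]
        summary.mean_amplitudes = [s.mean_amplitude for s in signals]
        summary.taus = [s.tau for s in signals]
    return signals, summary
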