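"""Active-pixel detection and neighbour merging for fluorescence stacks.

A pixel is called active when its trace contains at least one peak whose
height above the trace's time mean exceeds both

* a relative threshold (default 5% of the time-averaged fluorescence), and
* a multiple (default 4x) of the stack-wide noise floor, taken as the
  smallest temporal standard deviation over all pixels.

Peaks are local maxima of the trace after a 3-frame moving average; the
peak height is measured on the smoothed trace, above the raw trace's time
mean.  Selected pixels are grouped by 8-connectivity and averaged into
cell-level signals, with groups spanning 20 px or more in either dimension
split by greedy seeded growth.

Detection runs on raw (pre-bleach-correction) traces by default; both the
smoothing and the correction order are configuration switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from calmech.simulate import MovieStack

__all__ = [
    "PixelStatistics",
    "DetectionMask",
    "NeuronSignal",
    "pixel_statistics",
    "smooth_trace",
    "find_trace_peaks",
    "detect_active_pixels",
    "merge_detections",
]

#: 8-connectivity structuring element for grouping neighbouring detections.
_CONNECTIVITY_8 = np.ones((3, 3), dtype=bool)


@dataclass
class PixelStatistics:
    """Per-pixel temporal summaries of a stack.

    ``sd_floor`` is the minimum temporal SD over all pixels — the stack-wide
    noise floor used by the second detection criterion.  Population (n)
    normalisation is used for the SD.
    """

    time_mean: np.ndarray       # H x W
    temporal_sd: np.ndarray     # H x W
    sd_floor: float


@dataclass
class DetectionMask:
    """Boolean selection mask plus the qualifying peak indices per pixel."""

    selected: np.ndarray                            # H x W bool
    peak_indices: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


@dataclass
class NeuronSignal:
    """A merged ROI: member-pixel mask, bounding box and averaged trace.

    ``events``/``frequency``/``mean_amplitude``/``tau`` are filled in by the
    metrics stage; they stay ``None`` straight out of detection.
    """

    roi_mask: np.ndarray                # H x W bool
    bbox: tuple[int, int, int, int]     # (row0, col0, row1, col1), exclusive stop
    trace: np.ndarray                   # per-frame mean over member pixels
    frame_rate: float
    events: list | None = None
    frequency: float | None = None
    mean_amplitude: float | None = None
    tau: float | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.roi_mask.sum())


def pixel_statistics(stack: MovieStack) -> PixelStatistics:
    """Time mean, temporal SD and the stack-wide SD floor, per pixel."""
    data = stack.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames for temporal statistics")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)  # population normalisation
    return PixelStatistics(time_mean=mean, temporal_sd=sd,
                           sd_floor=float(sd.min()))


def smooth_trace(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average along the last axis with edge replication."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    return ndimage.uniform_filter1d(
        np.asarray(values, dtype=float), size=window, axis=-1, mode="nearest"
    )


def find_trace_peaks(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Indices of strict local maxima of the smoothed trace.

    A peak is an interior sample strictly greater than both neighbours of
    the ``window``-frame moving average.
    """
    s = smooth_trace(values, window)
    if len(s) < 3:
        return np.array([], dtype=int)
    interior = (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])
    return np.nonzero(interior)[0] + 1


def trace_passes_criteria(values: np.ndarray, time_mean: float,
                          sd_floor: float, rel_thresh: float,
                          sd_factor: float,
                          window: int = 3) -> np.ndarray:
    """Peak indices of a single trace that pass the dual threshold.

    Height is the smoothed-trace value at the peak minus ``time_mean``.
    When the SD floor is zero the second criterion is trivially satisfied.
    """
    s = smooth_trace(values, window)
    peaks = find_trace_peaks(values, window)
    if len(peaks) == 0:
        return peaks
    height = s[peaks] - time_mean
    ok = height > rel_thresh * time_mean
    if sd_floor > 0:
        ok &= height > sd_factor * sd_floor
    return peaks[ok]


def detect_active_pixels(stack: MovieStack, rel_thresh: float = 0.05,
                         sd_factor: float = 4.0,
                         smooth_window: int = 3) -> DetectionMask:
    """Select pixels whose traces carry at least one supra-threshold peak.

    Vectorised over all pixels: peaks are strict local maxima of the
    3-frame-smoothed traces and must clear both ``rel_thresh`` times the
    pixel's time mean and ``sd_factor`` times the stack's SD floor.
    """
    if rel_thresh < 0 or sd_factor < 0:
        raise ValueError("thresholds must be non-negative")
    stats = pixel_statistics(stack)
    data = stack.data
    T, H, W = data.shape
    flat = data.reshape(T, H * W).T                    # (HW, T)
    s = smooth_trace(flat, smooth_window)
    is_peak = np.zeros_like(s, dtype=bool)
    if T >= 3:
        is_peak[:, 1:-1] = (s[:, 1:-1] > s[:, :-2]) & (s[:, 1:-1] > s[:, 2:])
    mean = stats.time_mean.reshape(-1)
    height = s - mean[:, None]
    good = is_peak & (height > rel_thresh * mean[:, None])
    if stats.sd_floor > 0:
        good &= height > sd_factor * stats.sd_floor
    selected = good.any(axis=1).reshape(H, W)
    peak_indices = {
        (r, c): np.nonzero(good[r * W + c])[0]
        for r, c in zip(*np.nonzero(selected))
    }
    return DetectionMask(selected=selected, peak_indices=peak_indices)


def _split_component(coords: np.ndarray, max_extent: int) -> list[np.ndarray]:
    """Greedy seeded growth splitting a pixel set into ROIs of bounded box.

    Seeds at the topmost-leftmost unassigned pixel and grows by
    8-connectivity, accepting a pixel only while the ROI's bounding box
    stays below ``max_extent`` in both dimensions.
    """
    remaining = {tuple(p) for p in coords}
    rois: list[np.ndarray] = []
    while remaining:
        seed = min(remaining)
        roi = {seed}
        remaining.discard(seed)
        rmin, rmax = seed[0], seed[0]
        cmin, cmax = seed[1], seed[1]
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q not in remaining:
                        continue
                    nrmin, nrmax = min(rmin, q[0]), max(rmax, q[0])
                    ncmin, ncmax = min(cmin, q[1]), max(cmax, q[1])
                    if nrmax - nrmin + 1 >= max_extent or \
                       ncmax - ncmin + 1 >= max_extent:
                        continue
                    rmin, rmax, cmin, cmax = nrmin, nrmax, ncmin, ncmax
                    roi.add(q)
                    remaining.discard(q)
                    frontier.append(q)
        rois.append(np.array(sorted(roi), dtype=int))
    return rois


def merge_detections(mask: DetectionMask, stack: MovieStack,
                     max_extent: int = 20) -> list[NeuronSignal]:
    """Group selected pixels into ROIs and average their traces.

    8-connected components become ROIs directly; components whose bounding
    box reaches ``max_extent`` pixels in either dimension are split by
    greedy seeded growth so every ROI spans fewer than ``max_extent`` px
    per dimension.  Each ROI trace is the per-frame mean over its pixels.
    """
    labels, n = ndimage.label(mask.selected, structure=_CONNECTIVITY_8)
    signals: list[NeuronSignal] = []
    H, W = mask.selected.shape
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        extent = coords.max(axis=0) - coords.min(axis=0) + 1
        if extent[0] >= max_extent or extent[1] >= max_extent:
            groups = _split_component(coords, max_extent)
        else:
            groups = [coords]
        for g in groups:
            roi = np.zeros((H, W), dtype=bool)
            roi[g[:, 0], g[:, 1]] = True
            r0, c0 = g.min(axis=0)
            r1, c1 = g.max(axis=0) + 1
            trace = stack.data[:, roi].mean(axis=1)
            signals.append(NeuronSignal(
                roi_mask=roi,
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                trace=trace,
                frame_rate=stack.frame_rate,
            ))
    return signals
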