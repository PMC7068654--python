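"""Ratiometric (G/T) transient quantification.

A Ca-sensitive channel (G, e.g. GCaMP5g) over a Ca-insensitive channel
(T, e.g. tdTomato): after background subtraction the ratio cancels volume
fraction and expression level. Event baseline and peak are 3-frame
averages; because the G channel saturates, the measured amplitude
G_P/T - G_B/T shrinks with the baseline even when the underlying Ca
amplitude does not — the saturation correction maps ratios through the
inverse indicator response to Ca-equivalent units before any rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class IndicatorResponseModel:
    """Strictly increasing ratio-vs-Ca response used for the saturation
    correction: r(Ca) = r0 + (r_sat - r0) * Ca^h / (Ca^h + K_D^h)."""

    kd_nm: float
    hill_h: float = 1.0
    r_at_zero: float = 0.0
    r_at_sat: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_nm <= 0 or self.hill_h <= 0:
            raise ValueError("K_D and Hill slope must be > 0")
        if self.r_at_sat <= self.r_at_zero:
            raise ValueError("response must be strictly increasing")

    def forward(self, ca_nm):
        ca = np.asarray(ca_nm, dtype=float)
        occ = ca**self.hill_h / (ca**self.hill_h + self.kd_nm**self.hill_h)
        return self.r_at_zero + (self.r_at_sat - self.r_at_zero) * occ

    def inverse(self, ratio, clamp_eps: float = 1e-3):
        """Ca-equivalent (nM) of a measured ratio; out-of-range ratios are
        clamped just inside the open range and flagged."""
        r = np.asarray(ratio, dtype=float)
        span = self.r_at_sat - self.r_at_zero
        lo = self.r_at_zero + clamp_eps * span
        hi = self.r_at_sat - clamp_eps * span
        clamped = (r < lo) | (r > hi)
        r = np.clip(r, lo, hi)
        occ = (r - self.r_at_zero) / span
        ca = self.kd_nm * (occ / (1.0 - occ)) ** (1.0 / self.hill_h)
        if ca.ndim == 0:
            return float(ca), bool(clamped)
        return ca, clamped


def background_correct(
    movie: np.ndarray, background: tuple[float, float]
) -> np.ndarray:
    """Subtract a per-channel scalar background; negatives floored at 0.

    ``movie`` is (frame, channel, y, x); ``background`` one scalar per
    channel (from a dark ROI or a low-percentile rule).
    """
    movie = np.asarray(movie, dtype=float)
    bg = np.asarray(background, dtype=float)
    if movie.ndim != 4 or bg.size != movie.shape[1]:
        raise ValueError("movie must be (frame, channel, y, x) with one "
                         "background per channel")
    return np.clip(movie - bg[None, :, None, None], 0.0, None)


def estimate_background(movie: np.ndarray, percentile: float = 5.0) -> tuple:
    """Low-percentile rule: per-channel background over all pixels/frames."""
    movie = np.asarray(movie, dtype=float)
    return tuple(float(np.percentile(movie[:, ch], percentile))
                 for ch in range(movie.shape[1]))


@dataclass
class RatioSeries:
    """Per-ROI G/T ratio time course (frames where T is at/below background
    are NaN)."""

    roi: tuple[int, int]
    t_s: np.ndarray
    gt: np.ndarray
    g: np.ndarray
    t_channel: np.ndarray


def gt_ratio(
    corrected_movie: np.ndarray,
    roi_slices: dict,
    frame_interval_s: float,
) -> dict[tuple[int, int], RatioSeries]:
    """Ratio of ROI-mean G to ROI-mean T per frame.

    ``roi_slices`` maps an ROI id to its (row-slice, col-slice) over the
    field (~3x3 um boxes centred on the event site in practice).
    """
    movie = np.asarray(corrected_movie, dtype=float)
    n_frames = movie.shape[0]
    t = np.arange(n_frames) * frame_interval_s
    out = {}
    for roi, (sy, sx) in roi_slices.items():
        g = movie[:, 0, sy, sx].mean(axis=(1, 2))
        tt = movie[:, 1, sy, sx].mean(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            gt = np.where(tt > 0, g / np.where(tt > 0, tt, 1.0), np.nan)
        out[roi] = RatioSeries(roi, t.copy(), gt, g, tt)
    return out


@dataclass(frozen=True)
class GtEventMeasure:
    """3-frame baseline (G_B/T), 3-frame peak (G_P/T) and their difference
    for one event; optionally the Ca-equivalent remapped measures."""

    roi: tuple[int, int]
    t_event_s: float
    gb_over_t: float
    gp_over_t: float
    corrected_baseline_nm: float = float("nan")
    corrected_peak_nm: float = float("nan")
    locomotion_associated: bool = False

    @property
    def amplitude(self) -> float:
        return self.gp_over_t - self.gb_over_t

    @property
    def corrected_amplitude_nm(self) -> float:
        return self.corrected_peak_nm - self.corrected_baseline_nm


def measure_event_gt(
    series: RatioSeries,
    event_frame: int,
    search_frames: int = 3,
    onset_frame: int | None = None,
) -> GtEventMeasure:
    """3-frame measures around a detected event.

    Peak = mean of the argmax frame (within +-``search_frames`` of the
    nominal event frame) +-1; baseline = mean of the 3 frames ending one
    frame before the event onset (from the detector if given, otherwise
    taken as 3 frames before the peak frame). Events too close to the
    series edges are rejected.
    """
    gt = series.gt
    n = gt.size
    lo = max(event_frame - search_frames, 0)
    hi = min(event_frame + search_frames + 1, n)
    seg = gt[lo:hi]
    if np.all(np.isnan(seg)):
        raise ValueError("no defined frames around the event")
    i_peak = lo + int(np.nanargmax(seg))
    if i_peak - 1 < 0 or i_peak + 2 > n:
        raise ValueError("peak too close to the series edge for 3-frame mean")
    onset = onset_frame if onset_frame is not None else i_peak - 3
    b_start = onset - 3  # 3 frames, the last one frame before onset
    if b_start < 0:
        raise ValueError("insufficient pre-event frames for 3-frame baseline")
    baseline = float(np.nanmean(gt[b_start:onset]))
    peak = float(np.nanmean(gt[i_peak - 1:i_peak + 2]))
    return GtEventMeasure(series.roi, float(series.t_s[i_peak]),
                          baseline, peak)


def correct_nonlinearity(
    events: list[GtEventMeasure],
    model: IndicatorResponseModel,
    clamp_eps: float = 1e-3,
) -> list[GtEventMeasure]:
    """Map baseline and peak ratios through the inverse indicator response
    into Ca-equivalent units and recompute the amplitude there.

    Rank statistics downstream must use the corrected measures: the raw
    ratio amplitude is compressed at high baselines purely by indicator
    saturation, producing a spurious negative baseline-amplitude
    correlation.
    """
    out = []
    for ev in events:
        cb, _ = model.inverse(ev.gb_over_t, clamp_eps)
        cp, _ = model.inverse(ev.gp_over_t, clamp_eps)
        out.append(replace(ev, corrected_baseline_nm=float(cb),
                           corrected_peak_nm=float(cp)))
    return out


def bin_speed(
    speed_t_s: np.ndarray, speed_cm_s: np.ndarray, bin_s: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean speed over non-overlapping bins aligned to the trace start
    (equivalent to position change per window / window length)."""
    t = np.asarray(speed_t_s, dtype=float)
    v = np.asarray(speed_cm_s, dtype=float)
    if t.size == 0:
        return np.empty(0), np.empty(0)
    n_bins = int(np.floor((t[-1] - t[0]) / bin_s)) + 1
    idx = np.clip(((t - t[0]) / bin_s).astype(int), 0, n_bins - 1)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    starts = t[0] + np.arange(n_bins) * bin_s
    return starts, means


def associate_locomotion(
    events: list[GtEventMeasure],
    speed_t_s: np.ndarray,
    speed_cm_s: np.ndarray,
    bin_s: float = 3.0,
    speed_threshold_cm_s: float = 1.0,
    window_s: float = 6.0,
) -> tuple[list[GtEventMeasure], float]:
    """Flag events whose peak lies within +-``window_s`` of any 3-s speed
    bin exceeding the locomotion threshold; association is tested against
    the bin *interval*, not its centre. Returns the flagged events and the
    associated fraction."""
    starts, means = bin_speed(speed_t_s, speed_cm_s, bin_s)
    fast = means > speed_threshold_cm_s
    intervals = [(s, s + bin_s) for s, f in zip(starts, fast) if f]
    flagged = []
    n_assoc = 0
    for ev in events:
        assoc = any(s - window_s <= ev.t_event_s <= e + window_s
                    for s, e in intervals)
        n_assoc += bool(assoc)
        flagged.append(replace(ev, locomotion_associated=bool(assoc)))
    frac = n_assoc / len(events) if events else 0.0
    return flagged, float(frac)
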