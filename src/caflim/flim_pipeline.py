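"""From TCSPC stacks to per-ROI [Ca2+] time series and transient measures.

The analysis grid tiles the field with ~5x5 um ROIs; photons are pooled per
ROI over 600-ms windows; ROIs averaging fewer than 1500 photons per window
are discarded (this removes everything outside the dye-filled cell); the
photon-count ratio per window is translated to [Ca2+] through the
calibration curve after the decay-constant correction. Baseline, peak and
amplitude (= peak - baseline, exactly) are then read off per ROI or per
detected event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .flim_calibration import (
    CalibrationCurve,
    TauCorrectionMap,
    photon_count_ratio,
    ratio_to_ca,
)
from .io import TcspcStack

MIN_MEAN_PHOTONS = 1500.0
RESPONSE_THRESHOLD_NM = 6.0


@dataclass(frozen=True)
class RoiGrid:
    """Axis-aligned tiling of the field into square ROIs.

    ``tile_px`` pixels to a side; partial edge tiles are dropped. The
    exclusion mask marks tiles overlapping e.g. pipette regions.
    """

    tile_px: int
    n_rows: int
    n_cols: int
    pixel_um: float
    excluded: np.ndarray = field(default=None)  # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        if self.excluded is None:
            object.__setattr__(
                self, "excluded", np.zeros((self.n_rows, self.n_cols), bool))

    @property
    def tile_um(self) -> float:
        return self.tile_px * self.pixel_um

    @property
    def n_rois(self) -> int:
        return self.n_rows * self.n_cols

    def roi_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        y = (np.arange(self.n_rows) + 0.5) * self.tile_um
        x = (np.arange(self.n_cols) + 0.5) * self.tile_um
        return y, x


def make_roi_grid(
    field_shape: tuple[int, int],
    pixel_um: float,
    tile_um: float = 5.0,
    mask: np.ndarray | None = None,
) -> RoiGrid:
    """Deterministic tiling anchored at the image origin.

    ``mask`` (same shape as the field, True = excluded pixel) flags any tile
    it touches as excluded.
    """
    tile_px = int(round(tile_um / pixel_um))
    if tile_px < 2:
        raise ValueError("tile must span at least 2 pixels")
    ny, nx = field_shape
    n_rows, n_cols = ny // tile_px, nx // tile_px
    excluded = np.zeros((n_rows, n_cols), dtype=bool)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        for r in range(n_rows):
            for c in range(n_cols):
                tile = mask[r * tile_px:(r + 1) * tile_px,
                            c * tile_px:(c + 1) * tile_px]
                excluded[r, c] = bool(tile.any())
    return RoiGrid(tile_px, n_rows, n_cols, pixel_um, excluded)


def pool_photons(
    stack: TcspcStack, grid: RoiGrid, window_s: float = 0.6
) -> np.ndarray:
    """Sum microtime histograms over ROI pixels and frames per time window.

    Returns (n_windows, n_rows, n_cols, n_bins); total photons inside the
    tiled/windowed region are conserved. Frames that do not fill a complete
    window are dropped, as are partial edge tiles.
    """
    if stack.frame_interval_s > window_s:
        raise ValueError("frame interval must not exceed the pooling window")
    frames_per_window = int(round(window_s / stack.frame_interval_s))
    n_windows = stack.n_frames // frames_per_window
    t = grid.tile_px
    p = stack.photons[: n_windows * frames_per_window,
                      : grid.n_rows * t, : grid.n_cols * t, :]
    p = p.reshape(n_windows, frames_per_window, grid.n_rows, t,
                  grid.n_cols, t, stack.n_bins)
    return p.sum(axis=(1, 3, 5))


def filter_rois(
    pooled: np.ndarray,
    grid: RoiGrid,
    min_mean_photons: float = MIN_MEAN_PHOTONS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep ROIs whose mean photons per window is >= the threshold and that
    are not mask-excluded. Returns (kept bool field, rejection report)."""
    mean_photons = pooled.sum(axis=-1).mean(axis=0)
    kept = (mean_photons >= min_mean_photons) & ~grid.excluded
    rows = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if kept[r, c]:
                continue
            reason = "excluded_mask" if grid.excluded[r, c] else "low_photons"
            rows.append((r, c, float(mean_photons[r, c]), reason))
    report = pd.DataFrame(rows, columns=["roi_row", "roi_col",
                                         "mean_photons", "reason"])
    return kept, report


@dataclass
class CaTimeSeries:
    """Per-ROI [Ca2+] time course on the pooled 600-ms time base."""

    roi: tuple[int, int]
    t_s: np.ndarray
    ca_nm: np.ndarray  # NaN where the window ratio was undefined
    photons: np.ndarray
    clamped: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t_s) > 0):
            raise ValueError("time base must be strictly increasing")


def convert_to_ca(
    pooled: np.ndarray,
    grid: RoiGrid,
    kept: np.ndarray,
    curve: CalibrationCurve,
    bin_width_ns: float,
    correction: TauCorrectionMap | None = None,
    window_s: float = 0.6,
) -> dict[tuple[int, int], CaTimeSeries]:
    """Window ratio -> correction -> Hill inversion for every kept ROI.

    Undefined-ratio windows propagate as NaN gaps, never as zeros.
    """
    n_windows = pooled.shape[0]
    t = (np.arange(n_windows) + 0.5) * window_s
    ratios = photon_count_ratio(pooled, curve.windows, bin_width_ns)
    ca, clamped = ratio_to_ca(curve, ratios, correction)
    photons = pooled.sum(axis=-1)
    out: dict[tuple[int, int], CaTimeSeries] = {}
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if not kept[r, c]:
                continue
            out[(r, c)] = CaTimeSeries((r, c), t.copy(), ca[:, r, c],
                                       photons[:, r, c], clamped[:, r, c])
    return out


@dataclass(frozen=True)
class TransientMeasure:
    """Baseline, peak and amplitude of one transient (nM or G/T units)."""

    roi: tuple[int, int]
    t_event_s: float
    baseline: float
    peak: float
    rise_s: float = float("nan")
    decay_s: float = float("nan")
    modality: str = "FLIM"

    @property
    def amplitude(self) -> float:
        return self.peak - self.baseline


def measure_evoked(
    series: CaTimeSeries,
    stim_time_s: float,
    baseline_window_s: float = 5.0,
    response_window_s: float = 20.0,
) -> TransientMeasure:
    """Baseline = mean over the pre-stimulus window, peak = max over the
    response window; amplitude may be <= 0 for non-responders."""
    t = series.t_s
    b_mask = (t >= stim_time_s - baseline_window_s) & (t < stim_time_s)
    r_mask = (t >= stim_time_s) & (t < stim_time_s + response_window_s)
    if not b_mask.any() or not r_mask.any():
        raise ValueError("baseline or response window outside the series")
    baseline = float(np.nanmean(series.ca_nm[b_mask]))
    resp = series.ca_nm[r_mask]
    if np.all(np.isnan(resp)):
        raise ValueError("response window has no defined values")
    i_peak = int(np.nanargmax(resp))
    peak = float(resp[i_peak])
    t_peak = float(t[r_mask][i_peak])
    rise, decay = _event_kinetics(t, series.ca_nm, baseline, peak, t_peak)
    return TransientMeasure(series.roi, t_peak, baseline, peak, rise, decay)


def _event_kinetics(t, ca, baseline, peak, t_peak) -> tuple[float, float]:
    """Rise time 20-80% of amplitude before the peak; decay constant from a
    mono-exponential fit after the peak (repo conventions)."""
    amp = peak - baseline
    if amp <= 0:
        return float("nan"), float("nan")
    pre = (t <= t_peak) & np.isfinite(ca)
    rise = float("nan")
    tp, cp = t[pre], ca[pre]
    if cp.size >= 3:
        above20 = np.nonzero(cp >= baseline + 0.2 * amp)[0]
        above80 = np.nonzero(cp >= baseline + 0.8 * amp)[0]
        if above20.size and above80.size and above80[-1] >= above20[0]:
            rise = float(tp[above80[0]] - tp[above20[0]])
            rise = max(rise, 0.0)
    post = (t >= t_peak) & np.isfinite(ca)
    decay = float("nan")
    td, cd = t[post], ca[post]
    if cd.size >= 4:
        try:
            popt, _ = curve_fit(
                lambda x, tau: baseline + amp * np.exp(-x / tau),
                td - t_peak, cd, p0=(2.0,), maxfev=2000,
                bounds=(1e-3, 1e3))
            decay = float(popt[0])
        except RuntimeError:
            pass
    return rise, decay


def detect_spontaneous(
    series: CaTimeSeries,
    k_sigma: float = 4.0,
    min_duration_bins: int = 1,
    baseline_bins: int = 5,
) -> list[TransientMeasure]:
    """MAD-threshold event detector (automated stand-in for by-eye event
    picking).

    The noise scale is the MAD of the first-differences divided by sqrt(2)
    (robust to the events themselves); events are runs of >=
    ``min_duration_bins`` bins above median + k*sigma; overlapping or
    adjacent runs merge; per-event baseline is the mean of the
    ``baseline_bins`` bins before onset.
    """
    ca = series.ca_nm
    ok = np.isfinite(ca)
    if ok.sum() < 10:
        raise ValueError("need >= 10 defined bins for noise estimation")
    med = float(np.nanmedian(ca))
    diffs = np.diff(ca[ok])
    sigma = float(np.median(np.abs(diffs - np.median(diffs))) * 1.4826
                  / np.sqrt(2))
    if sigma == 0:
        sigma = 1e-12
    above = np.where(ok, ca > med + k_sigma * sigma, False)
    events: list[TransientMeasure] = []
    i, n = 0, above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and (above[j] or (j + 1 < n and above[j + 1])):
            j += 1
        if (j - i) >= min_duration_bins:
            lo = max(0, i - baseline_bins)
            base_seg = ca[lo:i]
            baseline = float(np.nanmean(base_seg)) if np.isfinite(
                base_seg).any() else med
            seg = ca[i:j]
            i_pk = int(np.nanargmax(seg))
            peak = float(seg[i_pk])
            t_pk = float(series.t_s[i + i_pk])
            rise, decay = _event_kinetics(series.t_s, ca, baseline, peak, t_pk)
            events.append(TransientMeasure(series.roi, t_pk, baseline, peak,
                                           rise, decay))
        i = j + 1
    return events


@dataclass(frozen=True)
class UncagingDelta:
    """after - before changes of baseline/peak/amplitude for one ROI."""

    roi: tuple[int, int]
    d_baseline: float
    d_peak: float
    d_amplitude: float
    included: bool


def uncaging_deltas(
    before: dict[tuple[int, int], TransientMeasure],
    after: dict[tuple[int, int], TransientMeasure],
    response_threshold_nm: float = RESPONSE_THRESHOLD_NM,
    criterion: str = "before",
) -> list[UncagingDelta]:
    """Per-ROI deltas across an uncaging intervention.

    A ROI is included iff its agonist-response amplitude exceeds the
    threshold — judged on the pre-uncaging response by default
    (``criterion`` may be "before", "after" or "both").
    """
    if set(before) != set(after):
        raise ValueError("before/after ROI sets differ")
    if criterion not in ("before", "after", "both"):
        raise ValueError("criterion must be 'before', 'after' or 'both'")
    out = []
    for roi in sorted(before):
        b, a = before[roi], after[roi]
        if criterion == "before":
            inc = b.amplitude > response_threshold_nm
        elif criterion == "after":
            inc = a.amplitude > response_threshold_nm
        else:
            inc = (b.amplitude > response_threshold_nm
                   and a.amplitude > response_threshold_nm)
        out.append(UncagingDelta(roi, a.baseline - b.baseline,
                                 a.peak - b.peak,
                                 a.amplitude - b.amplitude, bool(inc)))
    return out


def compute_vf(
    ca_insensitive_image: np.ndarray,
    grid: RoiGrid,
    soma_roi: tuple[int, int],
) -> np.ndarray:
    """Volume fraction (%) per ROI: local Ca-insensitive fluorescence
    normalized to the somatic ROI."""
    img = np.asarray(ca_insensitive_image, dtype=float)
    t = grid.tile_px
    means = img[: grid.n_rows * t, : grid.n_cols * t].reshape(
        grid.n_rows, t, grid.n_cols, t).mean(axis=(1, 3))
    soma = means[soma_roi]
    if soma <= 0:
        raise ValueError("somatic intensity must be > 0")
    return 100.0 * means / soma


def measures_to_frame(
    measures, cell_id: str = "cell", vf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Event/ROI table in the standard CSV column layout."""
    rows = []
    for m in measures:
        r, c = m.roi
        rows.append({
            "cell_id": cell_id, "roi_row": r, "roi_col": c,
            "t_event_s": m.t_event_s, "baseline": m.baseline,
            "peak": m.peak, "amplitude": m.amplitude,
            "rise_s": m.rise_s, "decay_s": m.decay_s,
            "vf_pct": float(vf[r, c]) if vf is not None else float("nan"),
            "modality": m.modality,
        })
    return pd.DataFrame(rows)
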