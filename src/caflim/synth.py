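"""Synthetic-data generators.

Ground truth first: a cell is a grid of ~5 um ROIs, each with its own
resting [Ca2+] (log-normal across the cell, default mean 62.7 nM, CV 0.36)
and astrocyte volume fraction (100% at the soma, decaying distally).
Transients ride on those baselines with a configurable coupling between the
local baseline and the true amplitude; the measurement chain then renders
photon-level FLIM stacks (two-state indicator, Poisson counts) or
two-channel intensity movies (saturating G channel over a Ca-insensitive T
channel). Every generator is a pure function of (parameters, seed) and
emits its ground-truth table so recovery tests never compare against
re-derived values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import biophysics
from .flim_calibration import (
    DEFAULT_WINDOWS,
    DecayModel,
    LifetimeWindows,
    expected_bin_probabilities,
)
from .io import TcspcStack

# ---------------------------------------------------------------------------
# indicator photophysics (two-state generative model)


@dataclass(frozen=True)
class TwoStateIndicator:
    """Ca-free / Ca-bound lifetime signatures mixed by occupancy.

    The chemistry is two-state: a fraction Ca/(Ca + K_D) of dye molecules
    is Ca-bound, emitting with the (longer) bound-state decay signature and
    ``brightness_bound``-fold more photons per molecule. The apparent
    half-saturation of the *photon-weighted* mixture is K_D / brightness.
    Triple-exponential decays are the fitting representation downstream,
    not the generative one.
    """

    kd_nm: float = 580.0
    tau_free_ns: float = 0.6
    tau_bound_ns: float = 3.5
    brightness_bound: float = 2.0
    t0_ns: float = 1.5
    irf_sigma_ns: float = 0.15
    record_length_ns: float = 12.5
    bin_width_ns: float = 0.1

    def occupancy(self, ca_nm):
        ca = np.asarray(ca_nm, dtype=float)
        return ca / (ca + self.kd_nm)

    def photon_fraction_bound(self, ca_nm):
        occ = self.occupancy(ca_nm)
        return occ * self.brightness_bound / (
            1.0 - occ + occ * self.brightness_bound)

    def brightness(self, ca_nm):
        """Photon yield per molecule relative to the Ca-free state."""
        occ = self.occupancy(ca_nm)
        return 1.0 - occ + occ * self.brightness_bound

    def _state_model(self, tau: float) -> DecayModel:
        return DecayModel((1.0,), (tau,), self.t0_ns, self.irf_sigma_ns,
                          self.record_length_ns, self.bin_width_ns)

    def free_model(self) -> DecayModel:
        return self._state_model(self.tau_free_ns)

    def bound_model(self) -> DecayModel:
        return self._state_model(self.tau_bound_ns)

    def state_bin_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        return (expected_bin_probabilities(self.free_model()),
                expected_bin_probabilities(self.bound_model()))

    def mixture_model(self, ca_nm: float) -> DecayModel:
        """Two-component DecayModel whose photon fractions equal the
        occupancy-weighted state mix at ``ca_nm``."""
        w = float(self.photon_fraction_bound(ca_nm))
        amps = ((1.0 - w) / self.tau_free_ns, w / self.tau_bound_ns)
        return DecayModel(amps, (self.tau_free_ns, self.tau_bound_ns),
                          self.t0_ns, self.irf_sigma_ns,
                          self.record_length_ns, self.bin_width_ns)


# Cuvette-calibration vs intracellular signatures: the bound/free decay
# constants shift slightly inside cells (viscosity, binding partners).
CALIB_INDICATOR = TwoStateIndicator()
INTRA_INDICATOR = replace(CALIB_INDICATOR, tau_free_ns=0.55, tau_bound_ns=3.2)


def simulate_calibration_series(
    indicator: TwoStateIndicator,
    ca_levels_nm: Sequence[float],
    photons_per_level: float,
    windows: LifetimeWindows = DEFAULT_WINDOWS,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cuvette-style series: one pooled decay histogram per [Ca2+] level,
    reduced to its photon-count ratio."""
    from .flim_calibration import photon_count_ratio, simulate_decay_histogram

    rng = np.random.default_rng(seed)
    ca = np.asarray(ca_levels_nm, dtype=float)
    ratios = np.empty(ca.size)
    for i, c in enumerate(ca):
        hist = simulate_decay_histogram(indicator.mixture_model(c),
                                        photons_per_level, rng)
        ratios[i] = photon_count_ratio(hist, windows, indicator.bin_width_ns)
    return ca, ratios


# ---------------------------------------------------------------------------
# cells and couplings


@dataclass(frozen=True)
class CellModel:
    """Ground-truth cell: per-ROI resting [Ca2+] and volume fraction."""

    baseline_nm: np.ndarray  # (rows, cols)
    vf_pct: np.ndarray  # (rows, cols), soma = 100
    roi_size_um: float = 5.0
    soma_rc: tuple[int, int] = (0, 0)
    target_mean_nm: float = 62.7
    target_cv: float = 0.36
    inside: np.ndarray | None = None  # bool mask; None = all inside

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline_nm, dtype=float)
        v = np.asarray(self.vf_pct, dtype=float)
        if b.shape != v.shape or b.ndim != 2:
            raise ValueError("baseline and VF fields must be 2-D and matching")
        if np.any(b <= 0):
            raise ValueError("baselines must be > 0")
        if np.any(v < 0) or np.any(v > 100):
            raise ValueError("volume fractions must lie in (0, 100]")
        object.__setattr__(self, "baseline_nm", b)
        object.__setattr__(self, "vf_pct", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.baseline_nm.shape

    @property
    def inside_mask(self) -> np.ndarray:
        if self.inside is None:
            return np.ones(self.shape, dtype=bool)
        return np.asarray(self.inside, dtype=bool)


def generate_baseline_field(
    shape: tuple[int, int] = (8, 8),
    mean_nm: float = 62.7,
    cv: float = 0.36,
    roi_size_um: float = 5.0,
    vf_length_um: float = 40.0,
    vf_floor_pct: float = 35.0,
    cell_radius_um: float | None = None,
    seed=None,
) -> CellModel:
    """Log-normal per-ROI resting [Ca2+] with requested mean/CV; VF field
    decays exponentially from the soma (grid centre) with space constant
    ``vf_length_um`` down to ``vf_floor_pct``. ROIs whose centre lies
    farther than ``cell_radius_um`` from the soma are outside the cell
    (VF forced to ~0, photon rate zero)."""
    if mean_nm <= 0 or cv < 0:
        raise ValueError("target mean must be > 0 and CV >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    if cv == 0:
        baseline = np.full(shape, mean_nm)
    else:
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean_nm) - sigma2 / 2
        baseline = rng.lognormal(mu, np.sqrt(sigma2), size=shape)
    soma = (rows // 2, cols // 2)
    rr, cc = np.indices(shape)
    dist_um = np.hypot(rr - soma[0], cc - soma[1]) * roi_size_um
    vf = np.maximum(100.0 * np.exp(-dist_um / vf_length_um), vf_floor_pct)
    vf[soma] = 100.0
    inside = None
    if cell_radius_um is not None:
        inside = dist_um <= cell_radius_um
        vf = np.where(inside, vf, 1e-6)
    return CellModel(baseline, vf, roi_size_um, soma, mean_nm, cv, inside)


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth rule linking local baseline to true amplitude.

    ``beta_amp`` is the fractional amplitude change per fractional baseline
    deviation from the cell mean (negative = anti-directional, the
    store-dependent signature). Peak is always baseline + amplitude, so
    beta_peak is implied. ``mode`` selects the generative rule:
    linear-in-baseline (store_dependent), baseline-independent
    (store_independent), or the Nernst store driving-force model.
    """

    beta_amp: float = -0.5
    a0_nm: float = 60.0
    noise_cv: float = 0.2
    mode: str = "store_dependent"
    store_ca_nm: float = 300.0
    v_store_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.a0_nm <= 0:
            raise ValueError("amplitude scale must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.mode not in ("store_dependent", "store_independent",
                             "driving_force_model"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")

    def true_amplitudes(self, baselines: np.ndarray, mean_nm: float,
                        rng: np.random.Generator) -> np.ndarray:
        b = np.asarray(baselines, dtype=float)
        if self.mode == "store_independent":
            det = np.full(b.shape, self.a0_nm)
        elif self.mode == "driving_force_model":
            df = np.array([biophysics.store_df(bi, self.store_ca_nm,
                                               self.v_store_mv) for bi in b.ravel()])
            df_ref = biophysics.store_df(mean_nm, self.store_ca_nm,
                                         self.v_store_mv)
            det = (self.a0_nm * np.clip(df, 0, None) / df_ref).reshape(b.shape)
        else:
            det = self.a0_nm * (1.0 + self.beta_amp * (b - mean_nm) / mean_nm)
        if self.noise_cv > 0:
            sigma2 = np.log1p(self.noise_cv**2)
            noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=b.shape)
        else:
            noise = 1.0
        return np.clip(det, 0.0, None) * noise


@dataclass(frozen=True)
class TransientKernel:
    """Difference-of-exponentials waveform, normalized to unit peak."""

    rise_s: float = 0.5
    decay_s: float = 3.0

    def __post_init__(self) -> None:
        if self.rise_s <= 0 or self.decay_s <= self.rise_s:
            raise ValueError("need 0 < rise < decay")

    @property
    def t_peak_s(self) -> float:
        r, d = self.rise_s, self.decay_s
        return r * d / (d - r) * np.log(d / r)

    def waveform(self, t_after_onset: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t_after_onset, dtype=float), 0.0, None)
        raw = np.exp(-t / self.decay_s) - np.exp(-t / self.rise_s)
        peak = (np.exp(-self.t_peak_s / self.decay_s)
                - np.exp(-self.t_peak_s / self.rise_s))
        return raw / peak


# stimulus descriptors ------------------------------------------------------


@dataclass(frozen=True)
class Evoked:
    """One agonist-puff transient on every ROI at ``t_stim_s``."""

    t_stim_s: float


@dataclass(frozen=True)
class Spontaneous:
    """Per-ROI Poisson process of events."""

    rate_per_min: float = 1.40


@dataclass(frozen=True)
class LocomotionCoupled:
    """Events time-locked to running bouts with probability ``p_assoc``."""

    speed_t_s: np.ndarray
    speed_cm_s: np.ndarray
    rate_per_min: float = 1.40
    p_assoc: float = 0.9
    window_s: float = 6.0
    speed_threshold_cm_s: float = 1.0


def generate_transients(
    cell: CellModel,
    coupling: CouplingSpec,
    stimulus,
    duration_s: float,
    frame_interval_s: float = 1.0 / 3.0,
    kernel: TransientKernel = TransientKernel(),
    seed=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """True Ca(t) per ROI plus the ground-truth event table.

    Returns ``(ca_movie, events)`` with ``ca_movie`` of shape
    (n_frames, rows, cols) in nM and ``events`` holding one row per event:
    roi_row, roi_col, t_peak_s, baseline_nm, amplitude_nm, peak_nm.
    Event times are kernel *peak* times.
    """
    rng = np.random.default_rng(seed)
    rows, cols = cell.shape
    n_frames = int(round(duration_s / frame_interval_s))
    t = np.arange(n_frames) * frame_interval_s
    movie = np.broadcast_to(cell.baseline_nm, (n_frames, rows, cols)).copy()
    mean_b = float(cell.baseline_nm[cell.inside_mask].mean())

    records = []
    if isinstance(stimulus, Evoked):
        amps = coupling.true_amplitudes(cell.baseline_nm, mean_b, rng)
        onset = stimulus.t_stim_s
        wave = kernel.waveform(t - onset)
        movie = movie + wave[:, None, None] * amps[None, :, :]
        t_peak = onset + kernel.t_peak_s
        for r in range(rows):
            for c in range(cols):
                records.append((r, c, t_peak, cell.baseline_nm[r, c],
                                amps[r, c]))
    elif isinstance(stimulus, (Spontaneous, LocomotionCoupled)):
        rate_s = stimulus.rate_per_min / 60.0
        for r in range(rows):
            for c in range(cols):
                n_ev = rng.poisson(rate_s * duration_s)
                if n_ev == 0:
                    continue
                peaks = _event_peak_times(stimulus, n_ev, duration_s, rng)
                amps = coupling.true_amplitudes(
                    np.full(n_ev, cell.baseline_nm[r, c]), mean_b, rng)
                for tp, a in zip(peaks, amps):
                    onset = tp - kernel.t_peak_s
                    movie[:, r, c] += a * kernel.waveform(t - onset)
                    records.append((r, c, tp, cell.baseline_nm[r, c], a))
    else:
        raise TypeError(f"unknown stimulus {stimulus!r}")

    events = pd.DataFrame(records, columns=[
        "roi_row", "roi_col", "t_peak_s", "baseline_nm", "amplitude_nm"])
    events["peak_nm"] = events["baseline_nm"] + events["amplitude_nm"]
    return movie, events


def _event_peak_times(stimulus, n_ev: int, duration_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    if isinstance(stimulus, Spontaneous):
        return rng.uniform(0, duration_s, size=n_ev)
    # locomotion-coupled: peaks land inside running periods for a fraction
    fast = stimulus.speed_cm_s > stimulus.speed_threshold_cm_s
    fast_times = stimulus.speed_t_s[fast]
    out = np.empty(n_ev)
    for i in range(n_ev):
        if fast_times.size and rng.random() < stimulus.p_assoc:
            out[i] = np.clip(float(rng.choice(fast_times)), 0, duration_s)
        else:
            out[i] = rng.uniform(0, duration_s)
    return out


# ---------------------------------------------------------------------------
# rendering: FLIM photon stacks


@dataclass(frozen=True)
class AcquisitionSpec:
    """Photon rates and geometry of the rendered recordings."""

    frame_interval_s: float = 1.0 / 3.0
    # sized so the dimmest in-cell ROIs (VF floor) still collect ~3x the
    # 1500-photon cutoff: the filter separates inside from outside the
    # dye-filled cell rather than grazing in-cell ROIs
    photons_per_roi_per_window: float = 12000.0
    window_s: float = 0.6
    pixels_per_roi_side: int = 4
    # intensity (ratiometric) mode: per-pixel photon gains sized so a
    # full-VF ROI collects ~10^3 photons per frame, the working regime of
    # frame-scanned two-photon GECI recordings
    gain_g: float = 150.0
    gain_t: float = 180.0
    background_g: float = 8.0
    background_t: float = 8.0
    read_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be > 0")
        if self.photons_per_roi_per_window < 0 or self.gain_g < 0 or self.gain_t < 0:
            raise ValueError("rates and gains must be >= 0")


def render_flim_movie(
    ca_movie_nm: np.ndarray,
    cell: CellModel,
    indicator: TwoStateIndicator = INTRA_INDICATOR,
    acquisition: AcquisitionSpec = AcquisitionSpec(),
    ca_ref_nm: float = 62.7,
    seed=None,
) -> TcspcStack:
    """Render a TCSPC photon stack from a true Ca movie.

    Per-pixel expected photons scale with local VF and with the indicator's
    Ca-dependent brightness (referenced to ``ca_ref_nm``); the microtime
    distribution is the occupancy-weighted mix of the free/bound decay
    signatures at the local true [Ca2+]; counts are Poisson.
    """
    rng = np.random.default_rng(seed)
    ca = np.asarray(ca_movie_nm, dtype=float)
    n_frames, rows, cols = ca.shape
    if (rows, cols) != cell.shape:
        raise ValueError("Ca movie grid does not match cell grid")
    k = acquisition.pixels_per_roi_side
    p_free, p_bound = indicator.state_bin_probabilities()
    n_bins = p_free.size

    rate_px = (acquisition.photons_per_roi_per_window
               * (acquisition.frame_interval_s / acquisition.window_s)
               / k**2)
    budget = (rate_px * (cell.vf_pct / 100.0)[None, :, :]
              * indicator.brightness(ca) / indicator.brightness(ca_ref_nm))
    w_bound = indicator.photon_fraction_bound(ca)

    mu_roi = budget[..., None] * ((1.0 - w_bound)[..., None] * p_free
                                  + w_bound[..., None] * p_bound)
    # expand each ROI to k x k pixels
    mu_px = np.repeat(np.repeat(mu_roi, k, axis=1), k, axis=2)
    photons = rng.poisson(mu_px).astype(np.int64)
    return TcspcStack(
        photons=photons,
        microtime_bin_ns=indicator.bin_width_ns,
        frame_interval_s=acquisition.frame_interval_s,
        pixel_um=cell.roi_size_um / k,
        irf_center_ns=indicator.t0_ns,
        irf_sigma_ns=indicator.irf_sigma_ns,
        record_length_ns=indicator.record_length_ns,
        meta={"n_bins": int(n_bins), "roi_size_um": cell.roi_size_um},
    )


# ---------------------------------------------------------------------------
# rendering: two-channel (G/T) intensity movies


@dataclass(frozen=True)
class GtIndicator:
    """Saturating intensity response of the Ca-sensitive channel:
    F(Ca) = f_min + (f_max - f_min) * Ca^h / (Ca^h + K_D^h)."""

    kd_nm: float = 200.0
    hill_h: float = 1.0
    f_min: float = 0.1
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_nm <= 0 or self.hill_h <= 0:
            raise ValueError("K_D and Hill slope must be > 0")
        if self.f_max < self.f_min:
            raise ValueError("f_max must be >= f_min")

    def response(self, ca_nm):
        ca = np.asarray(ca_nm, dtype=float)
        occ = ca**self.hill_h / (ca**self.hill_h + self.kd_nm**self.hill_h)
        return self.f_min + (self.f_max - self.f_min) * occ


def render_ratiometric_movie(
    ca_movie_nm: np.ndarray,
    cell: CellModel,
    indicator: GtIndicator = GtIndicator(),
    acquisition: AcquisitionSpec = AcquisitionSpec(),
    seed=None,
) -> np.ndarray:
    """Two-channel movie (frame, channel[G,T], y, x) in photon counts.

    G ~ Poisson(gain_g * VF * F(Ca)) + background + read noise; T is
    Ca-insensitive. After background subtraction the expected G/T ratio is
    independent of VF — the point of the ratiometric design.
    """
    rng = np.random.default_rng(seed)
    ca = np.asarray(ca_movie_nm, dtype=float)
    n_frames, rows, cols = ca.shape
    k = acquisition.pixels_per_roi_side
    vf = (cell.vf_pct / 100.0)[None, :, :]
    g_sig = acquisition.gain_g * vf * indicator.response(ca)
    t_sig = acquisition.gain_t * vf * np.ones_like(ca)
    g_px = np.repeat(np.repeat(g_sig, k, axis=1), k, axis=2)
    t_px = np.repeat(np.repeat(t_sig, k, axis=1), k, axis=2)
    movie = np.stack([
        rng.poisson(g_px) + acquisition.background_g,
        rng.poisson(t_px) + acquisition.background_t,
    ], axis=1).astype(float)
    if acquisition.read_noise_sd > 0:
        movie += rng.normal(0, acquisition.read_noise_sd, size=movie.shape)
    return movie


# ---------------------------------------------------------------------------
# uncaging and locomotion


def apply_uncaging(
    cell: CellModel,
    buffers: Sequence[biophysics.BufferSpec],
    photolysed_fraction: float,
    endogenous_kappa: float = 20.0,
) -> CellModel:
    """Shift every ROI's resting [Ca2+] by photolysing the photoactivatable
    buffers at the given fraction.

    Each ROI's total Ca is first chosen so that the *pre*-photolysis
    equilibrium reproduces its current baseline (endogenous fixed buffering
    enters as a linear kappa); photolysis then swaps the stated fraction of
    each buffer to its post-photolysis K_D and the equilibrium is re-solved.
    Diazo-2 parameter sets lower the field; NP-EGTA-style cages raise it.
    """
    buffers = tuple(buffers)
    endo = biophysics.BufferSpec("endogenous", total_um=endogenous_kappa * 10.0,
                                 kd_nm=10000.0)
    pre_buffers = buffers + (endo,)
    new_baseline = np.empty(cell.shape)
    for idx, b in np.ndenumerate(cell.baseline_nm):
        total = biophysics.total_ca_for_free(b, pre_buffers)
        post = tuple(
            replace(buf, photolysed_fraction=photolysed_fraction)
            if buf.kd_post_nm is not None else buf
            for buf in pre_buffers
        )
        new_baseline[idx] = biophysics.free_ca_equilibrium(
            biophysics.BufferSystem(total, post))
    return replace(cell, baseline_nm=new_baseline)


def generate_locomotion_trace(
    duration_s: float,
    bout_rate_per_min: float = 1.5,
    mean_speed_cm_min: float = 65.4,
    sd_speed_cm_min: float = 18.3,
    mean_bout_s: float = 12.0,
    min_bout_s: float = 6.0,
    sample_hz: float = 20.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Treadmill speed trace at 20 Hz: alternating rest and running bouts.

    Bout mean speeds are drawn from the stated moving-speed distribution
    truncated below at 60 cm/min (1 cm/s) — locomotion is *defined* by the
    >1 cm/s criterion, so speeds while moving sit above it by construction.
    Bout lengths are ``min_bout_s`` plus an exponential; the minimum spans
    two 3-s analysis bins, so every bout covers at least one full bin and
    remains detectable after speed binning.
    Returns (t_s, speed_cm_s, bout_intervals).
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_hz))
    t = np.arange(n) / sample_hz
    speed = np.zeros(n)
    bouts: list[tuple[float, float]] = []
    if bout_rate_per_min <= 0:
        return t, speed, bouts
    mean_gap_s = 60.0 / bout_rate_per_min
    pos = float(rng.exponential(mean_gap_s))
    floor_cm_s = 1.05
    while pos < duration_s:
        length = min_bout_s + rng.exponential(
            max(mean_bout_s - min_bout_s, 1e-9))
        end = min(pos + length, duration_s)
        v = -1.0
        while v < 60.0:  # truncation: moving means >1 cm/s
            v = rng.normal(mean_speed_cm_min, sd_speed_cm_min)
        v_cm_s = v / 60.0
        sl = slice(int(round(pos * sample_hz)), int(round(end * sample_hz)))
        jitter = rng.normal(0, 0.05 * v_cm_s, size=len(range(*sl.indices(n))))
        speed[sl] = np.clip(v_cm_s + jitter, floor_cm_s, None)
        bouts.append((pos, end))
        pos = end + rng.exponential(mean_gap_s)
    return t, speed, bouts
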