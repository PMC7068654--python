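"""FLIM photon-count-ratio quantification of [Ca2+].

The decay of a Ca-sensitive dye (OGB family) is modelled as a sum of
exponentials convolved with a Gaussian instrument response (IRF). The
lifetime surrogate used throughout is the photon-count ratio R = C1/C2,
the number of photons detected in an early vs a late microtime window:
it is robust at the photon budgets of in-tissue imaging, where full
reconvolution fits are noisy.

Calibration maps R to free [Ca2+] through a Hill curve fitted to a cuvette
series; a correction map compensates for the small mismatch between the
dye's decay constants inside cells and in the calibration solution by
translating intracellular ratios to calibration-equivalent ratios before
the Hill inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import erfc, erfcx


class UndefinedRatioError(ZeroDivisionError):
    """No photons in the denominator window."""


class NonMonotoneMapError(ValueError):
    """A ratio translation map came out non-invertible."""


# ---------------------------------------------------------------------------
# decay model


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential fluorescence decay with a Gaussian IRF.

    ``amplitudes`` are decay amplitudes A_i (the prefactors of
    A_i exp(-t/tau_i)); the photon fraction of component i is
    A_i tau_i / sum_j A_j tau_j.
    """

    amplitudes: tuple[float, ...]
    taus_ns: tuple[float, ...]
    t0_ns: float = 1.5
    irf_sigma_ns: float = 0.15
    record_length_ns: float = 12.5
    bin_width_ns: float = 0.1

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.taus_ns, dtype=float)
        if a.shape != t.shape or a.ndim != 1:
            raise ValueError("amplitudes and taus must be equal-length 1-D")
        if np.any(t <= 0):
            raise ValueError("all decay constants must be > 0")
        if np.any(a < 0) or not np.any(a > 0):
            raise ValueError("amplitudes must be >= 0 with at least one > 0")
        if self.irf_sigma_ns < 0 or self.bin_width_ns <= 0:
            raise ValueError("invalid IRF sigma or bin width")
        n = self.record_length_ns / self.bin_width_ns
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError("record length must be an integer number of bins")
        object.__setattr__(self, "amplitudes", tuple(float(x) for x in a))
        object.__setattr__(self, "taus_ns", tuple(float(x) for x in t))

    @property
    def n_bins(self) -> int:
        return int(round(self.record_length_ns / self.bin_width_ns))

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_ns

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


def _emg_cdf(t: np.ndarray, tau: float, t0: float, sigma: float) -> np.ndarray:
    """CDF of an exponential decay (constant tau, origin t0) convolved with a
    Gaussian IRF of width sigma, evaluated stably via erfcx."""
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        x = np.clip((t - t0) / tau, 0.0, None)
        return np.where(t >= t0, 1.0 - np.exp(-x), 0.0)
    u = (t - t0) / sigma
    k = sigma / tau
    # F = Phi(u) - exp(k^2/2 - u k) Phi(u - k); the exponential term is
    # evaluated via erfcx where the plain form would overflow (u << 0).
    term2 = np.empty_like(u)
    early = u < k
    ue = u[early]
    term2[early] = 0.5 * erfcx((k - ue) / np.sqrt(2)) * np.exp(-0.5 * ue**2)
    ul = u[~early]
    term2[~early] = np.exp(0.5 * k**2 - ul * k) * 0.5 * erfc((k - ul) / np.sqrt(2))
    return 0.5 * erfc(-u / np.sqrt(2)) - term2


def expected_bin_probabilities(model: DecayModel) -> np.ndarray:
    """Probability of a detected photon falling in each microtime bin,
    normalized over the record (truncation renormalized per component)."""
    edges = model.bin_edges()
    a = np.asarray(model.amplitudes)
    taus = np.asarray(model.taus_ns)
    weights = a * taus
    weights = weights / weights.sum()
    p = np.zeros(model.n_bins)
    for w, tau in zip(weights, taus):
        if w == 0:
            continue
        cdf = _emg_cdf(edges, tau, model.t0_ns, model.irf_sigma_ns)
        span = cdf[-1] - cdf[0]
        if span <= 0:
            raise ValueError("decay has no mass inside the record")
        p += w * np.diff(cdf) / span
    return p


def simulate_decay_histogram(
    model: DecayModel, photon_budget: float, seed=None
) -> np.ndarray:
    """Poisson TCSPC histogram around the IRF-convolved decay, scaled so the
    expected total equals ``photon_budget``."""
    if photon_budget < 0:
        raise ValueError("photon budget must be >= 0")
    rng = np.random.default_rng(seed)
    if photon_budget == 0:
        return np.zeros(model.n_bins, dtype=np.int64)
    mu = expected_bin_probabilities(model) * photon_budget
    return rng.poisson(mu).astype(np.int64)


# ---------------------------------------------------------------------------
# windows and the photon-count ratio


@dataclass(frozen=True)
class LifetimeWindows:
    """Early (C1) and late (C2) microtime windows, in ns."""

    w1_start: float
    w1_end: float
    w2_start: float
    w2_end: float

    def __post_init__(self) -> None:
        if not (self.w1_start < self.w1_end <= self.w2_start < self.w2_end):
            raise ValueError("windows must be ordered and non-overlapping")

    def masks(self, bin_midpoints_ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = np.asarray(bin_midpoints_ns)
        m1 = (m >= self.w1_start) & (m < self.w1_end)
        m2 = (m >= self.w2_start) & (m < self.w2_end)
        return m1, m2

    def to_dict(self) -> dict:
        return {"w1_start": self.w1_start, "w1_end": self.w1_end,
                "w2_start": self.w2_start, "w2_end": self.w2_end}


DEFAULT_WINDOWS = LifetimeWindows(0.0, 2.0, 2.0, 12.5)


def photon_count_ratio(
    counts: np.ndarray, windows: LifetimeWindows, bin_width_ns: float
):
    """R = C1/C2: photons whose bin midpoint lies in window 1 over window 2.

    ``counts`` may be N-D with microtime as the last axis; the ratio is
    computed along that axis. A zero C2 raises for scalar input and yields
    NaN for array input (callers discard those time bins).
    """
    counts = np.asarray(counts)
    n_bins = counts.shape[-1]
    mid = (np.arange(n_bins) + 0.5) * bin_width_ns
    m1, m2 = windows.masks(mid)
    c1 = counts[..., m1].sum(axis=-1).astype(float)
    c2 = counts[..., m2].sum(axis=-1).astype(float)
    if c1.ndim == 0:
        if c2 == 0:
            raise UndefinedRatioError("no photons in the late window")
        return float(c1 / c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(c2 > 0, c1 / np.where(c2 > 0, c2, 1.0), np.nan)
    return r


def expected_ratio(model: DecayModel, windows: LifetimeWindows) -> float:
    """Noiseless photon-count ratio implied by a decay model (the infinite-
    photon limit of :func:`photon_count_ratio`)."""
    p = expected_bin_probabilities(model)
    m1, m2 = windows.masks(model.bin_midpoints())
    c2 = p[m2].sum()
    if c2 <= 0:
        raise UndefinedRatioError("late window has no expected photons")
    return float(p[m1].sum() / c2)


# ---------------------------------------------------------------------------
# Hill calibration


@dataclass(frozen=True)
class CalibrationCurve:
    """Hill mapping between photon-count ratio and free [Ca2+].

    ratio(Ca) = r_at_zero + (r_at_sat - r_at_zero) * Ca^h / (Ca^h + k^h).
    ``r_at_zero``/``r_at_sat`` are the ratios at zero and saturating Ca, so
    the orientation (whether R rises or falls with Ca) is carried by their
    order; ``r_min``/``r_max`` are the sorted bounds.
    """

    r_at_zero: float
    r_at_sat: float
    k_app_nm: float
    hill_h: float
    windows: LifetimeWindows = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if self.k_app_nm <= 0 or self.hill_h <= 0:
            raise ValueError("k_app and Hill h must be > 0")
        if self.r_at_zero == self.r_at_sat:
            raise ValueError("degenerate curve: no dynamic range")

    @property
    def r_min(self) -> float:
        return min(self.r_at_zero, self.r_at_sat)

    @property
    def r_max(self) -> float:
        return max(self.r_at_zero, self.r_at_sat)

    @property
    def increasing(self) -> bool:
        return self.r_at_sat > self.r_at_zero

    def forward(self, ca_nm):
        ca = np.asarray(ca_nm, dtype=float)
        occ = ca**self.hill_h / (ca**self.hill_h + self.k_app_nm**self.hill_h)
        out = self.r_at_zero + (self.r_at_sat - self.r_at_zero) * occ
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"r_at_zero": self.r_at_zero, "r_at_sat": self.r_at_sat,
                "k_app_nM": self.k_app_nm, "hill_h": self.hill_h,
                "windows_ns": self.windows.to_dict()}


def fit_calibration(
    ca_nm, ratios, windows: LifetimeWindows = DEFAULT_WINDOWS
) -> tuple[CalibrationCurve, dict]:
    """Least-squares Hill fit of a (free [Ca2+], ratio) calibration series.

    Returns the curve and residual diagnostics; a series that is
    non-monotone beyond its noise scatter sets ``diagnostics['monotone']``
    False (fit-quality warning, not an error).
    """
    ca = np.asarray(ca_nm, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if ca.shape != r.shape or ca.ndim != 1:
        raise ValueError("ca and ratio series must be equal-length 1-D")
    if np.unique(ca).size < 4:
        raise ValueError("need >= 4 distinct [Ca2+] levels")
    if np.any(ca < 0):
        raise ValueError("[Ca2+] must be >= 0")
    if np.ptp(r) == 0:
        raise ValueError("degenerate series: all ratios identical")

    order = np.argsort(ca)
    ca_s, r_s = ca[order], r[order]
    span = np.ptp(r_s)
    geo_mid = np.sqrt(max(ca_s[ca_s > 0].min(), 1e-3) * ca_s.max())

    def hill(c, r0, rinf, k, h):
        c = np.asarray(c, dtype=float)
        occ = np.where(c > 0, c**h / (c**h + k**h), 0.0)
        return r0 + (rinf - r0) * occ

    p0 = (r_s[0], r_s[-1], geo_mid, 1.0)
    popt, _ = curve_fit(
        hill, ca_s, r_s, p0=p0, maxfev=20000,
        bounds=([-np.inf, -np.inf, 1e-6, 0.05], [np.inf, np.inf, 1e9, 20.0]),
    )
    curve = CalibrationCurve(*popt[:2], k_app_nm=float(popt[2]),
                             hill_h=float(popt[3]), windows=windows)
    resid = r_s - curve.forward(ca_s)
    diffs = np.diff(r_s)
    monotone = bool(np.all(diffs >= -0.05 * span) or np.all(diffs <= 0.05 * span))
    diagnostics = {
        "residuals": resid,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "monotone": monotone,
    }
    return curve, diagnostics


# ---------------------------------------------------------------------------
# decay-constant correction map


@dataclass(frozen=True)
class TauCorrectionMap:
    """Monotone pairing (intracellular ratio -> calibration ratio).

    Built by simulating noiseless decays over a grid of component-amplitude
    combinations under both tau sets and pairing the resulting ratios;
    applied by linear interpolation (edge-clamped outside the domain).
    """

    ratio_intra: tuple[float, ...]
    ratio_calib: tuple[float, ...]

    def __post_init__(self) -> None:
        ri = np.asarray(self.ratio_intra)
        rc = np.asarray(self.ratio_calib)
        if ri.shape != rc.shape or ri.size < 2:
            raise ValueError("need >= 2 paired ratios")
        di, dc = np.diff(ri), np.diff(rc)
        if not (np.all(di > 0) or np.all(di < 0)):
            raise NonMonotoneMapError("intracellular column not strictly monotone")
        if not (np.all(dc > 0) or np.all(dc < 0)):
            raise NonMonotoneMapError("calibration column not strictly monotone")
        if np.sign(di[0]) != np.sign(dc[0]):
            raise NonMonotoneMapError("columns run in opposite directions")

    def apply(self, ratio):
        ri = np.asarray(self.ratio_intra)
        rc = np.asarray(self.ratio_calib)
        if ri[0] > ri[-1]:
            ri, rc = ri[::-1], rc[::-1]
        out = np.interp(np.asarray(ratio, dtype=float), ri, rc)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def identity(cls) -> "TauCorrectionMap":
        return cls((0.0, 1e6), (0.0, 1e6))

    def to_table(self, max_knots: int = 200) -> list[list[float]]:
        """Knot table for serialization, thinned to ``max_knots`` (the
        endpoints are always kept; linear interpolation between surviving
        knots reproduces the map to well below measurement noise)."""
        n = len(self.ratio_intra)
        idx = np.unique(np.linspace(0, n - 1, min(n, max_knots)).astype(int))
        return [[round(self.ratio_intra[i], 6), round(self.ratio_calib[i], 6)]
                for i in idx]


def _amplitude_simplex(n_components: int, resolution: int) -> np.ndarray:
    """All non-negative amplitude combinations on the unit simplex with step
    1/resolution (the all-zero corner excluded)."""
    grids = np.meshgrid(*[np.arange(resolution + 1)] * n_components, indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    combos = combos[combos.sum(axis=1) > 0]
    combos = combos / combos.sum(axis=1, keepdims=True)
    return np.unique(np.round(combos, 12), axis=0)


def build_tau_correction(
    intra_taus_ns,
    calib_taus_ns,
    windows: LifetimeWindows = DEFAULT_WINDOWS,
    template: DecayModel | None = None,
    resolution: int = 12,
    n_knots: int = 40,
) -> TauCorrectionMap:
    """Build the intracellular->calibration ratio translation.

    For every amplitude combination on the simplex the noiseless expected
    ratio is computed under the intracellular and the calibration decay
    constants. With more than two components the pairs form a narrow band
    rather than a curve, so they are pooled into ``n_knots`` quantile bins
    of the intracellular ratio and bin means are paired; a non-monotone
    binned pairing raises :class:`NonMonotoneMapError`.
    """
    intra = tuple(float(t) for t in intra_taus_ns)
    calib = tuple(float(t) for t in calib_taus_ns)
    if len(intra) != len(calib):
        raise ValueError("tau sets must have the same number of components")
    if template is None:
        template = DecayModel((1.0,) * len(intra), intra)
    combos = _amplitude_simplex(len(intra), resolution)

    def ratios_for(taus: tuple[float, ...]) -> np.ndarray:
        out = np.empty(len(combos))
        for i, amps in enumerate(combos):
            m = DecayModel(tuple(amps), taus, template.t0_ns,
                           template.irf_sigma_ns, template.record_length_ns,
                           template.bin_width_ns)
            out[i] = expected_ratio(m, windows)
        return out

    r_intra = ratios_for(intra)
    r_calib = ratios_for(calib)
    order = np.argsort(r_intra)
    r_intra, r_calib = r_intra[order], r_calib[order]

    # collapse exact ties in the intracellular ratio
    uniq, inv = np.unique(np.round(r_intra, 12), return_inverse=True)
    rc_mean = np.bincount(inv, weights=r_calib) / np.bincount(inv)
    if np.all(np.diff(rc_mean) > 0) or np.all(np.diff(rc_mean) < 0):
        # exact functional pairing (always the case for 2 components)
        return TauCorrectionMap(tuple(uniq), tuple(rc_mean))

    # >2 components: the pairs form a band; pool into quantile bins of the
    # intracellular ratio and pair bin means
    n_knots = min(n_knots, uniq.size)
    edges = np.linspace(0, uniq.size, n_knots + 1).astype(int)
    ki, kc = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            ki.append(uniq[lo:hi].mean())
            kc.append(rc_mean[lo:hi].mean())
    return TauCorrectionMap(tuple(ki), tuple(kc))


def ratio_to_ca(
    curve: CalibrationCurve,
    ratio,
    correction: TauCorrectionMap | None = None,
    clamp_eps: float = 1e-3,
):
    """Convert measured photon-count ratios to [Ca2+] (nM).

    The correction map (if any) translates intracellular ratios to
    calibration-equivalent ratios first; the Hill curve is then inverted.
    Ratios outside the curve's open range are clamped ``clamp_eps`` (as a
    fraction of the dynamic range) inside it and flagged.

    Returns ``(ca_nm, clamped)``; scalar in, scalar out. NaN propagates.
    """
    r = np.asarray(ratio, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    if correction is not None:
        valid = np.isfinite(r)
        r[valid] = np.atleast_1d(correction.apply(r[valid]))
    span = curve.r_max - curve.r_min
    lo = curve.r_min + clamp_eps * span
    hi = curve.r_max - clamp_eps * span
    clamped = np.zeros(r.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        below, above = r < lo, r > hi
    clamped |= below | above
    r = np.clip(r, lo, hi)
    occ = (r - curve.r_at_zero) / (curve.r_at_sat - curve.r_at_zero)
    ca = curve.k_app_nm * (occ / (1.0 - occ)) ** (1.0 / curve.hill_h)
    ca = np.where(np.isfinite(r), ca, np.nan)
    if scalar:
        return float(ca[0]), bool(clamped[0])
    return ca, clamped


# ---------------------------------------------------------------------------
# amplitude-weighted lifetime and reconvolution fitting


def amplitude_weighted_tau(amplitudes, taus_ns) -> float:
    """tau = sum(A_i tau_i) / sum(A_i)."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(taus_ns, dtype=float)
    if a.shape != t.shape:
        raise ValueError("amplitude and tau vectors must match")
    if np.any(a < 0) or np.any(t <= 0):
        raise ValueError("amplitudes must be >= 0 and taus > 0")
    s = a.sum()
    if s <= 0:
        raise ValueError("at least one amplitude must be > 0")
    return float((a * t).sum() / s)


@dataclass(frozen=True)
class ReconvolutionFit:
    """Result of an IRF-reconvolution multi-exponential fit, components in
    ascending-tau order. ``success`` False means non-convergence: the
    parameters are the best iterate, not a usable estimate."""

    amplitudes: tuple[float, ...]
    taus_ns: tuple[float, ...]
    success: bool
    objective: str
    nll: float
    message: str

    @property
    def tau_amplitude_weighted_ns(self) -> float:
        return amplitude_weighted_tau(self.amplitudes, self.taus_ns)


def fit_decay_reconvolution(
    counts: np.ndarray,
    t0_ns: float,
    irf_sigma_ns: float,
    bin_width_ns: float,
    n_components: int = 3,
    min_counts: float = 1e4,
    objective: str = "poisson",
) -> ReconvolutionFit:
    """Fit an IRF-convolved multi-exponential to a TCSPC histogram.

    Default objective is the Poisson negative log-likelihood (the correct
    TCSPC noise model); "wls" uses weighted least squares with Poisson
    weights. Free parameters are log photon-fraction weights and log taus;
    reported amplitudes are decay amplitudes A_i (photon fraction / tau_i),
    normalized to sum 1.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total < min_counts:
        raise ValueError(
            f"total counts {total:.0f} below minimum {min_counts:.0f}")
    if objective not in ("poisson", "wls"):
        raise ValueError("objective must be 'poisson' or 'wls'")
    n_bins = counts.size
    record = n_bins * bin_width_ns

    mid = (np.arange(n_bins) + 0.5) * bin_width_ns
    mean_arrival = float((counts * mid).sum() / total) - t0_ns
    mean_arrival = max(mean_arrival, 0.2)
    tau_init = np.geomspace(mean_arrival / 3, mean_arrival * 2, n_components)

    def probs(theta: np.ndarray) -> np.ndarray:
        logw, logtau = theta[:n_components], theta[n_components:]
        w = np.exp(logw - logw.max())
        w = w / w.sum()
        taus = np.exp(logtau)
        p = np.zeros(n_bins)
        edges = np.arange(n_bins + 1) * bin_width_ns
        for wi, tau in zip(w, taus):
            cdf = _emg_cdf(edges, tau, t0_ns, irf_sigma_ns)
            span = cdf[-1] - cdf[0]
            p += wi * np.diff(cdf) / max(span, 1e-300)
        return np.clip(p, 1e-300, None)

    if objective == "poisson":
        def loss(theta):
            mu = probs(theta) * total
            return float(np.sum(mu - counts * np.log(mu)))
    else:
        wts = 1.0 / np.clip(counts, 1.0, None)

        def loss(theta):
            mu = probs(theta) * total
            return float(np.sum(wts * (counts - mu) ** 2))

    theta0 = np.concatenate([np.zeros(n_components), np.log(tau_init)])
    bounds = [(None, None)] * n_components + [
        (np.log(bin_width_ns / 10), np.log(record * 5))] * n_components
    res = minimize(loss, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-12})

    logw, logtau = res.x[:n_components], res.x[n_components:]
    w = np.exp(logw - logw.max())
    w = w / w.sum()
    taus = np.exp(logtau)
    amps = w / taus
    amps = amps / amps.sum()
    order = np.argsort(taus)
    return ReconvolutionFit(
        amplitudes=tuple(float(a) for a in amps[order]),
        taus_ns=tuple(float(t) for t in taus[order]),
        success=bool(res.success),
        objective=objective,
        nll=float(res.fun),
        message=str(res.message),
    )


def select_window_boundary(
    model_lo: DecayModel,
    model_hi: DecayModel,
    n_candidates: int = 40,
) -> LifetimeWindows:
    """Choose the C1/C2 boundary that best separates two decay signatures
    (e.g. the Ca-free and Ca-bound states of the dye).

    The score is the log-ratio separation |ln R_lo - ln R_hi| divided by
    its Poisson standard error at unit photon budget (sqrt of 1/C1 + 1/C2,
    summed over the two states) -- raw separation alone would favour
    boundaries so late that the windows starve. This is how the default
    windows were picked; they are stored on every
    :class:`CalibrationCurve` so analyses remain self-describing.
    """
    record = model_lo.record_length_ns
    lo_b = model_lo.t0_ns + model_lo.bin_width_ns
    candidates = np.linspace(lo_b, record * 0.8, n_candidates)
    best, best_score = None, -np.inf
    for b in candidates:
        b = round(b / model_lo.bin_width_ns) * model_lo.bin_width_ns
        if not 0.0 < b < record:
            continue
        w = LifetimeWindows(0.0, b, b, record)
        try:
            sep = abs(np.log(expected_ratio(model_lo, w))
                      - np.log(expected_ratio(model_hi, w)))
        except (UndefinedRatioError, FloatingPointError):
            continue
        noise2 = 0.0
        for model in (model_lo, model_hi):
            p = expected_bin_probabilities(model)
            m1, m2 = w.masks(model.bin_midpoints())
            p1, p2 = p[m1].sum(), p[m2].sum()
            if p1 <= 0 or p2 <= 0:
                noise2 = np.inf
                break
            noise2 += 1.0 / p1 + 1.0 / p2
        score = sep / np.sqrt(noise2)
        if score > best_score:
            best, best_score = w, score
    if best is None:
        raise ValueError("no admissible boundary found")
    return best
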