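"""Mechanistic calcium calculations.

Nernst driving forces across the plasma membrane and store membrane, a
linearized store-cytosol equilibration model for transient peaks, and a
multi-buffer free-Ca2+ equilibrium solver used to parameterize chelator
(diazo-2 / NP-EGTA) uncaging experiments.

Conventions: concentrations are in nM unless a name says otherwise;
potentials are in mV, cytosol relative to the reference compartment;
temperature in K (default 307 K, ~34 C bath temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

R_GAS = 8.314462618  # J / (mol K), CODATA
FARADAY = 96485.33212  # C / mol, CODATA
CA_VALENCE = 2
DEFAULT_TEMPERATURE_K = 307.0


@dataclass(frozen=True)
class BufferSpec:
    """A single Ca2+ buffer species.

    ``kd_post_nm`` and ``photolysed_fraction`` describe photoactivatable
    buffers: after UV, a fraction of the total swaps from ``kd_nm`` to
    ``kd_post_nm`` (diazo-2: affinity increases; NP-EGTA: collapses).
    """

    name: str
    total_um: float
    kd_nm: float
    kd_post_nm: float | None = None
    photolysed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.total_um < 0:
            raise ValueError("buffer total must be >= 0")
        if self.kd_nm <= 0:
            raise ValueError("buffer K_D must be > 0")
        if self.kd_post_nm is not None and self.kd_post_nm <= 0:
            raise ValueError("post-photolysis K_D must be > 0")
        if not 0.0 <= self.photolysed_fraction <= 1.0:
            raise ValueError("photolysed fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BufferSystem:
    """Total Ca2+ plus a list of buffers, all well mixed at equilibrium."""

    ca_total_um: float
    buffers: tuple[BufferSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ca_total_um < 0:
            raise ValueError("total Ca must be >= 0")
        object.__setattr__(self, "buffers", tuple(self.buffers))


@dataclass(frozen=True)
class IonConditions:
    """Electro-chemical conditions for driving-force calculations."""

    temperature_k: float = DEFAULT_TEMPERATURE_K
    ca_out_mm: float = 2.0
    v_m_mv: float = -85.0
    ca_store_nm: float = 300.0e3
    v_store_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")
        if self.ca_out_mm <= 0 or self.ca_store_nm <= 0:
            raise ValueError("concentrations must be > 0")


def nernst_ca(ca_in_nm: float, ca_ref_nm: float,
              temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst equilibrium potential (mV) for Ca2+.

    E = RT/(2F) * ln(ca_ref / ca_in), positive when the reference
    compartment is Ca-richer than the cytosol.
    """
    if ca_in_nm <= 0 or ca_ref_nm <= 0:
        raise ValueError("concentrations must be > 0")
    e_volts = (R_GAS * temperature_k / (CA_VALENCE * FARADAY)) * np.log(
        ca_ref_nm / ca_in_nm
    )
    return float(e_volts * 1e3)


def extracellular_df_change(
    baseline_range_nm: tuple[float, float] = (30.0, 150.0),
    shift_nm: float = 50.0,
    conditions: IonConditions | None = None,
    n_grid: int = 201,
) -> float:
    """Maximum relative change (%) of the transmembrane Ca2+ driving force
    caused by shifting the resting [Ca2+] by ``shift_nm``.

    DF(c) = E_Ca(c; ca_out) - V_m. Because E depends on ln(1/c), the change
    is largest at the low end of the baseline range. Physiological resting
    shifts of ~50 nM move the extracellular driving force by only a few
    percent — too little to explain strong amplitude modulation.
    """
    if conditions is None:
        conditions = IonConditions()
    lo, hi = baseline_range_nm
    if lo <= 0 or hi <= lo:
        raise ValueError("baseline range must be positive and increasing")
    if shift_nm < 0:
        raise ValueError("shift must be >= 0")
    if shift_nm == 0:
        return 0.0
    ca_out_nm = conditions.ca_out_mm * 1e6
    grid = np.linspace(lo, hi, n_grid)

    def df(c: np.ndarray) -> np.ndarray:
        e = (R_GAS * conditions.temperature_k / (CA_VALENCE * FARADAY)) * np.log(
            ca_out_nm / c
        ) * 1e3
        return e - conditions.v_m_mv

    rel = np.abs(df(grid + shift_nm) - df(grid)) / df(grid) * 100.0
    return float(np.max(rel))


def store_df(
    ca_cyt_nm: float,
    ca_store_nm: float,
    v_store_mv: float = 0.0,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Driving force (mV) for Ca2+ entry from a store into the cytosol.

    DF = E_Ca(cytosol vs store) - V_store. Values <= 0 mean no inward
    driving force (the caller should treat the flag, not an exception).
    """
    return nernst_ca(ca_cyt_nm, ca_store_nm, temperature_k) - v_store_mv


def store_df_reduction(
    baseline_from_nm: float,
    baseline_to_nm: float,
    ca_store_nm: float,
    v_store_mv: float = 0.0,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Fractional reduction (%) of the store driving force when the resting
    [Ca2+] rises from ``baseline_from_nm`` to ``baseline_to_nm``.

    The store-entry hypothesis hinges on this number being large: with a
    near-zero store potential the store [Ca2+] must be only a few hundred nM
    for a 30->90 nM baseline rise to halve the driving force, whereas at
    hundreds of uM the same rise barely matters.
    """
    df0 = store_df(baseline_from_nm, ca_store_nm, v_store_mv, temperature_k)
    df1 = store_df(baseline_to_nm, ca_store_nm, v_store_mv, temperature_k)
    if df0 <= 0:
        raise ValueError("no inward driving force at the starting baseline")
    return float((df0 - df1) / df0 * 100.0)


def store_df_surface(
    baseline_grid_nm: np.ndarray,
    store_grid_nm: np.ndarray,
    v_store_mv: float = 0.0,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray:
    """Driving force (mV) on a baseline x store-[Ca2+] grid (sensitivity
    surface for the store-entry hypothesis)."""
    b = np.asarray(baseline_grid_nm, dtype=float)[:, None]
    s = np.asarray(store_grid_nm, dtype=float)[None, :]
    if np.any(b <= 0) or np.any(s <= 0):
        raise ValueError("concentrations must be > 0")
    e = (R_GAS * temperature_k / (CA_VALENCE * FARADAY)) * np.log(s / b) * 1e3
    return e - v_store_mv


def store_equilibration_peak(
    ca_cyt0_nm: float,
    ca_store0_nm: float,
    volume_ratio: float = 0.1,
    kappa_cyt: float = 50.0,
    kappa_store: float = 20.0,
) -> float:
    """Free [Ca2+] (nM) after full store-cytosol equilibration.

    Conservation of total calcium under linearized buffering
    (total_i = free_i * (1 + kappa_i) * V_i) across the two compartments:

        c_eq = (b (1+k_c) V_c + s (1+k_s) V_s) / ((1+k_c) V_c + (1+k_s) V_s)

    with V_s / V_c = ``volume_ratio``. The implied transient amplitude
    c_eq - b is strictly decreasing in the baseline b for fixed store
    parameters: the signature of the equilibration mechanism.
    """
    if ca_cyt0_nm <= 0 or ca_store0_nm <= 0:
        raise ValueError("concentrations must be > 0")
    if volume_ratio < 0 or kappa_cyt < 0 or kappa_store < 0:
        raise ValueError("volumes and buffering capacities must be >= 0")
    wc = 1.0 + kappa_cyt
    ws = (1.0 + kappa_store) * volume_ratio
    return float((ca_cyt0_nm * wc + ca_store0_nm * ws) / (wc + ws))


def equilibration_amplitude_curve(
    baseline_grid_nm: np.ndarray,
    ca_store0_nm: float,
    volume_ratio: float = 0.1,
    kappa_cyt: float = 50.0,
    kappa_store: float = 20.0,
) -> np.ndarray:
    """Amplitude(b) = equilibrated peak - baseline over a baseline grid."""
    b = np.asarray(baseline_grid_nm, dtype=float)
    wc = 1.0 + kappa_cyt
    ws = (1.0 + kappa_store) * volume_ratio
    return (b * wc + ca_store0_nm * ws) / (wc + ws) - b


def _bound_ca_um(ca_free_um: float, buffers: tuple[BufferSpec, ...]) -> float:
    bound = 0.0
    for buf in buffers:
        f = buf.photolysed_fraction
        if f > 0.0 and buf.kd_post_nm is not None:
            kd_post_um = buf.kd_post_nm * 1e-3
            bound += buf.total_um * f * ca_free_um / (ca_free_um + kd_post_um)
            tot_intact = buf.total_um * (1.0 - f)
        else:
            tot_intact = buf.total_um
        kd_um = buf.kd_nm * 1e-3
        bound += tot_intact * ca_free_um / (ca_free_um + kd_um)
    return bound


def free_ca_equilibrium(system: BufferSystem) -> float:
    """Free [Ca2+] (nM) of a mixed Ca/buffer system at equilibrium.

    Solves Ca_total = Ca_free + sum_i B_i * Ca_free / (Ca_free + K_D,i)
    for the unique root on [0, Ca_total] (the right-hand side is strictly
    increasing in Ca_free, so the root exists and is unique). This is the
    in-package replacement for WebMaxC-style chelator calculators, without
    Mg2+/ATP competition (see docs/methods.md).
    """
    ca_tot = system.ca_total_um
    if ca_tot == 0.0:
        return 0.0

    def resid(free_um: float) -> float:
        return free_um + _bound_ca_um(free_um, system.buffers) - ca_tot

    if not system.buffers:
        return ca_tot * 1e3
    free_um = brentq(resid, 0.0, ca_tot, xtol=ca_tot * 1e-15, rtol=1e-15)
    # Newton polish: under heavy buffering the residual slope is steep, so
    # brentq's x-tolerance alone does not pin the residual itself
    for _ in range(3):
        r = resid(free_um)
        if abs(r) <= ca_tot * 1e-14:
            break
        h = max(free_um * 1e-8, 1e-15)
        slope = (resid(free_um + h) - r) / h
        step = r / slope
        if not np.isfinite(step):
            break
        free_um = min(max(free_um - step, 0.0), ca_tot)
    return float(free_um * 1e3)


def total_ca_for_free(free_nm: float, buffers: tuple[BufferSpec, ...]) -> float:
    """Total Ca (uM) that yields a requested free [Ca2+] (nM) — the forward
    map, used to load synthetic cells so their pre-photolysis baseline is a
    chosen value."""
    if free_nm < 0:
        raise ValueError("free Ca must be >= 0")
    free_um = free_nm * 1e-3
    return float(free_um + _bound_ca_um(free_um, tuple(buffers)))


def uncaging_shift(
    system: BufferSystem, buffer_name: str, photolysed_fraction: float,
    kd_post_nm: float | None = None,
) -> float:
    """Re-solve free [Ca2+] (nM) after photolysing a fraction of one buffer.

    The named buffer is split into (1 - f) at its pre-photolysis K_D and f
    at the post-photolysis K_D.
    """
    if not 0.0 <= photolysed_fraction <= 1.0:
        raise ValueError("photolysed fraction must lie in [0, 1]")
    names = [b.name for b in system.buffers]
    if buffer_name not in names:
        raise KeyError(f"unknown buffer {buffer_name!r}")
    new_buffers = []
    for buf in system.buffers:
        if buf.name == buffer_name:
            kd_post = kd_post_nm if kd_post_nm is not None else buf.kd_post_nm
            if kd_post is None:
                raise ValueError(f"buffer {buffer_name!r} has no post-photolysis K_D")
            buf = replace(buf, kd_post_nm=kd_post,
                          photolysed_fraction=photolysed_fraction)
        new_buffers.append(buf)
    return free_ca_equilibrium(BufferSystem(system.ca_total_um, tuple(new_buffers)))


# Canonical photoactivatable buffers at published affinities.
DIAZO2 = BufferSpec("diazo-2", total_um=2500.0, kd_nm=2200.0, kd_post_nm=73.0)
NP_EGTA = BufferSpec("NP-EGTA", total_um=5000.0, kd_nm=80.0, kd_post_nm=1.0e6)
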