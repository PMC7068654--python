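"""File formats and run configuration.

TCSPC photon stacks travel as HDF5 (dataset ``/photons`` with dimensions
frame x y x x x microtime_bin plus acquisition attributes); two-channel
intensity movies as multi-page TIFF with a JSON sidecar declaring channel
order and geometry; tables as CSV; configuration as YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

REQUIRED_STACK_ATTRS = (
    "microtime_bin_ns",
    "frame_interval_s",
    "pixel_um",
    "irf_center_ns",
    "irf_sigma_ns",
    "record_length_ns",
)


@dataclass
class TcspcStack:
    """4-D photon-count histogram (frame, y, x, microtime_bin) with the
    acquisition metadata needed to interpret it."""

    photons: np.ndarray
    microtime_bin_ns: float
    frame_interval_s: float
    pixel_um: float
    irf_center_ns: float
    irf_sigma_ns: float
    record_length_ns: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.photons)
        if p.ndim != 4:
            raise ValueError("photons must be 4-D (frame, y, x, microtime_bin)")
        if np.any(p < 0):
            raise ValueError("photon counts must be >= 0")
        n_bins = p.shape[-1]
        if abs(n_bins * self.microtime_bin_ns - self.record_length_ns) > 1e-6:
            raise ValueError("record_length must equal n_bins * bin width")
        self.photons = p

    @property
    def n_frames(self) -> int:
        return self.photons.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.photons.shape[1], self.photons.shape[2]

    @property
    def n_bins(self) -> int:
        return self.photons.shape[3]


def write_tcspc(path, stack: TcspcStack) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("photons", data=stack.photons.astype(np.int64),
                                compression="gzip", compression_opts=4)
        for name in REQUIRED_STACK_ATTRS:
            dset.attrs[name] = getattr(stack, name)
        f.create_group("meta").attrs["json"] = json.dumps(stack.meta)


def read_tcspc(path) -> TcspcStack:
    with h5py.File(path, "r") as f:
        if "photons" not in f:
            raise ValueError("malformed stack: missing /photons dataset")
        dset = f["photons"]
        missing = [a for a in REQUIRED_STACK_ATTRS if a not in dset.attrs]
        if missing:
            raise ValueError(f"stack missing required attributes: {missing}")
        meta = {}
        if "meta" in f and "json" in f["meta"].attrs:
            meta = json.loads(f["meta"].attrs["json"])
        return TcspcStack(
            photons=dset[()],
            meta=meta,
            **{a: float(dset.attrs[a]) for a in REQUIRED_STACK_ATTRS},
        )


def write_movie(path, movie: np.ndarray, sidecar: dict) -> None:
    """Two-channel movie as channel-interleaved multi-page TIFF + JSON
    sidecar. ``movie`` is (frame, channel, y, x); the sidecar must declare
    ``channels`` (e.g. ["G", "T"]), ``frame_interval_s`` and ``pixel_um``."""
    movie = np.asarray(movie)
    if movie.ndim != 4 or movie.shape[1] != len(sidecar.get("channels", ())):
        raise ValueError("movie must be (frame, channel, y, x) matching sidecar")
    pages = movie.reshape(-1, *movie.shape[2:])
    tifffile.imwrite(path, pages)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_movie(path) -> tuple[np.ndarray, dict]:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    pages = tifffile.imread(path)
    n_ch = len(sidecar["channels"])
    if pages.shape[0] % n_ch:
        raise ValueError("page count not divisible by declared channel count")
    movie = pages.reshape(-1, n_ch, *pages.shape[1:])
    return movie, sidecar


def write_calibration(path, curve, correction=None) -> None:
    """Calibration curve (+ optional tau-correction table) as JSON."""
    payload = {"version": 1, **curve.to_dict()}
    if correction is not None:
        payload["correction_table"] = correction.to_table()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration(path):
    from .flim_calibration import CalibrationCurve, LifetimeWindows, TauCorrectionMap

    payload = json.loads(Path(path).read_text())
    if "version" not in payload:
        raise ValueError("calibration file missing version field")
    curve = CalibrationCurve(
        r_at_zero=payload["r_at_zero"],
        r_at_sat=payload["r_at_sat"],
        k_app_nm=payload["k_app_nM"],
        hill_h=payload["hill_h"],
        windows=LifetimeWindows(**payload["windows_ns"]),
    )
    correction = None
    if "correction_table" in payload:
        tab = np.asarray(payload["correction_table"], dtype=float)
        correction = TauCorrectionMap(tuple(tab[:, 0]), tuple(tab[:, 1]))
    return curve, correction


DEFAULT_CONFIG = {
    "seed": 0,
    "roi_tile_um": 5.0,
    "flim_window_s": 0.6,
    "min_mean_photons": 1500.0,
    "uncaging_response_threshold_nm": 6.0,
    "locomotion": {"speed_threshold_cm_s": 1.0, "association_s": 6.0,
                   "bin_s": 3.0},
    "evoked": {"baseline_window_s": 5.0, "response_window_s": 20.0},
    "detection": {"k_sigma": 4.0, "min_duration_bins": 1},
}


def load_config(path=None) -> dict:
    """Run configuration (YAML or JSON), validated against the default
    schema: unknown keys rejected, thresholds must be positive."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        for key, val in user.items():
            if key not in cfg:
                raise KeyError(f"unknown config key: {key!r}")
            if isinstance(cfg[key], dict):
                for k2, v2 in val.items():
                    if k2 not in cfg[key]:
                        raise KeyError(f"unknown config key: {key}.{k2}")
                    cfg[key][k2] = v2
            else:
                cfg[key] = val
    for key in ("roi_tile_um", "flim_window_s", "min_mean_photons",
                "uncaging_response_threshold_nm"):
        if cfg[key] <= 0:
            raise ValueError(f"config {key} must be positive")
    return cfg
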