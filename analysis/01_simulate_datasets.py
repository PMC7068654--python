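"""Generate one synthetic dataset of each modality and archive it.

Produces a FLIM photon stack (HDF5) and a two-channel G/T movie (TIFF +
JSON sidecar) under scratch/, with their ground-truth event tables under
results/data/ as CSV. Downstream scripts regenerate data on the fly; this
script exists to exercise and demonstrate the on-disk formats.
"""

import argparse
from pathlib import Path

import numpy as np

from caflim import io, synth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    scratch = ROOT / "scratch"
    out = ROOT / "results" / "data"
    scratch.mkdir(exist_ok=True)
    out.mkdir(parents=True, exist_ok=True)

    # FLIM: one agonist-evoked cell
    cell = synth.generate_baseline_field((8, 8), seed=rng.integers(2**31))
    acq = synth.AcquisitionSpec(frame_interval_s=0.3, pixels_per_roi_side=2)
    ca_movie, truth = synth.generate_transients(
        cell, synth.CouplingSpec(), synth.Evoked(6.0), 18.0,
        frame_interval_s=acq.frame_interval_s, seed=rng.integers(2**31))
    stack = synth.render_flim_movie(ca_movie, cell, acquisition=acq,
                                    seed=rng.integers(2**31))
    io.write_tcspc(scratch / "flim_evoked_cell.h5", stack)
    truth.to_csv(out / "flim_evoked_truth.csv", index=False)
    print(f"FLIM stack: {stack.photons.shape}, "
          f"{stack.photons.sum()/1e6:.1f} M photons "
          f"-> scratch/flim_evoked_cell.h5")
    print(f"  cell mean baseline {cell.baseline_nm.mean():.1f} nM, "
          f"within-cell CV {cell.baseline_nm.std()/cell.baseline_nm.mean():.2f}")

    # ratiometric: spontaneous-style events on a grid of ROIs
    cell2 = synth.generate_baseline_field((10, 10),
                                          seed=rng.integers(2**31))
    acq2 = synth.AcquisitionSpec()
    ca2, truth2 = synth.generate_transients(
        cell2, synth.CouplingSpec(beta_amp=0.0, mode="store_independent"),
        synth.Evoked(4.0), 12.0, frame_interval_s=acq2.frame_interval_s,
        seed=rng.integers(2**31))
    movie = synth.render_ratiometric_movie(ca2, cell2, acquisition=acq2,
                                           seed=rng.integers(2**31))
    io.write_movie(scratch / "gt_movie.tif",
                   movie.astype(np.uint16),
                   {"channels": ["G", "T"],
                    "frame_interval_s": acq2.frame_interval_s,
                    "pixel_um": cell2.roi_size_um / acq2.pixels_per_roi_side})
    truth2.to_csv(out / "ratiometric_truth.csv", index=False)
    print(f"G/T movie: {movie.shape} -> scratch/gt_movie.tif")

    # locomotion trace (binned summary to results, raw to scratch)
    t, speed, bouts = synth.generate_locomotion_trace(
        600.0, seed=rng.integers(2**31))
    np.savetxt(scratch / "speed_trace.csv",
               np.column_stack([t, speed]), delimiter=",",
               header="t_s,speed_cm_per_s", comments="")
    with open(out / "locomotion_bouts.csv", "w") as fh:
        fh.write("bout_start_s,bout_end_s\n")
        for b0, b1 in bouts:
            fh.write(f"{b0:.2f},{b1:.2f}\n")
    moving = speed[speed > 1.0]
    print(f"locomotion: {len(bouts)} bouts over 600 s, mean moving speed "
          f"{moving.mean()*60:.1f} cm/min -> scratch/speed_trace.csv")


if __name__ == "__main__":
    main()
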