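"""Per-cell baseline-vs-peak/amplitude correlations through the full FLIM
measurement chain.

Two populations of synthetic cells: one with the anti-directional
baseline->amplitude coupling (the study's central effect), one with no
coupling (negative control). Writes results/flim_correlations.csv and
prints standard population statistics (R mean +- sem, t, p, n).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from caflim import stats, synth, workflows

ROOT = Path(__file__).resolve().parents[1]


def summarize(label, results):
    rows = []
    for key, attr in (("peak", "r_baseline_peak"),
                      ("amplitude", "r_baseline_amplitude")):
        rs = np.array([getattr(r, attr) for r in results])
        t = stats.one_population_t(rs[np.isfinite(rs)])
        print(f"  {label} baseline-vs-{key}: R = {t.mean:+.3f} +- "
              f"{t.sem:.3f}, t({t.df}) = {t.t:.2f}, p = {t.p:.2g}, "
              f"n = {t.n}")
        rows.append({"population": label, "measure": key, "r_mean": t.mean,
                     "r_sem": t.sem, "t": t.t, "p": t.p, "n": t.n})
    return rows


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--n-cells", type=int, default=40)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    curve, correction, _ = workflows.build_synthetic_calibration(
        seed=rng.integers(2**31))

    print(f"coupled population ({args.n_cells} cells, beta_amp = -0.5):")
    coupled = workflows.flim_population_correlations(
        args.n_cells, rng.integers(2**31), curve, correction,
        coupling=synth.CouplingSpec(beta_amp=-0.5))
    rows = summarize("coupled", coupled)
    n_sign = sum(r.r_baseline_amplitude < 0 and r.r_baseline_peak > 0
                 for r in coupled)
    print(f"  sign structure (R_amp < 0 and R_peak > 0) recovered in "
          f"{n_sign}/{len(coupled)} cells")

    print("null population (11 cells, no coupling):")
    null = workflows.flim_population_correlations(
        11, rng.integers(2**31), curve, correction,
        coupling=synth.CouplingSpec(beta_amp=0.0, mode="store_independent"))
    rows += summarize("null", null)

    per_cell = pd.DataFrame(
        [{"population": "coupled", "cell": r.unit_id,
          "r_peak": r.r_baseline_peak, "r_amp": r.r_baseline_amplitude,
          "n_rois": r.n} for r in coupled]
        + [{"population": "null", "cell": r.unit_id,
            "r_peak": r.r_baseline_peak, "r_amp": r.r_baseline_amplitude,
            "n_rois": r.n} for r in null])
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    per_cell.to_csv(out / "flim_correlations.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "flim_correlations_summary.csv",
                              index=False)
    print("wrote results/flim_correlations.csv and _summary.csv")


if __name__ == "__main__":
    main()
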