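#!/usr/bin/env python
"""Generate a calibrated synthetic cohort and check its calibration.

Draws one cohort of n=500 from the generator calibrated to the published
four-class adult-outcome typology, writes it (with true labels) under
scratch/, and writes a small calibration summary table — per class and
variable, the generated sample mean against the calibration target —
under results/analysis/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lcpa.io import write_cohort_csv
from lcpa.simulate import default_cohort_config, generate_cohort

SEED = 0
N = 500

def main() -> None:
    outdir = Path("results/analysis")
    outdir.mkdir(parents=True, exist_ok=True)
    scratch = Path("scratch")
    scratch.mkdir(exist_ok=True)

    cfg = default_cohort_config()
    table, truth = generate_cohort(cfg, n=N, seed=SEED)
    write_cohort_csv(table, scratch / "cohort_n500.csv")
    pd.Series(truth, name="true_class").to_csv(
        scratch / "cohort_n500_labels.csv", index_label="row"
    )

    rows = []
    for name, g in cfg.gaussian.items():
        for k in range(4):
            vals = table.data[name][truth == k].dropna()
            rows.append({
                "variable": name, "class": k + 1, "family": "gaussian",
                "target_mean": g.means[k],
                "sample_mean": round(float(vals.mean()), 2),
                "n_obs": len(vals),
                "sd_residual_flag": round(float(g.sd_residuals[k]), 2),
            })
    for name, o in cfg.ordinal.items():
        for k in range(4):
            vals = table.data[name][truth == k].dropna()
            rows.append({
                "variable": name, "class": k + 1, "family": "ordinal",
                "target_mean": o.target_means[k],
                "sample_mean": round(float(vals.mean()), 2),
                "n_obs": len(vals), "sd_residual_flag": 0.0,
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "01_calibration_check.csv", index=False)

    shares = np.bincount(truth, minlength=4) / N
    print(f"cohort n={N} seed={SEED}: class shares {np.round(shares, 3)} "
          "(targets 0.22/0.26/0.25/0.27)")
    dev = (summary.sample_mean - summary.target_mean).abs()
    print(f"max |sample - target| class mean over {len(summary)} cells: "
          f"{dev.max():.2f} (MC noise at ~125 rows/class)")
    print("wrote scratch/cohort_n500.csv and results/analysis/01_calibration_check.csv")


if __name__ == "__main__":
    main()
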