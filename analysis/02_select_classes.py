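#!/usr/bin/env python
"""How many adult-outcome classes does BIC support, and at which sample size?

Fits the mixed-family latent class profile model for K = 2..5 on replicate
calibrated cohorts at the study's sample size (n=123) and at n=500, and
tabulates which K minimizes BIC.  The calibrated generator carries the
published class-specific SDs while the model's variances are class-
invariant, so a fifth class picks up real heteroscedasticity misfit whose
log-likelihood gain grows linearly with n; the BIC penalty grows only as
ln(n).  The run shows the consequence: at the study scale the four-class
model is selected in most replicates, at n=500 it no longer is.
"""

from pathlib import Path

import pandas as pd

from lcpa.lpa import enumerate_classes
from lcpa.preprocess import prepare_indicators
from lcpa.simulate import default_cohort_config, generate_cohort

N_REPLICATES = 10


def main() -> None:
    outdir = Path("results/analysis")
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_cohort_config()
    records = []
    for n in (123, 500):
        for rep in range(N_REPLICATES):
            table, _ = generate_cohort(cfg, n=n, seed=3000 + rep)
            Y, specs = prepare_indicators(table)
            sel, chosen, _ = enumerate_classes(
                Y, specs, [2, 3, 4, 5], n_restarts=4, seed=rep, max_iter=300
            )
            records.append({
                "n": n, "replicate": rep, "chosen_K": chosen,
                **{f"bic_K{K}": round(sel.loc[K, "bic"], 1) for K in (2, 3, 4, 5)},
            })
            print(f"n={n} rep={rep}: chose K={chosen}")
    df = pd.DataFrame(records)
    df.to_csv(outdir / "02_class_enumeration.csv", index=False)
    for n in (123, 500):
        sub = df[df.n == n]
        rate = (sub.chosen_K == 4).mean()
        print(f"n={n}: K=4 selected in {rate:.0%} of {len(sub)} replicates")
    print("wrote results/analysis/02_class_enumeration.csv")


if __name__ == "__main__":
    main()
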