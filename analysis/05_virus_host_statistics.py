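#!/usr/bin/env python
"""Virus and host abundance statistics at the SOM.

Heterotroph accounting, percent of Prochlorococcus infected by T4- and
T7-like cyanophages, SOM-versus-layer fold changes with rank tests, and
the monthly Prochlorococcus-VLP power-law exponents.
"""

import argparse
from pathlib import Path

import pandas as pd

from somshunt import simulate
from somshunt import viruses as vir


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/viruses")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    pt = vir.heterotroph_counts(
        simulate.gen_polony_table(simulate.PolonyConfig(seed=args.seed)))
    folds = []
    for var in vir.PHAGE_COLUMNS:
        tbl, _ = vir.depth_fold_changes(pt, var)
        tbl.insert(0, "variable", var)
        folds.append(tbl)
    folds = pd.concat(folds, ignore_index=True)
    folds.to_csv(out / "folds.csv", index=False)

    inf = vir.percent_infected(pt)
    inf.to_csv(out / "infections.csv", index=False)
    som = inf[inf.layer == "SOM"]
    print(f"SOM infection: T4 {som.pct_t4.mean():.2f}%, "
          f"T7 {som.pct_t7.mean():.2f}%, total {som.pct_total.mean():.2f}%")
    for var in ("free_t4", "free_t7"):
        sub = folds[folds.variable == var]
        srf = sub[sub.contrast == "SOM_vs_SRF"].iloc[0]
        print(f"{var}: SOM/SRF fold {srf.fold:.2f} (BH-adjusted p = {srf.p_adj:.4f})")
    som_r = (pt[pt.layer == 'SOM']['heterotrophs'] / pt[pt.layer == 'SOM']['prochlorococcus']).mean()
    ml_r = (pt[pt.layer == 'SRF']['heterotrophs'] / pt[pt.layer == 'SRF']['prochlorococcus']).mean()
    print(f"heterotroph:Prochlorococcus ratio {som_r:.1f} at the SOM vs {ml_r:.1f} at the surface")

    pa = simulate.gen_vlp_pairs(simulate.VlpConfig(seed=args.seed))
    fits = vir.vlp_power_law(pa, seed=args.seed)
    pw = vir.power_law_frame(fits)
    pw.to_csv(out / "powerlaw.csv", index=False)
    print(f"monthly VLP~Prochlorococcus power-law exponents: "
          f"median {pw.exponent.median():.2f} "
          f"(range {pw.exponent.min():.2f}-{pw.exponent.max():.2f}), "
          f"{(pw.perm_p <= 0.05).sum()}/12 months significant at alpha 0.05")


if __name__ == "__main__":
    main()
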