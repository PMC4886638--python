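#!/usr/bin/env python
"""Mixed-effects differential analysis: fluorescence vs concentration.

Fits the reduced and global crossed random-intercept models on log2
fluorescence, compares them by ML likelihood ratio, then produces the
omnibus tissue table and the Normal-vs-disease pairwise contrast table on
both response scales.  The concentration run first drops analytes with
empty design cells (the censoring casualties); the fluorescence run keeps
all 37.
"""

from pathlib import Path

import pandas as pd

from fluorplex import differential_model as dm
from fluorplex import plate_data as pdm

ROOT = Path(__file__).resolve().parents[1]

def fit_pipeline(ds, response):
    kept, dropped = pdm.filter_estimable_analytes(ds, response)
    if dropped:
        sub = ds.df[(ds.df["well_role"] != "sample")
                    | ds.df["analyte"].isin(kept)]
        ds = pdm.PlateDataset(sub.reset_index(drop=True))
    spec = dm.ModelSpec(response=f"log2_{response}")
    fit = dm.fit_lmm(ds, spec)
    return fit, sorted(dropped)

def main():
    ds = pdm.read_plate_table(ROOT / "scratch" / "plates_mapped.csv")

    cmp_ = dm.compare_models(ds, dm.REDUCED_SPEC, dm.GLOBAL_SPEC)
    print("reduced vs global (log2 fluorescence, ML refits):")
    print(f"  AIC {cmp_['aic'][0]:.0f} -> {cmp_['aic'][1]:.0f}, "
          f"BIC {cmp_['bic'][0]:.0f} -> {cmp_['bic'][1]:.0f}, "
          f"chisq={cmp_['chisq']:.1f} on {cmp_['df_diff']} df, "
          f"p={cmp_['p']:.3g}")

    tables = {}
    for response in ("fluorescence", "concentration"):
        fit, dropped = fit_pipeline(ds, response)
        print(f"{response}: n={fit.n_obs}, fixed df={fit.fixed_df}, "
              f"variance components={ {k: round(v, 3) for k, v in fit.variance_components.items()} }, "
              f"resid={fit.sigma2:.3f}"
              + (f", dropped={dropped}" if dropped else ""))
        omni = dm.omnibus_table(fit, "tissue")
        contr = dm.contrast_table(fit, reference="Normal")
        omni.to_csv(ROOT / "results" / f"04_omnibus_tissue_{response}.csv",
                    index=False)
        contr.to_csv(ROOT / "results" / f"04_contrasts_{response}.csv",
                     index=False)
        tables[response] = (omni, contr)
        print(f"  tissue omnibus: {(omni['p_holm'] < 0.05).sum()} of "
              f"{len(omni)} analytes significant (Holm)")
        print(f"  condition contrasts: {(contr['p_holm'] < 0.05).sum()} of "
              f"{len(contr)} significant (Holm)")

    # disagreement summary: significant on one scale but not the other
    of, oc = tables["fluorescence"][0], tables["concentration"][0]
    merged = of.merge(oc, on="analyte", suffixes=("_fl", "_conc"))
    only_conc = merged[(merged["p_holm_conc"] < 0.05)
                       & (merged["p_holm_fl"] >= 0.05)]["analyte"]
    only_fl = merged[(merged["p_holm_fl"] < 0.05)
                     & (merged["p_holm_conc"] >= 0.05)]["analyte"]
    print(f"tissue-omnibus significant only by concentration: "
          f"{sorted(only_conc)}")
    print(f"tissue-omnibus significant only by fluorescence: "
          f"{sorted(only_fl)}")

if __name__ == "__main__":
    main()
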