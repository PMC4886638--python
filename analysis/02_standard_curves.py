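#!/usr/bin/env python
"""Fit 5PL standard curves, map fluorescence to concentration, tally censoring.

For every analyte x plate the weighted 5PL is fitted to the 8-point
standard series, the blank-based detection limit derived, and all sample
wells mapped through the inverse curve.  The point of the exercise: the
fluorescence table keeps every record, while the concentration table loses
the out-of-range wells of the low-abundance analytes.
"""

import json
from pathlib import Path

import pandas as pd

from fluorplex import plate_data as pdm
from fluorplex import standard_curve as sc

ROOT = Path(__file__).resolve().parents[1]

def main():
    ds = pdm.read_plate_table(ROOT / "scratch" / "plates.csv")
    fits, rows = {}, []
    blanks = ds.blanks()
    for (analyte, plate), grp in ds.standards().groupby(["analyte", "plate"]):
        fit = sc.fit_5pl(grp[["concentration", "fluorescence"]].to_numpy())
        bl = blanks[(blanks["analyte"] == analyte)
                    & (blanks["plate"] == plate)]["fluorescence"]
        fit.lod_fl, fit.lod_conc = sc.lod_from_blanks(fit, bl)
        fits[(analyte, plate)] = fit
        rows.append({"analyte": analyte, "plate": plate,
                     "bottom": fit.bottom, "top": fit.top, "ec50": fit.ec50,
                     "hill": fit.hill, "asym": fit.asym,
                     "lod_fl": fit.lod_fl, "lod_conc": fit.lod_conc})
    pd.DataFrame(rows).to_csv(ROOT / "results" / "02_curve_fits.csv",
                              index=False)

    mapped = sc.map_dataset(ds, fits)
    mapped.write_csv(ROOT / "scratch" / "plates_mapped.csv")
    tally = mapped.samples()["censor_status"].value_counts()
    tally.to_csv(ROOT / "results" / "02_censoring_tally.csv")
    kept_c, dropped_c = pdm.filter_estimable_analytes(mapped, "concentration")
    kept_f, dropped_f = pdm.filter_estimable_analytes(mapped, "fluorescence")
    with open(ROOT / "results" / "02_estimability.json", "w") as fh:
        json.dump({"fluorescence_dropped": sorted(dropped_f),
                   "concentration_dropped": sorted(dropped_c)}, fh, indent=1)
    print("censor statuses:", dict(tally))
    print(f"concentration-inestimable analytes "
          f"({len(dropped_c)}): {sorted(dropped_c)}")
    print(f"fluorescence-inestimable analytes: {sorted(dropped_f)}")

if __name__ == "__main__":
    main()
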