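# fluorplex

Fluorescence-first statistics for multiplex bead immunoassays (Luminex
xMAP-style panels).

Multiplex immunoassays report a median fluorescence intensity (MFI) per
analyte per well; standard practice converts MFI to concentration (pg/ml)
through a five-parameter logistic (5PL) standard curve before any
statistics. That conversion censors every reading outside the curve's
invertible range — which for low-abundance analytes can be most of the
data — and distorts the shape of the response distribution. `fluorplex`
implements the alternative: run the differential analysis on log2 MFI
directly, and quantify exactly what the concentration detour costs.

The package provides:

- **`plate_data`** — a long-format well table (samples, standards, blanks)
  with validation, design summaries, estimability filtering and
  plate-capacity arithmetic (a 96-well duplicate layout holds 39 samples
  with a standard curve, 47 without one).
- **`standard_curve`** — weighted 5PL fitting
  `f(x) = bottom + (top−bottom)/(1+(x/ec50)^(−hill))^asym`, the inverse
  mapping with censoring statuses (`in_range` / `extrapolated` /
  `oor_low` / `oor_high`), and blank-based detection limits
  (mean + 2·sd).
- **`lod_diagnostics`** — evidence that log2 MFI needs no detection limit:
  balanced above/below-LOD coefficient-of-variation comparisons with
  F-tests and Mann-Whitney / paired-t aggregation, rank-difference
  profiles (which expose the half-unit MFI quantization as a flat level at
  −1), and p-value uniformity scans.
- **`differential_model`** — the crossed random-intercept linear mixed model

      log2(response) ~ analyte + tissue + condition
                       + analyte:tissue + analyte:condition
                       + (1 | plate:condition:tissue) + (1 | patient)

  fitted by profiled REML/ML (written here, with a dense-matrix likelihood
  oracle in the tests), likelihood-ratio model comparison, Wald chi-square
  omnibus and pairwise contrasts with Holm adjustment, and adjusted means
  with 95% intervals.
- **`curve_mapping_sim`** — a sigmoid-mapping simulation showing that
  two-sample t-tests on MFI are exactly translation invariant
  (t-test(x, y) = t-test(x+b, y+b), so background subtraction is a no-op)
  while t-tests on mapped concentrations lose power as the responses move
  away from the curve's EC50, asymmetrically so for skewed inputs.
- **`synthetic_data`** — a generator reproducing the reference design
  (169 patients / 191 samples / 37 analytes / 3 plates / 14
  plate:condition:tissue groups, paired patients, duplicate wells,
  half-unit quantization) with full ground truth.

## Worked example

```python
from fluorplex import synthetic_data, plate_data, standard_curve, differential_model

ds, truth = synthetic_data.generate_dataset(synthetic_data.GeneratorConfig(seed=20260924))
print(plate_data.design_summary(ds).plate_group_count)   # 14

fits = {key: standard_curve.fit_5pl(grp[["concentration", "fluorescence"]].to_numpy())
        for key, grp in ds.standards().groupby(["analyte", "plate"])}
mapped = standard_curve.map_dataset(ds, fits)
print(mapped.samples()["censor_status"].value_counts().to_dict())
# {'in_range': 10260, 'extrapolated': 2271, 'oor_low': 1250, 'oor_high': 353}

kept, dropped = plate_data.filter_estimable_analytes(mapped, "concentration")
print(len(dropped))   # 5  (low-abundance analytes with censor-emptied cells)
kept, dropped = plate_data.filter_estimable_analytes(mapped, "fluorescence")
print(len(dropped))   # 0  (fluorescence loses nothing)
```

The numbered drivers under `analysis/` run the full narrative on the
synthetic study (`python analysis/01_simulate_plates.py` … `05_…`), writing
tables to `results/`. Step 04, for instance, fits both response pipelines
and reports that the global model crushes the reduced one (ML likelihood
ratio χ² = 6643.8 on 259 df, p ≈ 0) and that several analytes flip
significance between the fluorescence and concentration scales. Step 05
prints, per skew level, the constant fluorescence p-value against the
level-dependent concentration p-values, e.g. for left-skewed inputs
(α = −5): p_fl = 7.5e-06 constant, median log10 p_conc −3.9 below the EC50
(power lost) and −6.2 above it (power gained).

A thin CLI mirrors the library: `fluorplex validate`, `fluorplex summary`,
`fluorplex synth`, `fluorplex curve fit/map`, `fluorplex lod table/rankdiff`,
`fluorplex diff fit/contrasts`, `fluorplex sim scan`.

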