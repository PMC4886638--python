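# Methods

`fluorplex` analyses multiplex bead-immunoassay (Luminex xMAP-style) data on
the raw fluorescence scale and quantifies what is lost when the same data are
first mapped to concentrations through a standard curve. This note records
the models, the numerical choices, and what the synthetic experiments do and
do not establish.

## Data model

The substrate is a long table with one row per well reading: `patient_id`,
`tissue`, `condition`, `plate`, `analyte`, `well_role` (sample / standard /
blank), `standard_level` (1–8, standards only), `fluorescence` (median
fluorescence intensity, MFI, > 0), optional `concentration` (pg/ml) and a
`censor_status`. All transformed analyses use log2. Duplicate sample wells
are averaged (arithmetic mean of MFI) into one observation per
sample × analyte before modelling; a switch keeps per-well rows. Whether
replicate wells should be pre-averaged before mixed-effects modelling is a
genuinely open design point — we average because the models below carry one
response per patient × analyte, and the replicate scatter is already
summarised by %CV diagnostics. Blank fluorescence is never subtracted from
sample responses: the translation-invariance results below show subtraction
is unnecessary for differential analysis, and on low-signal analytes it only
injects noise.

## Standard curves and censoring

Concentration→fluorescence follows the five-parameter logistic

    f(x) = bottom + (top − bottom) / (1 + (x/ec50)^(−hill))^asym,

increasing in x, with `asym = 1` the symmetric 4PL. Fits minimise weighted
least squares; the default weight is 1/f² (constant-CV error, the standard
immunoassay assumption), with unweighted and inverse-replicate-variance modes
available. The optimiser is multi-start local least squares with `ec50`,
`hill`, `asym` log-parameterised, warm-started from a 4PL fit and restarted
over an asymmetry grid {1, 0.5, 2, 0.25, 4, 0.8} — the 5PL is ill-conditioned
for extreme asymmetry and a symmetric start alone can stall in a local
optimum. Convergence is 1e-10 on relative RSS change.

Curves are fitted per analyte × plate (between-plate variation of a standard
curve is a plate-level property). The inverse maps fluorescence to
concentration with a censoring status: `in_range` inside the standards'
observed fluorescence span, `extrapolated` outside the span but strictly
inside (bottom, top), `oor_low`/`oor_high` (no concentration) at or beyond
the asymptotes. The fluorescence analysis path ignores these statuses
entirely — no record is ever censored there.

The detection limit is derived from blanks as mean + k·sd with k = 2 by
default; k is configuration because vendor software computes its LOD by an
unpublished algorithm, so published LOD values are treated as given inputs
rather than reproduction targets.

## Detection-limit diagnostics

*Balanced CV comparison.* For each analyte × tissue with at least 5
responses on each side of its fluorescence LOD, the N nearest responses above
and below are selected (N = min of the side counts; a value exactly at the
LOD counts as above; distance ties break toward the smaller value, then input
order — the selection is deterministic and order-invariant). Equality of the
two CVs is tested as equality of log2 variances by a two-sided F-test
(doubled smaller tail). Across rows, the log2 CVs are aggregated two ways,
both reported: a Mann-Whitney rank-sum test treating the above/below columns
as independent samples, and a paired t-test on the row differences. On the
published 17-row table the paired t reproduces the printed values exactly
(t = −0.42, df = 16, p = 0.68); the rank-sum W on the 3-decimal printed CVs
is 130.5 rather than the printed 135, which was computed on unrounded CVs —
the package asserts agreement with an exhaustive pair-counting oracle, not
with the printed statistic.

*Rank differences.* `rank.diff(r) = Fl(r+1) − Fl(r)` over the unique sorted
responses, logged base 2; the head mean averages the first half of ranks. A
true detection floor would drive the head toward −∞; instrument quantization
at half-unit steps pins it at exactly −1. The signature is only visible
where responses are dense (the low-abundance analytes); sparse high ranges
have larger gaps by counting alone.

*Uniformity scan.* One two-sided Mann-Whitney test per analyte × unordered
tissue pair on log2 MFI for the low-abundance analytes, with a
Kolmogorov-Smirnov statistic against Uniform(0,1) and the fraction of
p < 0.05. Caveat established by our null simulations: the C(4,2) pairwise
p-values share samples within an analyte, so they are positively dependent
and the joint KS test over-rejects under the null (~10–13% at α = 0.05)
even though each p-value is marginally calibrated. The KS number is a
descriptive summary; the marginal fraction below 0.05 is the calibrated
quantity. Structure in real low-abundance responses shows up as a gross
excess of small p-values, far outside either null band.

## Mixed-effects differential analysis

The global model for the log2 response is

    y ~ analyte + tissue + condition + analyte:tissue + analyte:condition
        + (1 | plate:condition:tissue) + (1 | patient)

with treatment coding; the reduced model drops `condition` and
`analyte:condition`. The analyte:tissue:condition interaction is excluded by
construction: the design is sparse and the three-way term would overfit.
The two random intercepts are crossed: the plate-group effect absorbs which
plate a condition × tissue combination ran on; the patient effect ties the
two tissues of paired patients together.

Estimation is profiled (RE)ML. With V = σ²(I + ZGZ′) and G the diagonal of
variance ratios γ_k = σ_k²/σ², the GLS coefficients and σ² are closed-form
given γ, so only the ratios are optimised — bounded L-BFGS-B on log γ,
started from method-of-moments values, tolerance 1e-10 on the criterion.
Every solve goes through a Cholesky factor of the q×q system Z′Z + G⁻¹
(Woodbury identity), so the cost scales with the number of random levels
(≈ 183 in the full design), not with observations. A dense-matrix evaluation
of the same REML criterion serves as an independent oracle in the tests
(agreement ≈ 1e-9). A ratio pinned at its lower bound is reported as a
zero variance component with a warning, not an error.

Model comparison refits both structures by full ML (REML likelihoods are not
comparable across fixed structures) and reports AIC/BIC from the ML fits
plus the likelihood-ratio chi-square on the fixed-df difference. Calibration
note from our simulations: with few random-effect levels per tested fixed
effect the chi-square reference is anticonservative; it approaches nominal
(5.0% at α = 0.05 over 200 null replicates) once conditions span a dozen or
more plate-groups.

Inference on fixed effects is by Wald quadratic forms on *cell-mean*
contrasts, which makes every statistic invariant to the coding reference:
omnibus factor tests span all level differences within an analyte
(df = levels − 1, so df = 3 for four tissues); pairwise condition contrasts
are df-1 tests of reference-minus-other adjusted differences (negative =
higher in the disease). Adjusted means average the remaining fixed factors
with equal level weights (the interaction-means convention; observed-
frequency weighting is a configuration choice we did not take), with
normal-quantile 95% intervals — no Kenward-Roger/Satterthwaite correction,
acceptable at these sample sizes. Holm's step-down adjustment is applied
over whole emitted tables (all omnibus rows, or all analyte × condition
contrasts), the widest defensible family.

Analytes with any empty (analyte, tissue, condition) cell in the chosen
response are removed before fitting (rank-deficiency guard); with complete
fluorescence data nothing is removed, which is the asymmetry the package
exists to demonstrate — censoring empties concentration cells for
low-abundance analytes only.

## Sigmoid-mapping simulation

Two groups of normalized log2 fluorescence responses (values in (0,1), the
response axis of a unit sigmoid `1/(1+2^(−slope·x))`) are drawn once from a
centered skew-normal — standardized so location/scale are exact population
moments for every shape α — separated by Δ = d·sd with Cohen's d = 0.8, and
translated so the pair midpoint sits at each response level 0.05…0.95 (step
0.01). At each level:

* the fluorescence t-test p-value is exactly independent of the translation
  (t-statistics are translation invariant), so it is evaluated once from the
  seeded pair and repeated — making the constancy bitwise rather than
  subject to float re-association;
* responses are mapped through the inverse sigmoid to log2 concentrations
  (responses outside (0,1) are unmappable and are dropped, reducing the
  t-test df — the simulation's image of out-of-range censoring), and the
  concentration t-test is run on the mapped values.

Concentration-side statistics are computed on the log2 scale, the same scale
the plate analyses use; `2^x` is exposed for pg/ml reporting. Defaults:
n = 100 per group (large enough for stable p-value dynamics without floor
effects), sd = 0.05 normalized units (narrow relative to the curve's span,
as in the motivating figures), pooled-variance t-test (the groups share
their sd by construction; Welch available), fixed-draw translation (a
redraw-per-step mode exists for sensitivity checks).

The inverse sigmoid stretches the tails symmetrically about the EC50 on the
log2 scale, so for normal inputs the concentration p-values bottom out near
level 0.5 and grow toward both ends; skewed inputs (α = ∓5) lose power on
one side of the EC50 and gain it on the other. A single n = 100 draw
carries ≈ ±0.3 decades of per-level noise — more than the shallow interior
dip — so shape assertions in the tests run on the mean log10 p profile over
20 fixed seeds; the direction of the skew asymmetry is already stable per
seed in band medians (the outermost ~5 levels are dominated by censoring
drops, which blow p up regardless of skew, hence medians rather than means).

## Synthetic data generator

The generator reproduces the reference design: 169 patients, 191 samples
(16 mononucleosis and 6 myeloma patients contribute paired plasma + serum),
four tissues × eight conditions allocated across three plates by a fixed
documented map yielding exactly 14 nonempty plate:condition:tissue groups;
37 analytes in duplicate wells; an 8-point 4-fold standard dilution series
from 10⁴ pg/ml plus blanks per analyte × plate; half-unit MFI quantization.
The 4-fold standard dilution factor is borrowed from the stated sample
dilution; the kit's actual series is not public.

Latent log2 concentration = per-analyte baseline + tissue effect + condition
effect + patient effect + plate-group effect + residual, with default
variances (0.25, 0.09, 0.04) log2² units and effect sds 0.5. Baselines are
spread over [−5, 11] log2 pg/ml so roughly nine analytes sit below their
lowest standard — the low-abundance subset whose concentration cells empty
under censoring while their fluorescence stays analysable. Fluorescence is
the analyte's 5PL curve at the latent concentration times multiplicative
lognormal noise (sd 0.1 log2 units ≈ 7% CV), then quantized.

Two deliberate limitations. First, the default study allocation makes the
plate-group variance nearly unidentifiable — its 14 groups coincide with
condition:tissue cells and are largely absorbed by the condition fixed
effects — which is faithful to the real design but means parameter-recovery
experiments use a reduced *crossed* design (cells spread over all plates,
48 groups) where every component is identified. Second, the 5PL readout
compresses log2-MFI variance analyte-by-analyte through the local curve
slope, so latent-scale variance components are not recoverable from the
fluorescence of a curved readout by construction; recovery experiments use
the generator's `readout="linear"` option (log2 MFI = latent exactly, the
identity-curve limit), which isolates the estimation machinery. Under those
conditions, 100-seed recovery gives median relative errors of ~3% (patient),
~12% (plate-group) and <1% (residual), with 94–95% coverage of injected
condition contrasts.

What the generator does not emulate: bead-count QC and well failures, plate
spatial effects, drift/carryover, non-monotone matrix interference.
Passing tests on this generator therefore establish nothing about those
failure modes; they certify the statistical machinery under the stated
model.

## Problem sizes used by the test suite

Simulation-backed tests run at deliberately reduced sizes chosen to keep the
estimates meaningful: 5PL recovery over 50 noise seeds; F-test calibration
over 1000 null replicates; LRT calibration over 200 replicates of a
4-analyte crossed design; mixed-model recovery over 100 seeds of a
10-analyte × 4-tissue × 4-condition × 3-plate design; translation-scan shape
over 20 seeds of n = 100 scans. These sizes are the package's own choices
for stable Monte-Carlo summaries.
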