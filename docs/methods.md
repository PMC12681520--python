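# Methods

This note documents the models, rules and numerical choices behind
`gmmquant`: what the pipeline assumes, what the synthetic-data generator
emulates (and what it does not), and where genuinely open design decisions
were settled.

## Panel arithmetic

The shipped panel holds 35 entries: 33 quantification targets (17 uremic
toxins, 16 bile acids) plus the two isotope-labelled internal standards.
Three targets — glycocholic acid (GCA), chenodeoxycholic acid (CDCA) and
4-guanidinobutyric acid (GB) — are excluded for on-column accumulation,
leaving 16 UTs + 14 BAs = 30 quantified targets. The six co-eluting
conjugated bile acids (TCDCA/TDCA/TUDCA and GCDCA/GDCA/GUDCA) collapse into
taurine- and glycine-conjugate reporting groups, so the analysis operates on
30 − 6 + 2 = 26 reporting entities. `PanelConfig.summary()` exposes this
arithmetic so any disagreement with an external target count is visible in
the run outputs rather than silently reconciled. Bile-acid class labels
(primary vs secondary) are chemical metadata only — conjugates of the
primary acids and the muricholic acids are tagged primary, microbially
transformed species secondary — and never enter computation. Internal
standards pair by acquisition mode (ESI⁻ targets normalise to p-CS-d₇, ESI⁺
to GDCA-d₆), overridable per analyte. MRM transition masses are optional
metadata and are never used.

## Instrument and quantification model

Peak areas follow a linear response:

    area = slope_analyte × ME(matrix) × c_vial × f_day × f_inj × f_noise + intercept

where `f_day = exp(N(0, σ_inter))` is shared by all injections of a day (a
batch-level drift), `f_inj = exp(N(0, σ_inj))` is shared by the analyte and
internal-standard areas of one injection (injection-volume variation — it
cancels in the response ratio), and `f_noise = exp(N(0, σ_intra))` is
independent per integrated area. The matrix-effect multiplier applies to
analyte areas only; the internal standard is spiked at its nominal
concentration in every vial, so the ratio of matrix-matched to neat
calibration slopes recovers ME exactly, which is what the matrix-effect
metric reports. Whole-sample ion suppression multiplies analyte and IntStd
areas alike: it cancels in the response ratio (quantification stays
accurate) but violates the 80–120 % IntStd-recovery window, which is
precisely what the QC gate is designed to catch. Areas below a detection
threshold are reported missing.

Defaults: σ_intra = 3 %, σ_inter = 5 %, σ_inj = 2 %, suppression probability
5 % at magnitude 0.5, matrix-effect multipliers 0.9 (plasma) and 0.7
(feces). These were calibrated once to the method's stated operating
characteristics — all calibration curves above the R² > 0.99 linearity
criterion, intra-day area %RSD in the low single digits and inter-day around
5–10 % (inside the reported 1.14–16.39 % and 0.76–18.60 % bands), matrix
effects inside the reported 0.4–141.9 % range — and are user-overridable.

Calibration uses weighted least squares of response ratio on nominal
concentration, 1/x weighting by default (appropriate for a 0.005–20 µM range
spanning nearly four decades; unweighted and 1/x² are selectable), with R²
computed on the weighted scale. LOD/LOQ follow the ICH-style 3.3·s/slope and
10·s/slope estimator with `s` the residual SD over the lowest six distinct
levels, so LOQ/LOD = 10/3.3 identically; a perfect line gives 0/0. The
quantitation curve uses 10 points, the validation design 12 — both are a
parameter. Fewer than five usable (non-censored) levels is a per-analyte
calibration failure that propagates as "no curve" rather than aborting the
run.

Dilution selection: each sample is injected at every factor of its matrix's
scheme (plasma 1/2/50, feces 1/2/10, encoding the neat, 1:1 and 1:49 or 1:9
preparations). The reported value comes from the least-diluted record whose
undiluted concentration lies inside the calibration range; if every
quantifiable record exceeds the range the most-diluted one is used
(flagged extrapolation upward is preferred to discarding the sample); if all
records are censored the cell is censored. Specimen conversion: plasma
extract µM × 10 (100 µL plasma in 1000 µL extract); feces extract µM × 0.002
L / 0.25 g = × 0.008 µmol/g.

## QC cascade

Order is fixed and logged: exclusions → conjugate collapsing →
detection-rate filter → group-minimum imputation → IntStd gate →
group-median imputation. Choices made where the rules are underspecified:

- "Detected" means a quantifiable back-calculated value at or above the
  LOQ; censored and absent cells count as undetected. The ≥ 80 % boundary
  is inclusive (exactly 80 % detected is kept; "fewer than 80 %" drops).
- The detection filter applies per matrix per group; matrices are analysed
  independently throughout and never pooled.
- A collapsed conjugate cell is `measured` only when all members are
  measured; otherwise it takes the weakest member provenance and is left
  for imputation. Partial member presence in the matrix is summed over the
  present members with a warning.
- The IntStd gate back-calculates each sample's IntStd concentration
  against a single-point response factor derived from the calibration
  standards (the IntStd is spiked at one nominal level everywhere, so a
  ratio-on-itself curve would be degenerate). Bounds are strict: exactly
  80 % or 120 % recovery passes.
- Group-minimum imputation precedes the gate's median imputation, matching
  the order in which the rules are stated; the order is configurable.
- Median-imputation donors are measured values from unflagged samples of
  the same clinical group; flagged samples never donate.

Re-running the cascade on its own output is the identity, and the audit
counts reconcile exactly with the per-cell provenance labels (median
imputation records how many previously min-imputed cells it overwrote).

## Statistics

Concentrations are log-transformed before the linear model (right-skewed,
multiplicative biology; a raw-scale option exists). The model is OLS of
log concentration on group (HC = 0, PD = 1) + age (linear, years) + sex
(female indicator); the reported effect is the PD offset in natural-log
units. P-values for the group coefficient are BH-adjusted across entities.
Because the cohorts are strongly age-confounded by design, the group
coefficient's standard error is variance-inflated — the package mirrors the
study design rather than idealising it, and the Mann–Whitney subgroup
machinery (exact enumeration for n ≤ 8 without ties, tie-corrected normal
approximation otherwise; Holm–Šidák step-down within a family) supports the
age-restricted sensitivity analysis. The 2×2 chi-square uses no continuity
correction — the only convention that reproduces the printed cohort-table
p-value (0.00677) from its counts. Spearman correlations use pairwise
deletion (clinical covariates are unevenly available between cohorts) with
BH across the full pair family. MAD is raw (no 1.4826 consistency factor),
matching the cohort table's median ± MAD presentation. PCA operates on
log-transformed, centred, unit-variance-scaled entities via SVD;
zero-variance columns are dropped with a warning.

## Synthetic cohort and concentration model

The cohort generator reproduces the study conditions: 60 HC / 31 PD; HC ages
from a shifted log-normal (median 22, clipped to 19–57), PD from a truncated
normal (median ≈ 58, clipped to 29–82); sex proportions 56.1 % / 25 %
female; PD comorbidity mix 35.7 % diabetes only, 57.1 % diabetes and/or
cardiovascular disease, remainder neither.

True concentrations are log-normal per analyte × matrix with a
multiplicative PD fold-change. Fold-changes are keyed per analyte × matrix
because the reported biology requires it: lithocholic acid falls in PD
plasma (default fold-change 0.4, direction configurable) while rising in PD
feces (2.0). Default medians were chosen once so that (a) the twelve
plasma-detectable and twenty feces-detectable entities match the study's
detection pattern, (b) healthy-control plasma composition is dominated by
LCA (~94 %) with PS near 2 %, and (c) the PD effects reproduce the reported
direction and approximate magnitude: IS exactly ten-fold, PS ~25-fold
(driving its composition share toward ~44 %), and 3–8-fold elevations for
HA, ImP, CMG, PAG, HHA and PAGlu in plasma, with fecal elevations confined
to UDCA, CA, ω-MCA, TCA, DG, DMG, the taurine conjugates, LCA, HA, HHA and
PAGlu. Analytes not detectable in a matrix get detection probability 0
(truly absent) rather than a sub-threshold concentration, which makes the
detection-filter outcome exactly predictable from the generator
configuration. Optional age/sex slopes on the log scale default to zero.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: chromatography (no retention times, peak
shapes, integration error or carryover), between-batch calibration drift
and injection-order effects (the study randomised injection order instead of
modelling drift), correlated metabolite networks (analytes are drawn
independently given group), non-log-normal heavy tails, and real
inter-individual covariate structure beyond age/sex/group. Conclusions
about statistical calibration (type-I error, unbiased fold-change recovery)
hold under the generator's assumptions, not unconditionally.

## Problem sizes and reproducibility

Simulated analyses use the study's sample sizes (60 + 31 subjects, 10-point
triplicate calibration, 10 × 3 precision replicates). Monte-Carlo checks
use 1000 replicates for type-I error and multiple-testing oracles, and 8–12
full-pipeline replicates for fold-change recovery — sizes at which the
binomial band around α = 0.05 is ±1.4 % and the recovery CI is a few percent
of ln 10. Every stochastic component draws from an explicitly passed seed or
generator (`numpy.random.Generator`); named child seeds are spawned per
stage, so full runs are byte-reproducible. Degenerate inputs are defined
throughout: zero noise yields exact round-trips (machine precision), zero
geometric CV yields constant groups (the group test flags constant columns
rather than testing them), empty groups and all-flagged groups are errors,
and a zero mean leaves %RSD undefined (NaN) rather than infinite.

## Known limitations

- The IntStd gate summarises a sample's injections by their mean recovery;
  per-dilution partial suppression is not modelled or detected separately.
- Recovery experiments are simulated at the concentration level (pre- vs
  post-spiked), not re-derived from areas through the full extraction
  model.
- The calibration-failure path (`no_curve`) drops an analyte from the
  matrix; no fallback single-point quantification is attempted.
- Retention-time precision columns are supported in the validation report
  but empty unless the input carries retention times.
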