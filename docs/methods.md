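# Methods

This note documents the models, defaults and numerical choices behind
`synscreen`, and what the synthetic-data generator does and does not
emulate.

## Plate model and normalization

Wells are addressed in the standard microtiter convention (row letters
A–P, 1-based column numbers, string form `A01`) on 384-well (16×24) or
96-well (8×12) geometry. Input tables are long-format UTF-8 CSV with a
mandatory header; geometry is declared, never inferred. Missing signals
are retained as NaN with a flag and excluded from statistics — silent
deletion of dropped wells would hide QC problems, so the reader logs a
count instead. Concentrations are fixed to µM throughout.

Normalization is strictly per plate: compound signal divided by the mean
untreated-control signal of the same plate. This cancels any common
multiplicative factor (reader gain, seeding density, lysis efficiency),
which is verified as an exact invariance property. A plate must carry at
least 3 usable untreated-control wells before normalization is allowed.
Compound randomization across replicates is a property of the input
data, not enforced by the reader; a QC warning flags any compound that
occupies the same address in every replicate.

## Hit threshold

The null spread is estimated from the controls themselves: the sample SD
(n−1) of untreated-control fold changes pooled across all plates of the
run. Pooling yields one screen-wide cutoff rather than per-plate
cutoffs, matching how a single printed band is applied to a whole
campaign. The band is a symmetric additive offset on the linear
fold-change scale, 1 ± k·σ with k = 4 by default; with σ = 0.0825 the
offset is 0.33 and the band (0.67, 1.33). A log-scale band was
considered and rejected: a single additive offset around 1 is what a
printed cutoff of 0.33 on a linear fold-change axis implies.

"More than" the threshold is read strictly: boundary values are
inactive. The replicate consensus rule is configurable ({mean, majority,
all}; default mean of the replicate fold changes), because screening
practice varies and the choice is not dictated by the band itself. A
zero control SD collapses the band to (1, 1) and emits a degenerate-
threshold warning; 1 − k·σ ≤ 0 is rejected outright.

Note a consequence of consensus-by-mean: with r replicates the null
dispersion of a compound's mean fold change is σ/√r, so the realized
false-positive rate sits far below the nominal two-sided 4σ tail
(2Φ(−4) ≈ 6.3×10⁻⁵) computed from single-well spread. The operating-
characteristics checks therefore treat the nominal tail as an upper
bound, not a point prediction.

## Viability and toxicity

Resazurin viability is mean(treated)/mean(vehicle controls), clamped to
[0, 1] with a log entry (values slightly above 1 are routine for healthy
wells under multiplicative noise). High-content viability is
live/(live+dead) per well; the counting itself is upstream of this
package and counts are taken as given. The toxicity verdict is
rule-based on measured points — no IC50/Hill fit is performed, since the
decision needs only "does viability dip below the bound in the relevant
dose range":

* threshold 0.70 (the conventional ~70% cytotoxicity bound; config
  parameter),
* OR-combination of the two assays (conservative for an exclusion
  filter),
* only concentrations at or below the screening concentration count —
  toxicity above the tested dose cannot confound the screen readout.

## qPCR quantification

Relative expression uses the efficiency-corrected ratio with ΔCT
oriented control − treated, so up-regulation gives ratios > 1. Multiple
reference genes are aggregated by the geometric mean of the
per-reference efficiency-corrected factors (the geNorm convention),
computed in log space for numerical stability; this makes the ratio
invariant under permutation of the references and under any global CT
shift. Technical replicates are averaged on the CT scale (the measured
quantity) before ratios are formed. Per-gene amplification efficiency
defaults to 2.0 (no standard curves assumed) and is a config override;
efficiencies outside (1, 2.2] are rejected.

For group comparisons (Dunnett versus the vehicle group) every sample —
vehicle samples included — receives its own ratio against the pooled
vehicle mean CTs, and the test runs on log ratios, since ratios are
multiplicative.

## Protein quantification

Target signal over loading signal (actin for blots, CellTag700 for ICW,
Lamin B1 for nuclear extracts), then each sample's loading-normalized
ratio over the mean vehicle ratio of its batch. Batches (a membrane, an
ICW plate) are normalized independently because loading references are
only comparable within one blot/plate; the vehicle group's own mean fold
change is exactly 1 by construction. ICW background wells (secondary
antibody + CellTag only) are mean-subtracted per channel and batch
*before* the loading division — subtract-then-divide is the documented
order, chosen because background is additive on the raw channel while
loading correction is a ratio; negative corrected targets clamp to 0
with a warning, and a loading signal at or below background marks the
well unusable.

## ANOVA and Dunnett

Both are owned by the package; SciPy contributes only distribution
functions and quadrature. The ANOVA is the classical fixed-effects
decomposition; all-constant input raises a degenerate-data error rather
than returning an infinite or undefined F.

Dunnett's two-sided many-to-one test uses t_i = (x̄_i − x̄_0) /
√(MS_w(1/n_i + 1/n_0)) with pooled error df, and adjusted p-values from
P(max|T| ≤ t) for the equicorrelated-by-control multivariate t, with
λ_i = √(n_i/(n_i + n_0)) — unbalanced designs are handled through the
λ_i, no equal-n assumption. The probability is evaluated by conditioning
on the control variate z and the pooled scale u (u² ~ χ²_ν/ν): the inner
z-integral is analytic and rapidly decaying, so a fixed 160-node
Gauss–Legendre rule on [−9, 9] resolves it far below the outer
tolerance, while the outer u-integral uses adaptive quadrature to
absolute tolerance 10⁻⁶ over the essential support of the scale density.
For a single treatment group the maximum reduces exactly to a Student-t
variable and the closed form is used, which makes the k = 1 case agree
with the pooled two-sample t-test to machine precision. A seeded,
block-vectorized Monte-Carlo sampler of the same max-|t| null serves as
an independent validation path; quadrature and 10⁶-draw Monte-Carlo
agree within ~10⁻³ across a (k, n, t) grid.

Stars are binned at {0.05, 0.01, 0.001, 0.0001}. Reports of this
workflow occasionally show a single-star level of 0.1 in one legend
while stating α = 0.05 elsewhere; that is treated as a typographical
slip and the ladder is configurable.

## Triage cascade

Stages run in fixed order: primary classification → toxicity filter
(inhibitors only; activators are exempt by the screen's stated rule, and
an inhibitor without a viability call is a coverage error, never a pass)
→ reporter qPCR in the screening line → counter-screen specificity →
wildtype target-gene qPCR → protein confirmation. Verdicts are
append-only: the first exclusion wins and later stages cannot re-admit a
compound; compounds missing data while still in play are reported in an
`incomplete` section. The surviving set at each stage is a subset of the
previous stage's, and exclusion reasons plus survivors account for every
compound entering triage.

Decisions where the screening workflow leaves the rule open, resolved
here as package defaults:

* **Specificity band.** The counter-screen "inactive" band is 1 ± k·σ
  computed from the counter-screen's own vehicle ratios, falling back to
  a fixed (0.8, 1.25) when fewer than 4 vehicle samples exist. A
  compound is specific iff its screening-line response is significant
  *and* its counter-screen ratio lies inside the band.
* **Candidate confirmation.** Significance in the screening line *and*
  an effect in the expected direction in wildtype cells are both
  required (neither supersedes the other), and protein confirmation
  requires both ICW and WB by default (`either` is a config option).
* **Follow-up selection.** The "most potent" subset carried into
  validation assays is reproduced as a potency-ranked cap
  (|mean FC − 1|, a package convention) with configurable per-class
  limits; no quantitative definition of "low-activity hits" exists, so
  they are supported only as pass-through selection, not a computed
  class.
* **Degenerate significance.** On noise-free data every within-group
  variance is zero and the t statistic is undefined; the significance
  wrapper then uses the exact zero-noise limit — a group is significant
  iff its mean differs from the control mean. This is what makes
  noise-free round trips exact; it never triggers on real (noisy) data.

## Synthetic-data generator

The generator emulates the study conditions: 384-well plates with a
fixed control block in the last two columns (22 untreated + 6 vehicle +
2 positive-control wells per plate — the original layout fixes the
control block but not its size, so the count is a generator parameter), compound
positions re-randomized for each of 3 replicate experiments, screening
concentration 10 µM, and a positive-control fold change of 1.5. Spiked
effects default to the validated ranges: activator reporter/mRNA fold
changes U(1.4, 2.0), protein U(1.3, 2.0); inhibitors mirrored below 1;
toxic compounds get Hill midpoints of 1–6 µM (below the screening dose)
with slope 2 over the dose series {0.25, 1, 2.5, 5, 10, 25, 40} µM
inside the tested 0.25–40 µM range.

Noise is multiplicative and log-normal (screens are multiplicative),
parameterized by CV for scale-freeness and mean-corrected so the
expected factor is 1: well CV 0.08, per-plate gain CV 0.10, CT noise
0.15 cycles, ~500 cells per imaged well. No noise parameters are
published for the original screen; these are chosen once as realistic
values for automated luminescence screens and SYBR-green qPCR. Base
levels (1000 RLU, target CT 24, reference CTs 20/25/26, ICW background
≈7% of signal) only anchor scales — every downstream statistic is
ratio-based and independent of them, which the invariance tests verify.

At zero noise the generator is exactly deterministic (HCS counts become
deterministic roundings), so every pipeline stage must reproduce the
ground-truth table bit-for-bit — hit classes, toxicity labels under the
Hill rule, Pfaffl ratios, and the final candidate set. Ground truth is
always written as a separate file so pipeline code cannot read it by
accident; every generated CSV records the seed in a header comment, and
identical seed + parameters reproduce all files byte-identically.

What the generator does **not** emulate: spatial artefacts (edge
effects, dispenser striping — there is no B-score/median-polish
correction in the pipeline either), signal cross-talk between wells,
compound fluorescence interfering with the readout, plate-to-plate
control drift within a run, qPCR efficiency differences between genes,
or heteroscedastic protein backgrounds. Passing round-trip tests
therefore demonstrates correctness of the analysis logic under the
stated noise model, not robustness to every artefact of real screens.

## Problem sizes

Test and acceptance runs use a 500-compound library (3 replicates, two
384-well plates per replicate) for round trips, 100 simulated screens
for operating characteristics, 10⁶ Monte-Carlo draws per cell of the
Dunnett validation grid, and 100 seeds × 3 compounds for effect-size
recovery — sizes chosen so the whole suite completes in well under a
minute on one core while keeping Monte-Carlo error far below the
tolerances being checked.

## Known limitations

* The Dunnett quadrature targets absolute tolerance ~10⁻⁶; p-values
  below that are reported but not individually certified.
* The potency ranking used for follow-up caps is a convention, not a
  published rule; reported survivor counts depend on it only through
  the cap.
* The toxicity verdict is pointwise; a compound toxic only *between*
  tested concentrations is invisible, as it would be to the assay.
* Technical and biological replicates are not distinguished in the
  qPCR group comparisons; replicates are pooled per compound.
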