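# Methods

## Scope and model

The package analyzes promoter DNA methylation of a gene panel across a
longitudinal tumor cohort (stages Primary, Recur1, Recur2, with Recur3
carried descriptively only), and integrates the resulting hypo-/
hypermethylated gene sets with expression and survival data.  β values
(fraction methylated signal, in [0, 1]) are consumed as produced by
upstream array preprocessing; probe QC, normalization and IDAT parsing
are out of scope.

Assumptions baked into the design:

- The promoter of a gene is fully described by the manifest annotation
  (TSS1500 / TSS200 / 5UTR / 1stExon); no genome-coordinate windows.
- Patients are the independent units.  Multiple samples from one patient
  at one stage are averaged before any test; repeated measures across
  stages are handled by the patient random intercept in the M-scale
  models and by patient-level blocking in LOPO.
- 0.50 is the hemi-methylated reference: a promoter is only biologically
  "called" when its median β clears both a significance criterion and an
  absolute-level gate.

## Stage calling

Per gene and stage the per-patient promoter β values are tested against
0.50 with a one-sample Wilcoxon signed-rank test.  Exact null
distribution for n ≤ 25 when the |differences| are tie-free; normal
approximation with continuity correction otherwise; values exactly equal
to 0.50 are dropped before ranking (Wilcoxon convention); if all values
equal 0.50 the p-value is 1 by convention, and with fewer than 3 usable
values it is undefined and the gene is reported NS with a reason.
BH-FDR is applied across panel genes within the stage.

Call gates (all configurable through `CallingParams`):

| parameter | default | meaning |
|---|---|---|
| `beta_lo` | 0.30 | β_median ≤ this → HYPO-eligible (boundary inclusive) |
| `beta_hi` | 0.70 | β_median ≥ this → HYPER-eligible (boundary inclusive) |
| `min_delta` | 0.20 | required |β_median − 0.50| |
| `alpha` | 0.05 | FDR threshold |

At the defaults the β gates imply the Δβ gate (|0.30 − 0.50| = 0.20),
but the two are enforced independently so either can be changed alone.

Patient-level calls (used for burden and transition analyses) cannot use
a significance test at n = 1; they apply the β gates alone.

## M-scale models and calling agreement

M = log₂((β + ε)/(1 − β + ε)) with ε = 10⁻⁶ keeps the transform finite
at β ∈ {0, 1} and variance-stabilizes the scale for linear modelling.

The per-gene trend model is a linear mixed model: M ~ stage (ordinal,
coded 0/1/2) with a patient random intercept, REML estimation, and a
Wald z test on the slope (Satterthwaite corrections are not applied; the
choice is documented here and the fallback path makes it visible).  When
fewer than 3 patients contribute ≥2 stages, or the mixed fit fails, the
model falls back to OLS and the result is flagged `method="ols"`.

The threshold test of H₀: |effect| ≤ τ uses the shifted-statistic
construction p = P(T > (|e|−τ)/se) + P(T > (|e|+τ)/se); the default
τ = |log₂(0.7/0.3)| ≈ 1.2224 is the M-scale image of the β effect gate.
Model-based stage calls, used for the agreement analysis, test the
stage-wise mean M against M(0.5) = 0 with this threshold test (Student-t
tails, BH across genes) and call by the sign of the mean.  This mapping
from model decisions to HYPO/HYPER/NS labels is a design choice of this
package and is stated here because several mappings are defensible.

Cohen's κ is the unweighted multi-category statistic
(p_o − p_e)/(1 − p_e); when both call vectors are the same constant
label, p_e = 1 and κ is defined as 1.  The implementation is
cross-checked against scikit-learn in the test suite.

On well-separated data (class means 0.15/0.85/0.50 at n = 80) the β-gate
and model-based calls agree perfectly (κ = 1).  At very small n (the
14-patient second-recurrence stage of the default design) the rank test
and the t-based threshold test can diverge on borderline genes; this is
a power phenomenon, not a defect, and the acceptance checks therefore
measure agreement at the well-powered stage.

## Longitudinal dynamics

Burden is the per-patient count of HYPO and HYPER patient-level calls at
a stage.  k-means (squared Euclidean, 25 restarts, fixed seed) clusters
the raw 2-D count space — both axes share the count scale, so no
standardization — and groups are labelled Low/Mid/High by ascending
centroid count sum (ties broken by the n_hypo centroid).  Average
silhouette widths for k = 2..5 are reported per stage; identical counts
make the silhouette undefined and are reported as NaN.  Clustering is
done within stage; cross-stage burden comparisons use the same
Kruskal–Wallis + BH pairwise rank-sum machinery with stage as the group.

Transition events compare a patient's promoter β between adjacent
stages: Δβ ≤ −0.20 → HypoGain, Δβ ≥ +0.20 → HyperGain, else Stable.
Per-gene totals (HypoGain and HyperGain summed across transitions) feed
an exact two-sided binomial test against 0.5 using the minimum-likelihood
two-sided definition (sum of all outcome probabilities not exceeding the
observed one); BH across genes with ≥1 event.

## Enrichment

Over-representation is the hypergeometric upper tail P(X ≥ k) with the
user-supplied background as the universe; terms are intersected with the
background first and filtered to 3–500 in-background members (both
configurable).  BH-FDR replaces service-specific multiple-testing
schemes so that significance criteria are uniform across the package.
Collections are plain GMT inputs; nothing is bundled.

## Scores, coupling, survival

In-sample Z standardizes each sample's expression across a gene universe
(default: all genes supplied; a panel-restricted universe is available —
the full-transcriptome default is the more stable choice when the panel
is small).  ExprScore = mean(Z_HYPO) − mean(Z_HYPER);
MethScore = mean(β_HYPER) − mean(β_HYPO).  Set coherence uses a paired
Wilcoxon on the per-sample set difference with a Hodges–Lehmann
pseudo-median; per-gene one-sample Wilcoxon tests on Z count as coherent
only when FDR < 0.05 *and* the shift sign matches the set.

Spearman coupling uses mid-ranks with the t-approximation for n > 20 and
a seeded Monte-Carlo permutation p (9,999 permutations) at smaller n,
where the approximation is unreliable and full enumeration is
infeasible.  Significant coupling requires FDR < 0.05 and |ρ| ≥ 0.30.

Cox models use lifelines with Efron tie handling (Breslow available).
The per-SD model standardizes the score in-cohort and adjusts for age
and sex; a Schoenfeld-residual test on the score term is reported as the
proportional-hazards diagnostic.  Quartiles use linear-interpolation
quantile cut points with boundary values assigned to the lower quartile;
the Q4-vs-Q1 contrast reports KM curves with 95% bands, the two-group
log-rank p, and the adjusted Cox HR.  Per-gene analyses dichotomize at
the cohort median (High > median, values at the median → Low), report an
unadjusted binary Cox HR (age/sex adjustment behind a flag), and control
BH-FDR over the log-rank p-values.  Samples with missing subtype are
excluded from subtype tests only.

## The synthetic cohort generator

The generator emulates the *structure* of a longitudinal EPIC-array
glioblastoma cohort, with every downstream estimand planted explicitly:

- **Manifest**: 60 genes by default, 2–6 promoter probes each plus
  occasional gene-body probes; a configurable number of genes is forced
  below the 2-probe panel gate.
- **Classes**: genes are HYPO / HYPER / NS in proportions 0.54/0.15/0.31
  with promoter β means 0.15 / 0.85 / 0.50 — the approximate mix and
  separation a gliogenesis promoter panel exhibits.
- **Noise**: per-probe β ~ Beta(μc, (1−μ)c) with concentration c = 50,
  giving the few-percent probe-level spread typical of arrays.  The
  paper trail for array noise is thin; this is the package's choice.
- **Patients**: 106 by default; every patient has a Primary sample,
  ~50% a first recurrence, ~18% a second, and two patients a third
  (nested subsets).  A per-patient random intercept with SD 0.15 on the
  M (log₂-odds) scale is back-transformed into β, which keeps β bounded
  — the `patient_effect_sd` unit is therefore M, not β.
- **Events**: each (patient, gene, available transition) receives a ±0.30
  β step with probability 0.05, applied from the later stage onward.
  Direction is sampled uniformly but flipped when the step would push the
  promoter mean outside [0.05, 0.95], so planted events remain
  recoverable; as a consequence HYPO-class genes accumulate upward steps
  and HYPER-class genes downward ones, which creates genuine (and
  intended) stage trends on the M scale.
- **Expression**: log-scale, baseline ~ N(6, 1.5); for a coupled gene
  (33% of the panel) expression adds 1.0·(−M(β)) plus N(0, 0.5) noise,
  which lands Spearman ρ near −0.45 at n ≈ 74 — the regime of interest
  for the coupling analysis.
- **Survival**: exponential event times with
  log-hazard = ln(hr_per_sd)·z(score) + 0.02·(age − 60) + 0.1·sex over a
  baseline median of 14 months; censoring is an independent exponential
  clock calibrated to the requested censoring fraction (default 0.2).

What the generator does **not** emulate: probe-level spatial
correlation, detection-p missingness, batch effects, copy-number
contamination of β, treatment covariates, within-stage replicate
samples, or non-proportional hazards.  Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
under idealized array-like noise — not robustness to the full messiness
of real cohorts.

## Problem sizes used in the checks

The automated checks run the pipeline at 60 genes × 80 patients for
calling/agreement/stability (where the behaviors of interest are already
asymptotic), 347 samples × 200 replicates for Cox CI coverage, and 500
replicates for the type-I calibration of the Kruskal–Wallis, log-rank
and stage-calling nulls.

## Known limitations

- The model-based call mapping (threshold test on stage-wise mean M) is
  one of several defensible readings of "model decisions"; alternatives
  (e.g. contrast-based calls between stages) would need a different
  agreement baseline.
- The mixed model uses Wald z inference; for very few patients the
  p-values are anti-conservative, which is why the OLS fallback and the
  `method` flag exist.
- LOPO retention is reported only for calls significant in the full
  data; it does not measure discovery of calls that appear on resampling.
- The exact Wilcoxon path requires tie-free |differences|; tied data at
  n ≤ 25 silently use the normal approximation (with correction), which
  is standard but approximate.
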