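# Methods

`mirnorm` implements a quality-controlled RT-qPCR analysis workflow for
circulating miRNAs in plasma, centred on an exhaustive combinatorial search
for the most stable set of endogenous reference miRNAs ("normalizers").
This note describes the models and procedures, the parameters that matter,
the numerical choices, what the synthetic cohorts do and do not emulate,
and the known limitations.

## Relative quantification: −ΔΔCq

All stability computations consume log2 relative expression derived from
quantification cycles (Cq). For sample *s*, target assay *t* and a
combination *C* of reference assays:

```
ΔCq_s  = Cq(t, s) − mean_{r∈C} Cq(r, s)
ΔΔCq_s = ΔCq_s − m
value  = −ΔΔCq_s        ( = log2(2^−ΔΔCq) )
```

The per-sample reference is the arithmetic mean of the member Cq values,
which equals the log2 of the geometric mean of the members' relative
quantities — the standard way to pool multiple reference genes.
Amplification efficiency is fixed at perfect per-cycle doubling; no
Pfaffl-type per-assay efficiency calibration is attempted.

The anchor *m* is configurable:

* `control_group_mean` (default) — the mean ΔCq over control-group
  samples, the classical ΔΔCq convention. The control-group mean of the
  output is then identically zero for every target.
* `grand_mean` — the mean over all samples; the all-sample mean is zero.
  This variant makes the "deviation from zero" metric informative for both
  groups rather than only the case group.

Samples missing the target or any member Cq are excluded pairwise for that
(target, combination), never imputed; in particular an "Undetermined" well
is missing, not Cq 40, because any imputation rule materially distorts the
stability metrics downstream.

## Covariate adjustment

Circulating miRNA levels drift with age and differ by sex in ageing
cohorts, so an optional adjustment step removes linear age trends within
sex strata before stability analysis: per stratum and assay, ordinary
least squares of Cq on age; the adjusted value is the residual recentred
on the stratum's assay mean. This preserves each stratum's location and
spread, so Cq-scale thresholds (e.g. the haemolysis ΔCq cut-off, if applied
to adjusted data) stay meaningful. Strata with fewer than 3 samples, or
with constant age, pass through unchanged with a warning. The pipeline
default applies QC exclusions before adjustment.

## The combinatorial normalizer search

For a panel of *n* candidates (*n* ≤ 11 by default; the cost doubles per
added candidate) all 2^n − 1 non-empty subsets are enumerated. Each subset
is identified by a bitmask code over the declared panel order — code =
Σ 2^i over member indices — so codes cover 1…2^n − 1 exactly once and a
code↔members translation table is always emitted alongside results.

Each combination is scored against an evaluation set of targets (default:
all *n* candidates, including the combination's own members; a member
normalized against a combination containing only itself yields exactly
zero, a legal degenerate case that keeps the full-panel combination
evaluable — `exclude_self_targets` flips this). For every target, the
−ΔΔCq values of the case and control groups are compared on three
metrics, each averaged over targets:

1. **KS** — the two-sample Kolmogorov–Smirnov statistic D between the two
   groups' value distributions (0 = identical, 1 = disjoint). The D
   statistic, not the p-value, is used by default because p-values are
   sample-size dependent; with `ks_measure="pvalue"` the complement
   1 − p is scored so that lower remains better.
2. **dev** — the mean over the two groups of |group mean|, the
   displacement of each group's centre from zero.
3. **sd** — the mean over the two groups of the within-group sample
   standard deviation (n − 1 denominator).

A good normalizer combination makes every candidate's normalized values
indistinguishable between groups (low KS), centred (low dev) and tight
(low sd). Targets where either group has fewer than `min_group_size`
(default 3) complete samples are dropped with a warning; a combination
with no surviving target is reported unevaluable, never silently zero.

### Rank aggregation and weights

Within each metric, combinations are ranked ascending (smaller is better)
and converted to points: best = n_combinations − 1, worst = 0, ties
averaged, so points per metric always sum to n_c(n_c − 1)/2. The final
score is `w_ks·P_ks + w_dev·P_dev + w_sd·P_sd` with nonnegative user
weights (default (1, 1, 1)); the final rank is descending in that total,
with deterministic tie-breaks on lower KS metric, then lower sd metric,
then smaller code. Multiplying all weights by a positive constant cannot
change the ordering, which is why the default weight grid — {1, 2, 3}³
minus the two redundant uniform scalings (2,2,2) and (3,3,3), 25
weightings — spans relative emphases only. `weight_grid_scan` computes
scores once and re-aggregates per weighting, reporting each weighting's
top-k codes and how often each combination stays in the top k.

A note on the points scheme: with n_c items and unit steps one cannot
simultaneously give the top item n_c points and the bottom 0; this package
fixes best = n_c − 1 and bottom = 0. For unweighted ranking the choice is
immaterial by scale invariance.

### Properties of rank-point aggregation worth knowing

Rank points deliberately discard the magnitude of metric differences; two
consequences are documented because they shape results:

* metrics with tiny raw spreads (often sd) carry the same point range as
  metrics with large spreads (often KS), and
* larger combinations enjoy a systematic sd advantage because averaging
  more reference assays shrinks reference noise.

On synthetic cohorts this means the winning combination reliably equals
the planted stable set only when that set is large enough (≈5 of 7
candidates at shift 1.5 Cq, SD 0.2 Cq) to claim the size advantage itself;
with fewer stable candidates the winner tends to annex one shifted
candidate for its reference-size benefit, trading compressed KS/dev points
for sd points. Users who consider group displacement disqualifying should
up-weight KS/dev accordingly — this is exactly the judgement the weight
surface exists to express.

## Baseline stability algorithms

For benchmarking, three classical single-candidate measures are
re-implemented, operating on Cq directly under perfect doubling (log2
expression = −Cq, so variances are unchanged):

* **geNorm** — M_j = mean over other candidates k of SD(Cq_j − Cq_k);
  stepwise exclusion removes the highest-M candidate until two remain.
  Pairwise differences cancel per-sample effects, so M is invariant to
  global sample shifts.
* **BestKeeper** — per-candidate SD and CV of Cq plus Pearson r against
  the BestKeeper index (per-sample mean of candidate Cq). Zero-variance
  candidates report r as undefined with a reason.
* **NormFinder-style** — on sample-centred Cq (each sample's mean across
  candidates subtracted), for candidate i and group g let d_ig be the
  group mean and s²_ig the within-group sample variance; stability_i =
  mean_g |d_ig − mean_g' d_ig'| + mean_g √(s²_ig / n_g). This is a
  simplified variant of the published model-based decomposition: the
  intergroup bias term is unshrunken and the simple (uncorrected) variance
  estimator is used. With a single group the fallback stability is the SD
  of the centred residuals.

`aggregate_and_compare` ranks all size-k combinations under each method —
single-candidate methods score a combination by the mean of member
stabilities, a convention of this package — plus a mean-rank composite,
and reports pairwise Spearman correlations between the method rankings.

## Haemolysis quality control

Red-blood-cell lysis releases both haemoglobin and RBC-enriched miRNAs
(miR-451a) into plasma. Two detector families are provided:

* **ΔCq rule** — score = Cq(miR-23a-3p, plasma-enriched) −
  Cq(miR-451a, RBC-enriched); a score strictly above the threshold
  (default 7 cycles) flags contamination; exact equality is not flagged
  but raises a boundary warning; a sample missing either marker is
  unevaluable, never flagged. miR-16-5p is supported as the alternate RBC
  comparator. Raw (unadjusted) Cq is used by default.
* **Absorbance scores** — read off a 220–750 nm wavelength scan,
  exploiting the oxyhaemoglobin Soret band near 414 nm. `peak414` is the
  raw absorbance at 414 nm. The named multi-wavelength presets carry the
  wavelength triples of two published schemes — `shkurnikov`
  (415 / 450 / 700 nm) and `kahn` (578 / 562 / 598 nm) — combined here as
  baseline-corrected peak height: A(primary) minus the straight line
  through the two reference wavelengths. The published coefficient
  constants are not baked in; an arbitrary wavelength→weight map is
  accepted for exact transcriptions. Baseline-corrected scores are
  invariant to adding a constant to the whole spectrum and scale linearly
  with it. Spectra are linearly interpolated between grid points
  (1 nm grids make higher-order schemes immaterial); queries outside the
  measured range are errors, not extrapolations.

`method_concordance` reports Pearson r, least-squares slope/intercept and
n for each score column against a reference score (default `peak414`),
with explicit "not evaluable" statuses for <3 pairs or zero variance.

## Spike-in controls

Synthetic C. elegans miRNAs added before isolation (cel-miR-39-3p,
cel-miR-2-3p) and before reverse transcription (cel-miR-238-3p,
cel-miR-54-3p) should be constant across samples. Per spike-in, z-scores
are computed within a stratum (default: cohort, deliberately not the
diagnostic group, so flagging cannot depend on diagnosis); a stage is
flagged when |z| exceeds the threshold (default 2.0 — a package default,
not a published cut-off) for ANY spike-in of that stage, the conservative
choice given that individual spike-ins can behave idiosyncratically.
Strata smaller than 3 or with zero SD yield undefined z with a reason.

Correction is off by default (`mode="none"`): the recommendation to
correct for isolation/RT efficiency comes without a published formula, so
data are never silently altered. The documented option
`subtract_stage_deviation` removes from each sample's targets the mean
spike-in deviation from the batch **median** (robust to the very outliers
the controls exist to find); samples missing spike-in Cq are left
uncorrected with a warning.

## Synthetic cohorts

The generator emulates a two-group ageing cohort: default 40 samples per
group (HC vs AD labels), the 7-candidate endogenous panel with plasma-like
baseline Cq values (21–27), Gaussian within-group noise (default SD
0.2 Cq — log-scale noise, where multiplicative expression noise is
approximately additive), optional case-group shifts, uniform ages 55–85
with optional per-assay linear age slopes and sex effects, both spike-in
stages (baseline 23 Cq, SD 0.3, 5% planted outlier samples shifted
+3 Cq), and a haemolysis mechanism: 20% of samples draw a contamination
level uniform on [0.5, 2.0] that lowers the miR-451a Cq by 2 per unit
level and raises the 414 nm absorbance band by 0.3 OD per unit level.
Spectra are a smooth decaying plasma baseline plus Gaussian bands at
414/541/577 nm and Gaussian noise (SD 0.005 OD). Ground truth ships in
`gt_*` metadata columns.

What the generator does **not** emulate: physically calibrated haemoglobin
extinction spectra, bilirubin/lipaemia interference, qPCR efficiency
variation, machine/software batch structure, missing-well patterns, or
non-Gaussian heavy-tailed noise. Passing tests therefore demonstrate
algorithmic correctness and qualitative behaviour under the assumed
structure, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

* Group SD uses the n − 1 denominator throughout.
* The KS statistic is computed directly from the two ECDFs evaluated over
  the pooled sample points; the unit tests cross-check it against an
  independent library implementation and a naive enumeration oracle.
* Tie handling everywhere is average-rank; final-total ties break
  deterministically (KS metric, then sd metric, then code).
* Cq plausibility gate [0, 45] at load, with a permissive override;
  "Undetermined"/blank map to missing.
* All-equal metric columns degrade to uniform points with a warning;
  unevaluable combinations and unevaluable concordance pairs carry
  explicit statuses.
* Simulations are deterministic under a fixed seed
  (`numpy.random.default_rng`); spectra derive their stream from the same
  seed via a seed sequence so Cq and spectral noise are independent.

## Problem sizes used in the shipped checks

The test suite exercises cohorts of 20–60 samples per group and panels of
up to 11 candidates (2047 combinations); the recovery property uses 20
seeded cohorts of 40 samples per group with a 7-candidate panel. These
sizes were chosen to mirror the cohort scale the method targets while
keeping the full suite fast on a laptop.

## Known limitations

* The rank-point aggregation properties above mean the "best" combination
  is a weighted compromise, not a guarantee that every member is
  individually stable.
* The NormFinder variant is simplified (no variance shrinkage); absolute
  stability values are not comparable to the original implementation's,
  though orderings agree on the structures tested.
* Absorbance presets without published coefficients quantify relative, not
  absolute, haemoglobin content; no g/L calibration is provided.
* Combination-level scores for single-candidate baselines (mean of member
  stabilities) are a pragmatic convention for comparison plots, not part
  of those methods' definitions.
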