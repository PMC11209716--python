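# Methods

## The screening procedure

`depscreen` implements a behavioral screen that partitions a two-group
mouse cohort — unstressed controls (Ctrl) and animals exposed to chronic
unpredictable mild stress (CUMS) — into depressive (Dep), non-depressive
(noDep) and control subgroups. The screen has three stages.

**1. Per-measure ROC and Youden cutoff.** Each behavioral measure —
sucrose preference (SPT, %), open-arm time in the elevated plus maze
(EPM, s), immobility time in the forced swim test (FST, s) — is treated as
a diagnostic marker for CUMS-group membership (positive = CUMS, negative =
Ctrl; group membership is the only binary available before scoring, and
this labeling choice is an assumption of the implementation). Measures are
first *oriented* so that larger values mean "more depressive": SPT and EPM
are negated (low values are depressive), FST passes through. The ROC sweep
uses the unique observed oriented values as thresholds (plus a +∞
sentinel), with the decision rule "oriented value ≥ threshold ⇒ positive",
so the reported cutoff is always an attained data value. The AUC is
computed both as the trapezoidal integral of the ROC polygon and as the
Mann–Whitney concordance probability P(score⁺ > score⁻) + ½·P(tie); the
two are mathematically identical on this grid and the code asserts their
equality on every call. The optimal cutoff maximizes the Youden index

    J = TPR − FPR = sensitivity + specificity − 1

over all thresholds. Ties in J are broken in favor of higher sensitivity
(a screening context prefers catching susceptible animals), then lower
oriented threshold; the result is deterministic and identical to an
exhaustive scan. Cutoffs are reported back on the original measure scale.

**2. D-score.** Each animal is flagged on each criterion by comparing its
raw value with the cutoff. Equality counts as positive: this follows from
the "≥ threshold" ROC convention after un-orienting, so a "low"-direction
measure flags at value ≤ cutoff and a "high"-direction measure at
value ≥ cutoff. The depression score (D-score) is the number of positive
flags, 0–3 for the standard triple. The score is monotone: moving any
measure further in its depressive direction can never lower it.

**3. Subgroups.** CUMS animals with D-score 3 are Dep; with D-score 0 or 1,
noDep; with D-score 2, excluded (the named subgroups exhaust only scores
0, 1 and 3, so exclusion is the only consistent reading). Ctrl animals are
retained only at D-score 0 and excluded otherwise. Exclusions are always
counted and reported, never dropped silently. Cutoffs are derived on the
full cohort and applied to the same cohort by default; frozen criteria can
also be applied to a second cohort, which is how recovery is evaluated on
synthetic data.

Stability of the fitted cutoffs can be reported via a stratified bootstrap
(resampling within label classes, percentile intervals; default 2000
resamples, 95% level, seeded).

## The synthetic cohort generator

No raw per-animal behavioral data are available to this package, so all
statistical validation runs on synthetic cohorts with known ground truth.
The generator draws:

- **Ctrl** animals from a control component;
- **CUMS** animals from a latent two-component mixture: with probability
  `susceptible_prop` (per-animal Bernoulli; an exact-count option exists
  for fixtures) an animal is *susceptible*, otherwise *resilient*
  (control-like). Each record carries its latent tag.

Within an animal, the measures are joined by a Gaussian copula and given
truncated-normal marginals on each measure's physical support (SPT on
[0, 100] %, EPM on [0, 300] s for the 5-minute test, FST on [0, 240] s for
the scored last 4 minutes). Sampling maps a correlated standard-normal
vector through Φ and then through the inverse CDF of the component's
truncated normal, so bounds are respected exactly with no clipping. The
copula correlation is specified on oriented scales (depressive direction
positive), so one positive-definite matrix expresses "depressive measures
co-vary"; on raw scales this implies, e.g., a *negative* SPT–FST
correlation. For a Gaussian copula the implied Spearman correlation is
6/π·asin(ρ/2), which the tests use as the analytic oracle.

Reproducibility: a single integer master seed is expanded into three
sub-streams (control measures, CUMS latent assignment, CUMS measures) via
`numpy.random.SeedSequence.spawn`, so the same seed always yields a
byte-identical cohort and the latent assignment is unaffected by changes
to the measure draws.

### Default parameters (calibration stand-ins)

The default configuration (`default_paper_params`) uses group sizes
n_ctrl = 25 and n_cums = 50 — the two-group design the screen targets. The
remaining values are **implementer-chosen calibration stand-ins, not
estimates of any real cohort** (no distributional form or effect sizes are
published for these measures):

| parameter | default | rationale |
|---|---|---|
| Ctrl SPT | 85 ± 8 % | healthy mice strongly prefer 1% sucrose |
| Ctrl EPM open-arm time | 60 ± 20 s | ~20% of a 300-s test |
| Ctrl FST immobility | 100 ± 30 s | ~40% of the scored 240 s |
| susceptible shift | 1.75 pooled SD toward depression per measure | large but overlapping effect |
| susceptible_prop | 0.35 | roughly a third of stressed animals succumb |
| copula correlation | 0.5 pairwise (oriented) | clearly positive cross-measure coherence |

The resilient component is identical to Ctrl. With these settings the
generator produces moderate per-measure AUCs and a Dep fraction broadly
in the expected range, but individual draws vary; nothing in the defaults
is tuned to reproduce any published cutoff or proportion.

### What the generator does and does not emulate

It emulates bounded, correlated, unimodally distributed measures with a
latent susceptibility mixture. It does not emulate: time-course
trajectories (weekly body weight or sucrose preference), floor/ceiling
clumping from timer resolution, batch or cage effects, measurement error
distinct from biological variation, or non-Gaussian dependence. Passing
tests therefore demonstrate correctness and calibration of the *pipeline*,
not fidelity to any real cohort's distributions.

## Recovery evaluation

On synthetic cohorts the Dep label is scored against the latent tag among
CUMS animals (Dep = predicted susceptible; noDep and excluded = predicted
not). Sensitivity, specificity and balanced accuracy are reported with
confusion counts; with zero latent positives (or negatives) the
corresponding rate is undefined and reported as `None` rather than 0. A
pre-registered simulation with the default configuration over seeds 0–99
gave mean balanced accuracy 0.801 (SD 0.066), rising from 0.678 at a
1.0-SD shift to 0.879 at 2.5 SD; the test suite freezes the bound
"mean > 0.8 at the default shift, monotone across shifts" from that run.

## Assay calculators

Pure, unit-annotated arithmetic for the accompanying biochemistry:

- Sucrose preference % = 100 · sucrose / (sucrose + water).
- ATP production (μmol/g) = 0.625 · ΔA_test / (ΔA_standard · W_test),
  with ΔA = A2 − A1 from 3-min kinetics at 340 nm.
- ETC complex activity (U/mg protein) = 1099 · ΔA / W_protein, with
  ΔA = (A1ᵗᵉˢᵗ − A2ᵗᵉˢᵗ) − (A1ᵇˡᵃⁿᵏ − A2ᵇˡᵃⁿᵏ) from 1-min kinetics at
  550 nm. Citrate synthase control activity uses the same arithmetic
  (assumption: no separate formula applies).
- Relative values are plain percent-of-control ratios.
- ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = ΔCt_treated −
  ΔCt_control, fold change = 2^(−ΔΔCt); used for mRNA (GAPDH reference)
  and mtDNA content alike.

The kit constants 0.625 and 1099 are treated as opaque printed values that
already absorb path length, extinction coefficient and kinetic timing; the
calculators never rescale per minute. Negative blank-corrected ΔA is
returned as computed with a warning (decreasing-absorbance kinetics with a
noisy blank), never clipped; fold changes are necessarily positive. Ct
values outside 5–40 cycles warn but do not error.

## Numerical choices and degenerate inputs

- ROC requires ≥ 1 animal per class; single-class input raises. NaN scores
  raise, naming the record index.
- Between-class ties get half credit in the concordance identity; the
  trapezoid handles them via shared threshold points. The two AUCs agree to
  machine precision and the code asserts `|Δ| < 1e-12`.
- If only the +∞ sentinel attains the maximal J (J = 0 everywhere), the
  highest observed value is reported as the cutoff so the result is always
  an attained data value.
- Correlations on constant columns are reported as undefined (a `defined`
  flag), never as silent NaN. Correlation p-values are raw by default; a
  Holm adjustment is available behind a flag.
- Cohort CSVs are written with shortest round-trip float repr and read
  with `float_precision="round_trip"`, so write→read is bit-exact.
- Proportions in summaries are rounded to 0.1%; no rounding occurs inside
  any comparison.

## Problem sizes used in the shipped checks

The test suite and the reproduction script use: 1,000 random small ROC
instances (3–30 per class, integer-valued to force ties) for oracle
equivalence; 200 seeds at n = 25/50 for null calibration; 100 seeds for
recovery, at three shift levels; 500 label permutations; n = 50,000 for
marginal fidelity and n = 10,000 for copula dependence. These sizes give
sub-percent Monte-Carlo error on the quantities checked while keeping a
full run in the low minutes on one CPU.

## Known limitations

- The screen is purely threshold-based; it inherits the instability of
  Youden cutoffs at small n (hence the bootstrap reporting).
- Group membership as the ROC reference standard is an interpretive
  choice; with a different reference the cutoffs would differ.
- The generator's Gaussian-copula + truncated-normal form is a modeling
  convenience; heavy-tailed or multimodal real data could behave
  differently, and published cutoffs/proportions cannot be reproduced
  without the underlying per-animal data.
- NSF latency and open-field measures are supported as data columns but
  are deliberately not scoring criteria (validation measures only).
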