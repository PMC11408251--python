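# Methods

## Scope and model

`crossmem` operationalises a cross-species candidate-gene analysis: blood
probe-level expression correlated with a continuous symptom score in a
case–control human cohort, hippocampal gene-level expression contrasted
between reactivated and non-reactivated animals, symbol-level joining of
the two effect tables, direction-consistency gating, case–control
curation, target-gene co-expression with gene-set overrepresentation, and
a candidate-gene CpG screen with mediation. The pipeline starts from
expression matrices; alignment, quantification and array/IDAT parsing are
out of scope.

## Normalization

Raw intensities are floored at 1.0 (below-floor signals are
noise-dominated), log2-transformed, shifted so each sample's 75th
percentile is zero, then baseline-transformed by subtracting each
feature's across-sample median. The percentile uses linear interpolation
between order statistics; vendor software does not document its
convention, so the percentile (and floor) are parameters of
`NormalizationParams`. The two invariants hold at different points of the
chain — the per-sample percentile is exactly zero *after the shift step*,
the per-feature median exactly zero *after the baseline step* (the
baseline step necessarily perturbs sample percentiles) — so
`normalize_microarray(..., return_stages=True)` exposes the intermediate
matrices and the tests check each invariant where it is defined.

## Statistical conventions

* All p-values are two-tailed; correlation p-values use the exact t
  transform with n − 2 df (n − 2 − k for partial correlation with k
  covariates).
* Case–control contrasts use the pooled-variance (Student) t-test, not
  Welch. The optional ANCOVA fits expression ~ group + covariate per
  feature and reports the group term's F on (1, n − 3) df.
* Mouse differential expression applies the same pooled t-test to
  log2-scale expression — a deliberate choice to mirror the analysis
  this package operationalises rather than a count model (a count-model
  route is out of scope). BH adjustment is the classical step-up
  q(i) = min over ranks j ≥ i of p(j)·m/j over the family of genes with
  nonzero variance in at least one group; flat genes are flagged and
  excluded from the family.
* Fold changes are reported both as log2FC (difference of group means)
  and as signed linear FC = sign(log2FC)·2^|log2FC|, so a 1.4-fold
  decrease prints as −1.4 and |FC| ≥ 1 always.
* All gate inequalities are strict (|r| > 0.40 excludes 0.40 exactly).

## Integration gates

Human probes and mouse genes are matched case-insensitively on gene
symbol; probes without symbols are dropped, and a multi-probe gene
contributes one record per probe (a gene *passes* a gate if any of its
probes does). A record is *consistent* when both effects are nonzero and
share a sign; zero or undefined effects make the record degenerate and
inconsistent (conservative). Three gates exist because effect-size and
significance screens answer different questions:

* `broad`: human p < 0.05 ∧ mouse q < 0.05, no consistency requirement,
  single-pass exclusion of records more than 10 SD above the mean on the
  standardized mouse fold-change axis (the axis where a fold-change
  blow-up is plausible; the exclusion axis is a package choice).
* `hybrid`: |human r| > 0.40 ∧ mouse q < 0.001 — the
  joint-sign-characterisation gate.
* `strict`: hybrid plus |linear FC| > 1.36 plus consistency — the
  candidate-gene gate.

Curation then requires a case–control p below threshold *and* a direction
match: a gene negatively correlated with severity must be lower in
patients. Concordance summaries z-standardize both axes (signed linear FC
by default, log2 optionally) and report Pearson r, the consistent
fraction, and the 2×2 sign-quadrant counts.

## Enrichment

Overrepresentation uses the hypergeometric upper tail P(X ≥ k) with BH
across sets. The background universe is all measured genes after symbol
harmonization — enrichment backgrounds are frequently left implicit in
published analyses, so the universe is an explicit argument. No GO-graph
propagation or rank-based (GSEA-style) statistics are attempted.

## Methylation screen and mediation

The tripartite screen requires, per CpG, p < α (default 0.05, uncorrected
— a BH flag exists but the default mirrors common candidate-gene practice)
for both methylation~symptom and methylation~expression, and sign
compatibility sign(r_me)·sign(r_es) = sign(r_ms) with all three signs
nonzero. Mediation uses ordinary least squares throughout; the indirect
effect a·b carries the Sobel normal-theory SE and a case-resampling
bootstrap percentile CI (BCa by flag; percentile is the default because
the estimator's bias is small at these n and percentile intervals are the
more transparent choice). For OLS on complete data, c = c′ + a·b is an
algebraic identity and is enforced to 1e-8 in tests. Because published
mediation tables often mix scales (raw paths whose product does not equal
the printed indirect effect imply standardization somewhere),
`mediate_both_scales` reports raw and fully z-scored parameterizations
side by side; the standardized indirect effect is the headline number.
In the pipeline the screen and the mediation run on patients only by
default (`mediation_group="PTSD"`): the symptom score carries meaningful
variance within patients, while the full cohort's case–control separation
would dominate otherwise. The symptom-correlation screen itself always
uses the full cohort.

## Synthetic-data generator

The generator emulates the study design's statistical skeleton: 32
patients and 16 controls; a 0–40-like intrusion-subscale symptom score
(patients centred at 22, controls at 4, residual SD 4 — the exact scale is
irrelevant to correlation-based stages and is recorded in the truth file);
tens of thousands of probes with log2-scale Gaussian noise around
per-probe baselines, emitted as raw intensities 2^log2 so the full
normalization chain applies; mouse groups of 8 animals. Planted structure:

* **Shared-signal genes** — human probe = baseline + sign·β·z(symptom) +
  σ·ε with β = σ·r/√(1−r²), giving population correlation magnitude
  exactly `human_effect_r` (default 0.55); the matching mouse genes shift
  by `mouse_log2fc` (default 0.585, |FC| = 1.5) with the same sign.
  The default sign is negative, mirroring a cAMP-phosphodiesterase-like
  target that falls as symptoms rise; it is configurable.
* **Mediation chain** — a latent Gaussian drives the mediator CpG
  (beta = logistic(−1 + 0.5·latent), keeping [0,1] support) and the
  target gene's expression (slope `mediation_a` = 2, residual SD
  `mediation_noise_sd` = 1 — the chain's own scale, deliberately larger
  than probe noise so methylation and expression are strongly associated
  without being collinear); the symptom score receives
  `mediation_b`·(expression − baseline) (default −1.5) plus the direct
  path `mediation_cprime` (default 0).
* **Co-expression block** — members = baseline + λ·z(target) +
  √(1−λ²)·ε at loading λ = 0.8, comfortably above the 0.6 screen
  threshold at n = 48.

`noise_sd` (default 0.14, log2 scale) was fixed once by an oracle power
simulation (`scripts/power_oracle.py`): at these design sizes it puts a
planted mouse gene's probability of passing the q < 0.001 ∧ |FC| > 1.36
gate at ≈ 0.91, alongside the analytic ≈ 0.93 probability that a planted
human probe passes |r| > 0.40 — the per-test ≈ 0.9 power regime the
recovery analyses assume. Every draw flows from one
`numpy.random.Generator(seed)`, so a configuration reproduces its bundle
bit for bit. One patient's reexperiencing score can optionally be set
missing to exercise the pairwise-complete policy; the default has no
missingness.

What the generator does **not** emulate: probe chemistry and background
signal, count-based RNA-seq noise, batch and cell-composition effects,
heterogeneous per-gene effect sizes (planted effects share one magnitude,
so cross-gene magnitude concordance is uninformative on synthetic data),
sex or genotype structure, and correlated phenotype missingness. Passing
tests therefore demonstrate correctness and calibration of the machinery
under the assumed model, not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1]; |r| = 1 reports p = 0. Zero-variance
features are flagged (`defined`/`tested` False), carry NaN statistics and
are excluded from screens and BH families. Partial correlation treats a
residual sum of squares below 1e-12 of the total as fully explained
(partial r = 0, p = 1) and reports collinear covariates by name.
Outlier exclusion is single-pass (no re-iteration) and never triggers when
the spread is zero or the cutoff infinite. Bootstrap resamples with
degenerate variance yield non-finite indirect estimates and are dropped
from the percentile computation. The BCa interval uses the standard
bias-correction from the bootstrap distribution and jackknife
acceleration.

## Problem sizes in tests

The test and acceptance workloads use scaled designs chosen to keep the
whole suite fast while leaving Monte-Carlo error well inside each
tolerance: 5000-probe null screens at the n = 48 design size, 10-seed
recovery runs with 100 planted genes among 5000 nulls, 200-cohort
bootstrap-coverage sweeps at n = 32 with 1000 resamples, and exhaustive
oracle sweeps (all hypergeometric configurations to N = 15; 1000 random
BH vectors to length 50). Fixture cohorts for unit tests of planted
structure use a somewhat larger cohort (48 patients / 24 controls) so
fixed-seed assertions sit away from significance boundaries.

## Known limitations

Symbol matching is case-insensitive string equality — no ortholog
database, so genes whose human/mouse symbols differ beyond case are
dropped. The probe→gene collapse takes the largest-|r| probe, one of
several defensible rules. The mouse t-test inherits the usual caveats of
Gaussian tests on RNA-seq-derived values. The tripartite screen's
uncorrected α reflects candidate-gene practice, not an endorsement;
switch on the BH flag for family-wise discipline.
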