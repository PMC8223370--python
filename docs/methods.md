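# Methods

## The analysis

cytodyna implements a dynamic network analysis (DyNA) of multiplexed
inflammatory-mediator time courses measured across body compartments in two
mouse strains (a wild-type and a receptor-null comparison group). The design
is terminal: at each of the time points 0, 1, 4, 6, 12, 24 and 48 h a
separate group of animals is sacrificed, so no animal has a trajectory and
every correlation is cross-sectional.

For each of the five consecutive intervals (1–4, 4–6, 6–12, 12–24,
24–48 h) and each (strain, compartment):

1. **Sample assembly.** All animals sacrificed at either endpoint of the
   interval are pooled into one cross-section. The pooled-endpoints rule is
   the minimal assembly consistent with five two-endpoint intervals on the
   seven-point sampling grid; interior time points can be included by
   widening the interval definition.
2. **Baseline-change filter.** A mediator may carry edges only if its pooled
   interval values differ from the 0 h control group by a two-sided
   Mann–Whitney U test at α = 0.05. The U test is used rather than a t-test
   because group sizes run as low as 4; the exact null distribution is used
   whenever a group has ≤ 8 untied observations (scipy's `method="auto"`),
   the normal approximation otherwise. No multiple-testing correction is
   applied by default; α is a parameter.
3. **Edges.** For every unordered pair of changed mediators the Pearson
   correlation of the pooled samples is computed on pairwise-complete cases;
   an undirected edge is added iff |r| ≥ 0.7, *inclusive*, signed by the
   sign of r. Pairs with fewer than 3 complete cases or a constant vector
   are skipped and the skip is recorded on the network (silent skipping
   would bias connectivity counts).
4. **Statistics.** Network complexity per interval is the degree sum over
   (n − 1) with n the number of mediators analyzed (the panel size, 20 — not
   the number of changed nodes), i.e. 2·|E|/19. The total number of
   connections is the edge count summed over the five intervals, and the
   connection ratio between strains is the ratio of these totals, with
   `inf`/`nan` as in-band markers for zero denominators.

Both edge endpoints must pass the baseline filter. Requiring both (rather
than one) follows the node semantics of the networks this analysis
produces, where edges join only mediators flagged as changed.

**AUC summaries.** Because per-animal AUCs are impossible under terminal
sampling, the AUC of a mediator is the trapezoidal integral of its
per-time-point *group mean* over 0–48 h on the actual sampling grid, in
concentration-unit × hours (pg/ml·h for plasma, pg/mg·h for tissue — never
summed across compartments). Gaps in the grid are bridged linearly and
logged. The compartment summary sums mediator AUCs per strain and forms the
wild-type : null ratio with the same degenerate-value markers as the
connection ratio. Means, not medians, are integrated, and no baseline
subtraction is applied.

**Windowed rank correlation.** For selected mediator pairs (canonically
IL-17A–GM-CSF and IL-17A–TNF in plasma and spleen) Spearman's ρ is computed
over the animals pooled within the windows 0–12 h and 12–48 h, with a
percentile bootstrap confidence interval: B = 1000 resamples of animal
index pairs, ρ recomputed on each, CI from the 2.5/97.5 percentiles.
"Significant" means the CI excludes zero; no p-values are attached. The
12 h boundary belongs to *both* windows by default (configurable to
exclusive-upper). The percentile bootstrap was chosen over BCa as the
simplest defensible variant; replicates with a degenerate (constant)
resample are redrawn and counted. The percentile CI can in principle
exclude the point estimate; this is flagged, not corrected.

## The synthetic-cohort generator

No measurements are deposited for this study design, so the package ships a
generator that emulates it with known ground truth. Concentrations are
log-normal: `exp(μ + σ·z)` with σ = sqrt(log(1 + cv²)) and cv = 0.3 by
default, reflecting positive, right-skewed immunoassay readouts.
Responder effects are mean shifts on the log scale in units of σ
(scale-free); planted correlations are specified per interval and induced
at both endpoint time points through the Cholesky factor of the planted
correlation matrix, so the pooled two-endpoint cross-section — the sample
DyNA actually consumes — carries the planted association. Group sizes
default to 8 (wild-type) and 4 (null) animals per time point.

Validity constraints: planted |ρ| ≤ 1; every per-interval planted matrix
must be positive semi-definite; and because consecutive intervals share an
endpoint, the union of all blocks touching a time point must also be PSD,
with conflicting targets for the same pair rejected. Designs violating any
of these raise before any data are drawn.

What the generator does *not* emulate: assay floor/ceiling censoring,
between-batch effects, missingness mechanisms, heavier-than-log-normal
tails, and mechanistic kinetics (no ODEs). Passing tests therefore
demonstrate correct recovery of structure under an idealized version of
the study design, not robustness to those artifacts.

A note on pooled cross-sections: when two mediators' means move together
across an interval's two endpoints, the pooled Pearson correlation picks up
that shared trend even without within-time-point correlation. This is a
property of the method itself, and the canned scenario exhibits it (its
broad wild-type heart response adds trend-driven edges beyond the planted
ones); the parameter-recovery tests instead use constant shifts at both
endpoints so that non-planted pairs are exactly null.

### The canned scenario

`scenario_paperlike()` encodes the qualitative study findings as ground
truth: densest planted structure in wild-type heart (TNF-centred blocks at
4–12 h), sparser wild-type blocks in liver/kidney/plasma, null-strain
blocks matching or exceeding wild-type in gut, lung and spleen at
4–6/12–24 h (negative planted correlations in lung, positive in spleen),
broader and larger wild-type responder amplitudes (largest in heart, which
drives the AUC ratio), and IL-17A–GM-CSF / IL-17A–TNF association planted
only at 24 and 48 h in wild-type plasma and spleen. The late planting
deliberately avoids the 12 h point: 12 h belongs to both analysis windows,
so structure planted there would leak into the 0–12 h window.

Strain asymmetry in the scenario is encoded in explicit per-strain
responder amplitudes and block densities with the global strain scaling
left at 1.0, because the null strain's few genuine responders must still
clear the baseline filter for its networks to be non-empty; a small global
multiplier would zero every null network and make all connection ratios
infinite. The scaling field remains available for power experiments. Null
responder amplitudes on planted mediators are set to 4 σ so that the
8-pooled-vs-4-baseline exact U test retains high power.

## Numerical choices

- Pearson r is computed from centered sums and clipped to [−1, 1]; a
  constant vector raises rather than propagating NaN.
- The edge threshold comparison is `>=` (inclusive).
- Mann–Whitney: identical constant groups are reported as unchanged with
  p = 1 rather than erroring.
- Bootstrap resampling is vectorized (midranks via `scipy.stats.rankdata`
  per replicate row); degenerate replicates are redrawn up to 50 rounds
  before the data are declared effectively constant.
- Pipeline randomness derives from one seed via named `SeedSequence`
  substreams (simulate = 0, correlate = 1), so stage order cannot silently
  change results. Reports are JSON with sorted keys and no timestamps;
  fixed seed + config gives byte-identical output.
- Ratios with zero denominators are `inf` (numerator > 0) or `nan` (0:0),
  serialized as the strings "inf"/"nan" in strict-JSON reports.

## Problem sizes used in the test suite

Statistical checks run at the study's own scale: planted-edge recovery uses
pooled n = 16 (8 + 8) over 500 simulated cohorts; bootstrap CI coverage
uses n = 20, B = 1000 over 500 replicates against the closed-form normal
rank correlation (6/π)·arcsin(ρ/2); window localization uses 200 cohorts of
the scenario restricted to plasma and spleen (the two compartments that
analysis inspects); the compartment-ranking check runs 100 full end-to-end
cohorts. Acceptance bands for stochastic rates (false-edge envelope 0.004;
bootstrap coverage band [0.92, 0.99]) were frozen from larger independent
Monte-Carlo runs before the package's own tests were written.

## Known limitations

- The baseline filter's test family and α, the edge threshold, and window
  boundary policy are faithful defaults for this analysis style but are all
  single switches; no sensitivity analysis is built in.
- With 4 animals per time point the exact U test's smallest attainable
  two-sided p is 2/C(12,4) ≈ 0.004; α much below that is unattainable for
  the null strain.
- Trend-driven pooled correlations (above) mean DyNA edges do not separate
  within-time-point covariation from shared kinetics; that is inherent to
  the method, not an implementation artifact.
- AUC of the mean trajectory has no dispersion estimate (terminal sampling
  leaves no independent replicates of a trajectory), so AUC ratios are
  reported without confidence intervals.
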