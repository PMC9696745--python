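# Methods

## The mapping model

`bglm` treats LOINC mapping as nearest-distribution assignment. The only
signal used is the marginal distribution of a lab test's numeric reading
values; metadata, units and language are ignored. Its core assumptions:

- distinct analytes produce distinguishable value distributions in the
  populations both datasets sample from;
- the query and reference populations are similar enough that the same
  analyte's distribution shifts only mildly between sites;
- a usable reference exists in which observations are keyed by LOINC code.

Under these assumptions, the two-sample Kolmogorov–Smirnov statistic
between empirical CDFs is a natural distance: it is a metric on
distributions, bounded in [0, 1], distribution-free, and sensitive to
location, scale and shape alike.

### Sampling and eCDF construction

For each code a fixed-size sample (default `sample_size = 1000`,
dimensionless count) is drawn uniformly **without replacement**; drawing
without replacement represents the stored population of values directly,
and for the >1000-observation codes the tool targets, the distinction from
with-replacement sampling is negligible. Codes holding fewer observations
contribute everything they have, with a warning, rather than being
dropped. Ties collapse into single eCDF support points carrying pooled
probability, so integer-valued analytes are represented exactly.

Per-code sub-seeds are derived by hashing `(master_seed, code_id)`
(BLAKE2, reduced modulo 2^31), so samples are independent across codes and
stable under panel edits.

### Exact KS on step functions

The difference of two right-continuous step functions is piecewise
constant and changes only at support points, so
`sup_x |F_a(x) − F_b(x)|` is attained on the union of the two supports and
is computed exactly by scanning it. Computing from materialized eCDFs
(rather than re-pooling raw samples) also enables the shareable-reference
deployment: `bglm build-reference` serializes a code → eCDF panel with
full float precision, letting a site publish its distribution panel
without raw patient values. Tests pin this implementation against two
independent oracles (a dense-grid brute force and `scipy.stats.ks_2samp`
on the raw samples) to 1e−12.

### Z-scores and acceptance

Each distance-matrix row is standardized to mean 0 and unit standard
deviation; the divisor is the sample convention (n−1), matching mainstream
statistical environments, with the population variant behind the `ddof`
flag. Acceptance is the strict inequality `z < cutoff`, default
`cutoff = −5`, with `−3.80` as the ensemble's confidence threshold; both
are configurable and both were calibrated on a single real dataset pair,
so neither should be treated as universal.

Two degenerate cases are handled without crashing: a constant distance row
(all references equally distant) yields a NaN Z-score and an automatic
reject, and argmin ties break to the lexicographically smallest LOINC code
with a logged warning, keeping output independent of column order.

A structural fact worth knowing when choosing cutoffs: the minimum
Z-score a row of length K can attain is −(K−1)/√K (one entry low, the
rest equal). A cutoff of −5 therefore *cannot* accept anything unless
K ≳ 29. This is not a defect but a feature of the standardization — the
method presumes a reference panel much wider than the query set, which is
what real LOINC-coded references provide.

## The synthetic data generator

The generator emulates a MIMIC-style long-format lab-event extract: a
reference table keyed by LOINC, a query table keyed by opaque local codes,
and a truth table linking them. Six distribution families cover common
analyte shapes — normal (electrolytes), lognormal (enzymes), gamma (skewed
markers), uniform, Poisson-discrete (integer counts, exercising the tie
path of the KS scan), and a **mixture** family described below. Defaults:
5000 stored observations per code per table (the >1000-observation regime
the tool targets, leaving real subsampling work for the 1000-value draw),
mild query-vs-reference shift of at most 5% of a code's sd in location and
2% in scale, emulating cross-site assay differences.

### Why the mixture family exists

Direct experiments with panels of mutually well-separated codes (grids,
jittered grids, Poisson scatter of locations) showed a failure mode of the
Z-score itself: when almost all of a row saturates at KS = 1, the row is
"one low entry versus a constant bulk", and the Z-score of the minimum
equals the −(K−1)/√K floor *regardless of how small the minimum is* —
standardization is scale-invariant, so a perfect match (KS 0.03) and a
mediocre best-available match (KS 0.7) become indistinguishable. Real lab
panels do not look like this: many analytes share parts of their numeric
range, so inter-code distances form a graded bulk well below 1.

The mixture family reproduces that regime directly: each code draws a
fraction `w` (per-code, uniform in 0.65–0.85) of its values from a
code-specific normal component and the rest from one broad background
common to every code. The shared background cancels exactly in any
pairwise KS comparison, capping inter-code distances near `w`. A true
match is then a strong outlier below the bulk (Z ≈ −5 to −6 at K = 50)
while the best available match for a withheld code sits in the bulk's
lower tail (Z ≈ −2 to −4) — exactly the contrast the cutoff exploits.
`make_analyte_panel` builds such panels; `make_confusable_panel` retains
the simpler normal-grid design (adjacent separation `6·(1−overlap)` sd)
used for separation sweeps and perfect-recovery checks.

### Scenario devices

- `unmapped_fraction`: that share of query codes has its true LOINC
  withheld from the reference, creating the necessarily-wrong mappings the
  cutoff must reject (the synthetic analogue of local codes without a
  reference counterpart).
- `reference_only` codes: widen the candidate panel the way a large
  reference dwarfs one site's query set; required for stringent cutoffs to
  be meaningful (see the Z floor above).
- `confuser_pairs`: force two LOINC codes to near-identical parameters
  (location offset by 1% of sd), creating genuinely ambiguous candidates.

### What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline recovers truth when
distributions are separable, that the Z-score cutoff trades acceptance
for precision in the intended direction, and that correct mappings carry
systematically lower Z-scores than incorrect ones under controlled
conditions. They do **not** demonstrate performance on real EHR data:
real value distributions are messier (censoring at reporting limits,
unit mix-ups within one code, temporal drift), the mixture family is a
stylized stand-in for real range overlap, and precision figures measured
on synthetic panels say nothing quantitative about any real dataset pair.
Unit-of-measure consistency is out of scope entirely.

## Evaluation harness

Because the 1000-value draw is random, evaluation repeats the full
pipeline (default 30 runs, each from a sub-seed of `(master_seed, run)`)
and averages the precision curve. Precision with zero accepted mappings is
reported as absent (NaN), never 0 or 1. The correct-versus-incorrect
Z-score comparison uses a one-sided Wilcoxon rank-sum test (correct group
lower); a Welch t-test is available via `method="ttest"`. The rank-sum
test uses the exact null distribution when the pooled sample is small
(≤ 60) and tie-free, the asymptotic approximation otherwise; at the exact
sizes used in the calibration tests the p-value is mildly discrete, which
is why "approximately uniform under the null" is asserted with a KS
distance tolerance of 0.1 rather than exact uniformity.

## Problem sizes

The shipped experiments use panels of 20–50 codes with 3000–5000 stored
observations per code, 30 evaluation runs, and 500 null-calibration
replicates — small enough to regenerate everything from scratch in well
under a minute per scenario while keeping every statistical contrast far
from its decision boundary.

## Known limitations

- Quantitative tests only; text-valued results are dropped at ingestion.
- One candidate per code from the external mapper (ranked lists collapse
  to their first entry).
- The −5 and −3.80 thresholds will not transfer across datasets without
  recalibration; K-dependence of the Z floor makes them panel-size
  sensitive as well.
- No unit-of-measure checking, no multi-reference integration.
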