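# Methods

## Problem setting

Commercial triploid (3n) oysters are produced by crossing tetraploid males
with diploid (2n) females. Odd ploidy makes chromosome segregation
error-prone, so triploid lines may carry aneuploid individuals — whole
chromosomes at copy 2 or 4 instead of 3. In bulk RNA-seq, transcript
abundance is, to first order, proportional to gene copy number. Library-size
normalization (CPM) divides every gene by the sample's total output, so a
*genome-wide* dosage difference between a diploid and a triploid cancels
exactly; only a *chromosome-restricted* departure from the individual's
ploidy baseline survives normalization as a coherent block shift. This is
the signal the screen detects, and simultaneously the reason euploid
triploids are indistinguishable from diploids chromosome-by-chromosome.

## Simulator

For gene *g* in sample *s*:

    count[g,s] ~ NB(mean = L_s * p[g,s], size = theta)
    p[g,s] ∝ c[chr(g),s]^gamma * e_g * m[g,s]        (normalized per sample)

* `e_g = exp(N(mu0, sigma0))` — per-gene baseline expression, shared by all
  samples. Defaults `mu0 = 2.0`, `sigma0 = 1.5` (natural log), giving the
  orders-of-magnitude spread of real bulk RNA-seq expression.
* `c[chr(g),s]` — chromosome copy number: 2 for diploids, 3 for triploids,
  overridden per (sample, chromosome) by planted aneuploidy events. The
  exponent `gamma` (default 1.0) models dosage response: 1.0 is fully
  proportional dosage, 0.0 is complete dosage compensation. The default is
  proportional because that is the premise that makes an expression-based
  screen possible at all; the knob exists to probe how compensation would
  erode sensitivity.
* `m[g,s]` — product of gene-wise multiplicative effects for the sample's
  site, cohort and ploidy levels, log-normal with sd
  `covariate_effect_sd` (default 0.2) on a random `frac_affected_genes`
  subset (default 0.3). An optional site x ploidy interaction
  (`interaction_site`, `interaction_sd`) gives triploids an extra gene-wise
  response at one site, reproducing the situation where the triploid
  expression shift is larger at the stressful site.
* `L_s` — log-normal library size with mean `lib_size_mean` (default 1e6)
  and CV `lib_size_cv` (default 0.3); the log-normal is parametrized so its
  arithmetic mean equals `lib_size_mean`.
* `theta` — negative-binomial size (variance `mu + mu^2/theta`). Default 10,
  a typical bulk overdispersion; `theta = inf` switches to exact Poisson
  sampling and is used wherever a near-noiseless dosage reading is wanted.
* Genes are allocated to chromosomes by largest-remainder rounding of
  `chromosome_weights` (default: 10 equal chromosomes), in contiguous
  blocks — positional structure within a chromosome is not modelled.

The default design is the full field layout: 2 outplant sites x 2 hatchery
cohorts x 3 maternal dams, 8 individuals per cross per ploidy — 192
samples. All randomness flows from one integer seed through a single
`numpy` generator, so identical configs give byte-identical outputs.

What the simulator does **not** emulate: read-level artifacts (mapping
bias, multi-mapping, 3'-bias of tag-based protocols), gene-gene
correlation beyond shared covariate effects, partial-chromosome or mosaic
aneuploidy, and dosage compensation that varies by gene. Passing tests on
synthetic data therefore demonstrate the statistical machinery under the
stated count model, not robustness to those artifacts.

## Normalization and filtering

CPM rescales each sample to 1e6 total; the working scale is
`log2(CPM + 1)`. The pseudocount keeps zero-CPM genes at 0 and is applied
once, after CPM. The low-expression filter keeps a gene iff its CPM is at
least 5 in at least `ceil(0.8 * n_samples)` samples. Two readings of the
"fewer than five CPM in 80% of samples" rule are possible
(remove-if-low-in-80% vs keep-if-high-in-80%); this package adopts
keep-if-high-in-at-least-80%, the stricter and more common form, and the
boundary is inclusive: CPM exactly 5 in exactly 80% of samples is kept.
Whether the screen should run on the filtered or unfiltered gene set is
not dictated by the method; the default is filter-first (the pipeline and
CLI expose `--no-filter`). Variance-stabilizing transformations from
dispersion-model packages are deliberately out of scope; log-CPM is used
for both the screen and the PCA, which mainly affects the influence of
low-expression genes on PC loadings.

## Pairing

Within every (site, cohort, dam) cell, diploids and triploids are paired
one-to-one up to `min(n_2n, n_3n)`; by default pairing is lexicographic in
sample id (deterministic), with a seeded random within-cell permutation
available to check that conclusions do not depend on the arbitrary
assignment. Cells missing one ploidy produce a warning and unmatched ids,
never an exception. Exhaustive one-to-one pairing maximizes the number of
usable pairs; since every statistic is per-pair, alternatives only change
how many rows the output has.

## The screen

Per pair and chromosome the package reports the OLS slope (with
intercept), its standard error, and the median log2 ratio `m_c`. Flags are
based on the robust z of `m_c` against the within-pair cross-chromosome
baseline (median of the ten medians; scale 1.4826 x MAD), **not** on the
slope: a uniform dosage shift on one chromosome is a vertical translation
in the log-log scatter, which an intercept-including OLS fit absorbs
entirely into the intercept. The slope is nevertheless computed and
reported for every pair x chromosome because it is the traditional
overview summary. Using the within-pair baseline (rather than a cross-pair
model) makes the statistic immune to pair-level global effects such as
differential expression shared across the genome, and makes the expected
deviation of a copy-k chromosome exactly `log2(k/3)` regardless of the
fraction of expression the chromosome carries — the fraction shifts all
ten medians equally and cancels in the baseline subtraction.

Defaults: `z_threshold = 3` (conventional robust-outlier cutoff),
`effect_floor_log2 = log2(1.15)` (a 15% dosage change; guards against
flagging trivial deviations when the MAD is very small — with only ten
chromosomes the MAD is itself noisy), `min_genes = 20` (keeps the median
stable). If the MAD collapses to zero with nonzero deviations, flags fall
back to the effect floor with a warning. Fewer than five chromosomes with
defined statistics is an error: the baseline needs a majority.

Numerical notes: the slope is `cov(x,y)/var(x)` with the standard OLS
standard error; fits are marked undefined (with a reason, never dropped)
when a chromosome has fewer than `min_genes` genes after filtering or when
the diploid values are constant. Observed euploid slopes sit slightly
below 1 (typically 0.95–1.02 at Poisson-level noise and 500 genes per
chromosome) — counting noise on the diploid axis attenuates the OLS slope
(regression dilution), most visibly for genes near the filter boundary.
This is a property of the scatter-plot summary, not of the dosage
statistic, and is one more reason flags are not based on slopes.

## Transcriptomic shift

PCA is computed by SVD of the gene-centered log-CPM matrix with samples as
observations; variance fractions are `sigma_i^2 / sum(sigma^2)` and each
component is oriented so its largest-magnitude loading is positive
(deterministic sign). The shift for a pair is the Euclidean distance
between its two samples after multiplying each PC coordinate by that
component's variance fraction, over PC1 and PC2 by default. "Weight by the
percent of variation explained" admits two arithmetics — multiplying
coordinates (squares the weight's effect on the distance) or weighting the
squared terms; both are implemented (`fraction` and `sqrt-fraction`), with
`fraction` (coordinate multiplication) the default, and the choice is
recorded in the output metadata along with the variance fractions.
Distances are reported per pair plus a median/IQR summary by site x
cohort, the shape a box plot of site-wise pair distances needs.

## Calibration

`power_analysis` simulates single-pair datasets per scenario (euploid null
or a planted copy number on one chromosome carrying a configurable
fraction of expression) and reports flag sensitivity and false-positive
rate with binomial standard errors. At the defaults — 10 chromosomes x 500
genes, library 1e6, near-Poisson noise — a single-copy loss (2-of-3) or
gain (4-of-3) is detected with sensitivity 1.0 and the euploid
false-positive rate is 0.0 over 200 replicates; the deviation of the
affected chromosome's median log-ratio matches log2(2/3) within ~0.015
(the residual bias comes from the pseudocount compressing ratios of
low-expression genes).

## Problem sizes

The bundled analyses and tests use 5000 genes on 10 chromosomes, up to 200
simultaneous pairs, and 200-replicate calibration runs; these sizes give
sub-percent Monte-Carlo error on every reported rate while keeping any
single stage under a minute on one core.

## Known limitations

* Proportional dosage is assumed; pervasive dosage compensation would
  shrink the `log2(k/3)` signal toward 0 (the `dosage_exponent` knob
  quantifies this in simulation).
* The screen targets whole-chromosome events; segmental or mosaic
  aneuploidy dilutes the median log-ratio and is out of scope.
* With ten chromosomes the MAD baseline tolerates at most a few
  simultaneous aneuploid chromosomes per individual before the baseline
  itself moves.
* Log-CPM is not variance-stabilized; PC1/PC2 and hence the shift metric
  weight high-variance low-expression genes more than a VST-based PCA
  would.
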