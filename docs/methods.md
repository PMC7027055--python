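# Methods

This note records the models, numerical choices and limitations behind
`peakvar`, in the spirit of the methods documentation that statistical
genomics packages ship alongside their APIs.

## Quantification model

Reads are treated as single-end sequencing tags and assigned to peaks by
their 5′ position (interval start on the forward strand, `end − 1` on the
reverse strand).  A tag is counted in every peak whose half-open interval
contains it; tags outside all peaks are ignored.  This choice is
deterministic and fragment-length-free: an any-overlap rule would make
counts depend on an unknown fragment size.

**Background correction.**  For each peak, tags are counted in flanking
windows of `flank_bp / 2` on each side (default 1000 bp total), clipped at
the chromosome start and excluding any base covered by a peak.  The flank
count is scaled by `peak_width / usable_flank_width` and subtracted;
negative results are clipped to 0 because the downstream CV and log
transforms require non-negative intensities.  A peak whose flanks are
entirely covered by neighboring peaks keeps its raw count (with a logged
warning) rather than receiving an undefined correction.

**Between-sample normalization.**  Each sample's column is multiplied by
`mean(column totals) / column total`, so every column total equals the
cross-sample mean and the grand total of the matrix is conserved.  This is
a total-signal normalization: it assumes overall IP efficiency, not
biology, drives total-count differences.

**Filters.**  The minimum-signal filter drops a peak only when its
*maximum* across samples is below the threshold (default 2 normalized
counts).  The per-sample rule was deliberately rejected: cell-line-specific
peaks are near zero in most lines, and requiring signal in all samples
would delete exactly the peaks the variability stage exists to find.
Presence calls (default threshold 4) use a strict inequality, "more than".

## The mean-CV model for variable peaks

For each peak, the mean `m` and coefficient of variation `CV` (unbiased
n−1 standard deviation over mean) of normalized intensity across samples
are computed.  Counting statistics alone predict `CV² = 1/m` for Poisson
counts, so the expected CV at a given mean is modelled as

    CV²(m) = a/m + b ,

with `a ≥ 0` the shot-noise coefficient (≈1 in normalized-count units when
shot noise dominates) and `b ≥ 0` an asymptotic floor absorbing
multiplicative biological and technical variability.  The fit is ordinary
least squares on `(1/m, CV²)` over peaks with `m > 0`, with negative
coefficients clipped to 0; when per-line variability dominates (large `b`),
`a` can legitimately clip to 0 at moderate depth.  A LOESS-style local
trend was considered and rejected for the default: the two-parameter form
is interpretable, cheap, and the null calibration below shows it is
adequate.

A peak is flagged *highly variable* when `m ≥ min_mean` (default 2) and
`CV > fold × expected_cv(m)` (default fold 1.5).  These defaults are
calibration parameters, not estimates: on pure-Poisson null simulations
(12 samples, 5000 peaks) they flag ≈1% of peaks (the test suite enforces
≤2%), and with 5% planted single-line 4-fold peaks at base mean ≥20 they
recover ≥90% of planted peaks at FDR ≤0.2 (observed ≈2%).  Users changing
the sample count or depth regime should recalibrate `fold` on a matched
Poisson null, which the simulator makes a one-liner.

TSS proximity uses point distance to width-1 TSS intervals (gap 0 when the
TSS lies inside the peak; default window 10 kb), with nearest-TSS ties
broken toward the smaller coordinate.

## Motif scoring

A PWM is an L×4 row-stochastic matrix.  Before scanning, every cell is
raised to a probability floor (default 0.01) and rows are renormalized —
note that renormalization leaves cells at `floor / row_sum`, slightly below
the nominal floor; the container enforces the effective bound
`floor / (1 + 4·floor)`.  Scores are best-site log-odds in bits against a
uniform background:

    score(s) = max over offsets and strands of Σᵢ log2(p[i, sᵢ] / 0.25).

Max (best-site) scoring was chosen over summed occupancy because a single
number per site is what downstream binning and regression consume; both the
floor and the background are configurable.  Windows containing N are
skipped; a sequence with no N-free window scores −∞ with offset −1.  The
reverse strand is scored by forward-scanning the reverse complement with
the identical summation order, which makes strand symmetry an exact
floating-point identity rather than an approximate one.

Background regions for motif comparison are the 500 bp windows adjacent to
each peak, kept only when they lie within the genome and overlap no peak in
the set.

The subset-averaging analysis computes, for every k-subset of samples (all
subsets up to a cap of 1000, then seeded sampling of distinct subsets), the
Pearson correlation between motif score and subset-mean intensity.
Averaging reduces per-line noise, so the median correlation rises with k
when binding has a sequence-encoded component — the synthetic datasets
reproduce this rise and the test suite requires it in ≥19/20 seeds.

## Integration models

Binding is regressed on predictors after a `log2(x + 1)` transform; the
pseudocount of 1 keeps the zeros of cell-line-specific peaks finite and is
configurable.  The fit is OLS (statsmodels), rejecting designs with
condition number above 1e10; R² and adjusted R² are both reported because
adding predictors can only raise the former.  The two-condition comparison
correlates `Δlog2(binding)` with `Δlog2(accessibility)` and reports r, its
two-tailed t-distribution p-value, and r².

Group comparisons of correlation distributions use Welch's t-test
(unequal-variance) rather than the pooled-variance form, since group sizes
are typically very different (dozens of variable peaks vs hundreds of
canonical targets); a Fisher z-transform option exists but is off by
default to keep the comparison on the raw r scale.  Enrichment tests are
upper-tail hypergeometric, `P(X ≥ k)`, with Benjamini-Hochberg correction
by default (Bonferroni available).

## Clustering

Distances are `1 − Pearson r` between sample (or peak) vectors; constant
vectors are rejected rather than silently assigned NaN.  Merging is
unweighted average linkage (UPGMA) via scipy, verified in the test suite
against an exhaustive reference implementation on all small instances.
Peak-axis clustering is intended to run on row-normalized (relative)
intensities so that peak shape, not peak height, drives the grouping.

## The synthetic-data generator

The generator emulates the cross-cell-line design the pipeline targets.
Defaults (the simulated "study conditions"): 12 samples, 8742 peaks, 5%
variable peaks active in 1 line with a 4-fold effect, log-normal latent
affinity (σ = 0.5 log-units), mean depth 50 reads per unit affinity,
Poisson counts, 500 bp peaks separated by 2.5 kb on a single synthetic
chromosome `chrS`.

Expected intensity is

    λ[p,s] = depth · affinity[p] · fold^{active} · accessibility[p,s]^{acc_coupling}
             · lineage[p, pair(s)] · line_noise[p,s] ,

where accessibility factorizes into a per-peak level (σ = 0.5, the
chromatin context of the locus), a smaller per-line fluctuation (σ = 0.1)
and an `effect_fold` elevation in the active lines of variable peaks.  The
split matters: per-peak accessibility variance drives the across-peak
variance decomposition, while keeping per-line accessibility small ensures
shared peaks do *not* co-vary with expression across lines — mirroring the
biology the pipeline assumes, where shared binding is
accessibility-independent and only the cell-line-specific class tracks
chromatin state.  Because the accessibility elevation compounds with the
direct fold, active-line intensity rises by `fold^(1 + acc_coupling)`;
simulations that need an exactly 4-fold effect (e.g. detector calibration)
set `acc_coupling = 0`.  Per-line log-normal noise (σ = 0.3 by default)
models line-to-line biological variability, and optional lineage pairs
share a multiplicative factor to mimic tissue-of-origin correlation.

Sequences carry one motif site per peak, sampled position-wise from the PWM
sharpened by a per-peak temperature tied to log-affinity (temperature → 0
gives the consensus everywhere), on a uniform-random background of 60 bp.
Expression is one gene per peak, `base · accessibility^γ · noise`, so that
variable peaks' genes co-vary with binding exactly where chromatin opens.
Read-level output realizes each count as uniform 5′ positions inside its
peak plus Poisson background tags in the gaps, so re-counting reproduces
the matrix bit-exactly.

What the generator does **not** model: fragment-length distributions,
GC/mappability bias, overlapping peaks, multiple genes per locus,
replicate-level structure, and negative binomial overdispersion by default
(a gamma-Poisson switch exists for robustness checks).  Passing tests on
this generator therefore demonstrate the statistical machinery — detector
calibration against shot noise, recovery of planted structure,
conservation laws — not robustness to every artifact of real sequencing
data.

## Determinism and problem sizes

Every stochastic stage takes a seed; the generator derives independent
per-stage streams from the config seed, and the pipeline manifest records
SHA-256 checksums so reruns can be verified byte-for-byte.  The test suite
and the acceptance script use simulations of 1000–8742 peaks and 10–20
seeds per claim — sizes at which every check completes in seconds while the
monitored quantities (flagging rates, R², correlations, ARI) are stable to
well within the asserted tolerances.
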