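# Methods

## Phenotype model

Barcode counts are normalised within each sample; the raw phenotype of
segregant *i* in sample *s* is the fractional frequency change
(f_TF − f_T0)/f_T0 relative to the injected pool. This is bounded below by
−1 (extinction); a segregant with zero reads in a sample at adequate
sequencing depth is treated as an observed extinction, not as missing —
only f_T0 = 0 makes a segregant unmeasurable. Recovery from organs
requires outgrowth on rich-medium plates, so raw phenotypes are
residualised by OLS on the mean raw phenotype of the plate-control samples
(default: the mean of 3 controls); the residuals are the *persistence*
values. Residuals of an intercept model are mean-zero per sample and
orthogonal to the control regressor. A constant control regressor
degenerates gracefully to intercept-only centering.

For aggregation, raw phenotypes are first divided by days since injection
(day 1, 2 or 5), then plate-corrected, then averaged per segregant over
the brain and the nonbrain (kidney + liver + spleen) sample groups that
passed the significance filter; the differential phenotype is brain −
nonbrain. Per-sample scans use un-time-corrected persistence: a
single-sample scan is invariant to a common scale factor, so time
correction only matters when samples from different days are averaged.

## Heritability

Broad-sense H² is the one-way sum-of-squares ratio SS_genotype/SS_total
with genotype identity as the grouping factor (a random-effects fit with
the same grouping yields the identical ratio). Within a sample the groups
are the triplicate-barcoded segregants; across samples the groups are
segregants and samples act as replicates. Two properties matter for
interpretation:

* The ratio is **affinely invariant** but **not unbiased** for the
  generating genetic-variance fraction: its null expectation is
  (G−1)/(N−1), about 0.33 for 86 genotypes × 3 replicates, and at 3
  replicates it substantially overstates small variance fractions. It is
  consistent as the replicate number grows (analytic bias < 0.015 at a
  fraction of 0.2 with 50 replicates), which is how the estimator-recovery
  test is designed: recovery of planted fractions (0.2/0.5/0.8) is checked
  at 50 replicates per genotype, while the null-expectation identity is
  checked at the assay's own 86 × 3 design.
* The one-way ANOVA F statistic is a deterministic function of (H², G, N),
  F = (H²/(G−1)) / ((1−H²)/(N−G)); the sample filter uses its P-value at a
  Bonferroni threshold α/n_samples_tested (α = 0.05). Organs left with
  fewer than `min_organ_replicates` (default 2) significant samples are
  dropped entirely — a lone significant sample cannot be checked for
  reproducibility. Known-bad samples are removed by an explicit exclusion
  list rather than an automatic distortion detector.

For the differential (brain − nonbrain) phenotype no direct replicate
structure exists; its H² is estimated by decomposing the matrix of
brain-sample values minus each segregant's nonbrain aggregate, with brain
samples as replicates. This is the package's own convention and is only
used to express scan R² as a fraction of H².

## Genotype correction

Observed 3S fractions are thresholded (> 0.5 → 3S, < 0.5 → BY; exactly 0.5
and zero-coverage sites are missing) and corrected per chromosome with a
two-state HMM: stay probability 0.9999, switch 0.0001, emission 0.75 for
the concordant call. Decoding is Viterbi, which returns a legal meiotic
mosaic (posterior decoding can produce inconsistent per-site maxima).
Missing sites emit with likelihood 1 in both states, so the path imputes
them; the initial distribution is uniform; ties prefer state 0 (BY), so an
all-missing chromosome decodes to BY — an arbitrary but deterministic
convention. Viterbi output is idempotent under re-correction.

The per-step switch probability encodes a *dense* genotyping panel
(tens of thousands of SNPs, meiotic blocks spanning hundreds of sites).
On a sparse mapping grid (~30 markers per chromosome) the same transition
penalty correctly flattens short terminal blocks and correction can hurt;
HMM correction is therefore exercised and validated on genotyping-density
maps (2,000–8,000 sites), matching where it is used in practice. After
correction, maximal runs of adjacent markers with identical columns
across the whole panel are collapsed to their first marker (recording the
run's physical extent); this leaves every chromosome's single-marker scan
minima unchanged.

## Barcode quantification

Reads below mean quality 30 in the barcode region (boundary inclusive:
exactly 30 is kept) or lacking the landing-pad flank are discarded; PCR
duplicates are collapsed to one read per UMI within a sample. Because the
barcode library is known, de novo cluster discovery is unnecessary: each
read is assigned to the unique whitelist barcode within `max_hamming`
(default 3) mismatches, and the whitelist is required to be pairwise
separated by more than 2×`max_hamming` so assignment is unambiguous;
unassigned reads are discarded and counted. The >5%-of-reads rule for
calling a strain's true barcodes is provided as a validation utility only.

## Linkage mapping

Each stage fits `phenotype ~ covariates + locus` per marker and records
the 1-df F-test P-value of the locus term, computed by projecting the
intercept and covariates out of both phenotype and genotypes (QR) and
testing the residual regression — algebraically identical to the full OLS
fit, and with no covariates identical to the pooled two-sample t-test.
Markers whose residual variance vanishes (i.e. collinear with covariates,
including every already-admitted peak) get P = 1, so a chromosome never
re-admits its own peak; a constant phenotype yields all P = 1 and no
detections.

Stage thresholds shuffle the phenotype while holding genotypes and
covariates fixed; the threshold is the k-th smallest of the permutation
minimum P-values with k = floor(quantile × n_perm) (the 50th of 1,000 at
the default 5th percentile). An explicit permutation set can be supplied
for exact/enumerated tests. Detection requires peak P ≤ threshold, at most
one admission per chromosome per stage (ties broken toward the lower
marker index), admitted peaks join the covariates, and scanning stops when
a stage admits nothing (guard: 20 stages). With one RNG stream per scan
the procedure is deterministic end-to-end.

Confidence intervals are the maximal contiguous marker run around the peak
within `drop` units of −log₁₀(P) of the peak value (default 2 — the
"2 × −log₁₀(P) drop" is read as a drop of 2 units, the LOD-drop analogue;
reading it as doubling the peak's −log₁₀ P would make CIs grow without
bound for strong loci). A flat profile spans its whole chromosome.
Variance explained is the R² of the joint OLS on all detected peak
markers, divided by the phenotype's H².

All scans are vectorised (one matrix product per stage over all
permutations), so 1,000-permutation thresholds at ~500 markers × ~800
segregants cost well under a second; since the minimum P over markers is
the maximum F at fixed degrees of freedom, only one survival-function
evaluation per permutation is needed.

## Consolidation and pleiotropy

Detections on a chromosome whose closed CIs overlap (shared endpoints
count) merge transitively — connected components of the interval-overlap
graph — because a pairwise-only rule leaves chains ambiguous. Each locus
records the union (merge extent) and intersection (resolution) of member
CIs; a chain with an empty intersection is flagged and the intersection
collapses to a zero-length point at the deepest interval coverage, rather
than erroring, mirroring regions that fractionate into linked sub-loci.
Each locus's representative marker is the peak of its smallest-P member.

Locus effects are mean(3S) − mean(BY) in a context; 95% CIs resample each
allele class independently with replacement (1,000 draws, 2.5th/97.5th
percentiles). Classification is by quadrant of (brain Δ, nonbrain Δ):
same sign → general, opposite → antagonistic; an exactly-zero delta is
classified by the other context's sign and flagged degenerate (the
boundary has measure zero in practice). Allele-dose counts use defaults of
≥7 / <3 (general) and ≥6 / <3 (brain-favouring) for enriched/depleted; an
auto-tune mode instead moves each cutoff until at most 25% of segregants
fall in either tail. The 2×2 contingency test (enriched-for-both ×
positive time slope) is a plain Pearson χ² on 1 df without continuity
correction.

## The simulator

Selection acts multiplicatively on log frequency: barcode *i* in organ
*o* at day *t* has expected frequency ∝ f0_i · exp(t · Σ_l s_{o,l} ·
allele_{i,l}) — the simplest model consistent with frequency-change
phenotypes, and one with closed-form expectations for oracle tests.
Defaults mirror the assay: 822 segregants (86 triplicated → 994 barcodes),
16 chromosomes with real S. cerevisiae physical lengths, Poisson
crossovers (mean 3 per chromosome, uniform positions, no interference),
mild log-normal jitter (σ = 0.2) around an equimolar T0 pool, a
full-factorial 5 organs × 2 sexes × 2 treatments × 3 days × 3 replicates
design, per-organ CFU bottlenecks (liver 69,150; spleen 32,032; kidney
3,843; brain 1,741; gonads 69) applied as a multinomial draw of recovered
cells, a per-segregant on-plate log-growth coefficient (σ = 0.2) shared
between organ samples and plate controls — which makes the plate
correction identifiable by construction — and multinomial read counts at
10⁶ depth. Sex and treatment carry no phenotypic effect, matching the
absence of such effects in the assay this emulates. Planted loci come in
two classes with per-organ per-day selection coefficients of magnitude
`effect_scale` × U(0.8, 1.2): general (one sign everywhere) and
antagonistic (brain sign opposite to kidney/liver/spleen). The default
`effect_scale` = 0.25/day was chosen by an ex-ante power calculation: a
locus must contribute partial R² well above the genome-wide threshold
(≈ 16/822 ≈ 0.02) in the aggregate phenotypes for forward scans to have
high power, while keeping 5-day frequency spreads within a realistic
range.

What the simulator does **not** emulate: read-level errors and FASTQ
structure (reads are counts; the read-record path is exercised with
synthetic records), PCR amplification bias, within-host spatial dynamics,
immune clearance kinetics (no systematic decline of total recovery over
days), mating or diploidy, and crossover interference. Passing tests
therefore demonstrate the statistical machinery under the assay's
sampling structure, not robustness to those real-data artefacts.
In particular, low-bottleneck organs produce reproducible extinction
patterns tied to barcode starting frequencies, which inflate across-sample
H² slightly relative to the planted-locus contribution — visible as
variance-explained fractions below 100% even when all planted loci are
found.

## Problem sizes and numerical conventions

Tests and the acceptance script run at the design scale for the pipeline
itself (822 × ~510 collapsed-scale markers, 183 samples) with 1,000
permutations for aggregate scans and 250 for the per-sample scan sweep;
null-calibration uses 200 independent scans (the 95% binomial band around
the nominal 5% stage-1 FWER). Oracle tests run exhaustively at tiny sizes
(≤ 12 Viterbi sites, 6! permutations). Floats are written as `%.10g` and
all randomness flows from explicit integer seeds (one RNG stream per
scan), making repeated runs byte-identical. Collinearity is declared at
residual column sum-of-squares ≤ 1e-8·n; P-values are floored at 1e-300
before taking logs.

## Known limitations

* The SS-ratio H² is an upward-biased estimator at few replicates (see
  above); values from triplicates should be read as a significance/ranking
  device, as in the sample filter, not as unbiased variance fractions.
* Forward regression with permutation thresholds controls stage-wise FWER
  but detections across 90+ correlated per-sample scans still accumulate
  false positives; the consolidation counts inherit that.
* No mixed-model/kinship correction, no interval mapping between markers,
  no epistasis scans; effects are per-locus mean differences.
* The gonad samples' tiny bottleneck usually removes them via the
  significance filter at design scale, but this is data-driven, not
  guaranteed, at other configurations.
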