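# Methods

## Scope and data model

`asbkit` detects allele-specific binding (ASB) of RNA-binding proteins at
heterozygous SNVs in eCLIP-Seq data. The unit of analysis is one *experiment*
(one RBP in one cell type): k ≥ 2 eCLIP replicates plus one size-matched
input (SMInput). Inputs are coordinate-sorted, duplicate-removed alignments
of "usable" reads (deduplicated, uniquely mapped — produced upstream; the
readers additionally drop unmapped, secondary, supplementary and QC-fail
records and reads below MAPQ 10), called peak intervals, a candidate SNV
list, and the reference genome. All coordinates are 0-based half-open
internally; VCF input and the printed position column of the output table
are converted at the boundary. Only second-in-pair mates are counted —
in paired-end eCLIP the read-2 5′ end marks the reverse-transcription
truncation point — with a `single_end` switch that treats every read as the
informative mate. Peaks on the − strand have all sequence work done on the
reverse complement, and counting is restricted to reads whose strand matches
the peak.

## Peak retention

A peak is kept when at least one replicate's library-normalized coverage is
at least 4-fold that of the SMInput over the same interval (inclusive
threshold). "Library-normalized" is reads per million usable reads (RPM);
nothing more exotic is attempted. A peak with zero SMInput coverage passes
whenever any replicate covers it, treating the fold change as infinite.

## Crosslink sites and the sequence-propensity table

Within each peak, the number m_i of read-2 5′ ends at each position i is
compared with a permutation null in which the peak's read starts are redrawn
i.i.d. uniformly over the peak's positions (equivalent, for start-count
statistics, to permuting read positions within the peak). For each candidate
threshold m the empirical FDR is the permutation-mean number of positions
with count ≥ m divided by the observed number; the curve is clipped to [0, 1]
and made monotone non-increasing in m, and sites with FDR ≤ 0.001 are called.
Several sites per peak are allowed, since reverse transcription can read
through a 3′ crosslink and stall upstream. Defaults: 1000 permutations,
seeded from the run configuration.

The crosslinking sequence propensity q(a, d) — nucleotide a ∈ {A,C,G,T},
offset d ∈ [−25, 25] — is the per-offset relative frequency of each base in
the strand-oriented 51-mers centred on the *SMInput* crosslink sites of the
experiment. SMInput is used because its composition reflects crosslinking
chemistry, not the RBP's motif; the table is re-estimated per experiment.
Sites whose window runs off a chromosome edge are skipped and counted. T
stands in for U throughout.

## Count normalization

Raw allelic counts are corrected as x = y / (q(a, d) · R), with R the
library size in millions and d the strand-oriented offset of the SNV to the
*nearest* called crosslink site in its peak (ties broken toward the 5′
site — a rule this implementation had to choose, since multi-site peaks are
otherwise ambiguous). SNVs with no site in the peak, or |d| > 25, use
q = 0.25. A propensity below 0.005 is floored there with a warning: a zero
cell in a finite-sample frequency table is almost always a sampling zero,
and dividing by it would be absurd. Under a uniform table the correction
reduces to RPM scaling × 4 and leaves every allelic ratio unchanged.

## Variance moderation

For each allele of each SNV the mean μ and unbiased (k−1) variance σ² of the
normalized counts across replicates give ω = σ²/μ² (CV²). All alleles of all
SNVs in the experiment are pooled and ω is regressed on log₂ μ by LOESS:
tricube weights, degree-1 local fits, span 0.75, **no robustness
iterations**, with statsmodels' `delta` shortcut at 1% of the x-range.
Robustness iterations matter here and are deliberately off: at k = 2 the CV²
response is χ²₁-skewed, and robust reweighting would shrink the fit toward
the median (≈ 0.45 × the mean), roughly halving every expected variance and
destroying the calibration of the test. Predictions interpolate the fitted
curve, clamp to the boundary fitted values outside the training range, and
are floored at ω̂ ≥ 10⁻⁶. Fewer than 30 positive-mean training alleles is an
error; `ParametricVarianceTrend` (ω̂ = a + b/μ, least squares) is the
documented fallback for data that sparse. A known property of the degree-1
smoother: on strongly convex trends (e.g. pure Poisson ω = 1/μ) the wide
default span over-smooths by ~20–25% mid-range; span 0.5 tracks such curves
within 15%. On realistic mean–CV² shapes (Poisson term plus plateau) the
default span recovers the generating curve within a few percent.

The expected variance of an allele with mean μ is σ̂² = ω̂(μ) · μ².

## The test

At each SNV the allele with the higher mean normalized count is the major
allele M, the other the minor m (ties: reference, deterministically). Under
a Gaussian model for normalized counts with a flat prior on the mean
(the infinite-prior-variance limit of a conjugate normal prior), the
posterior of the major-allele mean is N(μ_M, σ̂²_M/k), and the two-sided
p-value is p = min(1, 2Φ((μ_m − μ_M)/√(σ̂²_M/k))). The factor 2 can push
past 1 only at exact ties, where p is capped at 1. Untestable SNVs (an
allele with zero mean) are flagged and excluded from testing.
Benjamini–Hochberg adjustment is applied per experiment (events are reported
per RBP; pooling across RBPs is a configuration choice), and FDR < 0.10
flags significance. The major/minor assignment uses normalized counts —
the test operates entirely on the normalized scale.

An important behavioural note: the test attributes the whole moderated
variance σ̂²_M to the major allele and treats μ_m as fixed, so its null
calibration depends on the variance structure of real replicates. Part of
the between-replicate variance of each allele is *shared* between the two
alleles of the same SNV (library depth, IP efficiency, expression level) and
cancels in the allelic difference; the single-allele σ̂² absorbs it anyway.
With roughly half of the between-replicate variance shared — which is what
replicated eCLIP data look like — the test is close to calibrated, which the
all-null simulation confirms (KS distance from uniform ≈ 0.03 at 5000 SNVs,
0% called at FDR < 10%). If replicate noise were entirely independent
between alleles the test would be anti-conservative by √2 on the z-scale.

## Heterozygous SNVs

All SMInput data sets of a cell line are pooled; a bi-allelic candidate SNV
is called heterozygous when pooled ref+alt coverage ≥ 10 and the reference
ratio lies in [0.25, 0.75] (bounds inclusive; configurable). Base calls
below quality 10 are excluded, as are deletions and reference skips;
qualities are taken as stored in the BAM, so if upstream processing wrote
realignment-adjusted qualities those are what is thresholded. Third-allele
reads are excluded from ratios but do not by themselves disqualify a site.
A user VCF of known heterozygous genotypes (GT 0/1, 0|1, 1|0) is merged in;
on a position conflict the user record wins with a warning; multi-allelic
records are skipped. On synthetic pileups with binomial(cov, 0.5) het sites,
the caller's recall exceeds 95% at coverage ≥ 20 and its false het rate from
homozygous sites (error rate 10⁻³) is below 0.1%.

## Posterior filters

Applied to significant candidates on real data, in fixed order, each a pure
predicate; a candidate failing several filters is charged to the first.

1. **Homopolymer**: remove if the SNV lies inside a run of ≥ 5 identical
   reference bases (the run includes the SNV's reference base).
2. **Microsatellite**: remove on 0-based half-open overlap with an annotated
   microsatellite BED.
3. **Mappability**: remove if the best off-target identity of the 101-mer
   centred on the SNV is ≥ 95%. The similarity source is pluggable — a
   precomputed per-SNV table, or any external aligner adapter; missing
   entries are kept with a warning unless strict mode is set.
4. **Allele-specific expression (ASE)**: a gene is ASE within an RNA-Seq
   data set when ≥ 2 of its heterozygous SNVs are testable (≥ 10 reads) and
   every one is biased at BH FDR < 0.05 (exact binomial test against 0.5;
   the BH family is all testable SNVs of the data set). A gene is confirmed
   when ASE in ≥ 2 data sets and every testable SNV's reference frequency is
   < 40% or > 60% in each passing data set. Candidates in confirmed ASE
   genes are removed — their imbalance is transcriptional, not binding.
   With no RNA-Seq tables the filter is skipped with a prominent warning.
5. **Reference-mapping bias**: with θ, σ the mean and SD of allelic ratios
   at known heterozygous SNVs in the SMInput, remove candidates with
   z = |θᵢ − θ|/σ < 1 — an imbalance that small is indistinguishable from
   reference bias.
6. **Hotspot**: bin the genome into 2000-nt windows; count candidates at
   positions shared by **more than four** distinct RBPs; flag windows whose
   count exceeds the genome-wide background (mean multi-RBP count over all
   candidate-bearing windows; Poisson upper tail, BH FDR < 0.01, plus a hard
   floor of 3 so tiny data sets never flag) and drop everything inside.
   Specific hotspot coordinates are assembly-specific and never hard-coded.

The per-step attrition report (removed, remaining, percentage) makes the
order auditable; counts always reconcile with input − output.

## The simulator

The generator emulates the count structure of a two-replicate eCLIP
experiment at heterozygous SNVs; it is the test bed for everything above.
Per experiment (defaults in parentheses, which are the benchmark study
conditions): n SNVs (5000), ASB fraction (0.10) with major-allele ratio
r ∈ (0.5, 1) (0.8), k replicates (2).

- **Coverage**: one total coverage per SNV, resampled to ≥ 10, from an
  empirical file if given, else log-normal with median 55 and log-SD 1.0 —
  a broad, right-skewed spread typical of peak-restricted SNV coverage.
- **Replicate structure**: each replicate gets a shared multiplicative depth
  factor, log-normal with log-SD 0.25 (~25% between-replicate CV), applied
  to both alleles of an SNV alike. This models replicate-level depth/IP/
  expression variability, which in real data is common to the two alleles.
  Alternatives (`coverage_mode`): `shared` (no replicate factor) and
  `independent` (fresh coverage draw per replicate). The hierarchical
  default is the realistic one: fully independent draws would make
  between-replicate variability as large as the across-SNV spread, and
  fully shared draws would leave no shared component at all.
- **Counts**: per replicate and allele, zero-truncated negative binomial
  with mean r·C (major) or (1−r)·C (minor) and variance from the target
  v(m) = m + 0.05·m² — Poisson counting noise plus a CV² plateau of 0.05,
  the shape observed in replicated eCLIP allelic counts. NB is
  parameterized by (mean, size), size = mean²/(v − mean); v ≤ mean falls
  back to Poisson with a warning. Truncation is by rejection resampling,
  which realizes the conditional distribution exactly.
- **Bias injection**: each SNV gets a random offset d ~ U[−25, 25] and
  random distinct allele bases; counts are rescaled by q(a, d)/0.25,
  rounded, floored at 1. `example_bias_table()` provides a synthetic
  propensity profile (uridine peak 0.70 at d = 0 decaying with |d|/4,
  remainder split equally) mimicking the shape of SMInput-derived tables.
  Injection followed by normalization with the same table restores the
  original integers to within the ±1 that injection's rounding introduces,
  and leaves allelic ratios exactly unchanged when the table is uniform.
- **High-variance regime**: replicate deviations are scaled until each
  SNV's between-replicate SD exceeds the 95th percentile of a reference SD
  distribution while preserving means within 10%; SNVs that cannot reach
  the target with integer counts are dropped with a logged count.

Everything is reproducible from a single seed (per-experiment child seeds
via `SeedSequence.spawn`; all derived seeds < 2³¹). What the generator does
**not** emulate: read-level artifacts (mapping bias, base-call errors,
PCR duplicates), peak calling, linkage between nearby SNVs, and any
dependence of the propensity table on true binding motifs. Tests passing on
this generator therefore validate the count-level statistics, not the
upstream read processing.

## Benchmarking

Comparators are the standard count tests on replicate-pooled allelic counts:
a 1-df χ² goodness-of-fit against the balanced expectation (n/2, n/2), no
continuity correction, and a two-sided Fisher's exact test of
(M, m) against (round(n/2), n − round(n/2)). How a two-outcome allelic count
becomes a Fisher 2×2 is genuinely underdetermined; contrasting the observed
counts with the balanced expectation of the same total is this package's
construction and is stated prominently because it shapes comparator (never
moderated-test) behaviour. A vectorized log-hypergeometric batch path is
used in benchmark loops; it is tested for agreement with scipy.

Scores are −log₁₀ p. Precision–recall curves sweep unique scores (tied
scores collapse to one operating point) and the PR-AUC integrates precision
over recall trapezoidally in sweep order; PR is preferred to ROC because
truth is 10:90 unbalanced. SEN95 is the best sensitivity among thresholds
with specificity ≥ 0.95 (specificity = TN/(TN+FP)); SPE95 conversely; 0
where unattainable. Coverage bins for the overdispersion diagnostics:
[10,20), [20,50), [50,100), [100,200), [200,500), [500,∞), binned by each
SNV's mean observed total coverage across replicates; empty bins are
reported missing, not zero.

Benchmark results at the study conditions (50–100 experiments × 5000 SNVs,
recomputed by `scripts/acceptance.py` and the acceptance tests): the
moderated test's PR-AUC exceeds both comparators in every experiment with
bias injected; its mean PR-AUC moves by < 0.01 between the bias and no-bias
arms while the comparators collapse; the χ² per-bin %ASB increases strictly
monotonically with coverage while the moderated test's stays flat from 20×
up with stable median p-values.

## Numerical choices and degenerate inputs

- p capped at min(p, 1); exact mean ties give p = 1 with reference as major.
- ω̂ floor 10⁻⁶ keeps σ̂² > 0; q floor 0.005 keeps normalization finite.
- FDR curves (crosslink calling) clipped to [0, 1] and forced monotone.
- BH via statsmodels `multipletests`; NaN p-values (untestable SNVs) pass
  through untested.
- Zero SMInput coverage at a peak → retained; zero usable reads in a
  library → hard error (normalization undefined).
- Reference-bias filter with σ = 0 → hard error (degenerate SMInput ratio
  distribution), not a silent pass.
- Empty inputs: empty peak file → empty collection with a warning; empty
  start-count table → no crosslink sites; empty candidate set → error at
  the allelic-counting stage naming the stage.

## Known limitations

- **Low-coverage power.** At coverage 10–20× with k = 2 and r = 0.8 the
  moderated test's expected z is ≈ −2.2 against a BH cutoff near −2.7, so
  per-bin recall in the lowest coverage bin is ~25%, and the called
  fraction there (~2–3% when truth is 10%) sits below the truth level. This
  is the price of modelling replicate variance honestly: comparators "find"
  more there only because they also flood high-coverage bins with false
  positives. More replicates, not a looser variance model, is the fix.
- The test treats the minor-allele mean as fixed; calibration relies on
  part of the replicate variance being shared between alleles (see above).
- Only bi-allelic SNVs; no indels; no multi-allelic sites.
- BAQ-style realignment qualities are used only if already present in the
  BAM; the package thresholds stored base qualities and does not recompute
  realignment-based qualities itself.
- The mappability filter needs a precomputed similarity table (or external
  aligner adapter); no aligner is bundled.
- The degree-1 LOESS over-smooths strongly convex trends at the default
  span (see Variance moderation).
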