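# asbkit

Allele-specific binding (ASB) of RNA-binding proteins from eCLIP-Seq data.

When a protein binds RNA in a sequence-specific way, the two alleles of a
heterozygous single-nucleotide variant (SNV) can be bound with different
affinities. In eCLIP-Seq this shows up as an imbalance between the reads
carrying each allele inside a binding peak — but two artifacts confound the
naive read-count comparison:

1. **Crosslinking-induced sequence bias.** Reverse transcription truncates at
   the protein–RNA crosslink, and UV crosslinking prefers uridines, so the
   nucleotide composition around crosslink sites is skewed. An SNV whose
   alleles sit at a biased offset accumulates reads unequally for reasons that
   have nothing to do with binding.
2. **Between-replicate overdispersion.** Allelic counts vary between
   biological replicates far more than a binomial or Poisson model allows, so
   χ² or Fisher tests on pooled counts produce ever-smaller p-values as
   coverage grows, regardless of truth.

`asbkit` addresses both. It is written for genomics analysts working with
eCLIP/CLIP-seq data who have peak calls, replicate alignments and a
size-matched input (SMInput) control, and for methodologists who want a
simulation and benchmarking harness for overdispersed allelic-count tests.

## The model

For SNV *i*, allele *a* and replicate *j* with raw allelic read count
*y*<sub>*i,a,j*</sub>, counts are normalized by the crosslinking propensity
and library size:

    x_{i,a,j} = y_{i,a,j} / (q(a, d) · R_j)

where *q*(*a*, *d*) is the relative frequency of nucleotide *a* at offset
*d* ∈ [−25, 25] from a crosslink site (estimated per experiment from the
SMInput sample; *q* = 0.25 outside the window) and *R*<sub>*j*</sub> is the
replicate's usable reads in millions. Crosslink sites themselves are called
per peak from read-2 5′-end pileups against a within-peak permutation null at
empirical FDR ≤ 0.001.

With only *k* ≈ 2 replicates, the per-SNV sample variance is hopeless, so the
expected variance is moderated globally: the squared coefficient of variation
ω = σ²/μ² of every allele of every SNV is regressed on log₂ μ with LOESS, and
σ̂² = ω̂(μ) · μ². Writing *M* and *m* for the major and minor allele (higher /
lower mean normalized count), the posterior of the major-allele mean under a
flat prior is N(μ_M, σ̂²_M / k) and the two-sided p-value is

    p = min(1, 2 · Φ((μ_m − μ_M) / √(σ̂²_M / k)))

Benjamini–Hochberg FDR < 10% flags significant ASB. On real data six
posterior filters then remove artifact-prone candidates (homopolymers,
microsatellites, multi-mapping regions, allele-specific expression of the
host gene, reference-mapping bias, multi-RBP hotspot windows).

The statistical core follows the scikit-learn idiom
(`LoessVarianceTrend`, `EmpiricalGaussianASB` with `fit` and
trailing-underscore results), so it composes with sklearn tooling; the
pipeline modules around it handle BED/BAM/VCF/FASTA plumbing.

## Worked example

Simulate one experiment at the benchmark study conditions (5000 SNVs, 10%
true ASB at major-allele ratio 0.8, two replicates) and compare the
moderated test against the χ²/Fisher comparators:

```python
from asbkit import (SimConfig, simulate_study, benchmark_experiment,
                    example_bias_table, inject_crosslink_bias)
import numpy as np

ds = simulate_study(SimConfig(n_snvs=5000, seed=1))[0]
print(benchmark_experiment(ds).summary())

table = example_bias_table()
biased = inject_crosslink_bias(ds, table, np.random.default_rng(1))
print(benchmark_experiment(biased, correction=table).summary())
```

Output (first block: no crosslinking bias; second: bias injected and
corrected):

```
   method   pr_auc  sen95    spe95
moderated 0.970667  0.974 0.979111
     chi2 0.835289  0.870 0.862222
   fisher 0.838102  0.864 0.834444

   method   pr_auc  sen95    spe95
moderated 0.968865  0.970 0.981333
     chi2 0.440232  0.406 0.646667
   fisher 0.443455  0.424 0.606667
```

`pr_auc` is the area under the precision–recall curve against the embedded
truth labels; `sen95`/`spe95` are sensitivity at 95% specificity and vice
versa. The moderated test dominates both comparators; injecting
crosslinking bias collapses the comparators (PR-AUC 0.84 → 0.44) while the
bias-corrected moderated test is essentially unchanged (0.971 → 0.969).

## Command line

```sh
asbkit call --config run.yaml        # full pipeline on BAM/BED/VCF/FASTA
asbkit snvs --config run.yaml        # heterozygous SNVs from pooled SMInput
asbkit simulate --n-snvs 5000 ...    # labelled synthetic data sets
asbkit benchmark sims/*.tsv          # PR-AUC / SEN95 / SPE95 per method
asbkit filters --config run.yaml --asb-table out/asb_table.tsv
```

`call` writes, under `out_dir`: `asb_table.tsv` (one row per SNV × RBP with
columns chrom, pos (1-based), ref, alt, rbp, major_allele, mu_major,
mu_minor, var_major, k, pvalue, fdr, filters_failed, significant),
`crosslink_sites.bed` (score column = read-start count), `bias_table.tsv`
(4 × 51 propensity matrix), `trend.tsv` (log₂ μ vs ω̂ grid),
`filter_report.tsv` (per-filter attrition) and `config_used.yaml`.
Exit codes: 0 ok, 2 configuration error, 3 data error.

## Layout

- `asbkit.io` — BED/BAM plumbing, peak retention (≥4-fold over SMInput), ASB table
- `asbkit.bias` — crosslink-site calling, propensity table, count normalization
- `asbkit.snv` — allele counting, heterozygote calling, user-VCF merging
- `asbkit.model` — variance trend + empirical Gaussian test (sklearn-style)
- `asbkit.filters` — the six posterior filters with attrition reporting
- `asbkit.simulate` — ZTNB study generator with truth labels
- `asbkit.evaluate` — comparators, PR machinery, overdispersion diagnostics
- `asbkit.pipeline`, `asbkit.cli` — orchestration and subcommands

See `docs/methods.md` for the full statistical description, parameter
defaults and known limitations.
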