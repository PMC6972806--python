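# Methods

`sweepscan` implements the population-genetic core of a blooming-time
selective-sweep study on a small resequenced fruit-tree panel: per-sample
diversity summaries, a two-group sliding-window sweep scan, LD decay, and
a kinship-corrected association stage, together with a synthetic-data
generator that reproduces the statistical structure those analyses
assume. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the simulation-based tests do
and do not demonstrate.

## Data model and coordinates

All genotypes live in a samples x variants matrix of alternate-allele
dosages (0/1/2, -1 for missing) holding biallelic SNPs only; half-calls
are conservatively treated as missing. Coordinates are 1-based inclusive
throughout the package — the published region tables this mirrors use
the `x0001..y0000` convention — and are converted to 0-based half-open
only when a BED file is written.

## Per-individual diversity

For one sample, `n_sites` counts non-missing genotypes and
`n_polymorphic` the heterozygous ones; HetObs = polymorphic/sites and
the per-individual nucleotide diversity is HetObs/2 (two haplotypes of
one diploid differ exactly at its heterozygous sites). The inbreeding
coefficient F_IS = 1 - Hobs/Hexp is evaluated per individual: at every
within-individual polymorphic site Hobs = 1 and, with allele frequency
1/2 in a single diploid, Hexp = 1/2, so F_IS = -1 whenever any
heterozygous site exists and is undefined (reported NA) otherwise. This
single-diploid convention is what per-accession resequencing summaries
report; it is a bookkeeping identity, not a population estimate.

## Window statistics

Windows are 50 kb sliding in 10-kb steps (defaults; both configurable).
Starts are 1, 10001, 20001, ...; the last window is truncated at the
chromosome end. Per window, over a designated sample set:

- **pi** — sum over sites of [n/(n-1)] 2p(1-p), with n the non-missing
  allele count and p the alternate-allele frequency from dosages,
  divided by the *full window span* in bp. The span denominator (rather
  than callable sites) was chosen because the region tables the scan
  mirrors are pure coordinate geometry; with uneven callability the
  absolute level is biased toward zero equally in both groups, which the
  log2 ratio cancels.
- **theta_W** — S / a_{n-1} / span, with S the segregating-site count
  and n = 2 x (samples with at least one call in the window). A single
  per-window n keeps one harmonic number per window; with near-complete
  data this matches the per-site haplotype count.
- **F_ST** — Weir & Cockerham (1984) variance components a, b, c per
  site, aggregated ratio-of-sums Σa / Σ(a+b+c) across the window's
  sites. Slightly negative values are reported raw. A Hudson
  (ratio-of-averages) estimator is available via
  `window_fst(..., estimator="hudson")` for single-window use. WC was
  fixed as the scan default because it is the field standard for
  window scans on small unbalanced samples.
- **log2 ratio** — log2(pi_high / pi_low), high = late-blooming group,
  low = early-blooming group, so a sweep (diversity loss) in the early
  group gives large positive values. pi_low = 0 with pi_high > 0 maps
  to +inf (always in the right tail); both zero makes the window
  unusable.

Sites with more than 50% missing genotypes within a group, or fewer
than two called samples there, are dropped from that window's
statistics (configurable). Windows need `min_snps` (default 10)
informative sites to be usable; the default guards the ratio against
single-site noise.

## Sweep calling

Empirical thresholds are nearest-rank order statistics at rank
ceil((1-q) n) over usable windows, q = 0.05 per tail. A window is a
candidate when F_ST *and* the log2 ratio both exceed their cuts (joint
AND of the two marginal 5% right tails). Overlapping or book-ended
significant windows merge into maximal regions; `min_length` (default
0) is exposed because published region sets of this kind show an
apparent unstated minimum-size post-filter. Genes overlap regions by
closed-interval intersection. For downstream enrichment input, sweep
genes are grouped by midpoint into 1-Mb bins, runs of adjacent
non-empty bins merge into segments, and segments with no more than five
genes are discarded.

## LD decay

r^2 is the squared Pearson correlation of dosage vectors over samples
non-missing at both sites (composite LD; the panel is unphased, so no
haplotype EM). All intra-chromosomal pairs within `max_dist` (default
500 kb, default bin width 10 kb) are pooled into distance bins; a
seeded uniform pair subsample caps the cost on large inputs. The
half-decay distance interpolates linearly between bin midpoints where
mean r^2 first reaches half its maximum; it is undefined with fewer
than two populated bins or when the curve never reaches half-maximum.
With n samples, r^2 between independent sites has expectation
~1/(n-1), the sampling floor visible in the tests.

## Association

Filters run in a fixed order: samples with call rate < 80% are dropped;
then SNPs with missing rate > 10%, minor allele frequency < 5% (from
non-missing dosages), and Hardy-Weinberg exact-test p < 0.001. The HWE
exclusion follows the conventional direction (drop disequilibrium);
`hwe_literal=True` inverts it for comparison with pipelines that keep
p <= 0.001. The exact test sums the conditional probabilities (given
allele counts) of all heterozygote counts no more probable than the
observed one — two-sided probability-mass criterion, no mid-p,
deterministic.

Kinship is the standardized genomic relationship matrix
K = (1/m) Σ (g-2p)(g-2p)^T / (2p(1-p)) with per-site mean imputation of
missing dosages. The phenotype is the ordinal blooming code
(early = 0, mid = 1, late = 2). The mixed model
y = Xb + u + e, cov(u) = s_g^2 K, is solved EMMAX-style: K is
eigendecomposed once, the variance ratio delta = s_e^2/s_g^2 is
estimated by null-model REML (61-point log grid on [1e-5, 1e5] plus
bounded refinement), and each SNP is tested by weighted least squares
in the rotated basis with the weight *shape* fixed and the residual
scale re-estimated per SNP (t-test, df = n - 2). Re-estimating the
scale makes the no-relatedness limit (K = 0) reduce exactly to
ordinary least squares. The per-SNP WLS projects the intercept out of
the whitened data first; the naive closed-form normal equations cancel
catastrophically when delta is small and several kinship eigenvalues
are near zero. Degenerate fits (constant phenotype, a genotype
collinear with the intercept after whitening, non-finite t) report
beta = 0, se = NA, p = 1.

P-values get Benjamini-Hochberg step-up q-values
(q_(i) = min_{j>=i} p_(j) m / j), with discoveries at q <= 0.01.
Significant SNPs are assigned to every gene whose body extended by a
2-kb flank on both sides contains the SNP.

## Synthetic data

The generator emulates the panel structure the analyses assume, not a
full evolutionary history. Per site: ancestral frequency
p ~ U(0.05, 0.95); early- and late-group frequencies independently
Beta(p(1-F)/F, (1-p)(1-F)/F) — the Balding-Nichols model, giving
Var(p_g) = F p(1-p) and expected F_ST = F; the mid group takes the
average of the two realized frequencies; genotypes are Binomial(2, p_g).
Inside a planted sweep interval the designated low-diversity group's
frequency is set, with probability = intensity, to 1 (with probability
p) or 0, collapsing its diversity and inflating differentiation.
Everything is a pure function of the seed; fixtures are byte-identical
across runs.

Defaults are the study conditions: 6 early / 5 mid / 8 late samples
(the published panel's partition of 19 accessions), F = 0.1 background
differentiation, two 5-Mb chromosomes at 0.002 SNPs/bp (~100 SNPs per
50-kb window, ~1,000 windows — enough for stable 5% tails at desk
scale), one 500-kb sweep of intensity 1.0 in the early group, 200
annotated genes. The full-genome scale of a real panel is not needed to
exercise any code path.

What the generator deliberately lacks: linkage (sites are independent,
so there is no LD decay structure and no hitchhiking flank around the
planted sweep), a coalescent-neutral frequency spectrum (uniform
ancestral frequencies overweight common variants, so genome-wide pi
exceeds theta_W by design rather than by selection — the pi = theta_W
neutral identity is therefore checked against an msprime coalescent
simulation instead), recombination maps, demographic history, and
sequencing error. Passing tests show the estimators and the scan logic
are correct and calibrated on the assumed structure; they do not show
robustness to LD, demography, or call-quality artifacts in real data.

## Test design notes

- Simulation power checks (causal-SNP recovery, null calibration) run
  at n ~ 100 samples (34/33/33). At the panel's actual n = 19 the
  mixed model is valid but underpowered: the causal SNP sits inside K
  and a group-coded phenotype is almost fully heritable, so its signal
  is partially absorbed (proximal contamination), and chance
  correlations of null SNPs with the group code win a few seeds in 20.
  This small-n caveat applies equally to real 19-sample panels.
- Power checks plant the causal effect on a common variant
  (MAF >= 0.2): a variant with no carriers in the sample has no
  marginal signal at any effect size.
- Under the global null, the probability that BH at FDR 0.01 makes any
  discovery is exactly 1%, so the "clean in >= 99% of replicates"
  check sits on its expectation; it is run with 100 fixed-seed
  replicates.
- The worked-example tables (per-cultivar CDS variant counts, the
  19-row diversity summary, the 21-region sweep table) ship as package
  data under `sweepscan/examples/` and drive the exact-arithmetic
  tests: HetObs = polymorphic/sites to the printed 6 decimals, pi =
  HetObs/2 (printed values are half-up rounded, hence the 5e-7
  comparison tolerance), region lengths/total/mean/max, and the
  percent of a 280-Mb genome covered.

## Known limitations

- The LD stage reports composite (dosage) r^2 only; haplotype-EM r^2
  is out of scope for an unphased panel.
- The association stage supports an intercept plus one SNP; no
  covariates, no dominance coding.
- `segment_genes` merges adjacent non-empty 1-Mb bins; the published
  description of segment merging is ambiguous and this is the
  straightforward reading.
- Tajima's D and haplotype-based scan statistics (iHS, XP-EHH) are
  intentionally absent.
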