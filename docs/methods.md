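# Methods

`dendrogwas` couples two data streams measured on the same individual
trees — annual ring widths (and needle morphology) on one side, a
genome-wide biallelic SNP matrix on the other — and carries them through a
single reproducible workflow: ring-series standardization, stress-response
phenotyping, population-genomic description, three-model association, and
gene-context annotation. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Ring-width standardization (`treering`)

Raw ring width TRW(t) mixes an age/size trend, a common climate signal,
discrete stress episodes and tree-level noise. We fit each series with a
cubic smoothing spline whose frequency response is 50% at a wavelength of
`spline_fraction x series length` (default 0.67, the conventional
dendrochronological setting) and take dimensionless indices
`width / fitted`. The spline is computed as the discrete
second-difference-penalized smoother: minimizing
`||y - f||^2 + lam ||D2 f||^2` gives the frequency response
`1 / (1 + lam (2 - 2 cos w)^2)`, so the 50% point at the target wavelength
fixes `lam` in closed form. Fitted values are floored at 1e-6 so indices
never divide by zero. Indices are scale-invariant and average ~1 by
construction.

Optional prewhitening removes the autoregressive (persistence) component:
AR(p) for p = 0..3 by conditional least squares on a common sample, order
selected by AICc with the usual parsimony convention (smallest order within
2 units of the minimum — plain AIC keeps a spurious AR term on white noise
roughly a quarter of the time, which defeats the purpose of the step).
Residuals are re-centered on the series mean.

Site chronologies are per-year central values across trees; the default is
Tukey's biweight robust mean (c = 9, median start, MAD scale) with an
arithmetic-mean fallback at depth < 3. The phrase "binomial weighted mean"
in the dendro literature is ambiguous between a weighting across series and
binomial-kernel smoothing of the mean chronology; both a plain mean and the
biweight are provided, binomial smoothing is not, and none of the site
chronologies feed the per-tree phenotypes, so the choice is cosmetic here.

Recent growth trends are OLS slopes of the standardized indices over the
last 30 years with a two-sided t-test at alpha = 0.05; trees are classed
positive / negative / nonsignificant.

## Dendrophenotypes (`dendropheno`)

**Stress-response (Lloret) indices.** For a reference stress period of 1-3
years, with Gprev/Gd/Gpost the mean TRW in the 3 years before, during, and
the 3 years after the period: resistance Rt = Gd/Gprev, recovery
Rc = Gpost/Gd, resilience Rs = Gpost/Gprev, relative resilience
RRs = (Gpost - Gd)/Gprev. The identities Rs = Rt x Rc and RRs = Rs - Rt
hold exactly and are asserted over large random sweeps. Multi-year periods
average Gd over the whole period while the flanking windows stay 3 years.
Zero denominators yield missing records, never infinities.

**Climate-conditioned mean indices.** Stress years are those whose monthly
climate value (e.g., April temperature) falls strictly in the lower or
upper tail of its empirical distribution; the quantile defaults to 0.25 and
is configurable because no canonical value exists. Single-year indices at
each qualifying ring year (shifted one year when the growth response lags
the climate variable) are averaged per tree. Strictly-beyond-threshold
qualification means an all-tied climate series selects no years — reported
as missing, not as an arbitrary subset.

**Defoliation reconstruction.** Host tree indices are corrected by a
non-defoliated reference species: the host anomaly minus the non-host
anomaly rescaled by the ratio of standard deviations, then re-standardized.
Center and scale are estimated robustly (median / 1.4826 x MAD): the
outbreak signal itself would otherwise inflate the host sd and over-subtract
the non-host, which in practice breaks episode runs whenever a shared cold
year falls inside an outbreak. A tree shows a defoliation signal when its
corrected series stays below zero for >= 5 consecutive years and dips below
-1.28 sd (the ~10th percentile of a standard normal; the duration and the
25% synchrony rule are fixed by the study design, the depth default follows
the outbreak-reconstruction tradition and is configurable). An episode is
emitted for each run of years in which at least 25% of candidate trees show
simultaneous signal; the event year is the year of deepest median corrected
depression within the run, and per-tree binary response flags
(`defol_YYYY`) plus the affected proportion are returned. Host and non-host
must share their low-frequency treatment: the pipeline (and the generator)
pass the non-host chronology through the same 67% spline as the host
indices, otherwise boundary mismatch between a detrended host and a raw
non-host manufactures synchronized spurious events at the series ends.

**Descriptive traits.** meanTRW / varTRW over the full record, meanTRW30
over the last 30 years, per-15-year-block means and variances where the
series covers the block (missing otherwise), and needle mean/variance
joined by tree id. Variances are unbiased (ddof = 1).

## Population genomics (`popgen`)

**Filtering** applies, in a fixed order so reports are reproducible:
tree call rate >= 0.8, locus call rate >= 0.8 within every population,
observed heterozygosity <= 0.7, and minor-allele frequency >= 0.05 (the
boundary is retained). Filtering is idempotent.

**LD-kNN imputation**: for each SNP with missing calls, the 30 SNPs in
highest r^2 define a mean-absolute-difference metric between trees; each
missing call takes the inverse-distance-weighted vote of the 5 nearest
genotyped trees, falling back to the modal genotype when fewer than k trees
are genotyped. Non-missing calls are never altered.

**Diversity**: per site, Ho is the heterozygote fraction and He the
unbiased expectation 2p(1-p) x 2n/(2n-1); for a biallelic site the
unbiased mean pairwise difference (pi per variant site) coincides with
that quantity. FIS = 1 - Ho/He averaged over sites polymorphic within the
population. Population summaries are means across SNPs with per-locus
standard errors. Per-bp pi requires an explicit assayed-length denominator
because it depends on the invariant-site count, which the variant matrix
does not carry.

**Differentiation**: pairwise FST is Weir & Cockerham's (1984) theta as a
ratio of sums across loci, with percentile bootstrap confidence intervals
over loci (default 10,000 replicates) and negative multi-locus values
reported as computed. The estimator is verified against an independently
coded textbook-formula implementation to 1e-12. Nei's (1972) standard
distance uses the multi-locus identity sums; zero shared identity is
reported as infinite and flagged.

**AMOVA** partitions the squared-Euclidean variance of mean-imputed allele
dosages across groups / populations-within-groups / trees, with the
standard unequal-size coefficients, and returns
FST = (s_a + s_b)/s_total, FSC = s_b/(s_b + s_c), FCT = s_a/s_total, which
satisfy (1-FCT)(1-FSC) = (1-FST) identically. Note the scale: on dosage
coding the AMOVA FST of Balding-Nichols data with parameter F sits near
2F/(1+F), roughly twice the pairwise theta at weak structure — the same
relationship visible between a published hierarchical FST and the mean of
the corresponding pairwise values. Permutation p-values use the standard
schemes (individuals across populations for FST; individuals within groups
for FSC; whole populations across groups for FCT). Negative components are
floored at zero for percentage reporting only.

**PCA** decomposes the centered (optionally 1/sqrt(p(1-p))-scaled) dosage
matrix by SVD. The **Mantel test** correlates off-diagonal entries of two
distance matrices with a label-permutation p-value (one-sided "greater" by
default, matching common ecological usage); it is implemented in-package so
the permutation stream is seedable, and agrees with scikit-bio's
implementation on the statistic. Geographic distances are haversine
great-circle distances between per-population mean coordinates on the mean
Earth radius (6371.0088 km).

## Association (`assoc`)

**GLM scan**: per SNP, ordinary least squares of the raw-scale trait on
allele dose (optional covariates via Frisch-Waugh residualization), a
two-sided t-test on the dose coefficient, and Benjamini-Hochberg adjustment
across SNPs per trait; the boundary uses <= so selection coincides exactly
with the textbook step-up definition. No structure covariates by default —
the target setting is weakly differentiated populations — with PCA
covariates available behind a flag. Missing trait values drop trees per
trait; they are never imputed.

**BSLMM**: y = mu + sum_j gamma_j x_j beta_j + u + eps, with
gamma_j ~ Bernoulli(pi), pi log-uniform on [1/p, 0.5] (Metropolis step),
slab variance inverse-gamma, and the polygenic term u ~ N(0, sg^2 K) for
the standardized genomic relationship matrix K, sampled in K's eigenbasis
so each sweep costs O(np + n^2). The trait and SNP columns are
standardized. The Gibbs sampler is compiled with numba; default 2,000
burn-in + 10,000 sampling sweeps. PIP_j is the posterior mean of gamma_j;
selection at PIP > 0.25. Two independent half-chains are run and a
non-convergence flag (warning, not fatal) raised when their top-PIP sets
disagree. Because the sweep visits SNPs in column order, permuting columns
changes the chain's random pairing; PIPs are therefore invariant to column
order statistically (tested to 0.15 on well-resolved problems), not
bitwise.

**BLINK-style scan**: iteratively (i) scan all SNPs conditioning on the
current pseudo-QTN set, (ii) rank by p, (iii) build a candidate list
greedily, admitting only SNPs significant at the Bonferroni level and
skipping any with r^2 > 0.7 to an already-kept candidate, (iv) keep the
candidate prefix minimizing the BIC of trait ~ pseudo-QTNs, (v) repeat to
stability (max 10 rounds). Pseudo-QTN members are tested conditioning on
the other members only. Final control is Bonferroni at 0.05. The
Bonferroni candidacy gate matters: with a nominal gate the BIC stage
admits spurious pseudo-QTNs freely (the best-ranked null SNP among
hundreds always looks informative) and the final scan over-selects.

**Heterozygosity associations**: per-tree heterozygosity (het calls over
non-missing calls) against every trait by Pearson and Spearman correlation
(pairwise-complete, two-sided), plus two-sample Student t-tests of mean
heterozygosity for every population pair.

**Consensus**: exact per-method selected-SNP sets, all pairwise and the
triple intersection, and the ">= 2 methods" list.

## Annotation (`annotate`)

GFF3 gene/mRNA/exon hierarchies are parsed with gffutils (1-based inclusive
coordinates preserved; malformed lines reported with line numbers). Each
SNP receives exactly one category: exon; intron (genic, non-exonic);
five_prime_region / three_prime_region when within 10 kb of a gene
boundary, the side named by the nearest gene's strand; otherwise intergenic
with the exact nearest-boundary distance. Equidistant genes tie toward the
lexicographically lower id with all ties reported. UTRs are deliberately
not modeled — the flanking categories describe position relative to the
gene span, which is what a structural annotation of a draft conifer genome
supports.

## Synthetic data (`synth`)

The generator emulates the study design: six populations named after the
study sites (25/18/48/48/48/47 trees, 234 total; the plains population
forms its own group against the five mountain populations), thousands of
biallelic SNPs from the Balding-Nichols model (ancestral frequency uniform
on [maf_floor, 1-maf_floor]; population frequencies Beta-distributed around
it with parameter F = 0.017 by default, matching the observed weak
structure), uniform missingness at 5%, and 90-year ring series (1931-2020).

Ring widths are multiplicative:
`TRW = A(age) x C(climate) x S(tree, year) x eps`, with a
negative-exponential age trend (1.5 e^(-age/40) + 0.6 mm), a linear
response to June temperature (coefficient 0.15 on the standardized
anomaly, clipped at 0.2 so widths stay positive), and lognormal noise
(sd 0.15, mean-corrected) — together giving an inter-tree index
correlation near 0.5, typical of climate-sensitive conifer stands. In
stress years the multiplier is `stress_multiplier x (1+causal_effect)^dose`
capped at 1, so planted causal alleles raise resistance and resilience —
the effects live on the stress response, not on mean growth, mirroring how
the association traits are defined. Defoliation episodes depress a random
subset (default 30%) of the plains-population trees with a peaked profile
(onset year x(1-0.8d), maximum depression x(1-d) in years 1-2, then slow
partial recovery), following the documented biology that stored nutrients
buffer the onset year and the maximum growth decline appears 1-2 years
after defoliation. The non-host reference chronology shares the climate
forcing, carries chronology-level noise (single-tree noise shrunk by
sqrt(20)), and is standardized with the same 67% spline as the host
indices.

What the generator does **not** emulate: linkage disequilibrium beyond
chance (loci are independent draws, so LD-based steps are exercised by
explicit duplicated-column constructions), selection, spatially structured
missingness, cross-dating error, and realistic climate autocorrelation
(monthly values are white across years). Passing tests therefore show the
estimators recover known signals under the study's sample sizes and noise
levels — not that they are robust to every pathology of real ddRAD or
ring-width data.

## Problem sizes and numerical choices

Simulation-based tests run at the study's scale where the contract demands
it (234-300 trees, 1,000-5,000 SNPs, 20 seeds for power/calibration
properties; 100 seeds for the defoliation false-positive control) and at
toy scale for oracle equivalences. Bootstrap and permutation defaults
(10,000 / 999) are exposed as parameters; the pipeline driver uses smaller
counts by default (1,000 / 199) which are ample for the synthetic study
size. All samplers take explicit seeds; fixed seed means bit-identical
output, including the full fixture bundle. Known numerical guards: spline
fit floor 1e-6; BSLMM variance components clamped to [1e-6, 1e4]; GRM
eigenvalues below 1e-8 excluded from the polygenic update; AMOVA negative
components floored only for percentages.

## Known limitations

* The BSLMM is a faithful-but-reduced sampler (Gibbs with a Metropolis
  step for pi), not a re-implementation of any particular package's
  proposal mechanics; PIPs on weak signals depend on chain length.
* The BLINK-style scan shares the published algorithm's structure
  (LD-pruned pseudo-QTNs, BIC model selection, iterative conditioning) but
  is not parameter-for-parameter identical to the reference tool.
* AMOVA assumes mean-imputed dosages are adequate; with the default
  filters (>= 80% call rates) the imputation share is small.
* The defoliation detector's sd-ratio correction over-subtracts shared
  signal when the host carries substantial tree-level noise; the robust
  scaling mitigates but does not remove this, which is why event-year
  localization is only tested on constructions where the depression
  dominates the noise.
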