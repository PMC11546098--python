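# dendrogwas

Dendrogenomics toolkit: joint analysis of tree-ring phenotypes and
genome-wide SNP variation in natural forest-tree populations.

Long-lived conifers record their response to droughts, cold spells and
insect defoliator outbreaks in their annual rings. Given ring-width series
and a reduced-representation SNP matrix for the same trees, `dendrogwas`
asks which genetic variants are associated with how individual trees
resist, recover from and are resilient to those stresses — the kind of
question a population of a few hundred weakly differentiated trees across
several natural stands can answer.

The pipeline covers:

* **Ring-series standardization** — cubic smoothing spline detrending (50%
  frequency cutoff at 67% of series length), optional AR prewhitening,
  Tukey-biweight site chronologies, 30-year growth-trend classification.
* **Dendrophenotypes** — stress-response indices per reference period
  (resistance Rt = G_d/G_prev, recovery Rc = G_post/G_d, resilience
  Rs = G_post/G_prev, relative resilience RRs = (G_post − G_d)/G_prev),
  climate-quantile-conditioned mean indices, insect-defoliation
  reconstruction from host vs non-host growth (≥ 5-year synchronized
  depressions in ≥ 25% of trees), and descriptive growth/needle traits.
* **Population genomics** — call-rate/heterozygosity/MAF filtering, LD-kNN
  imputation, per-population Ho/He/π/F_IS, pairwise Weir–Cockerham F_ST
  with bootstrap CIs, Nei's standard distance, hierarchical AMOVA with
  permutation tests, allele-frequency PCA, Mantel test, per-tree
  heterozygosity, great-circle geography.
* **Association** — three independently implemented models with a
  consensus: per-SNP GLM with Benjamini–Hochberg FDR; a sparse Bayesian
  linear mixed model (spike-slab effects + genomic-relationship polygenic
  term, Gibbs-sampled, selection at posterior inclusion probability
  PIP > 0.25); and an iterative pseudo-QTN scan with LD exclusion and BIC
  model selection (BLINK-style, Bonferroni-controlled). Heterozygosity–
  phenotype correlations and per-population t-tests round this out.
* **Annotation** — GFF3-based gene context for selected SNPs: exon, intron,
  5′/3′ region within 10 kb, or intergenic with exact nearest-gene
  distances.
* **Synthetic data** — a first-class generator (Balding–Nichols structure,
  multiplicative ring-width model with planted causal SNPs and defoliation
  episodes) so the whole pipeline is testable against known ground truth.

## Worked example

Simulate the default study conditions (six populations, 234 trees, 5,000
SNPs at target F_ST 0.017, five planted causal SNPs whose alleles modulate
stress-year growth), run the population-genomic summaries, compute the
resistance phenotype for the first reference stress period, and scan it
with all three association methods:

```python
import numpy as np
from dendrogwas import synth, dendropheno as dp, popgen, assoc

cfg = synth.SimConfig(seed=1)
g, truth, rings = synth.simulate_all(cfg)

gf, rep = popgen.filter_loci(g)
gi = popgen.impute_ld_knn(gf)
am = popgen.amova(gi, n_perm=199, seed=1)

periods = [dp.StressPeriod(str(i + 1), a, b)
           for i, (a, b) in enumerate(cfg.stress_years)]
traits = dp.lloret_trait_table(rings.series, periods)

res_glm = assoc.glm_scan(gi, traits["Rt1"], "Rt1")
res_bs  = assoc.bslmm_pip(gi, traits["Rt1"], "Rt1", seed=1)
res_bl  = assoc.blink_scan(gi, traits["Rt1"], "Rt1")
cs = assoc.consensus({m: set(r.loc[r.selected, "snp"]) for m, r in
                      [("GLM", res_glm), ("BSLMM", res_bs), ("BLINK", res_bl)]})
```

Output of the full script (printed values are from this exact run):

```
simulated 234 trees x 5000 SNPs in 6 populations
filters kept 4866/5000 SNPs (call-rate 66, het 0, MAF 68 dropped)
mean individual heterozygosity 0.362
pairwise WC FST: mean 0.0164, range 0.0152-0.0178
AMOVA: FST=0.033 FSC=0.032 FCT=0.001 (within-population 96.7%, p=0.005)
Rt1 selections: GLM 5, BSLMM 5, BLINK 5
>=2 methods: ['12.20400', '12.30500', '2.10600', '8.40100', '9.16600']  all 3: ['12.20400', '12.30500', '2.10600', '8.40100', '9.16600']
planted causal SNPs: ['12.20400', '12.30500', '2.10600', '8.40100', '9.16600']
```

Reading it: realized pairwise differentiation sits at the simulated target
(mean θ 0.0164 against a target of 0.017); the AMOVA F_ST is roughly twice
the pairwise mean because dosage-coded molecular variance sits on the
2θ/(1+θ) scale; nearly all genetic variance (96.7%) is within populations,
as expected for weakly structured stands. All five planted causal SNPs —
whose alleles multiply stress-year growth by 1.3 per copy — are recovered
by every method, so the three-method consensus contains exactly the ground
truth with no false positives.

The same stages are available from the shell:

```bash
dendrogwas simulate --out fixture --seed 1
dendrogwas popgen --vcf fixture/genotypes.vcf --popmap fixture/popmap.tsv --out popgen_out
dendrogwas run --config run.yaml     # full pipeline from a YAML config
```

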