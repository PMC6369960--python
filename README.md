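# sdmap

Maximum-likelihood detection, fine-mapping and quantification of
haploid-acting segregation distortion loci from paired bulk-gamete
(pollen) and somatic pooled sequencing of a single F1 hybrid.

A locus that distorts segregation in the male germline shifts the
ancestry ratio of gamete-derived reads away from the somatic ratio, and
the shift decays with recombination distance along the chromosome.
`sdmap` models this decay explicitly: per-site allele counts at
ancestry-informative SNPs are combined into a chromosome-wide binomial
likelihood whose success probability follows Haldane's mapping function
around a candidate distorter position. The somatic library — which
cannot carry distortion — calibrates an empirical null that absorbs
reference-mapping bias. The package provides:

- **site selection** (`sdmap.sites`): fixed-difference/heterozygote and
  genotype-quality filters, depth-quantile filtering, and a >100 bp
  spacing rule, from a multi-sample VCF or a pre-made counts table;
- **genetic map** (`sdmap.genmap`): monotone piecewise-linear
  interpolation of (bp, cM) anchors and Haldane recombination
  probabilities;
- **likelihood** (`sdmap.likelihood`): the sampling-configuration
  model with uniform error rate `E` and mapping-bias odds
  `b = K_s/(1-K_s)`, the somatic null ratio `K_s`, and profile ML
  estimation of the segregation ratio `k`;
- **scan** (`sdmap.scan`): likelihood-ratio maximization over candidate
  positions, chi-square(1) nominal p-values (anti-conservative because
  the statistic is maximized — use the stringent default cutoff
  5e-4), and percentile bootstrap mapping confidence intervals from
  site resampling;
- **simulation** (`sdmap.simulate`): synthetic paired counts under null
  and distorted models, plus power / false-positive / CI-coverage
  experiments;
- **downstream** (`sdmap.downstream`): windowed raw ancestry ratios and
  closed-form viability (`1/(1+X) = k`) and rate-of-evolution
  calculators.

## Command line

```sh
# build filtered ancestry-informative counts from a VCF
sdmap sites --vcf calls.vcf --roles roles.yaml --min-gq 30 \
    --depth-quantiles 0.10 0.90 --min-gap 100 --out counts.tsv

# genome scan with 1000 bootstrap replicates
sdmap scan --counts counts.tsv --map map.tsv --error-rate 0.001 \
    --alpha 0.0005 --bootstrap 1000 --seed 17 --out scan.json

# synthetic data and calibration experiments
sdmap simulate --sites 10000 --length-mb 25 --depth 40 --k 0.55 \
    --pos auto --seed 1 --out sim.tsv
sdmap power --k 0.505,0.510,0.520,0.550,0.640 --reps 100 \
    --bootstraps 200 --alpha 0.0005 --seed 1 --out power.tsv

# windowed raw ancestry ratios, viability and rate calculators
sdmap windows --counts counts.tsv --snps-per-window 1000 --out windows.tsv
sdmap viability --k 0.511,0.631 --model both
sdmap rate --n-loci 3 --divergence-years 337000
```

`roles.yaml` maps sample ids to roles:

```yaml
parent1: [lyr_parent_a, lyr_parent_b]   # lineage whose allele is counted as "lyr"
parent2: [hal_parent_a, hal_parent_b]
f1_soma: [f1_leaf]
f1_germ: [f1_pollen]
```

The counts table is an 8-column TSV
(`chrom pos allele_lyr allele_hal soma_lyr soma_hal germ_lyr germ_hal`);
the map is a `(chrom, pos_bp, cM)` TSV (use `--map-zero-based` for
BED-like input).

## Modelling notes

- The null hypothesis "germline ratio equals the somatic ratio K_s" is
  operationalized as `k = 0.5` plus a post-error read-sampling odds
  `b = K_s/(1-K_s)`, which predicts a constant germline lyrata-read
  fraction of exactly `K_s` at every site; the unbiased four-term
  configuration model is available via `bias=1`.
- The error rate `E` (default 0.001) is fixed by configuration, not
  estimated: under a constant-ratio somatic model it is not jointly
  identifiable with `K_s`.
- Binomial coefficients are omitted from all likelihoods (constant in
  `k`), making the site likelihood identical to the per-read product.
- Candidate positions default to the informative-site positions, evenly
  subsampled to `--max-grid`; percentile bootstrap CIs are not
  guaranteed to contain the point estimate.
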