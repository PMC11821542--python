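# anchorpgs

Local-ancestry-aware decomposition of polygenic scores (PGS) for admixed
cohorts, with an estimator of the correlation `rho` of causal effect
sizes between an admixed group and the GWAS reference group.

A PGS built in one ancestry loses accuracy in another for *local*
reasons (ancestry-specific LD between tag SNPs and causal variants) and
potentially *nonlocal* ones (effect sizes that genuinely differ).  This
package separates the two: using diploid local-ancestry probabilities it
splits each individual's score into a European-segment part (EPGS) and
an African-segment part (APGS) built from **mean-centered
ancestry-specific dosages**, fits

```
Y = I + (b_eu * EPGS + b_af * APGS) * (1 + omega * theta) + covariates + e
```

(`theta` = global African-ancestry fraction), and estimates
`rho = b_eu / b_obs_eu` against the phenotype-on-PGS slope `b_obs_eu`
in a European reference cohort.  Uncertainty comes from bootstrap
resampling of individuals in both cohorts.

A first-class simulator generates admixed cohorts for calibration:
Balding–Nichols divergence between two ancestral populations, Poisson
ancestry-tract mosaics, optional founder-block LD (so tag-SNP scores are
meaningful), and additive phenotypes with configurable heritability and
cross-ancestry effect-size correlation.

## Layout

| module | contents |
|---|---|
| `anchorpgs.synthetic_admix` | cohort / effect-size / phenotype simulation, scenario grid |
| `anchorpgs.local_ancestry` | diploid state probabilities, ancestry dosages, segment masking |
| `anchorpgs.ancestral_freq` | background allele-frequency regression, mean-centering |
| `anchorpgs.pgs_engine` | GWAS, LD clumping, PGS, reference slope, attenuation ratio |
| `anchorpgs.anchor_core` | decomposed-score model, grid search, bootstrap, binning, rho, pooling |
| `anchorpgs.ancestry_tools` | NNLS mixture coefficients, ancestry entropy, kernel smoothing |
| `anchorpgs.workflow_io` | VCF/TSV/JSON formats, cohort bundles, fit reports |
| `anchorpgs.pipeline` | end-to-end experiments and calibration studies |

## CLI

```bash
anchor simulate --config cfg.yaml --out sim          # VCF + ancestry/sample TSVs
anchor freqs    --vcf sim.vcf --ancestry sim.ancestry.tsv --out freqs.tsv
anchor gwas     --vcf train.vcf --samples train.samples.tsv \
                --phenotype phenotype --out gwas.tsv
anchor clump    --vcf train.vcf --gwas gwas.tsv --p1 0.05 --r2 0.1 --kb 500 \
                --out weights.tsv
anchor pgs      --vcf test.vcf --weights weights.tsv --out pgs.tsv
anchor decompose --vcf sim.vcf --ancestry sim.ancestry.tsv \
                --samples sim.samples.tsv --weights weights.tsv --out scores.tsv
anchor fit      --scores scores.tsv --samples sim.samples.tsv \
                --phenotype phenotype --omega zero --n-boot 1000 --seed 1 \
                --out fit.json
anchor bins     --scores scores.tsv --samples sim.samples.tsv \
                --phenotype phenotype --out bins.json
anchor pool     --reports fit1.json --reports fit2.json --out pooled.json
```

A config file is YAML with `SimulationConfig` keys (`seed` mandatory),
e.g.

```yaml
n_individuals: 2000
n_variants: 5000
n_causal: 100
h2: 0.6
rho: 1.0
fst: 0.15
n_founders: 4
theta_distribution: [uniform, 0.1, 0.9]
seed: 7
```

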