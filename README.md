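# rohburden

Runs-of-homozygosity (ROH) burden analysis for case-control SNP cohorts:
quality control, PLINK-style ROH calling, genomic inbreeding (Froh)
statistics, covariate-adjusted logistic burden regression with threshold
sweeps, and site-flip permutation nulls that expose type-I inflation under
site-level ascertainment confounding. A multi-site cohort simulator with
planted autozygous segments drives calibration, parameter-recovery and
power experiments without any real genotype data.

## Package layout

| module | contents |
|---|---|
| `rohburden.datamodel` | `GenotypeMatrix` (samples x variants hard calls), `VariantRecord`, `SampleRecord` |
| `rohburden.genotype_io` | PLINK text `.ped`/`.map` read/write, VCF (GT) read, `.hom`/`.hom.indiv` write/read |
| `rohburden.synthetic_cohort` | `CohortSpec`, multi-site simulator with planted IBD segments, logistic liability model, site-level confounding shifts |
| `rohburden.qc` | HWE exact test, relatedness/missingness/heterozygosity sample filters, SNP filters, sliding-window VIF LD pruning |
| `rohburden.roh` | run scan (>= 40 homozygous SNPs, no hets, density > 1 SNP/200 kb, 500 kb gap split), post-filtering over SNP-count and Mb grids |
| `rohburden.autozygosity` | Froh (total ROH bp / 2.77e9), short/long split at 8 Mb, variance-equalizing cutoff search, per-dataset descriptives |
| `rohburden.association` | GRM + principal components, IRLS logistic burden fit with Wald inference, per-1% odds transform, sweeps, interaction test, per-dataset fits |
| `rohburden.null_experiments` | whole-site flip permutation null, power simulation |
| `rohburden.pipeline` / `rohburden.cli` | YAML-configured end-to-end pipeline and `rohburden` CLI |

## CLI

```bash
rohburden demo --outdir out/demo --seed 1       # full pipeline on a synthetic cohort
rohburden run --config cfg.yaml --outdir out    # YAML-driven pipeline
rohburden simulate --config cohort.yaml --out-prefix data/cohort
rohburden qc --ped data/cohort.ped --map data/cohort.map --out-prefix data/clean
rohburden roh call --ped data/clean.ped --map data/clean.map --out data/run.hom
rohburden roh filter --hom data/run.hom --min-snps 110 --out data/run110.hom
rohburden froh compute --hom data/run110.hom --samples samples.tsv --out froh.tsv
rohburden assoc fit --froh froh.tsv --out assoc.tsv
rohburden null permute --froh froh.tsv --n-perm 1000 --seed 1 --out perm.json
rohburden null power --beta-true 16.1 --n 40000 --out power.json
```

All tables are TSV; the pipeline writes a `manifest.json` recording the
config hash, seed and artifact list.

## Conventions

- Genotypes are coded 0/1/2 as copies of the second (a2) allele, -1 missing.
- Coordinates are 1-based inclusive; segment length = end - start + 1.
- Froh always enters regression models on the proportion (0-1) scale, so a
  slope beta maps to a `100 * (exp(beta / 100) - 1)` percent odds change per
  additional 1% of genome in ROHs.
- Missing calls break ROH runs by default (configurable); a heterozygote
  always does.
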