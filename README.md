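# delcall

Indirect genotyping of a recurrent small deletion from SNP-array data.

A deletion that arose multiple times in a population sits on several
unrelated flanking-haplotype backgrounds, so linkage-based approaches
(tag SNPs, haplotype-copying imputation) break down even when probe
intensities inside the deletion still carry a clean dosage signal. This
package implements the full evaluation pipeline for that setting:

- **`delcall.synthetic`** — seeded cohort generator: mosaic-copying phased
  haplotype panels with a configurable number of independent deletion
  origins, copy-number dependent two-channel probe intensities, and a
  logistic case/control phenotype with confounders (sex, ethnicity, an
  rs334-like locus).
- **`delcall.popgen`** — pairwise LD (r, r², D′), LD profiles, extended
  haplotype homozygosity, haplotype spectra/diversity, Tajima's D and
  haplotype dendrograms.
- **`delcall.intensity`** — density-based intensity cut-off caller,
  hierarchical-clustering caller, Kruskal–Wallis/Dunn group tests and
  Cohen's d / Hedges' g effect sizes.
- **`delcall.models`** — multinomial (softmax) regression caller with the
  heterozygote as reference class and per-probe x, y, x·y terms; CART with
  Gini splits and a minimum node size of 5; bootstrap training-size curves
  and one-vs-rest ROC/AUC.
- **`delcall.impute`** — Li–Stephens haplotype-copying HMM imputing the
  masked deletion from a 100-individual reference panel (Ne = 20 000,
  thresholds 0.7/0.9), with repeated cross-validation and Table-style
  aggregate summaries.
- **`delcall.association`** — IRLS logistic regression with Wald CIs;
  additive/genotypic/dominant/recessive/heterozygous encodings; covariate
  adjustment; Bonferroni-thresholded region scans.
- **`delcall.evaluation`** — confusion-table performance reports
  (sensitivity/specificity/PPV/NPV, correct and adjusted-correct
  proportions, no-call rate, dosage correlation) and a side-by-side
  method comparison harness.
- **`delcall.io_formats`** — SHAPEIT-style HAPS/SAMPLE, IMPUTE-style GEN,
  intensity/phenotype TSV and recombination-map readers/writers.

## CLI

```bash
delcall simulate --config cfg.yaml --seed 13 --out-dir data/
delcall ld --in-dir data/ --focal DEL --out ld.tsv
delcall ehh --in-dir data/ --focal DEL --allele 1 --out ehh.tsv
delcall call-intensity --method hclust --in data/intensities.tsv --out calls.tsv
delcall train --method mrm --in-dir data/ --train-size 100 --out model.json
delcall impute --in-dir data/ --n-ref 100 --runs 1000 --thresholds 0.7,0.9 --out imp.tsv
delcall assoc --model genotypic --covariates sex,ethnicity,rs334 --in-dir data/ --out assoc.tsv
delcall evaluate --seed 1 --out-dir report/
delcall run --config cfg.yaml --seed 1 --out-dir run1/   # end-to-end + manifest
```

A config file is YAML with a `simulate:` section mirroring
`SimulationConfig` fields, e.g.

```yaml
simulate:
  n_individuals: 3036
  n_del_origins: 8
  del_freq: 0.382
```

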