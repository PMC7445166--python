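# toxmod

Network-module discovery and sparse genetic prediction of treatment-induced
myelosuppression.  Starting from germline genotypes (VCF) and per-patient
CTCAE toxicity grades, the pipeline

1. runs per-variant **allelic Fisher exact tests** against neutropenia,
   leukopenia, and thrombocytopenia (cases = grade 3–4, controls = grade
   0–1, grade-2 intermediates excluded), keeping nominal hits (p ≤ 1e-3);
2. maps nominal variants to their **nearest protein-coding gene** (within
   3 Mb) and uses those genes as seeds;
3. detects dense complexes on a STRING-style PPI network with an
   **MCODE-style algorithm** (k-core vertex weighting, greedy seed growth,
   2-core filter, haircut) and keeps seed-enriched complexes as the
   per-phenotype modules;
4. intersects the three modules into the **toxicity module** (genes shared
   by ≥2 phenotypes; ≥3 in validation mode);
5. reduces the nominal variants that map to the toxicity module with a
   **random-LASSO selection-frequency procedure** (randomized per-variant
   penalty factors, 10-fold CV logistic lasso path, counts of nonzero
   coefficients at the deviance-minimizing penalty over many rounds);
6. refits candidate sets at selection-frequency quantiles with a **ridge
   logistic model** (no L1 selection) and evaluates them by **ROC/AUC** on a
   stratified 80/20 train/validation split (intermediates are
   prediction-only and excluded from the ROC).

Enrichment utilities (overlap Fisher tests, Fisher's method, Bonferroni/BH,
TPM, the TPM > 1-in-≥2-samples expressed filter, and a 10,000-draw
expression permutation test) support the downstream expression analyses.

A first-class `synthetic` module generates a full test cohort — planted
PPI module, Hardy–Weinberg genotypes with planted causal variants, a
liability-threshold CTCAE grade model with exact 54/8/34 class sizes, and
negative-binomial expression counts — so everything is testable without
patient data.

## CLI

`toxmod` exposes one subcommand per stage plus an orchestrator:

```bash
toxmod simulate --seed 1 --out data/              # synthetic cohort
toxmod qc data/genotypes.vcf --out kept.txt
toxmod associate data/genotypes.vcf data/phenotypes.tsv --phenotype neutropenia --out assoc.tsv
toxmod map-genes data/genotypes.vcf data/genes.gff3 --out mapped.tsv
toxmod module data/network.tsv seeds.txt --vwp 0.5 --out module.tsv
toxmod overlap module_n.tsv module_l.tsv module_t.tsv --min-overlap 2 --out toxicity_module.tsv
toxmod tpm data/expression_counts.tsv --out tpm.tsv
toxmod perm-express data/truth_module_genes.txt data/expression_counts.tsv --n-perm 10000 --seed 1 --out perm.tsv
toxmod select dosages.tsv data/phenotypes.tsv --n-perm 100000 --seed 1 --out freq.tsv
toxmod run-all --config pipeline.yaml            # end-to-end with a YAML config
toxmod report results/                           # summary text + figures
```

`run-all` supports two modes: `main` (association on all samples,
module overlap ≥ 2, VWP 0.5) and `validation` (split first, association on
training samples only, overlap of all 3 phenotypes, VWP 0.1).  Every run
writes a `manifest.json` with the config hash, seeds, and per-stage counts;
reruns with the same config are byte-identical.

## Layout

```
src/toxmod/
  io_formats.py   VCF/BED/GFF3/GMT/edge-list readers, variant QC filter
  synthetic.py    synthetic cohort generator (network, genotypes, grades, expression)
  association.py  allelic Fisher tests, PCA, annotation, nearest-gene mapping
  network.py      MCODE-style weighting/complexes, seed modules, toxicity overlap
  enrichment.py   overlap tests, Fisher's method, TPM, expression permutation
  prediction.py   random-LASSO frequencies, quantile sets, ridge refit, ROC/AUC
  _path.py        numba L1-logistic path fitter (validated against R glmnet)
  pipeline.py     run_pipeline / report orchestration
  cli.py          click CLI
```
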