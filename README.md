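# doseffect

Gene-wise **dosage effect scoring** for tumor cohorts with paired copy-number
and expression profiles.

Copy-number alterations (CNAs) in cancers such as multiple myeloma span whole
chromosomes and thousands of genes, but not every amplified or deleted gene
actually changes its mRNA output: regulatory feedback and dosage compensation
decouple many genes from their copy number. `doseffect` quantifies, per gene,
how consistently a CNA is accompanied by a concordant expression change
across samples, separating *dosage-sensitive* genes (whose expression tracks
copy number, candidate functional targets of recurrent CNAs) from
*dosage-resistant* ones (highly expressed genes buffered against copy-number
change). It is aimed at cancer-genomics analysts working with gene × sample
expression matrices and SNP- or gene-level linear copy numbers (diploid = 2).

## The score

For gene *g* over *n* samples, split samples by copy number *c*:

- loss: *c* < 1.7, gain: *c* > 2.3, copy-neutral: 1.7 ≤ *c* ≤ 2.3
  (the band absorbs array noise and normal-cell contamination).

From the copy-neutral samples compute the reference expression mean μ_g and
standard deviation σ_g. A CNA sample is **concordant** when its expression
*x* moves past the reference band in the direction of its CNA:

    gain and x > μ_g + k·σ_g,   or   loss and x < μ_g − k·σ_g     (k = 1)

The dosage effect score is

    DES_g = (# concordant CNA samples) / (# CNA samples)  ∈ [0, 1],

defined only when CNAs affect more than 10 % of samples, at least five
copy-neutral samples exist, and σ_g > 0. Genes are low (DES < 0.2), medium
(0.2 ≤ DES ≤ 0.4) or high / dosage-sensitive (DES > 0.4); dosage-resistant
genes are the top 20 % by median expression with DES < 0.2.

Around the score the package provides: hyperdiploidy subtyping from the
median copy number of the eight characteristic trisomy chromosomes (3, 5, 7,
9, 11, 15, 19, 21; cutoff 2.3 or re-estimated from the cohort's bimodal
density), SNP-to-gene copy-number mapping (mean over SNPs within 5 kb of the
transcription region), moderated-t differential expression with
Benjamini–Hochberg control, Fisher / two-proportion / Cochran–Armitage trend
tests, GMT gene-set enrichment, a genome-wide karyotype CNA-frequency plot
colored by DES, and a ground-truthed cohort simulator.

## Worked example

```python
from doseffect import (SimConfig, simulate_cohort, classify_ploidy,
                       compute_des, truth_eval)

dataset, truth = simulate_cohort(SimConfig(seed=1))   # 200 samples x 2000 genes
calls = classify_ploidy(dataset)
print(calls.counts(), calls.cutoff_used)

des = compute_des(dataset)
print(len(des.defined()), (des.category_fractions() * 100).round(1).to_dict())
print(truth_eval(des, truth))
```

prints

```
{'NHMM': 100, 'HMM': 100} 2.3
946 {'low': 52.3, 'medium': 29.4, 'high': 18.3}
{'auroc': 0.9972275847275848, 'n_defined': 946,
 'mean_des_sensitive': 0.4253607314757146,
 'mean_des_resistant': 0.16330717442751166}
```

Half the simulated cohort is hyperdiploid (median trisomy copy number above
2.3); 946 of 2000 genes sit in regions altered often enough for a defined
DES; and the score separates the planted dosage-sensitive genes from
resistant ones almost perfectly (AUROC 0.997), with sensitive genes averaging
DES 0.43 versus 0.16 for resistant ones.

The same workflow runs from the shell:

```bash
doseffect simulate --seed 1 --out-dir cohort/
doseffect des --expression cohort/expression.tsv --cn cohort/copy_number.tsv \
              --annotation cohort/annotation.tsv --out des.tsv
doseffect run --config run.yaml          # end-to-end with manifest
```

Estimator-style classes (`DosageEffectScorer`, `PloidyClassifier`) expose the
same computations with scikit-learn `fit` / `get_params` conventions.

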