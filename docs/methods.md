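# Methods

## The dosage effect score

The dosage effect score (DES) treats each gene as a small case–control study
within a cohort of tumors profiled for both expression and copy number. The
copy-neutral samples at the gene (linear copy number in [1.7, 2.3]) define a
reference expression distribution through its mean and sample standard
deviation (n − 1 denominator); samples carrying a copy-number alteration
(CNA: CN < 1.7 or CN > 2.3) are scored concordant when expression exceeds
mean + k·sd for gains or falls below mean − k·sd for losses, with strict
inequalities and k = 1 by default. DES is the concordant fraction of CNA
samples.

The score makes three modeling assumptions worth stating:

- The CNA thresholds 1.7 / 2.3 are on the linear scale with diploid = 2 and
  already account for normal-cell contamination attenuating tumor signal;
  inputs must not be log-ratios (the reader rejects matrices whose overall
  median is below 1).
- One standard deviation is a deliberately permissive concordance band.
  Cis-regulatory buffering shrinks expression responses, so a stricter band
  would mostly add false negatives; `sd_multiplier` is exposed for users who
  want to tighten it.
- Only marginal (cis) dosage effects are measured; trans effects of CNAs on
  other genes' regulators are out of scope.

Reliability guards: DES is left undefined (NaN, with a recorded reason)
unless the CNA count strictly exceeds 10 % of the cohort
(`min_cna_fraction`), at least 5 copy-neutral samples exist
(`min_neutral_samples`; a mean/sd estimated from fewer points is too
unstable), and the reference sd is positive. The guard denominator is the
full cohort size; samples with a missing copy number at a gene count toward
neither CNAs nor the reference. Genes both gained and lost across samples
contribute concordance in each direction separately.

Categories follow the score's empirical terciles of practical interest:
low (DES < 0.2), medium (0.2 ≤ DES ≤ 0.4, closed on both ends) and high /
dosage-sensitive (DES > 0.4). Dosage-resistant genes are those in the top
20 % by median expression (`resistant_expr_quantile` = 0.80, quantile
membership inclusive) with a defined DES below 0.2. Category percentages can
be reported against all genes or only defined-DES genes; both denominators
are available because the choice materially changes the numbers.

## Hyperdiploidy subtyping

Hyperdiploid myeloma carries trisomies of chromosomes 3, 5, 7, 9, 11, 15, 19
and 21. Tumor purity and cross-array normalization pull an expected copy
number of 3 toward roughly 2.6, so the per-sample median of gene-level copy
numbers over the trisomy chromosomes is bimodal near 2.0 and 2.6. A sample is
called HMM when that median strictly exceeds the cutoff, 2.3 by default (the
midpoint of the two peaks). With `auto_cutoff` the cutoff is re-estimated as
the midpoint of the two highest modes of a Gaussian KDE (Silverman
bandwidth, modes closer than 0.2 CN merged); unimodal cohorts fall back to
2.3 with a warning, and fewer than 20 samples is an error because a density
estimate that small is not trustworthy. Medians are taken over gene-level
(not SNP-level) copy numbers to keep a single data path; this is a
documented divergence risk for cohorts where SNP density varies wildly
between genes.

## Preprocessing

Probe-level expression rows collapsing to gene symbols use the arithmetic
mean, as does SNP-to-gene copy-number summarization over the window
[tx_start − 5000, tx_end + 5000] (1-based, inclusive at both ends, strand
ignored). A SNP inside two overlapping gene windows contributes to both
genes. Genes with no SNP in the window get missing copy number and are
excluded from scoring (counted in a log line). Paired analysis restricts to
the intersection of gene symbols present in both matrices and the
annotation, sorted lexicographically, and the intersection of sample ids.

## Statistical tests

- *Differential expression* (HMM vs NHMM or any two-group labeling) uses a
  moderated two-sample t: the per-gene pooled variance is shrunk halfway
  toward the across-gene median pooled variance (weight 0.5), and the
  residual df are inflated by the implied prior df (d0 = df·w/(1 − w), so
  df doubles at w = 0.5) — the usual empirical-Bayes accounting for borrowed
  information. This is a deliberate, self-contained moderation scheme: exact
  equivalence with any particular external moderated-t implementation is a
  non-goal. Its type-I error is verified by simulation in the test suite.
- *Benjamini–Hochberg* adjustment delegates to statsmodels' step-up
  implementation behind input validation.
- *Fisher's exact test* (2×2) reports the probability-mass two-sided p
  (scipy) and a sample odds ratio with Haldane 0.5 correction when a cell is
  zero. It is verified against exhaustive margin-fixed enumeration for every
  table with total ≤ 40.
- *Two-proportion comparison* is the pooled chi-square/z test without
  continuity correction; degenerate margins return p = 1 with a warning.
- *Cochran–Armitage trend* on a 2×K table uses T = Σ s_j·x_1j with mean and
  variance conditional on all margins. For total counts ≤ 30 the default is
  the exact conditional tail P(|T − E| ≥ observed) under the multivariate
  hypergeometric, because the normal tail cannot approximate a heavily
  discrete null (sparse tables can differ from the exact tail by 0.3).
  Above 30 the asymptotic normal tail is used with a half-unit continuity
  correction (the plain z is available via `continuity=False`), which keeps
  it within ~0.01 of the exact tail at moderate counts.
- P-values are returned unclipped; display formatting floors at the
  conventional "< 2.2e-16".

The expression-quintile trend analysis ranks defined-DES genes by median
expression (ties broken lexicographically by symbol for determinism), splits
them into five groups as equal as possible (remainders to the
lower-expression groups) and tests high-DES membership for trend. A table
whose high-DES margin is empty or full carries no gradient and returns
p = 1 without invoking the trend test.

## The cohort simulator

The generator reproduces the features of a myeloma cohort that the pipeline
must detect: two subtypes (P(HMM) = 0.5) with whole-chromosome trisomies in
HMM; recurrent events with subtype-specific probabilities (chr13 loss 0.1 in
HMM / 0.7 in NHMM, 1q gain 0.3/0.5, 8p loss 0.2/0.2, 16q loss 0.2/0.2);
per-sample purity ~ Normal(0.6, 0.1) truncated to [0.1, 1]; observed CN =
2 + purity·(trueCN − 2) + Normal(0, 0.08), floored at 0.1; and log2
expression = mu_g + s_g·log2(cn_eff/2) + Normal(0, 0.5) with baseline
mu_g ~ Normal(8, 2) and sensitivity s_g ∈ {0, 1} (30 % sensitive). Purity
attenuation is applied to the expression-driving dosage as well, so a
sensitive trisomy gene shifts by log2(2.6/2) ≈ 0.38, not log2(1.5). Gene
coordinates are deterministic: 22 autosomes with human-scale lengths, genes
allocated proportionally and evenly spaced, so only the biology is random.
All draws come from one `numpy.random.Generator` in a fixed order (subtype,
purity, events, mu_g, s_g, CN noise, expression noise); a seed fully
determines the cohort.

What the simulator does **not** model — and hence what passing tests cannot
certify about real data: focal sub-arm events, subclonal mixtures,
translocations, copy-neutral LOH, heteroscedastic expression noise,
batch/normalization artifacts, and correlated co-expression structure. Real
cohorts will show lower AUROC and noisier category splits than the
simulator's.

Default problem sizes used in the test suite are the generator defaults
(200 samples × 2000 genes) for recovery properties, and 60 × 300 cohorts for
the 200-replicate trend-calibration study, a size at which each replicate
still yields ~140 defined-DES genes while the whole study stays cheap.

## Numerical and design choices

- Neutral band closed at both ends (CN exactly 1.7 or 2.3 is neutral); CNA
  calls strict. Expression concordance strict. Category bounds: medium is
  the closed interval [0.2, 0.4].
- Ploidy call strict (median > cutoff is HMM), matching the gain threshold's
  strictness; a median exactly at the cutoff is NHMM.
- Missing copy number is NaN everywhere, never 0 or 2; expression matrices
  must be complete.
- The karyotype plot places each gene at (tx_start + tx_end)/2, draws gain
  frequency upward and loss frequency downward with a 100 % reference bar
  per chromosome, colors bars by DES on a viridis [0, 1] scale
  (colorblind-safe) with undefined-DES genes in gray, and suppresses
  embedded timestamps/salts so vector output is byte-stable.
- The end-to-end runner writes every intermediate table, both figures and a
  JSON manifest (parameters, input checksums, outputs); reruns with the same
  config and seed are byte-identical.

## Known limitations

DES is a frequency, not an effect size: a gene whose expression doubles in
half its CNA samples scores 0.5, the same as one that barely crosses the
band in half of them. Its variance depends on the CNA count, so comparing
DES between genes with very different CNA frequencies conflates precision
with sensitivity. The 10 % frequency guard means genes in rarely altered
regions are simply not assessed. The hyperdiploidy cutoff assumes the
bimodal geometry produced by purity attenuation; cohorts with extreme purity
ranges may need `auto_cutoff` or a manual threshold.
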