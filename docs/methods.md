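# Methods

## Model and procedure

The analysis asks whether isoforms that carry a predicted miRNA target
site in a given region are more informative about the miRNA's expression
than isoforms that lack one. It operates entirely on the log2 scale:
expression matrices are assumed TPM/RPM-normalised and log-transformed
upstream, with a configurable floor value (default log2(0.001) ≈ −9.97)
marking "not expressed". A helper transform re-expresses log2(rpm + 1)
miRNA matrices on the log2(rpm + 0.001) scale (v ↦ log2(2ᵛ − 1 + 0.001))
so both conventions land on the same floor.

Per (miRNA, transcript), predicted sites are thresholded at binding
probabilities 0.5 and 0.8. No site above 0.5 → non-binding; only sites in
(0.5, 0.8] → discarded as noise; otherwise the union of regions hit by
the > 0.8 sites (CDS vs. UTRs, both when a site straddles a boundary)
yields coding-only / non-coding-only / both. A transcript with a > 0.8
site plus extra intermediate sites is classified by the > 0.8 sites
alone: the discard rule targets transcripts with *only* intermediate
evidence. All intervals are 0-based half-open in transcript coordinates;
GTF input is projected into transcript space at parse time (cumulative
exon lengths 5′→3′, strand-aware), so no strand logic exists anywhere
else.

The nested models regress miRNA expression on transcript expression by
plain OLS. Regressing in this direction (miRNA as response) is
statistically symmetric for detecting association and keeps one response
per pair regardless of how many isoforms a gene has. Pairs whose full
design has as many parameters as training samples are skipped, not
regularised — shrinkage would invalidate the likelihood-ratio test.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bind_prob_high` | 0.80 | high-confidence binding threshold |
| `bind_prob_low` | 0.50 | any-binding threshold |
| `min_mirna_variance` | 0.2 | miRNA sample-variance floor (ddof = 1, kept at equality) |
| `max_absent_fraction` | 0.25 | features absent in ≥ this fraction of samples are dropped |
| `top_k_mirnas` | none | alternative miRNA selection by mean expression (e.g. 100) |
| `train_fraction` | 0.8 | shared train/test split; one split per dataset |
| `rmse_threshold` | 0.7 | held-out RMSE gate; both models must be below it |
| `fdr_alpha` | 0.05 | BH level for the significance ratio |
| `subsample_size`, `subsample_iterations` | 10 000, 1000 | pair subsampling scheme |

Boundary conventions follow the published thresholds: variance exactly
0.2 is kept ("smaller than 0.2" is dropped), absence in exactly 25 % of
samples drops the feature ("25 % or more"), and only strictly negative
Pearson correlation passes the correlation filter.

## Statistical choices

**LRT.** The Gaussian-MLE form Λ = n·ln(RSSᵣ/RSS_f) with a χ²
reference (df = number of binding transcripts, plus nothing for the
covariate, which enters both models) is computed on the training fits,
while the RMSE gate uses the held-out split — gate and test never share
data. Λ is clipped at zero when numerical error inverts the RSS order,
and RSS values are floored at 1e−12 before the log. At the scales used
here (≥ 80 training samples, ≤ 5 parameters) the χ² approximation's
systematic deviation from the exact F-based p-value is ~0.01 in KS
distance, well below sampling noise.

**Multiple testing.** BH adjustment is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` behind the
package's own surface; the test suite checks it against an independent
hand-rolled step-up implementation. BH is applied *within* each
subsample iteration for both real and randomized draws (a global-BH mode
exists behind `global_bh` for sensitivity analysis; the per-pair results
table also carries globally adjusted p-values for reporting).

**Covariate.** For TNBN pairs, the covariate miRNA is the one most
correlated (signed Pearson by default; `covariate_abs_correlation`
switches to |r|) with the miRNA of interest among miRNAs with a > 0.5
site overlapping the non-coding region of any transcript of the gene.
Ties go to the lexicographically smaller identifier, as do ties in the
top-k expression filter, so runs are deterministic.

**Randomization null.** Binding labels are shuffled within each gene,
preserving the per-gene counts of binding and non-binding transcripts
exactly; only the reduced models are retrained per iteration (full-model
membership is invariant under the shuffle in all three settings, so full
fits are cached once). The gate is re-evaluated with the retrained
reduced RMSE and the cached full RMSE. Subsampling is without
replacement within an iteration; iteration i draws from a generator
seeded `random_seed + i`, making iterations independent, reproducible
and order-invariant. The Mann–Whitney comparison of the two ratio
samples is two-sided (one-sided available), exact for samples below 20,
normal approximation with tie correction otherwise; two all-identical
samples are reported as p = 1.

**Known limitation of the null comparison at small scales.** The real
branch computes each pair's LRT p-value once, while the randomized branch
redraws reduced-model p-values every iteration. When almost every pair is
null, per-iteration BH rejects *something* in a fraction ≈ α of
randomized iterations, whereas the real branch rejects only if some fixed
pair clears α/m — so the two ratio samples, though equal in mean to
within ~10⁻³, are not exchangeable conditional on one dataset, and the
tie-corrected Mann–Whitney test (its variance collapses under the mass of
tied zero ratios) flags the asymmetry in a substantial fraction of
all-null datasets. The difference of means (`dist`) remains the reliable
null summary at these scales; the test suite asserts the mean and KS
behaviour of the null and documents the Mann–Whitney sensitivity.

## Synthetic data

The generator emulates the structure the analysis assumes, not real
sequencing data. Genes receive 2–4 isoforms with random lengths
(0.9–3 kb) and CDS intervals leaving both UTRs non-empty. A configurable
fraction of (miRNA, gene) pairs is regulated: a proper subset of isoforms
gets a high-confidence site (probability 0.85–0.99) in the configured
region, at least one isoform stays site-free (the escape), and
intermediate-probability decoys (0.55–0.75) exercise the discard rule
without ever touching an escape isoform. For "both"-region pairs the
escape isoforms instead carry non-coding-only sites, which is the only
topology that gives the TBN setting a non-degenerate contrast.

Expression: miRNA values are N(mean, sd²) per sample on the log2 scale
(partner blocks can share a latent factor with loading λ, giving
inter-miRNA correlation λ²); binding isoforms respond as
t = baseline − effect·(m_driver − mean) + N(0, noise²); escapes are
baseline + noise; gene expression is the log2 of summed linear-scale
isoform abundances, so the gene-level correlation filter behaves
realistically. In confounder mode the driver is a partner miRNA that
binds the non-coding region — the scenario the covariate model deflates.

Default scale (300 genes × 20 miRNAs, 200 samples, 30 % regulated pairs,
effect 0.8, noise sd 0.3) is the package's scaled-down study condition
for end-to-end checks; ~10 s per run on one CPU. The miRNA sd default of
0.5 calibrates the simulated abundance scale to the pipeline's fixed
thresholds: variance 0.25 passes the 0.2 variance filter, and the
reduced model's residual sd (~0.5) sits below the 0.7 RMSE gate, so null
and planted runs exercise the gate rather than being emptied by it.

What passing tests on these data do **not** show: robustness to count
noise (no negative-binomial layer), batch effects, missing values,
non-linear dose-response, or the false-positive structure of real
sequence-based site predictions. The generator's probabilities are
calibrated to the 0.5/0.8 thresholds by construction.

## Numerical and degenerate-input conventions

OLS uses `numpy.linalg.lstsq`; rank-deficient designs get the
minimum-norm solution and a degeneracy flag (fitted values, hence RSS
and the LRT, are unaffected by collinearity). A constant response yields
adjR² = 1 for an exact fit, else 0. Readers reject rather than coerce:
duplicate identifiers, non-numeric or missing cells, probabilities
outside [0, 1], inverted intervals, and CDS intervals beyond the
transcript all name the offending record. Empty filter output completes
the run with a `degenerate` flag instead of raising mid-pipeline.
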