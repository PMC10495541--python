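# splicemir

Does alternative splicing let transcripts escape microRNA regulation?

miRNAs repress their targets through short complementary target sites —
not only in the 3′UTR but also inside coding exons. When a gene is
alternatively spliced, some isoforms may splice out the exon carrying the
site and become unresponsive to the miRNA. `splicemir` tests this
transcriptome-wide from paired miRNA / transcript / gene expression
matrices and a table of predicted target sites: if coding-region binding
matters, the expression of binding isoforms should predict miRNA
expression better than the expression of escape isoforms alone.

It is a library for computational biologists working with bulk expression
data (log2 TPM-like matrices) plus a thin CLI for end-to-end runs.

## Method

For each miRNA *m* and gene, transcripts are classified from predicted
site probabilities: **binding** (some site with p > 0.8, split by region
into coding-only / non-coding-only / both), **non-binding** (no site with
p > 0.5), or discarded (only intermediate sites, 0.5–0.8). Pairs are
filtered by expression presence (absent in ≥ 25 % of samples), miRNA
variance (≥ 0.2) or top-k expression, a splicing contrast (≥ 1 binding
and ≥ 1 non-binding isoform in the investigated region), and strictly
negative Pearson correlation between miRNA and gene expression.

Per surviving pair, nested OLS models are fit on a shared 80/20
train/test split:

```
full:     m = α + Σᵢ βᵢ·tᵢ,nb + Σⱼ γⱼ·tⱼ,b (+ δ·m₂) + ε
reduced:  m = α + Σᵢ βᵢ·tᵢ,nb              (+ δ·m₂) + ε
```

where the *k* transcripts t·,nb lack sites in the investigated region and
the *l* transcripts t·,b carry them (m₂ is an optional correlated-miRNA
covariate). Three settings choose the investigated region: **ALLT** (any
site), **TNBN** (coding sites, no non-coding binders in the full set),
**TBN** (coding sites on top of non-coding binding). Models with held-out
RMSE ≥ 0.7 (either of the pair) are gated out; the rest are compared with
the Gaussian-MLE likelihood-ratio test Λ = n·ln(RSSᵣ/RSS_f) ~ χ²_l,
Benjamini–Hochberg corrected at α = 0.05, with Cohen's
f² = (adjR²_f − adjR²_r)/(1 − adjR²_f) as effect size.

The headline quantity is the **significance ratio** — the fraction of
gated nested pairs whose full model wins — estimated over repeated
subsamples of pairs and compared (two-sided Mann–Whitney U) against the
same ratio after shuffling binding labels within each gene while
preserving per-gene label counts. `dist` is the difference of the two
mean ratios.

## Worked example

Fitting one planted pair (`examples/03_fit_nested_models.py`) — a binding
isoform coupled to the miRNA with slope −0.8 and an escape isoform:

```
k (escape) = 1, l (binding) = 1, LRT df = 1
test RMSE: full 0.287, reduced 0.493 (gate: both < 0.7 -> True)
LRT statistic 158.3, p = 2.71e-36
adjusted R^2: full 0.624, reduced -0.006
Cohen's f^2 = 1.67 (large)
```

The reduced model (escape isoform only) explains nothing (adjR² ≈ 0);
adding the binding isoform makes the miRNA predictable (adjR² = 0.62),
and the LRT rejects decisively with a large effect size.

A full run on 100 simulated genes (`examples/04_full_pipeline.py`):

```
mean significance ratio, real subsamples:       1.000
mean significance ratio, shuffled labels (null): 0.663
dist = 0.337, Mann-Whitney U = 10000, p = 5.59e-39
```

Real binding labels sort isoforms far better than the within-gene
shuffle, i.e. the coding-region sites carry genuine predictive signal.
The other examples cover data simulation, site categorization, and the
correlated-miRNA covariate that deflates a planted confounder.

The CLI mirrors this: `splicemir simulate --out data/` writes a synthetic
dataset, and

```
splicemir run --expression-mirna data/expression_mirna.tsv \
  --expression-transcript data/expression_transcript.tsv \
  --expression-gene data/expression_gene.tsv \
  --sites data/sites.tsv --annotation data/annotation.tsv \
  --setting TNBN --out out/
```

writes per-pair results, ratio samples, stage counts and a JSON summary.

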