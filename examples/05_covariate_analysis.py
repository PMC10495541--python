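"""Deflating a confounded signal with the correlated-miRNA covariate.

The dataset plants a partner miRNA that binds the non-coding region of the
same transcripts, is correlated with the miRNA of interest through a
shared latent factor, and is the *true* driver of expression.  Without
adjustment the TNBN analysis attributes the signal to coding-region
binding; adding the most correlated non-coding-binding miRNA as a
covariate in both nested models removes most of it.
"""

from splicemir import PipelineConfig, SimulationConfig, make_dataset, run_pipeline

sim = SimulationConfig(n_genes=100, n_mirnas=10, n_samples=120,
                       frac_regulated_pairs=0.3, confounder=True,
                       mirna_latent_loading=0.8, seed=33)
bundle = make_dataset(sim)
cfg = PipelineConfig(random_seed=33, subsample_size=100, subsample_iterations=100)


def run(covariate_mode):
    return run_pipeline(bundle.mirna_expr, bundle.transcript_expr, bundle.gene_expr,
                        bundle.sites, bundle.catalog, "TNBN", cfg,
                        covariate_mode=covariate_mode)


plain = run(False)
adjusted = run(True)
print(f"dist without covariate: {plain.comparison.dist:.3f} "
      f"(p = {plain.comparison.p_value:.3g})")
print(f"dist with covariate:    {adjusted.comparison.dist:.3f} "
      f"(p = {adjusted.comparison.p_value:.3g})")
print("\nThe drop in dist shows the apparent coding-region effect was largely"
      "\nexplained by the correlated miRNA binding the non-coding region.")
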