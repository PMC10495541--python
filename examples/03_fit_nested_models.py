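"""Fit the nested full/reduced OLS models for one miRNA-gene pair.

The full model predicts miRNA expression from all of the pair's
transcripts; the reduced model uses only the escape (non-binding)
transcripts.  If the binding transcripts carry real signal, the full model
fits significantly better (likelihood-ratio test) and Cohen's f^2
quantifies the gain.
"""

import numpy as np
import pandas as pd

from splicemir import (
    ExpressionMatrix,
    PairUniverse,
    PipelineConfig,
    Setting,
    fit_pair,
    split_samples,
)

rng = np.random.default_rng(0)
n = 200
samples = [f"s{i}" for i in range(n)]

m = 6.0 + 0.5 * rng.standard_normal(n)                    # miRNA, log2 scale
t_bind = 5.0 - 0.8 * (m - 6.0) + 0.3 * rng.standard_normal(n)  # repressed isoform
t_escape = 5.0 + 0.3 * rng.standard_normal(n)             # escapes regulation

mirna = ExpressionMatrix("mirna", pd.DataFrame({"miR-1": m}, index=samples))
tx = ExpressionMatrix("transcript", pd.DataFrame(
    {"t_bind": t_bind, "t_escape": t_escape}, index=samples))

pair = PairUniverse("miR-1", "GENE1", Setting.TNBN,
                    frozenset({"t_bind", "t_escape"}), frozenset({"t_escape"}))
cfg = PipelineConfig(random_seed=0)
split = split_samples(samples, cfg)

res = fit_pair(pair, tx, mirna, split, cfg)
print(f"k (escape) = {res.k}, l (binding) = {res.l}, LRT df = {res.df}")
print(f"test RMSE: full {res.rmse_full:.3f}, reduced {res.rmse_reduced:.3f} "
      f"(gate: both < {cfg.rmse_threshold} -> {res.passed_rmse_gate})")
print(f"LRT statistic {res.lrt_stat:.1f}, p = {res.p:.3g}")
print(f"adjusted R^2: full {res.adj_r2_full:.3f}, reduced {res.adj_r2_reduced:.3f}")
print(f"Cohen's f^2 = {res.cohens_f2:.2f} ({res.effect_bin})")
print("\nA tiny p-value with a large f^2 says the binding isoform explains"
      "\nmiRNA expression far beyond what the escape isoform can.")
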