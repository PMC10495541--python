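"""Subsampled significance ratios and the within-gene label-permutation null.

The pipeline's headline quantity is the *significance ratio*: among nested
model pairs passing the held-out RMSE gate, the fraction whose full model
significantly outperforms the reduced model (BH-adjusted LRT p < alpha).
Its sampling distribution is estimated by repeatedly drawing subsamples of
miRNA-gene pairs.  The null distribution comes from shuffling the
binding/non-binding transcript labels within each gene — preserving the
per-gene counts of binding and non-binding transcripts exactly — then
retraining only the reduced models (the full model's membership is
invariant under the shuffle) and recomputing gate, LRT and BH.  The real
and null ratio distributions are compared with a two-sided Mann-Whitney U
test, and `dist`, the difference of their means, summarises the effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .categorize import PairUniverse
from .config import PipelineConfig
from .io import ExpressionMatrix
from .models import SampleSplit, _RSS_FLOOR, _design, _ols_core, benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatioSample:
    """One subsampling iteration's significance ratio."""

    iteration: int
    ratio: float
    randomized: bool
    n_pairs_tested: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError(f"ratio {self.ratio} outside [0,1]")


@dataclass(frozen=True)
class DistributionComparison:
    """Real vs. randomized ratio distributions: means, dist and MWU test."""

    mean_ratio_real: float
    mean_ratio_random: float
    dist: float
    u_statistic: float
    p_value: float


def _draw_indices(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    if size >= n:
        return np.arange(n)
    return rng.choice(n, size=size, replace=False)


def subsample_significance_ratio(
    results: Sequence, cfg: PipelineConfig
) -> List[RatioSample]:
    """Significance ratio over repeated subsamples of fitted pairs.

    Per iteration i (seeded ``random_seed + i``): draw ``subsample_size``
    pairs without replacement, keep those passing the RMSE gate, apply BH
    within the subsample, and report #significant / #gate-passing.  With
    ``cfg.global_bh`` the adjustment is instead done once over all pairs.
    """
    if not results:
        raise ValueError("no fitted pairs to subsample")
    if cfg.subsample_size > len(results):
        logger.warning(
            "subsample_size %d > %d available pairs; sampling all",
            cfg.subsample_size, len(results),
        )
    gate = np.array([r.passed_rmse_gate for r in results])
    pvals = np.array([r.p for r in results])
    global_adj: Optional[np.ndarray] = None
    if cfg.global_bh:
        global_adj = np.full(len(results), math.nan)
        if gate.any():
            adj, _ = benjamini_hochberg(pvals[gate], cfg.fdr_alpha)
            global_adj[gate] = adj
    out: List[RatioSample] = []
    for i in range(cfg.subsample_iterations):
        rng = np.random.default_rng(cfg.random_seed + i)
        idx = _draw_indices(rng, len(results), cfg.subsample_size)
        sel = idx[gate[idx]]
        if sel.size == 0:
            out.append(RatioSample(i, 0.0, False, 0))
            continue
        if global_adj is not None:
            n_sig = int(np.sum(global_adj[sel] < cfg.fdr_alpha))
        else:
            _, flags = benjamini_hochberg(pvals[sel], cfg.fdr_alpha)
            n_sig = int(flags.sum())
        out.append(RatioSample(i, n_sig / sel.size, False, int(sel.size)))
    return out


def randomize_binding_labels(
    pair: PairUniverse, seed: int | np.random.Generator
) -> PairUniverse:
    """Shuffle binding labels within a gene, preserving the label counts.

    The full transcript set is unchanged; the reduced (non-binding) set is
    replaced by a uniformly drawn subset of the same size.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = sorted(pair.full_transcripts)
    n_reduced = len(pair.reduced_transcripts)
    chosen = rng.choice(len(full), size=n_reduced, replace=False)
    new_reduced = frozenset(full[i] for i in chosen)
    return PairUniverse(
        mirna_id=pair.mirna_id,
        gene_id=pair.gene_id,
        setting=pair.setting,
        full_transcripts=pair.full_transcripts,
        reduced_transcripts=new_reduced,
    )


class _PairCache:
    """Cached per-pair arrays and full-model fits for the randomized null.

    The label shuffle never changes full-model membership, so each pair's
    full fit (training RSS, held-out RMSE) is computed once; per iteration
    only the reduced design changes.
    """

    def __init__(
        self,
        pairs: Sequence[PairUniverse],
        transcript_expr: ExpressionMatrix,
        mirna_expr: ExpressionMatrix,
        split: SampleSplit,
        cfg: PipelineConfig,
        covariates: Optional[Mapping[Tuple[str, str], str]] = None,
    ) -> None:
        T_train = transcript_expr.values.loc[split.train_ids]
        T_test = transcript_expr.values.loc[split.test_ids]
        M_train = mirna_expr.values.loc[split.train_ids]
        M_test = mirna_expr.values.loc[split.test_ids]
        self.cfg = cfg
        self.n_train = len(split.train_ids)
        self.pairs: List[PairUniverse] = []
        self.full_cols_train: List[np.ndarray] = []
        self.full_cols_test: List[np.ndarray] = []
        self.full_ids: List[List[str]] = []
        self.y_train: List[np.ndarray] = []
        self.y_test: List[np.ndarray] = []
        self.cov_train: List[Optional[np.ndarray]] = []
        self.cov_test: List[Optional[np.ndarray]] = []
        self.rss_full: List[float] = []
        self.rmse_full: List[float] = []
        skipped = 0
        for pair in pairs:
            ids = sorted(pair.full_transcripts)
            cov_id = covariates.get((pair.mirna_id, pair.gene_id)) if covariates else None
            n_params_full = len(ids) + 1 + (1 if cov_id else 0)
            if self.n_train <= n_params_full:
                skipped += 1
                continue
            Xtr = T_train[ids].to_numpy(dtype=float)
            Xte = T_test[ids].to_numpy(dtype=float)
            ytr = M_train[pair.mirna_id].to_numpy(dtype=float)
            yte = M_test[pair.mirna_id].to_numpy(dtype=float)
            ctr = M_train[cov_id].to_numpy(dtype=float) if cov_id else None
            cte = M_test[cov_id].to_numpy(dtype=float) if cov_id else None
            Xd_tr = _design(Xtr if ctr is None else np.column_stack([Xtr, ctr]))
            coef, rss, _ = _ols_core(Xd_tr, ytr)
            Xd_te = _design(Xte if cte is None else np.column_stack([Xte, cte]))
            resid = yte - Xd_te @ coef
            self.pairs.append(pair)
            self.full_ids.append(ids)
            self.full_cols_train.append(Xtr)
            self.full_cols_test.append(Xte)
            self.y_train.append(ytr)
            self.y_test.append(yte)
            self.cov_train.append(ctr)
            self.cov_test.append(cte)
            self.rss_full.append(max(rss, 0.0))
            self.rmse_full.append(float(np.sqrt(np.mean(resid ** 2))))
        if skipped:
            logger.info("randomized null: skipped %d pairs with too few training samples", skipped)

    def reduced_stats(self, j: int, reduced_pos: np.ndarray) -> Tuple[float, float, int]:
        """Refit the reduced model for pair j on the given column positions.

        Returns (rss_reduced, rmse_reduced, df).
        """
        Xtr = self.full_cols_train[j][:, reduced_pos]
        Xte = self.full_cols_test[j][:, reduced_pos]
        if self.cov_train[j] is not None:
            Xtr = np.column_stack([Xtr, self.cov_train[j]])
            Xte = np.column_stack([Xte, self.cov_test[j]])
        coef, rss, _ = _ols_core(_design(Xtr), self.y_train[j])
        resid = self.y_test[j] - _design(Xte) @ coef
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        df = self.full_cols_train[j].shape[1] - reduced_pos.size
        return max(rss, 0.0), rmse, df


def randomized_significance_ratio(
    pairs: Sequence[PairUniverse],
    transcript_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    split: SampleSplit,
    cfg: PipelineConfig,
    covariates: Optional[Mapping[Tuple[str, str], str]] = None,
) -> List[RatioSample]:
    """Significance ratios under the within-gene label-permutation null.

    Per iteration (seeded ``random_seed + iteration``): draw a subsample of
    pairs, shuffle each pair's binding labels, retrain only the reduced
    models, re-evaluate the RMSE gate with the retrained reduced RMSE and
    the cached full RMSE, recompute LRT p-values and BH within the
    subsample, and report the significance ratio.
    """
    if not pairs:
        raise ValueError("no pairs for randomized resampling")
    cache = _PairCache(pairs, transcript_expr, mirna_expr, split, cfg, covariates)
    n = len(cache.pairs)
    if n == 0:
        raise ValueError("all pairs were skipped for insufficient training samples")
    if cfg.subsample_size > n:
        logger.warning(
            "subsample_size %d > %d available pairs; sampling all", cfg.subsample_size, n
        )
    out: List[RatioSample] = []
    for i in range(cfg.subsample_iterations):
        rng = np.random.default_rng(cfg.random_seed + i)
        idx = _draw_indices(rng, n, cfg.subsample_size)
        lams: List[float] = []
        dfs: List[int] = []
        n_gate = 0
        for j in idx:
            n_full = cache.full_cols_train[j].shape[1]
            n_reduced = len(cache.pairs[j].reduced_transcripts)
            reduced_pos = np.sort(rng.choice(n_full, size=n_reduced, replace=False))
            rss_r, rmse_r, df = cache.reduced_stats(j, reduced_pos)
            if not (cache.rmse_full[j] < cfg.rmse_threshold and rmse_r < cfg.rmse_threshold):
                continue
            n_gate += 1
            ratio = max(rss_r, _RSS_FLOOR) / max(cache.rss_full[j], _RSS_FLOOR)
            lams.append(max(0.0, cache.n_train * math.log(ratio)))
            dfs.append(df)
        if n_gate == 0:
            out.append(RatioSample(i, 0.0, True, 0))
            continue
        pvals = stats.chi2.sf(np.array(lams), np.array(dfs))
        _, flags = benjamini_hochberg(pvals, cfg.fdr_alpha)
        out.append(RatioSample(i, int(flags.sum()) / n_gate, True, n_gate))
    return out


def compare_ratio_distributions(
    real: Sequence[RatioSample], random: Sequence[RatioSample]
) -> DistributionComparison:
    """Two-sided Mann-Whitney U between real and randomized ratio samples.

    Exact enumeration for small samples (min n < 20), normal approximation
    with tie correction otherwise; ``dist`` is the difference of means.
    """
    if not real or not random:
        raise ValueError("both ratio lists must be non-empty")
    if any(s.randomized for s in real):
        raise ValueError("'real' list contains randomized samples")
    if any(not s.randomized for s in random):
        raise ValueError("'random' list contains non-randomized samples")
    x = np.array([s.ratio for s in real])
    y = np.array([s.ratio for s in random])
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        # degenerate: every ratio identical; no evidence of a shift
        return DistributionComparison(
            float(x.mean()), float(y.mean()), 0.0, x.size * y.size / 2.0, 1.0
        )
    method = "exact" if min(x.size, y.size) < 20 else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return DistributionComparison(
        mean_ratio_real=float(x.mean()),
        mean_ratio_random=float(y.mean()),
        dist=float(x.mean() - y.mean()),
        u_statistic=float(u),
        p_value=float(p),
    )
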