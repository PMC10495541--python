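"""Nested ordinary-least-squares models per miRNA-gene pair.

For a pair (M, G) under a given setting, miRNA expression m is regressed on
the expression of the gene's transcripts:

    full:    m = alpha + sum_i beta_i t_i,nb + sum_j gamma_j t_j,b [+ delta m2] + eps
    reduced: m = alpha + sum_i beta_i t_i,nb                       [+ delta m2] + eps

with eps ~ iid N(0, sigma^2); t_i,nb are the k transcripts without sites in
the investigated region, t_j,b the l transcripts with sites, and m2 an
optional correlated-miRNA covariate.  Both models are fit on a shared
training split; the held-out split supplies the RMSE gate (both models must
score below the threshold).  The nested comparison uses the Gaussian-MLE
likelihood-ratio statistic

    Lambda = n_train * ln(RSS_reduced / RSS_full)  ~  chi^2_l  under H0,

followed by Benjamini-Hochberg adjustment across pairs, and Cohen's
f^2 = (adjR2_full - adjR2_reduced) / (1 - adjR2_full) as the effect size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .categorize import PairUniverse, Region, Setting, classify_site_region
from .config import PipelineConfig
from .io import ExpressionMatrix, TargetSiteRecord, TranscriptCatalog

logger = logging.getLogger(__name__)

#: RSS below this is treated as an exact fit (guards log of ~0 ratios)
_RSS_FLOOR = 1e-12


@dataclass
class SampleSplit:
    """One train/test partition shared by every pair of a dataset."""

    train_ids: List[str]
    test_ids: List[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def split_samples(sample_ids: Sequence[str], cfg: PipelineConfig) -> SampleSplit:
    """Random train/test split: |train| = round(train_fraction * n)."""
    n = len(sample_ids)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(cfg.random_seed)
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    ids = np.asarray(sample_ids, dtype=object)
    return SampleSplit(
        train_ids=list(ids[perm[:n_train]]),
        test_ids=list(ids[perm[n_train:]]),
        seed=cfg.random_seed,
    )


@dataclass
class OLSFit:
    """An OLS fit: coefficients (incl. intercept), training RSS and adj. R2."""

    coefficients: Dict[str, float]
    predictor_ids: List[str]
    rss: float
    n_train: int
    n_params: int
    adj_r2: float
    degenerate: bool = False

    @property
    def intercept(self) -> float:
        return self.coefficients["intercept"]


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _ols_core(Xd: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float, int]:
    """Least squares on a design matrix with intercept column prepended.

    Returns (coefficients, rss, rank); rank-deficient designs get the
    minimum-norm solution that lstsq provides.
    """
    coef, resid, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if resid.size:
        rss = float(resid[0])
    else:
        r = y - Xd @ coef
        rss = float(r @ r)
    return coef, max(rss, 0.0), int(rank)


def fit_ols(
    predictors: pd.DataFrame | np.ndarray,
    response: Sequence[float],
    predictor_ids: Optional[Sequence[str]] = None,
) -> OLSFit:
    """Ordinary least squares of ``response`` on ``predictors`` + intercept."""
    if isinstance(predictors, pd.DataFrame):
        ids = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        ids = list(predictor_ids) if predictor_ids is not None else [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    if n == 0:
        raise ValueError("zero training samples")
    n_params = X.shape[1] + 1
    coef, rss, rank = _ols_core(_design(X), y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        r2 = 1.0 if rss <= _RSS_FLOOR else 0.0
    else:
        r2 = 1.0 - rss / tss
    if n > n_params:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    else:
        adj_r2 = -math.inf
    return OLSFit(
        coefficients={"intercept": float(coef[0]), **{pid: float(c) for pid, c in zip(ids, coef[1:])}},
        predictor_ids=ids,
        rss=rss,
        n_train=n,
        n_params=n_params,
        adj_r2=adj_r2,
        degenerate=rank < n_params,
    )


def predict(fit: OLSFit, predictors: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(predictors, pd.DataFrame):
        X = predictors[fit.predictor_ids].to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    beta = np.array([fit.coefficients[pid] for pid in fit.predictor_ids])
    return fit.intercept + X @ beta


def rmse_on(fit: OLSFit, predictors: pd.DataFrame | np.ndarray, response: Sequence[float]) -> float:
    """Root mean squared error of a fit on the given (held-out) samples."""
    y = np.asarray(response, dtype=float)
    if y.size == 0:
        raise ValueError("empty sample set")
    resid = y - predict(fit, predictors)
    return float(np.sqrt(np.mean(resid ** 2)))


def likelihood_ratio_test(full: OLSFit, reduced: OLSFit) -> Tuple[float, int, float]:
    """Gaussian-MLE LRT between nested OLS fits.

    Lambda = n * ln(RSS_reduced / RSS_full), clipped at 0 when numerical
    error makes the ratio dip below 1; p is the chi^2 upper tail with
    df = difference in parameter counts.
    """
    if full.n_train != reduced.n_train:
        raise ValueError("nested fits must share training samples")
    if not set(reduced.predictor_ids) <= set(full.predictor_ids):
        raise ValueError("reduced predictors must be a subset of the full predictors")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("full model must have more parameters than the reduced model")
    n = full.n_train
    rss_f = max(full.rss, _RSS_FLOOR)
    rss_r = max(reduced.rss, _RSS_FLOOR)
    lam = max(0.0, n * math.log(rss_r / rss_f))
    p = float(stats.chi2.sf(lam, df))
    return lam, df, p


def benjamini_hochberg(pvals: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """BH step-up adjusted p-values and significance flags (adjusted < alpha)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value {bad} outside [0,1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


_F2_BINS = (("large", 0.35), ("medium", 0.15), ("small", 0.02))


def cohens_f2(adj_r2_full: float, adj_r2_reduced: float) -> Tuple[float, str]:
    """Cohen's f^2 for a hierarchical-regression R2 increment, with its bin.

    f^2 = (adjR2_full - adjR2_reduced) / (1 - adjR2_full); bins at
    0.02 / 0.15 / 0.35 for small / medium / large.  The value may be
    negative (the adjustment can invert the order) and is reported as-is.
    """
    if adj_r2_full >= 1.0:
        raise ValueError(f"adj_r2_full must be < 1, got {adj_r2_full}")
    f2 = (adj_r2_full - adj_r2_reduced) / (1.0 - adj_r2_full)
    for name, lo in _F2_BINS:
        if f2 >= lo:
            return f2, name
    return f2, "none"


@dataclass
class PairModelResult:
    """Fitted nested-model statistics for one (miRNA, gene, setting)."""

    mirna_id: str
    gene_id: str
    setting: str
    k: int
    l: int
    rmse_full: float
    rmse_reduced: float
    lrt_stat: float
    df: int
    p: float
    adj_r2_full: float
    adj_r2_reduced: float
    cohens_f2: float
    effect_bin: str
    passed_rmse_gate: bool
    covariate_mirna: Optional[str] = None
    p_adj: float = math.nan
    degenerate: bool = False


def select_covariate_mirna(
    pair: PairUniverse,
    sites: Sequence[TargetSiteRecord],
    mirna_expr: ExpressionMatrix,
    catalog: TranscriptCatalog,
    cfg: PipelineConfig,
) -> Optional[str]:
    """Most correlated other miRNA with a non-coding site on the gene.

    Candidates are miRNAs (other than the pair's) with at least one site of
    probability > bind_prob_low overlapping the non-coding region of any
    transcript of the gene.  The candidate maximising the Pearson
    correlation with the pair miRNA's expression wins (signed by default,
    |r| behind a config switch); ties go to the lexicographically smaller
    id.  Returns None when there is no candidate.
    """
    if pair.setting != Setting.TNBN:
        raise ValueError("the covariate model is defined for the TNBN setting")
    gene_tids = {tid for tid, m in catalog.transcripts.items() if m.gene_id == pair.gene_id}
    candidates = set()
    for s in sites:
        if s.mirna_id == pair.mirna_id or s.transcript_id not in gene_tids:
            continue
        if s.probability <= cfg.bind_prob_low or s.mirna_id not in mirna_expr.values.columns:
            continue
        if Region.NONCODING in classify_site_region(s, catalog[s.transcript_id]):
            candidates.add(s.mirna_id)
    if not candidates:
        return None
    m1 = mirna_expr.values[pair.mirna_id].to_numpy()
    best: Optional[Tuple[float, str]] = None
    for m2_id in sorted(candidates):
        m2 = mirna_expr.values[m2_id].to_numpy()
        if m2.std() == 0.0 or m1.std() == 0.0:
            continue
        r = float(np.corrcoef(m1, m2)[0, 1])
        score = abs(r) if cfg.covariate_abs_correlation else r
        if best is None or score > best[0]:
            best = (score, m2_id)
    return best[1] if best else None


def fit_pair(
    pair: PairUniverse,
    transcript_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    split: SampleSplit,
    cfg: PipelineConfig,
    covariate: Optional[str] = None,
) -> Optional[PairModelResult]:
    """Fit the full and reduced models for one pair and run the LRT.

    Returns None (with a logged reason) when the training set is too small
    for the full design.  ``p_adj`` is left NaN; Benjamini-Hochberg is
    applied across pairs downstream.
    """
    full_ids = sorted(pair.full_transcripts)
    reduced_ids = sorted(pair.reduced_transcripts)
    if covariate is not None:
        full_ids = full_ids + [covariate]
        reduced_ids = reduced_ids + [covariate]
    n_params_full = len(full_ids) + 1
    if len(split.train_ids) <= n_params_full:
        logger.info(
            "skipping (%s, %s): %d training samples <= %d parameters",
            pair.mirna_id, pair.gene_id, len(split.train_ids), n_params_full,
        )
        return None

    def block(ids: List[str], samples: List[str]) -> pd.DataFrame:
        cols = {tid: transcript_expr.values[tid] for tid in ids if tid != covariate}
        if covariate is not None:
            cols[covariate] = mirna_expr.values[covariate]
        return pd.DataFrame(cols).loc[samples, ids]

    y_train = mirna_expr.values.loc[split.train_ids, pair.mirna_id].to_numpy()
    y_test = mirna_expr.values.loc[split.test_ids, pair.mirna_id].to_numpy()
    fit_full = fit_ols(block(full_ids, split.train_ids), y_train)
    fit_reduced = fit_ols(block(reduced_ids, split.train_ids), y_train)
    rmse_full = rmse_on(fit_full, block(full_ids, split.test_ids), y_test)
    rmse_reduced = rmse_on(fit_reduced, block(reduced_ids, split.test_ids), y_test)
    lam, df, p = likelihood_ratio_test(fit_full, fit_reduced)
    if fit_full.adj_r2 < 1.0:
        f2, f2_bin = cohens_f2(fit_full.adj_r2, fit_reduced.adj_r2)
    else:
        f2, f2_bin = math.nan, "undefined"
    return PairModelResult(
        mirna_id=pair.mirna_id,
        gene_id=pair.gene_id,
        setting=pair.setting.value,
        k=len(pair.reduced_transcripts),
        l=len(pair.full_transcripts) - len(pair.reduced_transcripts),
        rmse_full=rmse_full,
        rmse_reduced=rmse_reduced,
        lrt_stat=lam,
        df=df,
        p=p,
        adj_r2_full=fit_full.adj_r2,
        adj_r2_reduced=fit_reduced.adj_r2,
        cohens_f2=f2,
        effect_bin=f2_bin,
        passed_rmse_gate=(rmse_full < cfg.rmse_threshold and rmse_reduced < cfg.rmse_threshold),
        covariate_mirna=covariate,
        degenerate=fit_full.degenerate or fit_reduced.degenerate,
    )
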