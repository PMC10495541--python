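"""Filtering stages that define the analyzable miRNA-gene pairs.

Four stages, applied in dependency order:

1. presence — drop genes/transcripts not expressed in >= 25% of samples;
2. miRNA selection — variance >= 0.2 (TCGA-style) or the top-k most highly
   expressed miRNAs (k = 100 for PPMI-style data);
3. alternative splicing — keep pairs with at least one high-confidence
   binding transcript and at least one transcript not binding in the
   investigated region;
4. correlation — keep pairs whose gene expression correlates strictly
   negatively (Pearson) with the miRNA's expression, computed over all
   samples, reflecting the repressive mode of miRNA action.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Set, Tuple

import numpy as np

from .categorize import PairUniverse, TranscriptCategory
from .config import PipelineConfig
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def presence_filter(matrix: ExpressionMatrix, cfg: PipelineConfig) -> Set[str]:
    """Features expressed in enough samples.

    A feature is dropped when it is absent (value at the floor) in
    ``max_absent_fraction`` or more of the samples; the boundary fraction
    itself is dropped.
    """
    if matrix.kind not in ("transcript", "gene"):
        raise ValueError("presence filter applies to transcript/gene matrices")
    absent_frac = matrix.absent_mask().mean(axis=0)
    kept = absent_frac[absent_frac < cfg.max_absent_fraction].index
    logger.info(
        "presence filter (%s): kept %d of %d features",
        matrix.kind, len(kept), matrix.values.shape[1],
    )
    return set(kept)


def variance_filter(matrix: ExpressionMatrix, cfg: PipelineConfig) -> Set[str]:
    """miRNAs with sample variance (ddof=1) >= the configured minimum."""
    if matrix.kind != "mirna":
        raise ValueError("variance filter applies to the miRNA matrix")
    if matrix.n_samples < 2:
        raise ValueError("variance filter requires at least 2 samples")
    var = matrix.values.var(axis=0, ddof=1)
    kept = var[var >= cfg.min_mirna_variance].index
    logger.info("variance filter: kept %d of %d miRNAs", len(kept), len(var))
    return set(kept)


def top_k_expression_filter(matrix: ExpressionMatrix, k: int) -> Set[str]:
    """The k most highly expressed miRNAs by mean expression.

    Ties at the k-th rank are broken by identifier order so the selection
    is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > matrix.values.shape[1]:
        raise ValueError(f"k={k} exceeds the number of miRNAs ({matrix.values.shape[1]})")
    means = matrix.values.mean(axis=0)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return set(order[:k])


def alternative_splicing_filter(
    universes: Sequence[PairUniverse],
    categories: Mapping[Tuple[str, str], TranscriptCategory] | None = None,
) -> List[PairUniverse]:
    """Keep pairs with a binding/non-binding contrast in the investigated region.

    A pair survives when it has at least one transcript binding in the
    investigated region (full minus reduced non-empty) and at least one
    transcript not binding there (reduced non-empty).  For TBN the
    investigated region is the coding region, so NONCODING_ONLY transcripts
    count as non-binding.  ``PairUniverse`` construction already encodes
    these sets; the filter re-checks them explicitly.
    """
    kept = [u for u in universes if u.reduced_transcripts and (u.full_transcripts - u.reduced_transcripts)]
    logger.info("alternative splicing filter: kept %d of %d pairs", len(kept), len(universes))
    return kept


@dataclass(frozen=True)
class CorrelationDecision:
    keep: bool
    r: float
    reason: str = ""


def correlation_filter(mirna_expr: np.ndarray, gene_expr: np.ndarray) -> CorrelationDecision:
    """Pearson correlation sign gate for one (miRNA, gene) pair.

    Computed over all samples (before the train/test split); only strictly
    negative correlation is kept.  A constant vector makes r undefined and
    removes the pair.
    """
    m = np.asarray(mirna_expr, dtype=float)
    g = np.asarray(gene_expr, dtype=float)
    if m.shape != g.shape or m.ndim != 1:
        raise ValueError("expression vectors must be 1-D and equally long")
    if m.size < 3:
        raise ValueError("correlation filter requires at least 3 samples")
    sm, sg = m.std(), g.std()
    if sm == 0.0 or sg == 0.0:
        return CorrelationDecision(keep=False, r=math.nan, reason="constant expression vector")
    r = float(np.corrcoef(m, g)[0, 1])
    return CorrelationDecision(keep=r < 0.0, r=r)
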