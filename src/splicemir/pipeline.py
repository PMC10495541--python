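"""End-to-end orchestration: categorize -> filter -> fit -> resample -> compare.

A run takes the three expression matrices, the site-prediction table and
the transcript annotation, executes one setting (ALLT, TNBN or TBN), and
produces per-pair nested-model results, real and label-randomized
significance-ratio samples, their Mann-Whitney comparison, and a stage
count report mirroring the intermediate pair counts of each filter.  All
randomness derives from the config seed; two runs with identical inputs
and config are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .categorize import (
    PairUniverse,
    Region,
    Setting,
    build_pair_universe,
    categorize_all,
    category_table,
    classify_site_region,
)
from .config import PipelineConfig
from .filters import (
    alternative_splicing_filter,
    correlation_filter,
    presence_filter,
    top_k_expression_filter,
    variance_filter,
)
from .io import (
    ExpressionMatrix,
    TargetSiteRecord,
    TranscriptCatalog,
    write_results_table,
)
from .models import (
    PairModelResult,
    SampleSplit,
    benjamini_hochberg,
    fit_pair,
    split_samples,
)
from .resampling import (
    DistributionComparison,
    RatioSample,
    compare_ratio_distributions,
    randomized_significance_ratio,
    subsample_significance_ratio,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageCount:
    stage: str
    items_in: int
    items_out: int
    unit: str


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    setting: Setting
    config: PipelineConfig
    stage_counts: List[StageCount]
    results: List[PairModelResult]
    real_ratios: List[RatioSample]
    random_ratios: List[RatioSample]
    comparison: Optional[DistributionComparison]
    skipped_pairs: List[Tuple[str, str, str]] = field(default_factory=list)
    degenerate: bool = False


def stage_count_report(report: RunReport) -> pd.DataFrame:
    """Tabulate (stage, items_in, items_out); pair counts are non-increasing."""
    return pd.DataFrame(
        [(s.stage, s.items_in, s.items_out, s.unit) for s in report.stage_counts],
        columns=["stage", "items_in", "items_out", "unit"],
    )


def _covariate_map(
    pairs: Sequence[PairUniverse],
    sites: Sequence[TargetSiteRecord],
    mirna_expr: ExpressionMatrix,
    catalog: TranscriptCatalog,
    cfg: PipelineConfig,
) -> Dict[Tuple[str, str], str]:
    """Per (miRNA, gene): the most correlated other miRNA binding non-coding.

    Same semantics as :func:`splicemir.models.select_covariate_mirna`,
    computed with precomputed candidate sets and a miRNA correlation
    matrix so it stays linear in the number of sites.
    """
    expressed = set(mirna_expr.values.columns)
    gene_candidates: Dict[str, Set[str]] = {}
    for s in sites:
        if s.probability <= cfg.bind_prob_low or s.mirna_id not in expressed:
            continue
        if s.transcript_id not in catalog:
            continue
        model = catalog[s.transcript_id]
        if Region.NONCODING in classify_site_region(s, model):
            gene_candidates.setdefault(model.gene_id, set()).add(s.mirna_id)

    M = mirna_expr.values.to_numpy(dtype=float)
    cols = list(mirna_expr.values.columns)
    idx = {m: j for j, m in enumerate(cols)}
    sd = M.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, np.nan)
    corr = (Z.T @ Z) / M.shape[0]

    out: Dict[Tuple[str, str], str] = {}
    for pair in pairs:
        cands = gene_candidates.get(pair.gene_id, set()) - {pair.mirna_id}
        best: Optional[Tuple[float, str]] = None
        for m2 in sorted(cands):
            r = corr[idx[pair.mirna_id], idx[m2]]
            if not np.isfinite(r):
                continue
            score = abs(r) if cfg.covariate_abs_correlation else float(r)
            if best is None or score > best[0]:
                best = (score, m2)
        if best is not None:
            out[(pair.mirna_id, pair.gene_id)] = best[1]
    return out


def run_pipeline(
    mirna_expr: ExpressionMatrix,
    transcript_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    sites: Sequence[TargetSiteRecord],
    catalog: TranscriptCatalog,
    setting: Setting | str,
    cfg: PipelineConfig,
    covariate_mode: bool = False,
    out_dir: Optional[str | Path] = None,
) -> RunReport:
    """Run one setting end to end.

    Raises on an empty sample intersection; a run whose filters leave zero
    pairs completes with ``degenerate=True`` and no comparison.
    """
    setting = Setting(setting)
    if covariate_mode and setting != Setting.TNBN:
        raise ValueError(
            "covariate mode models coding-region pairs under non-coding "
            "co-regulation and is only defined for the TNBN setting"
        )
    logger.info("run config: %s", json.dumps(cfg.to_dict(), default=str))
    counts: List[StageCount] = []

    # sample intersection, keeping the miRNA matrix's sample order
    shared = [s for s in mirna_expr.sample_ids
              if s in set(transcript_expr.sample_ids) & set(gene_expr.sample_ids)]
    if not shared:
        raise ValueError("no samples shared by the miRNA, transcript and gene matrices")
    counts.append(StageCount("sample_intersection", mirna_expr.n_samples, len(shared), "samples"))
    mirna_expr = mirna_expr.subset_samples(shared)
    transcript_expr = transcript_expr.subset_samples(shared)
    gene_expr = gene_expr.subset_samples(shared)

    kept_transcripts = presence_filter(transcript_expr, cfg)
    counts.append(StageCount("presence_transcripts", len(transcript_expr.feature_ids),
                             len(kept_transcripts), "transcripts"))
    kept_genes = presence_filter(gene_expr, cfg)
    counts.append(StageCount("presence_genes", len(gene_expr.feature_ids),
                             len(kept_genes), "genes"))
    if cfg.top_k_mirnas is not None:
        kept_mirnas = top_k_expression_filter(mirna_expr, cfg.top_k_mirnas)
        counts.append(StageCount("top_k_mirnas", len(mirna_expr.feature_ids),
                                 len(kept_mirnas), "mirnas"))
    else:
        kept_mirnas = variance_filter(mirna_expr, cfg)
        counts.append(StageCount("mirna_variance", len(mirna_expr.feature_ids),
                                 len(kept_mirnas), "mirnas"))
    mirna_expr = mirna_expr.subset_features(sorted(kept_mirnas))

    # restrict the annotation to transcripts that survived the presence
    # filter and are quantified; fit_pair requires complete expression
    surviving = TranscriptCatalog()
    for tid, model in catalog.transcripts.items():
        if tid in kept_transcripts and model.gene_id in kept_genes:
            surviving.add(model)
    usable_sites = [s for s in sites
                    if s.mirna_id in kept_mirnas and s.transcript_id in surviving]

    categories = categorize_all(usable_sites, surviving, cfg)
    universes = build_pair_universe(categories, surviving, setting, cfg)
    counts.append(StageCount("pair_universe", len(categories), len(universes), "pairs"))

    universes = alternative_splicing_filter(universes, categories)
    counts.append(StageCount("alternative_splicing", counts[-1].items_out,
                             len(universes), "pairs"))

    kept_pairs: List[PairUniverse] = []
    skipped: List[Tuple[str, str, str]] = []
    gene_vals = gene_expr.values
    for u in universes:
        decision = correlation_filter(
            mirna_expr.values[u.mirna_id].to_numpy(),
            gene_vals[u.gene_id].to_numpy(),
        )
        if decision.keep:
            kept_pairs.append(u)
        elif decision.reason:
            skipped.append((u.mirna_id, u.gene_id, decision.reason))
    counts.append(StageCount("negative_correlation", len(universes), len(kept_pairs), "pairs"))

    report = RunReport(setting, cfg, counts, [], [], [], None, skipped_pairs=skipped)
    if not kept_pairs:
        logger.warning("zero pairs after filtering; run is degenerate")
        report.degenerate = True
        _write_artifacts(report, categories, out_dir)
        return report

    split = split_samples(shared, cfg)
    covariates: Dict[Tuple[str, str], str] = {}
    if covariate_mode:
        covariates = _covariate_map(kept_pairs, sites, mirna_expr, surviving, cfg)

    results: List[PairModelResult] = []
    fitted_pairs: List[PairUniverse] = []
    for u in kept_pairs:
        res = fit_pair(u, transcript_expr, mirna_expr, split, cfg,
                       covariate=covariates.get((u.mirna_id, u.gene_id)))
        if res is None:
            skipped.append((u.mirna_id, u.gene_id, "insufficient training samples"))
            continue
        results.append(res)
        fitted_pairs.append(u)
    counts.append(StageCount("model_fitting", len(kept_pairs), len(results), "pairs"))

    if not results:
        logger.warning("zero fitted pairs; run is degenerate")
        report.degenerate = True
        _write_artifacts(report, categories, out_dir)
        return report

    # annotate global BH over gate-passing pairs for the results table
    gate_idx = [i for i, r in enumerate(results) if r.passed_rmse_gate]
    if gate_idx:
        adj, _ = benjamini_hochberg([results[i].p for i in gate_idx], cfg.fdr_alpha)
        for i, a in zip(gate_idx, adj):
            results[i].p_adj = float(a)
    counts.append(StageCount("rmse_gate", len(results), len(gate_idx), "pairs"))

    report.results = results
    report.real_ratios = subsample_significance_ratio(results, cfg)
    report.random_ratios = randomized_significance_ratio(
        fitted_pairs, transcript_expr, mirna_expr, split, cfg,
        covariates=covariates or None,
    )
    report.comparison = compare_ratio_distributions(report.real_ratios, report.random_ratios)
    _write_artifacts(report, categories, out_dir)
    return report


def _write_artifacts(report: RunReport, categories, out_dir: Optional[str | Path]) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = report.setting.value.lower()
    write_results_table(report.results, out / f"results_{tag}.tsv")
    category_table(categories).to_csv(out / f"categories_{tag}.tsv", sep="\t", index=False)
    stage_count_report(report).to_csv(out / f"stage_counts_{tag}.tsv", sep="\t", index=False)
    ratios = pd.DataFrame(
        [(s.iteration, s.randomized, s.n_pairs_tested, s.ratio)
         for s in (*report.real_ratios, *report.random_ratios)],
        columns=["iteration", "randomized", "n_pairs_tested", "ratio"],
    )
    ratios.to_csv(out / f"ratio_samples_{tag}.tsv", sep="\t", index=False)
    if report.skipped_pairs:
        pd.DataFrame(report.skipped_pairs, columns=["mirna", "gene", "reason"]).to_csv(
            out / f"skipped_pairs_{tag}.tsv", sep="\t", index=False)
    summary = {
        "setting": report.setting.value,
        "degenerate": report.degenerate,
        "n_results": len(report.results),
    }
    if report.comparison is not None:
        summary.update({
            "mean_ratio_real": report.comparison.mean_ratio_real,
            "mean_ratio_random": report.comparison.mean_ratio_random,
            "dist": report.comparison.dist,
            "u_statistic": report.comparison.u_statistic,
            "mannwhitney_p": report.comparison.p_value,
        })
    with open(out / f"summary_{tag}.json", "w") as fh:
        json.dump(summary, fh, indent=2)
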