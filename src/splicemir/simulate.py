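"""Synthetic multi-isoform expression data with known miRNA regulation.

The generator emulates the statistical structure the analysis assumes:

* genes with several transcript isoforms, each with a CDS flanked by UTRs;
* per (miRNA, gene) pair, a configurable fraction is "regulated": a proper
  subset of the gene's transcripts carries a high-confidence target site
  (probability above 0.8) in a configurable region, while at least one
  other isoform carries no site — the alternative-splicing escape pattern;
* intermediate-probability decoy sites (0.5-0.8) exercise the DISCARD rule;
* miRNA expression is Gaussian on the log2 scale; binding transcripts are
  negatively coupled to the driving miRNA's expression with a tunable
  effect size plus Gaussian noise, escape transcripts are not; gene
  expression is the log2 of summed linear-scale transcript abundances.

A confounder mode plants a partner miRNA that binds the *non-coding*
region, is correlated with the miRNA of interest through a shared latent
factor, and is the true expression driver — the scenario the covariate
model is meant to deflate.

Defaults are the generator's study conditions for the scaled-down
end-to-end checks: 300 genes x 20 miRNAs, 200 samples, 30% regulated
pairs, effect 0.8, noise sd 0.3 (see docs/methods.md for the rationale
behind the abundance-scale choices).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    TargetSiteRecord,
    TranscriptCatalog,
    TranscriptModel,
)

SITE_LEN = 7  # nominal seed-match footprint, nt


@dataclass
class SimulationConfig:
    n_genes: int = 300
    transcripts_per_gene: Tuple[int, int] = (2, 4)  # inclusive range
    n_mirnas: int = 20
    n_samples: int = 200
    frac_regulated_pairs: float = 0.3
    effect_size: float = 0.8
    noise_sd: float = 0.3
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    mirna_mean: float = 6.0
    mirna_sd: float = 0.5
    frac_coding_sites: float = 1.0
    frac_noncoding_sites: float = 0.0
    frac_both: float = 0.0
    prob_high_range: Tuple[float, float] = (0.85, 0.99)
    prob_mid_range: Tuple[float, float] = (0.55, 0.75)
    decoy_rate: float = 0.1
    #: shared-latent-factor loading inducing miRNA-miRNA correlation
    mirna_latent_loading: float = 0.0
    #: plant a correlated partner miRNA (non-coding binder) as the true driver
    confounder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid transcripts_per_gene range ({lo},{hi})")
        if self.frac_regulated_pairs > 0 and hi < 2:
            raise ValueError("regulated pairs require genes with >= 2 transcripts")
        for name in ("frac_regulated_pairs", "frac_coding_sites", "frac_noncoding_sites",
                     "frac_both", "decoy_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.frac_coding_sites + self.frac_noncoding_sites + self.frac_both > 1.0 + 1e-9:
            raise ValueError("region fractions must sum to <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.8 < self.prob_high_range[0] <= self.prob_high_range[1] <= 1.0):
            raise ValueError("prob_high_range must lie in (0.8, 1]")
        if not (0.5 < self.prob_mid_range[0] <= self.prob_mid_range[1] <= 0.8):
            raise ValueError("prob_mid_range must lie in (0.5, 0.8]")
        if self.confounder and self.n_mirnas < 2:
            raise ValueError("confounder mode requires >= 2 miRNAs")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    regulated_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    binding_transcripts: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)
    effect_sizes: Dict[Tuple[str, str], float] = field(default_factory=dict)
    #: region the planted sites occupy per pair: CODING / NONCODING / BOTH
    regions: Dict[Tuple[str, str], str] = field(default_factory=dict)
    #: miRNA whose expression actually drives the binding transcripts
    drivers: Dict[Tuple[str, str], str] = field(default_factory=dict)


@dataclass
class DatasetBundle:
    """A complete simulated dataset: topology, sites, truth and expression."""

    catalog: TranscriptCatalog
    sites: List[TargetSiteRecord]
    truth: GroundTruth
    mirna_expr: ExpressionMatrix
    transcript_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    sim: SimulationConfig


def _mirna_ids(sim: SimulationConfig) -> List[str]:
    return [f"mir{i:03d}" for i in range(sim.n_mirnas)]


def _partner(i: int, n: int) -> int:
    return (i + n // 2) % n


def _place_site(rng: np.random.Generator, model: TranscriptModel, region: str) -> Tuple[int, int]:
    """A SITE_LEN interval inside the requested region of the transcript."""
    if region == "CODING":
        lo, hi = model.cds_start, model.cds_end - SITE_LEN
    elif region == "NONCODING":
        # use the 3'UTR; generated transcripts always have one
        lo, hi = model.cds_end, model.length - SITE_LEN
    elif region == "BOTH":
        s = model.cds_end - SITE_LEN // 2  # straddle the stop boundary
        return s, s + SITE_LEN
    else:
        raise ValueError(f"unknown region {region!r}")
    if hi < lo:
        raise ValueError(f"transcript {model.transcript_id} too short for a {region} site")
    start = int(rng.integers(lo, hi + 1))
    return start, start + SITE_LEN


def generate_topology(
    sim: SimulationConfig,
) -> Tuple[TranscriptCatalog, List[TargetSiteRecord], GroundTruth]:
    """Genes, transcripts, target sites and ground truth (no expression yet).

    Every regulated pair is guaranteed to survive categorization and the
    alternative-splicing filter by construction: >= 1 transcript with a
    high-probability site in the chosen region and >= 1 transcript with no
    site at all for that miRNA.  Decoy (0.5-0.8) sites go only onto binding
    transcripts of regulated pairs or onto transcripts of unregulated
    pairs, never onto a regulated pair's escape transcripts.
    """
    rng = np.random.default_rng(sim.seed)
    catalog = TranscriptCatalog()
    mirnas = _mirna_ids(sim)
    truth = GroundTruth()
    sites: List[TargetSiteRecord] = []
    lo_t, hi_t = sim.transcripts_per_gene
    region_probs = [sim.frac_coding_sites, sim.frac_noncoding_sites, sim.frac_both]
    region_names = ["CODING", "NONCODING", "BOTH"]

    for g in range(sim.n_genes):
        gene_id = f"g{g:04d}"
        n_t = int(rng.integers(lo_t, hi_t + 1))
        tids = []
        for t in range(n_t):
            length = int(rng.integers(900, 3001))
            cds_start = int(rng.integers(60, max(61, length // 4)))
            cds_end = int(rng.integers(int(length * 0.55), length - 60))
            tid = f"{gene_id}.t{t}"
            catalog.add(TranscriptModel(tid, gene_id, length, cds_start, cds_end))
            tids.append(tid)
        for mi, mirna in enumerate(mirnas):
            if n_t >= 2 and rng.random() < sim.frac_regulated_pairs:
                u = rng.random()
                total = sum(region_probs)
                region = "CODING"
                if total > 0:
                    acc = 0.0
                    for name, p in zip(region_names, region_probs):
                        acc += p / total
                        if u <= acc:
                            region = name
                            break
                n_binding = int(rng.integers(1, n_t))  # leave >= 1 escape transcript
                binding = [str(t) for t in rng.choice(tids, size=n_binding, replace=False)]
                for tid in binding:
                    start, end = _place_site(rng, catalog[tid], region)
                    prob = float(rng.uniform(*sim.prob_high_range))
                    sites.append(TargetSiteRecord(mirna, tid, start, end, prob))
                    if rng.random() < sim.decoy_rate:
                        ds, de = _place_site(rng, catalog[tid], region)
                        sites.append(TargetSiteRecord(
                            mirna, tid, ds, de, float(rng.uniform(*sim.prob_mid_range))))
                if region == "BOTH":
                    # TBN contrast: escape transcripts bind only in the
                    # non-coding region (uncoupled), binding ones straddle
                    for tid in tids:
                        if tid in binding:
                            continue
                        ns, ne = _place_site(rng, catalog[tid], "NONCODING")
                        sites.append(TargetSiteRecord(
                            mirna, tid, ns, ne, float(rng.uniform(*sim.prob_high_range))))
                key = (mirna, gene_id)
                truth.regulated_pairs.add(key)
                truth.binding_transcripts[key] = set(binding)
                truth.effect_sizes[key] = sim.effect_size
                truth.regions[key] = region
                if sim.confounder:
                    driver = mirnas[_partner(mi, sim.n_mirnas)]
                    truth.drivers[key] = driver
                    # the partner binds the non-coding region of the same
                    # transcripts, making it a covariate candidate
                    for tid in binding:
                        cs, ce = _place_site(rng, catalog[tid], "NONCODING")
                        sites.append(TargetSiteRecord(driver, tid, cs, ce, 0.9))
                else:
                    truth.drivers[key] = mirna
            elif rng.random() < sim.decoy_rate:
                tid = str(rng.choice(tids))
                ds, de = _place_site(rng, catalog[tid], "CODING")
                sites.append(TargetSiteRecord(
                    mirna, tid, ds, de, float(rng.uniform(*sim.prob_mid_range))))
    return catalog, sites, truth


def generate_expression(
    catalog: TranscriptCatalog,
    truth: GroundTruth,
    sim: SimulationConfig,
) -> Tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Coupled miRNA / transcript / gene expression for a topology.

    miRNA expression is N(mirna_mean, mirna_sd^2) per sample, optionally
    correlated in partner blocks through a shared latent factor.  A binding
    transcript of a regulated pair responds to its driver miRNA:
    t = baseline - effect * (m_driver - mirna_mean) + noise; escape
    transcripts are baseline + noise.  Gene expression is the log2 of the
    gene's summed linear-scale transcript abundances.
    """
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 1]))
    sample_ids = [f"s{j:04d}" for j in range(sim.n_samples)]
    mirnas = _mirna_ids(sim)
    n, q = sim.n_samples, sim.n_mirnas

    lam = sim.mirna_latent_loading
    eps = rng.standard_normal((n, q))
    if lam > 0.0 and q >= 2:
        half = q // 2
        z = rng.standard_normal((n, half))
        shared = np.column_stack([z[:, i % half] for i in range(q)])
        std = lam * shared + np.sqrt(1.0 - lam ** 2) * eps
    else:
        std = eps
    M = sim.mirna_mean + sim.mirna_sd * std
    mirna_df = pd.DataFrame(M, index=sample_ids, columns=mirnas)

    tids = sorted(catalog.transcripts)
    baselines = {tid: float(rng.normal(sim.baseline_mean, sim.baseline_sd)) for tid in tids}
    T = np.empty((n, len(tids)))
    for j, tid in enumerate(tids):
        T[:, j] = baselines[tid] + sim.noise_sd * rng.standard_normal(n)
    col = {tid: j for j, tid in enumerate(tids)}
    for key, binding in truth.binding_transcripts.items():
        effect = truth.effect_sizes[key]
        if effect == 0.0:
            continue
        driver = truth.drivers[key]
        dm = mirna_df[driver].to_numpy() - sim.mirna_mean
        for tid in binding:
            T[:, col[tid]] -= effect * dm
    transcript_df = pd.DataFrame(T, index=sample_ids, columns=tids)

    genes = catalog.genes()
    gene_ids = sorted(genes)
    G = np.empty((n, len(gene_ids)))
    for j, gid in enumerate(gene_ids):
        G[:, j] = np.log2(np.exp2(transcript_df[genes[gid]]).sum(axis=1))
    gene_df = pd.DataFrame(G, index=sample_ids, columns=gene_ids)

    return (
        ExpressionMatrix("mirna", mirna_df),
        ExpressionMatrix("transcript", transcript_df),
        ExpressionMatrix("gene", gene_df),
    )


def make_dataset(sim: SimulationConfig) -> DatasetBundle:
    """Topology + expression in one call."""
    catalog, sites, truth = generate_topology(sim)
    mirna_expr, transcript_expr, gene_expr = generate_expression(catalog, truth, sim)
    return DatasetBundle(catalog, sites, truth, mirna_expr, transcript_expr, gene_expr, sim)


def make_null_dataset(sim: SimulationConfig) -> DatasetBundle:
    """Same topology (sites included) but zero coupling everywhere.

    Pairs still pass the alternative-splicing filter by construction yet
    carry no signal — the type-I-error condition.
    """
    null_sim = dataclasses.replace(sim, effect_size=0.0)
    return make_dataset(null_sim)


def write_dataset(bundle: DatasetBundle, out_dir: str | Path) -> Dict[str, Path]:
    """Write a bundle as plain TSVs (expression as features x samples)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name, em in (("mirna", bundle.mirna_expr), ("transcript", bundle.transcript_expr),
                     ("gene", bundle.gene_expr)):
        p = out / f"expression_{name}.tsv"
        em.values.T.to_csv(p, sep="\t", index_label="feature")
        paths[f"expression_{name}"] = p
    p = out / "sites.tsv"
    pd.DataFrame(
        [(s.mirna_id, s.transcript_id, s.start, s.end, s.probability) for s in bundle.sites],
        columns=["mirna", "transcript", "start", "end", "probability"],
    ).to_csv(p, sep="\t", index=False)
    paths["sites"] = p
    p = out / "annotation.tsv"
    pd.DataFrame(
        [(m.transcript_id, m.gene_id, m.length, m.cds_start, m.cds_end)
         for m in bundle.catalog.transcripts.values()],
        columns=["transcript", "gene", "length", "cds_start", "cds_end"],
    ).to_csv(p, sep="\t", index=False, header=False)
    paths["annotation"] = p
    p = out / "ground_truth.tsv"
    pd.DataFrame(
        [(m, g, truth_region, bundle.truth.effect_sizes[(m, g)],
          bundle.truth.drivers[(m, g)], ";".join(sorted(bundle.truth.binding_transcripts[(m, g)])))
         for (m, g), truth_region in sorted(bundle.truth.regions.items())],
        columns=["mirna", "gene", "region", "effect_size", "driver", "binding_transcripts"],
    ).to_csv(p, sep="\t", index=False)
    paths["ground_truth"] = p
    return paths
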