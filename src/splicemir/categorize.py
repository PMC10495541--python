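"""Binding-site region mapping and transcript categorization.

Each predicted site is assigned to the coding region (CDS), the non-coding
region (5'UTR or 3'UTR, treated jointly), or both when it straddles a
boundary.  Per (miRNA, transcript) the sites then yield one of five
categories:

* ``NON_BINDING`` — no site with probability above the low threshold (0.5);
* ``DISCARD`` — only intermediate sites (0.5 < p <= 0.8), removed as noise;
* ``CODING_ONLY`` / ``NONCODING_ONLY`` / ``BOTH`` — by the union of regions
  hit by high-confidence sites (p > 0.8).

A transcript carrying a high-confidence site and additional intermediate
sites is categorized by its high-confidence sites alone.

From the categories, each (miRNA, gene) pair gets a full and a reduced
transcript set under one of three settings:

* ``ALLT``  — full: all four categories; reduced: non-binding.
* ``TNBN``  — full: non-binding + coding-only; reduced: non-binding.
* ``TBN``   — full: noncoding-only + both; reduced: noncoding-only.

Pairs where the reduced set is empty or equals the full set carry no
nested-model contrast and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .config import PipelineConfig
from .io import TargetSiteRecord, TranscriptCatalog, TranscriptModel


class Region(str, Enum):
    CODING = "CODING"
    NONCODING = "NONCODING"


class TranscriptCategory(str, Enum):
    NON_BINDING = "NON_BINDING"
    CODING_ONLY = "CODING_ONLY"
    NONCODING_ONLY = "NONCODING_ONLY"
    BOTH = "BOTH"
    DISCARD = "DISCARD"


class Setting(str, Enum):
    ALLT = "ALLT"
    TNBN = "TNBN"
    TBN = "TBN"


#: categories admitted to the full / reduced transcript sets per setting
SETTING_SETS: Dict[Setting, Tuple[FrozenSet[TranscriptCategory], FrozenSet[TranscriptCategory]]] = {
    Setting.ALLT: (
        frozenset({TranscriptCategory.NON_BINDING, TranscriptCategory.CODING_ONLY,
                   TranscriptCategory.NONCODING_ONLY, TranscriptCategory.BOTH}),
        frozenset({TranscriptCategory.NON_BINDING}),
    ),
    Setting.TNBN: (
        frozenset({TranscriptCategory.NON_BINDING, TranscriptCategory.CODING_ONLY}),
        frozenset({TranscriptCategory.NON_BINDING}),
    ),
    Setting.TBN: (
        frozenset({TranscriptCategory.NONCODING_ONLY, TranscriptCategory.BOTH}),
        frozenset({TranscriptCategory.NONCODING_ONLY}),
    ),
}


@dataclass(frozen=True)
class PairUniverse:
    """Full and reduced transcript sets for one (miRNA, gene, setting)."""

    mirna_id: str
    gene_id: str
    setting: Setting
    full_transcripts: FrozenSet[str]
    reduced_transcripts: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.full_transcripts:
            raise ValueError(f"({self.mirna_id},{self.gene_id}): empty full set")
        if not self.reduced_transcripts < self.full_transcripts:
            raise ValueError(
                f"({self.mirna_id},{self.gene_id}): reduced set must be a strict "
                "subset of the full set"
            )

    @property
    def binding_transcripts(self) -> FrozenSet[str]:
        return self.full_transcripts - self.reduced_transcripts


def classify_site_region(site: TargetSiteRecord, transcript: TranscriptModel) -> Set[Region]:
    """Regions a site overlaps; a straddling site belongs to both."""
    if site.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"site transcript {site.transcript_id!r} != model {transcript.transcript_id!r}"
        )
    if site.end > transcript.length:
        raise ValueError(
            f"site [{site.start},{site.end}) extends beyond transcript "
            f"{transcript.transcript_id!r} of length {transcript.length}"
        )
    regions: Set[Region] = set()
    if site.start < transcript.cds_end and site.end > transcript.cds_start:
        regions.add(Region.CODING)
    if site.start < transcript.cds_start or site.end > transcript.cds_end:
        regions.add(Region.NONCODING)
    return regions


def categorize_transcript(
    sites: Sequence[TargetSiteRecord],
    transcript: TranscriptModel,
    cfg: PipelineConfig,
) -> TranscriptCategory:
    """Four-way classification of one (miRNA, transcript) from its sites."""
    high = [s for s in sites if s.probability > cfg.bind_prob_high]
    any_binding = any(s.probability > cfg.bind_prob_low for s in sites)
    if not any_binding:
        return TranscriptCategory.NON_BINDING
    if not high:
        return TranscriptCategory.DISCARD
    regions: Set[Region] = set()
    for s in high:
        regions |= classify_site_region(s, transcript)
    if regions == {Region.CODING}:
        return TranscriptCategory.CODING_ONLY
    if regions == {Region.NONCODING}:
        return TranscriptCategory.NONCODING_ONLY
    return TranscriptCategory.BOTH


def categorize_all(
    sites: Iterable[TargetSiteRecord],
    catalog: TranscriptCatalog,
    cfg: PipelineConfig,
) -> Dict[Tuple[str, str], TranscriptCategory]:
    """Category per (miRNA, transcript) over every pair with >= 1 site.

    Pairs absent from the result are NON_BINDING by construction (no site
    at all); they are materialised lazily in :func:`build_pair_universe`.
    """
    grouped: Dict[Tuple[str, str], List[TargetSiteRecord]] = {}
    for s in sites:
        if s.transcript_id not in catalog:
            raise KeyError(f"site references unknown transcript {s.transcript_id!r}")
        grouped.setdefault((s.mirna_id, s.transcript_id), []).append(s)
    return {
        (mirna, tid): categorize_transcript(recs, catalog[tid], cfg)
        for (mirna, tid), recs in grouped.items()
    }


def build_pair_universe(
    categories: Mapping[Tuple[str, str], TranscriptCategory],
    catalog: TranscriptCatalog,
    setting: Setting | str,
    cfg: PipelineConfig,
) -> List[PairUniverse]:
    """Assemble full/reduced transcript sets per (miRNA, gene) for a setting.

    Transcripts of a gene with no recorded category for a miRNA count as
    NON_BINDING.  DISCARD transcripts appear in no set.  Only (miRNA, gene)
    pairs with at least one explicitly categorized transcript are
    considered; pairs whose reduced set is empty or equal to the full set
    are omitted.
    """
    setting = Setting(setting)
    full_cats, reduced_cats = SETTING_SETS[setting]
    genes = catalog.genes()

    gene_mirnas: Dict[str, Set[str]] = {}
    for (mirna, tid) in categories:
        gene_mirnas.setdefault(catalog[tid].gene_id, set()).add(mirna)

    out: List[PairUniverse] = []
    for gene_id in sorted(gene_mirnas):
        tids = genes[gene_id]
        for mirna in sorted(gene_mirnas[gene_id]):
            full: Set[str] = set()
            reduced: Set[str] = set()
            for tid in tids:
                cat = categories.get((mirna, tid), TranscriptCategory.NON_BINDING)
                if cat in full_cats:
                    full.add(tid)
                if cat in reduced_cats:
                    reduced.add(tid)
            if not reduced or full == reduced:
                continue
            out.append(
                PairUniverse(
                    mirna_id=mirna,
                    gene_id=gene_id,
                    setting=setting,
                    full_transcripts=frozenset(full),
                    reduced_transcripts=frozenset(reduced),
                )
            )
    return out


def category_table(categories: Mapping[Tuple[str, str], TranscriptCategory]) -> pd.DataFrame:
    """Audit table (miRNA, transcript, category), sorted for determinism."""
    rows = [
        {"mirna": mirna, "transcript": tid, "category": cat.value}
        for (mirna, tid), cat in sorted(categories.items())
    ]
    return pd.DataFrame(rows, columns=["mirna", "transcript", "category"])
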