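import itertools

import numpy as np
import pytest

from splicemir.categorize import (
    PairUniverse,
    Region,
    Setting,
    TranscriptCategory,
    build_pair_universe,
    categorize_transcript,
    classify_site_region,
)
from splicemir.config import PipelineConfig
from splicemir.io import TargetSiteRecord, TranscriptCatalog, TranscriptModel


def _site(start, end, prob=0.9, tid="t1", mirna="m1"):
    return TargetSiteRecord(mirna, tid, start, end, prob)


class TestClassifySiteRegion:
    def test_site_inside_cds_is_coding(self, transcript_1kb):
        assert classify_site_region(_site(150, 157), transcript_1kb) == {Region.CODING}

    def test_site_straddling_start_codon_is_both(self, transcript_1kb):
        assert classify_site_region(_site(95, 105), transcript_1kb) == {
            Region.CODING, Region.NONCODING,
        }

    def test_half_open_boundary_at_cds_end(self, transcript_1kb):
        # [700,707) touches the first 3'UTR base, not the CDS
        assert classify_site_region(_site(700, 707), transcript_1kb) == {Region.NONCODING}

    def test_site_beyond_transcript_rejected(self, transcript_1kb):
        with pytest.raises(ValueError, match="beyond"):
            classify_site_region(_site(995, 1005), transcript_1kb)

    def test_agrees_with_per_nucleotide_oracle(self):
        """Interval overlap must match brute-force nucleotide membership."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            length = int(rng.integers(30, 400))
            cds_start = int(rng.integers(0, length - 2))
            cds_end = int(rng.integers(cds_start + 1, length + 1))
            model = TranscriptModel("t1", "g1", length, cds_start, cds_end)
            start = int(rng.integers(0, length - 1))
            end = int(rng.integers(start + 1, length + 1))
            expected = set()
            for pos in range(start, end):
                if cds_start <= pos < cds_end:
                    expected.add(Region.CODING)
                else:
                    expected.add(Region.NONCODING)
            assert classify_site_region(_site(start, end), model) == expected


class TestCategorizeTranscript:
    def test_no_sites_is_non_binding(self, transcript_1kb, cfg):
        assert categorize_transcript([], transcript_1kb, cfg) is TranscriptCategory.NON_BINDING

    def test_only_intermediate_site_is_discarded(self, transcript_1kb, cfg):
        sites = [_site(150, 157, prob=0.65)]
        assert categorize_transcript(sites, transcript_1kb, cfg) is TranscriptCategory.DISCARD

    def test_high_site_overrides_intermediate(self, transcript_1kb, cfg):
        # the 0.6 site in the 3'UTR neither discards nor adds NONCODING
        sites = [_site(150, 157, prob=0.9), _site(800, 807, prob=0.6)]
        assert categorize_transcript(sites, transcript_1kb, cfg) is TranscriptCategory.CODING_ONLY

    def test_two_high_sites_in_different_regions_are_both(self, transcript_1kb, cfg):
        sites = [_site(150, 157, prob=0.9), _site(800, 807, prob=0.85)]
        assert categorize_transcript(sites, transcript_1kb, cfg) is TranscriptCategory.BOTH

    def test_exhaustive_truth_table(self, transcript_1kb, cfg):
        """All (probability class x region) site combinations up to 2 sites.

        An independent enumerator rederives the category from first
        principles: threshold the probabilities, then union nucleotide-level
        region memberships of the high-confidence sites.
        """
        prob_by_class = {"low": 0.4, "mid": 0.65, "high": 0.9}
        span_by_region = {
            "coding": (150, 157),
            "noncoding": (800, 807),
            "straddle": (95, 105),
        }
        site_types = list(itertools.product(prob_by_class, span_by_region))
        combos = [()] + [(t,) for t in site_types] + list(
            itertools.combinations_with_replacement(site_types, 2)
        )
        for combo in combos:
            sites = [
                _site(*span_by_region[reg], prob=prob_by_class[pc]) for pc, reg in combo
            ]
            # independent oracle
            if not any(prob_by_class[pc] > 0.5 for pc, _ in combo):
                expected = TranscriptCategory.NON_BINDING
            elif not any(prob_by_class[pc] > 0.8 for pc, _ in combo):
                expected = TranscriptCategory.DISCARD
            else:
                hit_cds = hit_utr = False
                for pc, reg in combo:
                    if prob_by_class[pc] <= 0.8:
                        continue
                    s, e = span_by_region[reg]
                    for pos in range(s, e):
                        if 100 <= pos < 700:
                            hit_cds = True
                        else:
                            hit_utr = True
                if hit_cds and hit_utr:
                    expected = TranscriptCategory.BOTH
                elif hit_cds:
                    expected = TranscriptCategory.CODING_ONLY
                else:
                    expected = TranscriptCategory.NONCODING_ONLY
            assert categorize_transcript(sites, transcript_1kb, cfg) is expected, combo


def _catalog(n_transcripts, gene="g1"):
    cat = TranscriptCatalog()
    for i in range(n_transcripts):
        cat.add(TranscriptModel(f"t{i}", gene, 1000, 100, 700))
    return cat


class TestBuildPairUniverse:
    def test_tnbn_full_and_reduced_sets(self, cfg):
        cat = _catalog(2)
        cats = {("m1", "t0"): TranscriptCategory.NON_BINDING,
                ("m1", "t1"): TranscriptCategory.CODING_ONLY}
        (u,) = build_pair_universe(cats, cat, Setting.TNBN, cfg)
        assert u.full_transcripts == {"t0", "t1"}
        assert u.reduced_transcripts == {"t0"}

    def test_tbn_full_and_reduced_sets(self, cfg):
        cat = _catalog(2)
        cats = {("m1", "t0"): TranscriptCategory.NONCODING_ONLY,
                ("m1", "t1"): TranscriptCategory.BOTH}
        (u,) = build_pair_universe(cats, cat, "TBN", cfg)
        assert u.full_transcripts == {"t0", "t1"}
        assert u.reduced_transcripts == {"t0"}

    def test_all_non_binding_pair_omitted(self, cfg):
        cat = _catalog(2)
        cats = {("m1", "t0"): TranscriptCategory.NON_BINDING,
                ("m1", "t1"): TranscriptCategory.NON_BINDING}
        for setting in Setting:
            assert build_pair_universe(cats, cat, setting, cfg) == []

    def test_discard_appears_in_no_set(self, cfg):
        cat = _catalog(3)
        cats = {("m1", "t0"): TranscriptCategory.NON_BINDING,
                ("m1", "t1"): TranscriptCategory.CODING_ONLY,
                ("m1", "t2"): TranscriptCategory.DISCARD}
        (u,) = build_pair_universe(cats, cat, Setting.ALLT, cfg)
        assert "t2" not in u.full_transcripts

    def test_uncategorized_transcripts_count_as_non_binding(self, cfg):
        cat = _catalog(3)
        cats = {("m1", "t1"): TranscriptCategory.CODING_ONLY}
        (u,) = build_pair_universe(cats, cat, Setting.TNBN, cfg)
        assert u.reduced_transcripts == {"t0", "t2"}

    def test_reduced_strictly_inside_full_enforced(self):
        with pytest.raises(ValueError, match="strict"):
            PairUniverse("m1", "g1", Setting.ALLT,
                         frozenset({"a"}), frozenset({"a"}))
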