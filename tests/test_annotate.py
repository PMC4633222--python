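"""Island length/context classes, gene regions, repeats, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylarray.annotate import (
    GENOMIC_REGIONS,
    annotate_probes,
    classify_genomic_region,
    classify_island_context,
    classify_island_length,
    classify_repeat,
    enrichment_log2,
)
from methylarray.genome import (
    AnnotationSet,
    CpGIsland,
    GeneModel,
    GenomicInterval,
    RepeatElement,
)


class TestIslandLength:
    def test_nearest_rank_percentiles(self):
        lengths = list(range(100, 1100, 100))
        labels = classify_island_length(lengths)
        by_len = dict(zip(lengths, labels))
        assert {k for k, v in by_len.items() if v == "short"} == {100, 200}
        assert {k for k, v in by_len.items() if v == "long"} == {800, 900, 1000}
        assert by_len[500] == "intermediate"

    def test_all_equal_lengths_are_intermediate(self):
        assert set(classify_island_length([300] * 7)) == {"intermediate"}

    def test_single_island_is_intermediate(self):
        assert classify_island_length([500]) == ["intermediate"]


class TestIslandContext:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (0, "island"),
            (1500, "shore"),
            (2000, "shore"),
            (2500, "shelf"),
            (4000, "shelf"),
            (5000, "open_sea"),
            (1, "shore"),  # the 0-1 kb gap merges into shore
            (None, "undefined"),
        ],
    )
    def test_distance_bins(self, distance, expected):
        assert classify_island_context(distance) == expected


def _plus_gene(gene_id, chrom, tss, exon_spans, strand="+"):
    exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in exon_spans)
    return GeneModel(gene_id, strand, tss, exons)


class TestGenomicRegion:
    @pytest.fixture
    def genes(self):
        # + strand gene at 100_000 with two exons, - strand gene at 300_000
        plus = _plus_gene("gplus", "c", 100_000,
                          [(100_000, 100_500), (101_000, 102_000)])
        minus = _plus_gene("gminus", "c", 301_999,
                           [(300_000, 300_500), (301_000, 302_000)], strand="-")
        return AnnotationSet(genes=[plus, minus])

    @pytest.mark.parametrize(
        "midpoint,expected",
        [
            (99_500, "proximal_promoter"),  # 500 upstream of + TSS
            (97_000, "promoter"),
            (80_000, "distal_promoter"),
            (40_000, "no_nearby_gene"),
            (100_200, "exon"),
            (100_700, "intron"),
        ],
    )
    def test_plus_strand_tiers(self, genes, midpoint, expected):
        probe = GenomicInterval("c", midpoint - 10, midpoint + 10)
        label, gene_id = classify_genomic_region(probe, genes)
        assert label == expected

    def test_minus_strand_upstream_is_rightward(self, genes):
        probe = GenomicInterval("c", 302_490, 302_510)  # 501 right of - TSS
        label, gene_id = classify_genomic_region(probe, genes)
        assert (label, gene_id) == ("proximal_promoter", "gminus")

    def test_gene_body_precedence_over_other_promoter(self):
        # exon of g1 sits inside the proximal-promoter window of g2
        g1 = _plus_gene("g1", "c", 1_000, [(1_000, 2_000)])
        g2 = _plus_gene("g2", "c", 2_500, [(2_500, 3_500)])
        ann = AnnotationSet(genes=[g1, g2])
        label, gene_id = classify_genomic_region(GenomicInterval("c", 1_890, 1_910), ann)
        assert (label, gene_id) == ("exon", "g1")

    def test_every_probe_gets_exactly_one_region(self, toy_probes, toy_annotations):
        intervals = {p.probe_id: p.fragment.interval for p in toy_probes}
        ctx = annotate_probes(intervals, toy_annotations)
        assert ctx["genomic_region"].isin(GENOMIC_REGIONS).all()


class TestRepeats:
    def test_multilabel_overlap(self):
        ann = AnnotationSet(repeats=[
            RepeatElement(GenomicInterval("c", 100, 300), "SINE"),
            RepeatElement(GenomicInterval("c", 250, 400), "simple"),
            RepeatElement(GenomicInterval("c", 5_000, 5_100), "LINE"),
        ])
        assert classify_repeat(GenomicInterval("c", 120, 160), ann) == {"SINE"}
        assert classify_repeat(GenomicInterval("c", 260, 290), ann) == {"SINE", "simple"}
        assert classify_repeat(GenomicInterval("c", 1_000, 1_100), ann) == set()


class TestContextConsistency:
    def test_in_island_iff_island_context(self, toy_probes, toy_annotations):
        intervals = {p.probe_id: p.fragment.interval for p in toy_probes}
        ctx = annotate_probes(intervals, toy_annotations)
        assert (ctx["in_island"] == (ctx["island_context"] == "island")).all()

    def test_island_bins_exhaustive_over_defined_distances(self, toy_probes,
                                                           toy_annotations):
        intervals = {p.probe_id: p.fragment.interval for p in toy_probes}
        ctx = annotate_probes(intervals, toy_annotations)
        defined = ctx[ctx["island_distance"] >= 0]
        assert defined["island_context"].isin(
            ["island", "shore", "shelf", "open_sea"]
        ).all()


class TestEnrichment:
    def _series(self, n_hyper_in, n_hypo_in, n_hyper_out, n_hypo_out):
        directions = (
            ["hyper"] * n_hyper_in + ["hypo"] * n_hypo_in
            + ["hyper"] * n_hyper_out + ["hypo"] * n_hypo_out
        )
        in_class = [True] * (n_hyper_in + n_hypo_in) + [False] * (
            n_hyper_out + n_hypo_out
        )
        idx = range(len(directions))
        return pd.Series(directions, index=idx), pd.Series(in_class, index=idx)

    def test_balanced_counts_give_zero(self):
        d, c = self._series(10, 10, 40, 40)
        assert enrichment_log2(d, c, "x").log2_enrichment == pytest.approx(0.0)

    def test_plug_in_arithmetic(self):
        d, c = self._series(8, 2, 42, 48)  # class 8:2, overall 50:50
        res = enrichment_log2(d, c, "x")
        assert res.log2_enrichment == pytest.approx(np.log2(8.5 / 2.5), abs=1e-12)
        assert res.ci_low <= res.log2_enrichment <= res.ci_high

    def test_empty_class_flagged_low_support(self):
        d, c = self._series(0, 0, 30, 30)
        res = enrichment_log2(d, c, "x")
        assert res.low_support
        assert res.log2_enrichment == pytest.approx(0.0)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(1, 50),
           st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_direction_swap(self, hi, yi, ho, yo):
        d, c = self._series(hi, yi, ho, yo)
        swapped = d.map({"hyper": "hypo", "hypo": "hyper"})
        a = enrichment_log2(d, c, "x", n_boot=10).log2_enrichment
        b = enrichment_log2(swapped, c, "x", n_boot=10).log2_enrichment
        assert a == pytest.approx(-b, abs=1e-12)

    def test_planted_exon_bias_recovered(self):
        # exon calls are a small share of all calls, so the overall odds stay
        # near 1:1 and the class estimate recovers the planted 3:1 bias
        rng = np.random.default_rng(9)
        n_exon, n_other = 2_000, 80_000
        directions = (
            list(rng.choice(["hyper", "hypo"], n_exon, p=[0.75, 0.25]))
            + list(rng.choice(["hyper", "hypo"], n_other, p=[0.5, 0.5]))
        )
        in_exon = [True] * n_exon + [False] * n_other
        idx = range(n_exon + n_other)
        res = enrichment_log2(
            pd.Series(directions, idx), pd.Series(in_exon, idx), "exon", n_boot=50
        )
        assert res.log2_enrichment == pytest.approx(np.log2(3), abs=0.2)


class TestPublishedLabels:
    @pytest.mark.parametrize("which", ["ZY", "4C", "16C"])
    def test_fixture_labels_are_gene_body_or_promoter_tiers(self, which):
        from methylarray.fixtures import load_dmr_island_table

        df = load_dmr_island_table(which)
        assert df["genomic_region"].isin(
            ["exon", "intron", "promoter", "proximal_promoter"]
        ).all()
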