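"""Context-interval construction, region classification, and term enrichment."""

from math import comb

import numpy as np
import pytest

from rapidcns.context import (
    build_context_intervals,
    classify_regions,
    enrich_terms,
    summarize_context_distribution,
)
from rapidcns.io import GeneModel


def _gene(gene_id="G", chrom="chr1", strand="+", exons=((5000, 6000), (8000, 9000)),
          cds=(), utr5=(), utr3=()):
    return GeneModel(gene_id, chrom, strand, list(exons), list(cds), list(utr5), list(utr3))


class _Region:
    def __init__(self, element_id, chrom, start, end):
        self.element_id, self.chrom, self.start, self.end = element_id, chrom, start, end


def _cats(intervals, category):
    return sorted((iv.start, iv.end) for iv in intervals if iv.category == category)


class TestBuildIntervals:
    def test_plus_strand_geometry(self):
        ivs = build_context_intervals([_gene()])
        assert _cats(ivs, "intron") == [(6000, 8000)]
        assert _cats(ivs, "upstream_2kb") == [(3000, 5000)]
        assert _cats(ivs, "downstream_2kb") == [(9000, 11000)]

    def test_minus_strand_mirrors_flanks(self):
        ivs = build_context_intervals([_gene(strand="-")])
        assert _cats(ivs, "upstream_2kb") == [(9000, 11000)]
        assert _cats(ivs, "downstream_2kb") == [(3000, 5000)]
        assert _cats(ivs, "intron") == [(6000, 8000)]

    def test_upstream_clipped_at_chromosome_start(self):
        ivs = build_context_intervals([_gene(exons=[(500, 900)])])
        assert _cats(ivs, "upstream_2kb") == [(0, 500)]

    def test_utr_intervals_carried_through(self):
        g = _gene(exons=[(5000, 6000)], utr5=[(5000, 5200)], utr3=[(5800, 6000)])
        ivs = build_context_intervals([g])
        assert _cats(ivs, "five_prime_utr") == [(5000, 5200)]
        assert _cats(ivs, "three_prime_utr") == [(5800, 6000)]

    def test_flank_must_be_positive(self):
        with pytest.raises(ValueError):
            build_context_intervals([_gene()], flank=0)


class TestClassify:
    def test_single_category_overlap(self):
        ivs = build_context_intervals([_gene()])
        (ctx,) = classify_regions([_Region("e", "chr1", 4500, 4600)], ivs)
        assert ctx.categories == {"upstream_2kb"}
        assert set(ctx.associated_genes) == {"G"}

    def test_multi_category_no_precedence_collapse(self):
        g = _gene(exons=[(5000, 6000), (8000, 9000)], utr5=[(5900, 6000)])
        ivs = build_context_intervals([g])
        (ctx,) = classify_regions([_Region("e", "chr1", 5950, 6050)], ivs)
        assert ctx.categories == {"five_prime_utr", "intron"}
        assert ctx.single_label() == "five_prime_utr"

    def test_no_overlap_empty(self):
        ivs = build_context_intervals([_gene()])
        (ctx,) = classify_regions([_Region("e", "chr7", 0, 100)], ivs)
        assert ctx.categories == set()
        assert ctx.single_label() == "intergenic"

    def test_gene_order_permutation_invariant(self):
        genes = [
            _gene("A", exons=[(1000, 2000)]),
            _gene("B", exons=[(4000, 9000), (12000, 13000)], strand="-"),
            _gene("C", chrom="chr2", exons=[(100, 400)]),
        ]
        regions = [_Region(f"e{i}", "chr1", s, s + 150) for i, s in enumerate(range(0, 14000, 700))]
        ref = classify_regions(regions, build_context_intervals(genes))
        perm = classify_regions(regions, build_context_intervals(genes[::-1]))
        for a, b in zip(ref, perm):
            assert a.categories == b.categories
            assert a.associated_genes == b.associated_genes

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and strands swaps upstream <-> downstream."""
        M = 20_000
        gene = _gene("G", exons=[(5000, 6000), (8000, 9000)], utr5=[(5000, 5100)],
                     utr3=[(8900, 9000)])
        mirrored = GeneModel(
            "G", "chr1", "-",
            [(M - e, M - s) for s, e in reversed(gene.exons)],
            [], [(M - e, M - s) for s, e in gene.utr5],
            [(M - e, M - s) for s, e in gene.utr3],
        )
        regions = [_Region(f"e{i}", "chr1", s, s + 80) for i, s in enumerate(range(2900, 11500, 400))]
        mirror_regions = [
            _Region(r.element_id, "chr1", M - r.end, M - r.start) for r in regions
        ]
        fwd = classify_regions(regions, build_context_intervals([gene]))
        rev = classify_regions(mirror_regions, build_context_intervals([mirrored]))
        # a full mirror (coordinates and strand together) preserves categories
        for a, b in zip(fwd, rev):
            assert a.categories == b.categories

    def test_strand_flip_in_place_swaps_flanks(self):
        plus = _gene("G", exons=[(5000, 6000), (8000, 9000)])
        minus = _gene("G", strand="-", exons=[(5000, 6000), (8000, 9000)])
        regions = [_Region("up", "chr1", 3500, 3600), _Region("down", "chr1", 9500, 9600)]
        fwd = classify_regions(regions, build_context_intervals([plus]))
        rev = classify_regions(regions, build_context_intervals([minus]))
        swap = {"upstream_2kb": "downstream_2kb", "downstream_2kb": "upstream_2kb"}
        for a, b in zip(fwd, rev):
            assert {swap[c] for c in a.categories} == b.categories


class TestSummary:
    def test_length_binning(self):
        ivs = build_context_intervals([_gene()])
        regions = [
            _Region("a", "chr1", 4000, 4012),
            _Region("b", "chr1", 4100, 4140),
            _Region("c", "chr1", 3100, 3400),
        ]
        contexts = classify_regions(regions, ivs)
        table = summarize_context_distribution(
            contexts, {"a": 12, "b": 40, "c": 300}, length_bins=(0, 100, 1000)
        )
        row = table[table["category"] == "upstream_2kb"].iloc[0]
        assert row["[0,100)"] == 2 and row["[100,1000)"] == 1

    def test_empty_input(self):
        table = summarize_context_distribution([], {}, length_bins=(0, 100))
        assert len(table) == 0

    def test_multi_category_double_count(self):
        g = _gene(exons=[(5000, 6000), (8000, 9000)], utr5=[(5900, 6000)])
        ivs = build_context_intervals([g])
        contexts = classify_regions([_Region("e", "chr1", 5950, 6050)], ivs)
        table = summarize_context_distribution(contexts, {"e": 100}, length_bins=(0, 1000))
        counted = table.set_index("category")["[0,1000)"]
        assert counted["five_prime_utr"] == 1 and counted["intron"] == 1


class TestEnrichment:
    def test_universal_term_not_significant(self):
        genes = [f"g{i}" for i in range(20)]
        g2t = [(g, "T:1", "everything") for g in genes]
        (res,) = enrich_terms(genes[:5], genes, g2t)
        assert res.p == pytest.approx(1.0)

    def test_exact_tail_value(self):
        # K=10 study, k=5 hits, M=100 background, m=10 term genes
        background = [f"g{i}" for i in range(100)]
        study = background[:5] + background[50:55]
        g2t = [(g, "T:1", "t") for g in background[:5] + background[90:95]]
        (res,) = enrich_terms(study, background, g2t)
        assert (res.k, res.K, res.m, res.M) == (5, 10, 10, 100)
        assert res.p == pytest.approx(6.7163e-4, rel=1e-3)

    def test_matches_brute_force_hypergeometric(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            M = int(rng.integers(10, 200))
            K = int(rng.integers(1, M))
            m = int(rng.integers(1, M))
            background = [f"g{i}" for i in range(M)]
            study = list(rng.choice(background, size=K, replace=False))
            term = set(rng.choice(background, size=m, replace=False))
            g2t = [(g, "T", "t") for g in term]
            k = len(term & set(study))
            if k == 0:
                assert enrich_terms(study, background, g2t) == []
                continue
            (res,) = enrich_terms(study, background, g2t)
            brute = sum(
                comb(m, x) * comb(M - m, K - x) for x in range(k, min(m, K) + 1)
            ) / comb(M, K)
            assert res.p == pytest.approx(brute, rel=1e-9)

    def test_zero_hit_terms_unreported(self):
        background = ["a", "b", "c", "d"]
        g2t = [("c", "T:1", "t"), ("d", "T:1", "t")]
        assert enrich_terms(["a", "b"], background, g2t) == []

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not in background"):
            enrich_terms(["x"], ["a"], [])

    def test_bh_ordering(self):
        background = [f"g{i}" for i in range(50)]
        g2t = [(g, "T:rare", "rare") for g in background[:4]]
        g2t += [(g, "T:common", "common") for g in background]
        res = enrich_terms(background[:4], background, g2t)
        assert [r.term_id for r in res] == ["T:rare", "T:common"]
        assert res[0].p_adjusted <= res[1].p_adjusted
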