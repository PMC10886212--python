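"""Genomic-element classification, candidate genes, enrichment p-values."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from selsig import (
    GeneModel,
    annotate_snp,
    annotate_snps,
    candidate_genes,
    category_counts,
    hypergeom_enrich,
    load_gene_models,
    read_gmt,
)

GFF3 = """\
##gff-version 3
1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA;Name=GENE_A
1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=txA;Parent=geneA
1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=exA1;Parent=txA
1\tsrc\texon\t1801\t2000\t.\t+\t.\tID=exA2;Parent=txA
1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=geneB;Name=GENE_B
2\tsrc\tgene\t100\t900\t.\t+\t.\tID=geneC;Name=GENE_C
"""

# the same three genes as BED12 (0-based half-open; blocks = exons)
BED12 = (
    "1\t1000\t2000\tgeneA\t0\t+\t1000\t2000\t0\t2\t200,200\t0,800\n"
    "1\t5000\t6000\tgeneB\t0\t-\t5000\t6000\t0\t1\t1000\t0\n"
    "2\t99\t900\tgeneC\t0\t+\t99\t900\t0\t1\t801\t0\n"
)


@pytest.fixture
def genes(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF3)
    return load_gene_models(p)


class TestLoadGeneModels:
    def test_gff3_coordinates_pass_through(self, genes):
        a = next(g for g in genes if g.gene_id == "geneA")
        assert (a.start, a.end, a.strand) == (1001, 2000, "+")
        assert a.exons == ((1001, 1200), (1801, 2000))

    def test_bed12_converts_to_one_based(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(BED12)
        models = load_gene_models(p)
        c = next(g for g in models if g.gene_id == "geneC")
        assert (c.start, c.end) == (100, 900)

    def test_dual_format_fixture_gives_identical_intervals(self, genes, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(BED12)
        from_bed = load_gene_models(p)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes] == \
               [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in from_bed]
        # multi-exon structure survives in both dialects
        assert from_bed[0].exons == genes[0].exons == ((1001, 1200), (1801, 2000))

    def test_malformed_gff3_reports_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("1\tsrc\tgene\t10\n")
        with pytest.raises(ValueError, match=":1"):
            load_gene_models(p)


class TestAnnotateSNP:
    def test_intron_when_inside_gene_outside_exons(self, genes):
        s = annotate_snp("1", 1500, genes)
        assert s.category == "intronic" and s.genes == ("geneA",)

    def test_exonic_takes_precedence(self, genes):
        assert annotate_snp("1", 1100, genes).category == "exonic"

    def test_upstream_within_1kb_of_plus_strand_start(self, genes):
        s = annotate_snp("1", 501, genes)  # 500 bp before geneA start
        assert s.category == "upstream" and s.genes == ("geneA",)

    def test_strand_aware_upstream_of_minus_strand_gene(self, genes):
        # geneB is on '-': its transcription start is the interval end (6000)
        s = annotate_snp("1", 6500, genes)
        assert s.category == "upstream" and s.genes == ("geneB",)

    def test_between_two_genes_both_flanks(self):
        models = [
            GeneModel("gA", "gA", "1", 100, 1000, "+"),
            GeneModel("gB", "gB", "1", 2700, 4000, "+"),
        ]
        # 800 bp after gA end, 900 bp before gB start
        s = annotate_snp("1", 1800, models)
        assert s.category == "upstream/downstream"
        assert set(s.genes) == {"gA", "gB"}

    def test_intergenic_records_flanking_neighbors(self, genes):
        s = annotate_snp("1", 3500, genes)
        assert s.category == "intergenic"
        assert set(s.genes) == {"geneA", "geneB"}

    def test_intergenic_neighbor_search_capped(self, genes):
        s = annotate_snp("1", 5_900_000, genes, max_flank_search=10_000)
        assert s.category == "intergenic" and s.genes == ()

    def test_agrees_with_brute_force_interval_scan(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(1, 200_000, 100), 40, replace=False))
        models = [
            GeneModel(f"g{i}", f"g{i}", "1", int(s), int(s) + 799,
                      "+" if i % 2 else "-")
            for i, s in enumerate(starts)
        ]
        flank = 1000
        for pos in rng.integers(1, 210_000, size=400):
            got = annotate_snp("1", int(pos), models, flank=flank)
            inside = [g for g in models if g.start <= pos <= g.end]
            up, down = [], []
            for g in models:
                tss, tes = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
                lo, hi = sorted([tss, tss + (-flank if g.strand == "+" else flank)])
                if lo <= pos <= hi and pos != tss:
                    up.append(g.gene_id)
                lo, hi = sorted([tes, tes + (flank if g.strand == "+" else -flank)])
                if lo <= pos <= hi and pos != tes:
                    down.append(g.gene_id)
            if inside:
                assert got.category == "intronic"  # models carry no exons
            elif up and down:
                assert got.category == "upstream/downstream"
            elif up:
                assert got.category == "upstream"
            elif down:
                assert got.category == "downstream"
            else:
                assert got.category == "intergenic"

    def test_category_counts_partition_snp_set(self, genes):
        variants = pd.DataFrame(
            {
                "chrom": ["1"] * 6,
                "pos": [1100, 1500, 501, 6500, 3500, 9000],
                "vid": [f"v{i}" for i in range(6)],
            }
        )
        snps = annotate_snps(variants, genes)
        counts = category_counts(snps)
        assert counts["n_snps"].sum() == 6


class TestCandidateGenes:
    def test_same_gene_deduplicated(self, genes):
        snps = [annotate_snp("1", 1500, genes), annotate_snp("1", 1100, genes)]
        assert candidate_genes(snps) == ["geneA"]

    def test_intergenic_neighbors_toggle(self, genes):
        snps = [annotate_snp("1", 3500, genes)]
        assert set(candidate_genes(snps)) == {"geneA", "geneB"}
        assert candidate_genes(snps, include_intergenic_neighbors=False) == []

    def test_hand_annotated_fixture_exact_id_set(self, genes):
        positions = [1100, 1500, 501, 6500, 150]  # geneA x3, geneB, geneC
        snps = [annotate_snp(c, p, genes)
                for c, p in zip(["1", "1", "1", "1", "2"], positions)]
        assert candidate_genes(snps) == ["geneA", "geneB", "geneC"]


def hypergeom_oracle(k, K, n, N):
    """Upper-tail enumeration with exact fractions."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return float(min(acc, Fraction(1)))


class TestEnrichment:
    UNIVERSE = [f"g{i}" for i in range(10)]

    def test_whole_universe_term_is_certain(self):
        res = hypergeom_enrich(
            self.UNIVERSE[:5], self.UNIVERSE, {"T": ("all", self.UNIVERSE)}
        )
        assert res[0].p == pytest.approx(1.0)

    def test_perfect_overlap_matches_enumeration(self):
        res = hypergeom_enrich(
            self.UNIVERSE[:5], self.UNIVERSE, {"T": ("hit", self.UNIVERSE[:5])}
        )
        assert res[0].p == pytest.approx(1 / math.comb(10, 5), abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        res = hypergeom_enrich(
            self.UNIVERSE[:3], self.UNIVERSE, {"T": ("miss", self.UNIVERSE[7:])}
        )
        assert res[0].k == 0 and res[0].p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_enumeration_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 41))
        universe = [f"g{i}" for i in range(N)]
        n = int(rng.integers(2, N // 2 + 2))
        cand = list(rng.choice(universe, size=n, replace=False))
        gmt = {}
        for t in range(4):
            K = int(rng.integers(1, N))
            gmt[f"T{t}"] = (f"T{t}", list(rng.choice(universe, K, replace=False)))
        for r in hypergeom_enrich(cand, universe, gmt):
            assert r.p == pytest.approx(
                hypergeom_oracle(r.k, r.K, r.n, r.N), abs=1e-12
            )

    def test_fdr_is_bh_adjusted_and_ordered(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(30)]
        cand = universe[:8]
        gmt = {f"T{t}": (f"T{t}", list(rng.choice(universe, 10, replace=False)))
               for t in range(6)}
        res = hypergeom_enrich(cand, universe, gmt)
        ps = [r.p for r in res]
        assert ps == sorted(ps)
        assert all(r.fdr >= r.p - 1e-15 for r in res)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hypergeom_enrich([], self.UNIVERSE, {})

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_enrich(["nope"], self.UNIVERSE, {})


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("T1\tdesc one\tg1\tg2\tg3\nT2\tdesc two\tg4\n")
    gmt = read_gmt(p)
    assert gmt["T1"] == ("desc one", ["g1", "g2", "g3"])
    assert gmt["T2"][1] == ["g4"]
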