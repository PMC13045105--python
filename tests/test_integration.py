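"""Regulatory domains, region-gene association and enrichment statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afepi import integration as integ
from afepi.tracks import RegionSet


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand", "biotype"])


class TestRegulatoryDomains:
    sizes = {"chr1": 2_000_000}

    def test_single_gene_domain_is_basal_plus_extension_clipped(self):
        genes = genes_df([("g1", "chr1", 1_000_000, "+", "protein_coding")])
        d = integ.build_regulatory_domains(genes, self.sizes).iloc[0]
        assert d["basal_start"] == 995_000 and d["basal_end"] == 1_001_000
        assert d["start"] == 0                      # 1 Mb extension clips at 0
        assert d["end"] == 2_000_000                # and at the chromosome end

    def test_two_genes_10kb_apart_meet_at_basal_edges(self):
        genes = genes_df([("g1", "chr1", 1_000_000, "+", "protein_coding"),
                          ("g2", "chr1", 1_010_000, "+", "protein_coding")])
        d = integ.build_regulatory_domains(genes, self.sizes).set_index("gene")
        # g1 extends right up to g2's basal start; g2 left to g1's basal end
        assert d.loc["g1", "end"] == d.loc["g2", "basal_start"] == 1_005_000
        assert d.loc["g2", "start"] == d.loc["g1", "basal_end"] == 1_001_000

    def test_minus_strand_basal_orientation(self):
        genes = genes_df([("g1", "chr1", 1_000_000, "-", "protein_coding")])
        d = integ.build_regulatory_domains(genes, self.sizes).iloc[0]
        # upstream of a minus-strand gene is to larger coordinates
        assert d["basal_start"] == 1_000_000 - 1000
        assert d["basal_end"] == 1_000_000 + 5000

    def test_domains_never_enter_neighbour_basal(self):
        rng = np.random.default_rng(0)
        tss = np.sort(rng.choice(1_900_000, 40, replace=False))
        genes = genes_df([(f"g{i}", "chr1", int(t), "+", "protein_coding")
                          for i, t in enumerate(tss)])
        d = integ.build_regulatory_domains(genes, self.sizes)
        for i, row in d.iterrows():
            for j, other in d.iterrows():
                if i == j:
                    continue
                inter = max(0, min(row["end"], other["basal_end"])
                            - max(row["start"], other["basal_start"]))
                own_basal = max(0, min(row["basal_end"], other["basal_end"])
                                - max(row["basal_start"], other["basal_start"]))
                assert inter <= own_basal  # overlap only where basals already overlap


class TestAssociation:
    def test_matches_brute_force_overlap_scan(self):
        rng = np.random.default_rng(1)
        tss = np.sort(rng.choice(900_000, 25, replace=False))
        genes = genes_df([(f"g{i}", "chr1", int(t), "+", "protein_coding")
                          for i, t in enumerate(tss)])
        domains = integ.build_regulatory_domains(genes, {"chr1": 1_000_000})
        regions = RegionSet.from_intervals(
            [("chr1", int(s), int(s) + 800, 0.0)
             for s in rng.choice(990_000, 12, replace=False)], raw=True)
        assoc = integ.associate_regions_to_genes(regions, domains)
        for row in regions.df.itertuples(index=False):
            key = f"{row.chrom}:{row.start}-{row.end}"
            brute = [d.gene for d in domains.itertuples(index=False)
                     if d.start < row.end and d.end > row.start]
            assert sorted(assoc[key]) == sorted(brute)


def hypergeom_tail_oracle(a, b, c, d):
    """P(overlap >= a) by enumeration over all more-extreme 2x2 tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        total += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                  / math.comb(n, row1))
    return total


class TestFisherOverlap:
    def test_no_association_table(self):
        universe = {"g1", "g2", "g3", "g4"}
        odds, p, table = integ.fisher_overlap({"g1", "g2"}, {"g1", "g3"}, universe)
        assert odds == pytest.approx(1.0)
        # one-sided enrichment tail P(X >= 1) for the (1,1,1,1) table is 5/6;
        # the two-sided flag reports 1 for this no-association table
        assert p == pytest.approx(5 / 6)
        _, p2, _ = integ.fisher_overlap({"g1", "g2"}, {"g1", "g3"}, universe,
                                        alternative="two-sided")
        assert p2 == pytest.approx(1.0)

    def test_perfect_overlap_is_one_over_choose(self):
        universe = {f"g{i}" for i in range(10)}
        near = {f"g{i}" for i in range(5)}
        _, p, _ = integ.fisher_overlap(near, set(near), universe)
        assert p == pytest.approx(1 / 252)

    def test_matches_enumeration_for_small_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 10, size=4)
            if a + b == 0 or a + c == 0 or a + b + c + d > 50:
                continue
            universe = {f"g{i}" for i in range(a + b + c + d)}
            items = sorted(universe)
            near = set(items[:a + b])
            de = set(items[:a]) | set(items[a + b:a + b + c])
            _, p, table = integ.fisher_overlap(near, de, universe)
            assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), rel=1e-9)


class TestGenesetOverrep:
    def test_external_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        k, p = integ.geneset_overrep(set(list(universe)[:5]), universe, universe)
        assert p == pytest.approx(1.0)

    def test_disjoint_sets_give_p_one_at_zero_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        k, p = integ.geneset_overrep({"g0", "g1"}, {"g10", "g11"}, universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_matches_enumeration(self):
        universe = {f"g{i}" for i in range(25)}
        items = sorted(universe)
        cands = set(items[:6])
        external = set(items[3:12])
        k, p = integ.geneset_overrep(cands, external, universe)
        oracle = sum(math.comb(9, j) * math.comb(16, 6 - j) / math.comb(25, 6)
                     for j in range(k, min(6, 9) + 1))
        assert p == pytest.approx(oracle, rel=1e-9)


class TestCandidateLoci:
    def make_de(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
        return df.set_index("gene")

    def test_de_up_gene_without_region_not_candidate(self):
        de = self.make_de([("g1", 2.0, 0.001)])
        out = integ.define_candidate_loci({"chr1:0-100": []}, de, "up")
        assert len(out) == 0

    def test_candidate_count_is_intersection_size(self):
        de = self.make_de([("g1", 2.0, 0.001), ("g2", -1.0, 0.001),
                           ("g3", 1.0, 0.5), ("g4", 3.0, 0.01)])
        assoc = {"r1": ["g1", "g3"], "r2": ["g4"]}
        out = integ.define_candidate_loci(assoc, de, "up")
        near = {"g1", "g3", "g4"}
        de_up = {"g1", "g4"}
        assert set(out["gene"]) == near & de_up


class TestVariantEnrichment:
    def test_target_equals_background_gives_p_one(self):
        bg = RegionSet.from_intervals([("chr1", 0, 10_000, 0.0)])
        variants = pd.DataFrame({"chrom": "chr1", "pos": [5, 500, 5000]})
        fold, p, k, n = integ.variant_region_enrichment(variants, bg, bg)
        assert p == pytest.approx(1.0) and fold == pytest.approx(1.0)

    def test_no_variant_in_target_gives_fold_zero(self):
        bg = RegionSet.from_intervals([("chr1", 0, 10_000, 0.0)])
        target = RegionSet.from_intervals([("chr1", 9000, 9500, 0.0)])
        variants = pd.DataFrame({"chrom": "chr1", "pos": [5, 500]})
        fold, p, k, n = integ.variant_region_enrichment(variants, target, bg)
        assert k == 0 and fold == 0.0

    def test_matches_exact_hypergeometric_sum(self):
        bg = RegionSet.from_intervals([("chr1", 0, 40, 0.0)])
        target = RegionSet.from_intervals([("chr1", 0, 10, 0.0)])
        variants = pd.DataFrame({"chrom": "chr1", "pos": [1, 3, 7, 15, 25, 35]})
        fold, p, k, n = integ.variant_region_enrichment(variants, target, bg)
        assert (k, n) == (3, 6)
        oracle = sum(math.comb(10, j) * math.comb(30, 6 - j) / math.comb(40, 6)
                     for j in range(3, 7))
        assert p == pytest.approx(oracle, rel=1e-9)


class TestShuffleEnrichment:
    sizes = {"chr1": 1000}

    def test_catalog_covering_genome_gives_p_one(self):
        target = RegionSet.from_intervals([("chr1", 100, 200, 0.0)])
        catalog = RegionSet.from_intervals([("chr1", 0, 1000, 0.0)])
        _, p = integ.shuffle_enrichment(target, catalog, self.sizes, 100, seed=0)
        assert p == pytest.approx(1.0)

    def test_zero_observed_overlap_gives_p_near_one(self):
        target = RegionSet.from_intervals([("chr1", 900, 950, 0.0)])
        catalog = RegionSet.from_intervals([("chr2", 0, 100, 0.0)])
        _, p = integ.shuffle_enrichment(target, catalog, self.sizes, 200, seed=0)
        assert p == pytest.approx(1.0)

    def test_one_region_toy_matches_closed_form(self):
        # target length 100 fully inside catalog [0,100); a shuffle matches
        # the observed overlap (100) only when placed exactly at 0:
        # P = 1/901 over uniform starts in [0, 900].
        target = RegionSet.from_intervals([("chr1", 0, 100, 0.0)])
        catalog = RegionSet.from_intervals([("chr1", 0, 100, 0.0)])
        n = 4000
        _, p = integ.shuffle_enrichment(target, catalog, self.sizes, n, seed=1)
        exact = 1 / 901
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(p - exact) < 4 * se + 1 / n
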