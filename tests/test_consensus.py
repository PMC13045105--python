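"""Pairwise LLR differential enrichment and replicate-voted consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from afepi import consensus as cns
from afepi import simulate as sim
from afepi.tracks import CoverageTrack, RegionSet, StudyDesign


def make_design(n):
    rows = []
    for i in range(n):
        rows.append({"sample": f"s{i}", "disease": "AF" if i % 2 else "SR",
                     "side": "LA" if i % 4 < 2 else "RA", "donor": f"d{i}", "batch": 1})
    return StudyDesign(pd.DataFrame(rows))


class TestEnumeratePairs:
    def test_twenty_samples_give_190_pairs(self):
        assert len(cns.enumerate_pairs(make_design(20))) == 190

    def test_two_samples_give_one_pair(self):
        assert len(cns.enumerate_pairs(make_design(2))) == 1

    def test_six_samples_match_explicit_enumeration(self):
        pairs = cns.enumerate_pairs(make_design(6))
        explicit = list(itertools.combinations([f"s{i}" for i in range(6)], 2))
        assert pairs == explicit and len(pairs) == 15

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cns.enumerate_pairs(make_design(1))


class TestLlr10:
    def test_zero_iff_equal(self):
        assert cns.llr10(7.0, 7.0) == 0.0
        assert cns.llr10(7.0, 7.1) > 0.0

    def test_known_value_20_vs_5(self):
        assert cns.llr10(20, 5) == pytest.approx(2.09, abs=0.005)

    def test_symmetric_and_monotone_at_fixed_sum(self):
        total = 30.0
        prev = -1.0
        for d in np.linspace(0, 14, 8):
            v = float(cns.llr10(total / 2 + d, total / 2 - d))
            assert v == pytest.approx(float(cns.llr10(total / 2 - d, total / 2 + d)))
            assert v >= prev
            prev = v


class TestPairwiseDiffEnrich:
    params = cns.ConsensusParams()

    def test_equal_tracks_give_empty_sets(self):
        t = CoverageTrack({"chr1": np.full(100, 12.0)}, 200)
        res = cns.pairwise_diff_enrich(t, t.copy(), self.params)
        assert len(res.enriched_in_a) == 0 and len(res.enriched_in_b) == 0

    def test_swapping_tracks_swaps_sets(self):
        rng = np.random.default_rng(0)
        a = CoverageTrack({"chr1": rng.poisson(10, 200).astype(float)}, 200)
        b = CoverageTrack({"chr1": rng.poisson(10, 200).astype(float)}, 200)
        a.counts["chr1"][50:56] = 70.0
        b.counts["chr1"][120:126] = 70.0
        r1 = cns.pairwise_diff_enrich(a, b, self.params)
        r2 = cns.pairwise_diff_enrich(b, a, self.params)
        pd.testing.assert_frame_equal(r1.enriched_in_a.df, r2.enriched_in_b.df)
        pd.testing.assert_frame_equal(r1.enriched_in_b.df, r2.enriched_in_a.df)

    def test_directional_sets_do_not_overlap_each_other(self):
        rng = np.random.default_rng(1)
        a = CoverageTrack({"chr1": rng.poisson(10, 500).astype(float)}, 200)
        b = CoverageTrack({"chr1": rng.poisson(10, 500).astype(float)}, 200)
        a.counts["chr1"][10:20] = 90.0
        b.counts["chr1"][100:110] = 90.0
        res = cns.pairwise_diff_enrich(a, b, self.params)
        assert not res.enriched_in_a.overlaps_any(res.enriched_in_b).any()
        assert (res.enriched_in_a.lengths() >= self.params.l).all()

    def test_collect_directional_sets_counts(self):
        t = CoverageTrack({"chr1": np.full(50, 10.0)}, 200)
        results = [cns.pairwise_diff_enrich(t, t.copy(), self.params, pair=(f"a{i}", f"b{i}"))
                   for i in range(3)]
        sets = cns.collect_directional_sets(results)
        assert len(sets) == 6
        assert {(s.winner, s.loser) for s in sets} == {
            (f"a{i}", f"b{i}") for i in range(3)} | {(f"b{i}", f"a{i}") for i in range(3)}


class TestVoting:
    def make_sets(self, design, region, winners_losers):
        sets = []
        for w, l in winners_losers:
            sets.append(cns.DirectionalSet(
                winner=w, loser=l,
                regions=RegionSet.from_intervals([region])))
        return sets

    def test_region_in_every_eligible_set_kept(self):
        cfg = sim.SimConfig(samples_per_group=2)
        design = sim.make_design(cfg)
        group = "AF-LA"
        members = design.groups[group]
        outside = [s for s in design.samples if s not in members]
        pairs = [(w, l) for w in members for l in outside]
        sets = self.make_sets(design, ("chr1", 1000, 2000, 3.0), pairs)
        out = cns.build_group_consensus(sets, design, group, cns.ConsensusParams())
        assert len(out) == 1
        assert out.df.iloc[0]["votes"] == len(pairs)

    def test_region_in_one_of_fifteen_sets_dropped(self):
        cfg = sim.SimConfig(samples_per_group=3)  # r=3, n=12 -> 27 eligible pairs
        design = sim.make_design(cfg)
        members = design.groups["AF-LA"]
        outside = [s for s in design.samples if s not in members]
        sets = self.make_sets(design, ("chr1", 1000, 2000, 3.0),
                              [(members[0], outside[0])])
        out = cns.build_group_consensus(sets, design, "AF-LA",
                                        cns.ConsensusParams(vote_fraction=0.5))
        assert len(out) == 0

    def test_increasing_vote_fraction_never_adds_regions(self):
        rng = np.random.default_rng(5)
        cfg = sim.SimConfig(seed=11, samples_per_group=3)
        bundle = sim.simulate_study(cfg)
        from afepi.pipeline import PipelineConfig, consensus_regions
        counts = []
        for f in (0.3, 0.5, 0.8):
            pc = PipelineConfig(seed=11)
            pc.sim = cfg
            pc.consensus = cns.ConsensusParams(vote_fraction=f)
            out = consensus_regions(bundle, pc)
            counts.append(sum(len(out[g]) for g in sim.GROUPS))
        assert counts[0] >= counts[1] >= counts[2]


class TestReferenceOverlapFilter:
    def test_fully_inside_reference_kept(self):
        c = RegionSet.from_intervals([("chr1", 1000, 2000, 1.0)])
        ref = RegionSet.from_intervals([("chr1", 0, 5000, 0.0)])
        assert len(cns.filter_by_reference_overlap(c, ref, 0.3)) == 1

    def test_boundary_299_vs_300_of_1000(self):
        c = RegionSet.from_intervals([("chr1", 0, 1000, 1.0)])
        ref299 = RegionSet.from_intervals([("chr1", 701, 1000, 0.0)])
        ref300 = RegionSet.from_intervals([("chr1", 700, 1000, 0.0)])
        assert len(cns.filter_by_reference_overlap(c, ref299, 0.3)) == 0
        assert len(cns.filter_by_reference_overlap(c, ref300, 0.3)) == 1

    def test_overlap_matches_brute_force(self):
        rng = np.random.default_rng(6)
        c_rows = [("chr1", int(s), int(s) + 400, 0.0)
                  for s in rng.choice(20_000, 10, replace=False)]
        r_rows = [("chr1", int(s), int(s) + 300, 0.0)
                  for s in rng.choice(20_000, 15, replace=False)]
        c = RegionSet.from_intervals(c_rows, raw=True)
        ref = RegionSet.from_intervals(r_rows, raw=True)
        got = c.overlap_lengths(ref)
        mask = np.zeros(25_000, dtype=bool)
        for _, s, e, _ in r_rows:
            mask[s:e] = True
        for i, (_, s, e, _) in enumerate(c.df.itertuples(index=False)):
            assert got[i] == mask[s:e].sum()


class TestRemoveCrossCategory:
    def test_disjoint_sets_unchanged(self):
        a = RegionSet.from_intervals([("chr1", 0, 1000, 1.0)])
        b = RegionSet.from_intervals([("chr1", 5000, 6000, 1.0)])
        out = cns.remove_cross_category({"A": a, "B": b})
        assert len(out["A"]) == 1 and len(out["B"]) == 1

    def test_identical_region_removed_from_both(self):
        a = RegionSet.from_intervals([("chr1", 0, 1000, 1.0)])
        b = RegionSet.from_intervals([("chr1", 0, 1000, 1.0)])
        out = cns.remove_cross_category({"A": a, "B": b})
        assert len(out["A"]) == 0 and len(out["B"]) == 0

    def test_outputs_pairwise_disjoint(self):
        rng = np.random.default_rng(7)
        sets = {}
        for name in "ABCD":
            rows = [("chr1", int(s), int(s) + 500, 0.0)
                    for s in rng.choice(50_000, 8, replace=False)]
            sets[name] = RegionSet.from_intervals(rows, raw=True).merge()
        out = cns.remove_cross_category(sets)
        for x in out:
            for y in out:
                if x != y:
                    assert not out[x].overlaps_any(out[y]).any()


def test_disease_consensus_recovers_af_shared_signal():
    # plant the same region in both AF groups: the AF disease consensus keeps it
    cfg = sim.SimConfig(seed=13, samples_per_group=3)
    design = sim.make_design(cfg)
    genome = sim.make_toy_genome(cfg)
    truth = sim.TruthTable()
    for group in ("AF-LA", "AF-RA"):
        truth.regions.append({"chrom": "chr1", "start": 100_000, "end": 101_000,
                              "group": group, "fold": 8.0})
    chips, _ = sim.simulate_chip(cfg, truth, genome, design)
    params = cns.ConsensusParams()
    results = [cns.pairwise_diff_enrich(chips[a], chips[b], params, pair=(a, b))
               for a, b in cns.enumerate_pairs(design)]
    sets = cns.collect_directional_sets(results)
    by_disease = cns.build_disease_consensus(sets, design, params)
    planted = RegionSet.from_intervals([("chr1", 100_000, 101_000, 0.0)])
    assert planted.overlaps_any(by_disease["AF"]).all()
    assert not planted.overlaps_any(by_disease["SR"]).any()
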