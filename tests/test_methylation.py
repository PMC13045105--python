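"""EWAS regression, same-direction windowing and inverse-variance DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afepi import methylation as meth_mod
from afepi import simulate as sim
from afepi.methylation import EwasResult
from afepi.tracks import RegionSet


def make_meth(betas, disease, positions=None, chrom="chr1"):
    n = betas.shape[0]
    samples = [f"s{i}" for i in range(betas.shape[1])]
    positions = positions if positions is not None else np.arange(n) * 100
    return sim.MethylationData(
        betas=pd.DataFrame(betas, index=[f"cg{i}" for i in range(n)], columns=samples),
        cpg_map=pd.DataFrame({"cpg": [f"cg{i}" for i in range(n)],
                              "chrom": chrom, "pos": positions}),
        design=pd.DataFrame({"sample": samples, "disease": disease}),
    )


class TestEwas:
    def test_matches_two_sample_t_test(self):
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.2, 0.8, size=(20, 12))
        disease = ["AF"] * 6 + ["SR"] * 6
        meth = make_meth(betas, disease)
        res = meth_mod.ewas(meth, n_svs=0)
        for i in range(20):
            t, p = stats.ttest_ind(betas[i, :6], betas[i, 6:], equal_var=True)
            assert res.stats["t"].iloc[i] == pytest.approx(t)
            assert res.stats["pvalue"].iloc[i] == pytest.approx(p)
            diff = betas[i, :6].mean() - betas[i, 6:].mean()
            assert res.stats["estimate"].iloc[i] == pytest.approx(diff)

    def test_constant_cpg_flagged_untestable(self):
        betas = np.vstack([np.full(8, 0.5), np.random.default_rng(1).uniform(size=8)])
        meth = make_meth(betas, ["AF"] * 4 + ["SR"] * 4)
        res = meth_mod.ewas(meth, n_svs=0)
        assert res.stats["estimate"].iloc[0] == 0.0
        assert res.stats["pvalue"].iloc[0] == 1.0

    def test_collinear_covariate_named_in_error(self):
        rng = np.random.default_rng(2)
        meth = make_meth(rng.uniform(size=(5, 8)), ["AF"] * 4 + ["SR"] * 4)
        cov = pd.DataFrame(
            {"dup_of_disease": [1.0] * 4 + [0.0] * 4},
            index=meth.betas.columns)
        with pytest.raises(ValueError, match="dup_of_disease"):
            meth_mod.ewas(meth, covariates=cov, n_svs=0)

    def test_too_few_samples_per_status_errors(self):
        meth = make_meth(np.random.default_rng(3).uniform(size=(5, 3)),
                         ["AF", "AF", "SR"])
        with pytest.raises(ValueError):
            meth_mod.ewas(meth)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        betas = np.clip(0.5 + rng.normal(0, 0.05, size=(4000, 16)), 0, 1)
        meth = make_meth(betas, ["AF"] * 8 + ["SR"] * 8)
        res = meth_mod.ewas(meth, n_svs=2)
        ks = stats.kstest(res.stats["pvalue"], "uniform")
        assert ks.pvalue > 0.01


class TestCandidateWindows:
    def fake_ewas(self, positions, estimates, chrom="chr1"):
        n = len(positions)
        df = pd.DataFrame({"cpg": [f"cg{i}" for i in range(n)], "chrom": chrom,
                           "pos": positions, "estimate": estimates,
                           "se": 0.01, "t": 1.0, "pvalue": 0.5})
        resid = pd.DataFrame(np.zeros((n, 4)), index=df["cpg"])
        return EwasResult(stats=df, residuals=resid, model_columns=[])

    def test_gap_boundary_500_included(self):
        ew = self.fake_ewas([0, 400, 900], [0.1, 0.2, 0.1])
        windows = meth_mod.find_candidate_windows(ew, max_gap=500)
        assert windows == [[0, 1, 2]]

    def test_sign_flip_breaks_run_singletons_dropped(self):
        ew = self.fake_ewas([0, 100, 200, 300], [0.1, 0.2, -0.1, 0.3])
        windows = meth_mod.find_candidate_windows(ew)
        assert windows == [[0, 1]]

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            pos = np.sort(rng.choice(20_000, size=n, replace=False))
            est = rng.normal(size=n)
            ew = self.fake_ewas(pos, est)
            got = meth_mod.find_candidate_windows(ew, max_gap=500)
            # oracle: brute-force enumeration of maximal same-sign runs
            expected = []
            run = [0]
            for i in range(1, n):
                if (pos[i] - pos[i - 1] <= 500
                        and np.sign(est[i]) == np.sign(est[i - 1]) != 0):
                    run.append(i)
                else:
                    if len(run) >= 2:
                        expected.append(run)
                    run = [i]
            if len(run) >= 2:
                expected.append(run)
            assert got == expected


class TestDmrStatistics:
    def ewas_with_residuals(self, b, s, resid):
        n = len(b)
        df = pd.DataFrame({"cpg": [f"cg{i}" for i in range(n)], "chrom": "chr1",
                           "pos": np.arange(n) * 100, "estimate": b, "se": s,
                           "t": np.array(b) / np.array(s), "pvalue": 0.5})
        return EwasResult(stats=df,
                          residuals=pd.DataFrame(resid, index=df["cpg"]),
                          model_columns=[])

    def test_two_independent_equal_cpgs_closed_form(self):
        rng = np.random.default_rng(6)
        resid = rng.normal(size=(2, 200))  # effectively independent residuals
        resid[1] -= resid[0] * np.corrcoef(resid)[0, 1]  # decorrelate
        b, s = 0.2, 0.05
        ew = self.ewas_with_residuals([b, b], [s, s], resid)
        out = meth_mod.dmr_statistics([[0, 1]], ew)
        r = np.corrcoef(resid)[0, 1]
        # closed form for correlation r: B = b, SE = s*sqrt((1+r)/2)
        assert out["effect"].iloc[0] == pytest.approx(b, rel=1e-6)
        assert out["se"].iloc[0] == pytest.approx(s * np.sqrt((1 + r) / 2), rel=1e-6)
        assert out["z"].iloc[0] == pytest.approx(b / (s * np.sqrt((1 + r) / 2)), rel=1e-6)

    def test_duplicate_cpg_does_not_double_count(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=200)
        resid = np.vstack([base, base + rng.normal(0, 1e-3, 200)])  # R ~ 0.999
        b, s = 0.2, 0.05
        ew = self.ewas_with_residuals([b, b], [s, s], resid)
        with pytest.warns(RuntimeWarning):
            out = meth_mod.dmr_statistics([[0, 1]], ew, cond_max=1e3)
        assert out["z"].iloc[0] == pytest.approx(b / s, rel=0.05)

    def test_power_scales_with_sqrt_window_size(self):
        rng = np.random.default_rng(8)
        for k in (2, 4):
            resid = rng.normal(size=(k, 5000))
            ew = self.ewas_with_residuals([0.1] * k, [0.05] * k, resid)
            out = meth_mod.dmr_statistics([list(range(k))], ew)
            assert out["z"].iloc[0] == pytest.approx(np.sqrt(k) * 0.1 / 0.05, rel=0.1)


@pytest.fixture(scope="module")
def called():
    cfg = sim.SimConfig(seed=9)
    genome = sim.make_toy_genome(cfg)
    truth = sim.plant_truth(cfg, genome)
    meth = sim.simulate_methylation(cfg, truth, genome)
    ew = meth_mod.ewas(meth, n_svs=2)
    windows = meth_mod.find_candidate_windows(ew)
    dmrs = meth_mod.dmr_statistics(windows, ew)
    return genome, truth, dmrs


class TestEndToEndDmrs:

    def test_output_dmrs_satisfy_type_invariants(self, called):
        genome, truth, dmrs = called
        pos = genome.cpgs.set_index("cpg")["pos"]
        for _, d in dmrs[dmrs["significant"]].iterrows():
            assert d["n_cpgs"] > 1
            p = pos.loc[d["cpgs"]].values
            assert (np.diff(p) <= 500).all()

    def test_planted_dmrs_recovered_with_correct_direction(self, called):
        genome, truth, dmrs = called
        sig = dmrs[dmrs["significant"]]
        recovered, direction_ok = 0, 0
        for t in truth.dmrs:
            hit = sig[(sig["chrom"] == t["chrom"]) & (sig["start"] < t["end"])
                      & (sig["end"] > t["start"])]
            if len(hit):
                recovered += 1
                if (hit["direction"] == t["direction"]).any():
                    direction_ok += 1
        assert recovered / len(truth.dmrs) >= 0.8
        assert direction_ok == recovered

    def test_classification_partition(self, called):
        _, _, dmrs = called
        classes = meth_mod.classify_dmrs(dmrs)
        n_sig = int(dmrs["significant"].sum())
        assert len(classes["hyper"]) + len(classes["hypo"]) == n_sig
        assert (classes["hyper"]["effect"] > 0).all()
        assert (classes["hypo"]["effect"] < 0).all()


class TestLinkDmrs:
    def test_linkage_matches_brute_force(self):
        dmrs = pd.DataFrame([
            {"chrom": "chr1", "start": 1000, "end": 1200, "direction": "hyper"},
            {"chrom": "chr2", "start": 1000, "end": 1200, "direction": "hypo"},
        ])
        domains = pd.DataFrame([("gA", "chr1", 500, 2000, 900, 1100)],
                               columns=["gene", "chrom", "start", "end",
                                        "basal_start", "basal_end"])
        cands = pd.DataFrame([("gA", "chr1:5000-6000", 2.0, 0.01)],
                             columns=["gene", "regions", "log2fc", "padj"])
        regions = {"AF-LA": RegionSet.from_intervals([("chr1", 5000, 6000, 1.0)])}
        out = meth_mod.link_dmrs_to_loci(dmrs, cands, domains, regions)
        assert list(out["dmr_index"]) == [0]  # chr2 DMR unlinked
        assert out["via_domain"].iloc[0]
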