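"""Call differentially methylated regions and test motif enrichment in them.

A per-CpG EWAS (OLS of beta on disease + 2 surrogate-variable PCs) feeds
candidate windows (runs of >= 2 same-sign CpGs at most 500 bp apart), which
are aggregated by inverse-variance weighting under the CpGs' residual
correlation and Bonferroni-corrected.  Sequences of the significant DMRs are
then scanned with the planted PWM (exact DP p-values, match p < 0.001) and
region-level hypergeometric enrichment is computed against background
regions.
"""

import numpy as np

from afepi import motifs as mm
from afepi import simulate as sim
from afepi import methylation as meth_mod
from afepi.tracks import RegionSet

cfg = sim.SimConfig(seed=1)
genome = sim.make_toy_genome(cfg)
truth = sim.plant_truth(cfg, genome)
meth = sim.simulate_methylation(cfg, truth, genome)

ew = meth_mod.ewas(meth, n_svs=2)
dmrs = meth_mod.dmr_statistics(meth_mod.find_candidate_windows(ew), ew)
sig = dmrs[dmrs["significant"]]
classes = meth_mod.classify_dmrs(dmrs)
print(f"candidate windows: {len(dmrs)}; significant DMRs: {len(sig)} "
      f"({len(classes['hyper'])} hyper, {len(classes['hypo'])} hypo in AF)")

# motif enrichment: planted PWM vs a random control PWM, DMRs vs a
# length-matched background (same region lengths, random placement)
dmr_regions = RegionSet.from_intervals(
    [(r["chrom"], r["start"] - 20, r["end"] + 20, 0.0) for _, r in sig.iterrows()])
rng = np.random.default_rng(0)
lengths = np.resize(dmr_regions.lengths(), 40)
bg_regions = RegionSet.from_intervals(
    [("chr1", int(s), int(s) + int(L), 0.0)
     for s, L in zip(rng.choice(900_000, 40, replace=False), lengths)], raw=True)
motif_id, mat = sim.planted_pwm_matrix()
pwms = [mm.PWM(motif_id, mat),
        mm.PWM("CONTROL.1", rng.dirichlet(np.ones(4), size=8))]
hits_t = [h for p in pwms for h in mm.scan_pwm(
    sim.simulate_region_sequences(cfg, truth, dmr_regions), p)]
hits_b = [h for p in pwms for h in mm.scan_pwm(
    sim.simulate_region_sequences(cfg, truth, bg_regions), p)]
enr = mm.motif_enrichment(hits_t, hits_b, len(dmr_regions), len(bg_regions),
                          motif_ids=[p.motif_id for p in pwms])
print(enr[["motif", "target_hit_regions", "fold", "pvalue", "padj"]].to_string(
    index=False))
# The planted motif should top the table: its instances sit inside planted
# DMRs (one covering a differentially methylated CpG), the control does not.
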