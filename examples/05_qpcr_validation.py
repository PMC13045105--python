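"""Replication-cohort qPCR arithmetic and validation rates.

Relative expression uses the delta-Ct method against the TBP reference gene;
ChIP enrichment is double-normalised (target vs GAPDH reference locus, ChIP
vs input).  A locus validates when the group difference keeps the expected
direction with one-sided Welch t p < 0.2; a region validates when either of
its two amplicons does.
"""

import pandas as pd

from afepi import qpcr
from afepi import simulate as sim

cfg = sim.SimConfig(seed=1)
genome = sim.make_toy_genome(cfg)
truth = sim.plant_truth(cfg, genome)
ct = sim.simulate_qpcr(cfg, truth)

rel = qpcr.rt_relative_expression(ct, ref_gene="TBP")
enr = qpcr.chip_qpcr_enrichment(ct, ref_locus="GAPDH_ref")

rows = []
for locus in truth.qpcr_loci:
    sub = rel[rel["target"] == locus["gene"]]
    call = qpcr.validate_target(sub["value"], sub["group"], locus["expected_up"])
    rows.append({"category": locus["expected_up"], "locus": locus["locus"],
                 "validated": call["validated"]})
summary = qpcr.validation_summary(pd.DataFrame(rows))
print(summary.to_string(index=False))
# At the generator's low noise every planted direction is recovered; rates
# drop as qpcr_noise_sd grows, with the direction gate bounding false calls.
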