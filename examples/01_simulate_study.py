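"""Generate the synthetic toy study and inspect its planted truth.

The generator emulates a 4-group atrial cohort (AF-LA, AF-RA, SR-LA, SR-RA;
5 samples each) over two 1 Mb chromosomes at 200 bp bins, planting
group-enriched H3K27ac regions, differentially expressed genes collocated
with them, same-direction methylation shifts over CpG runs, and qPCR tables
consistent with every planted direction.
"""

from afepi import SimConfig, simulate_study

bundle = simulate_study(SimConfig(seed=1))
truth = bundle["truth"]

print(f"samples:            {len(bundle['design'].samples)} "
      f"({', '.join(sorted(bundle['design'].groups))})")
print(f"genes / CpGs:       {len(bundle['genome'].genes)} / "
      f"{len(bundle['genome'].cpgs)}")
print(f"planted regions:    {len(truth.regions)} (10 per group, fold 6)")
print(f"planted DE genes:   {len(truth.de_genes)} (log2FC = 2)")
print(f"planted DMRs:       {len(truth.dmrs)} (|delta beta| = 0.15)")
print(f"qPCR loci:          {len(truth.qpcr_loci)} (8 AF-up, 5 SR-up)")
# Each count above is ground truth the downstream stages are scored against.
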