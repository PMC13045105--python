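"""Synthetic toy study with planted truth.

Generates every input the pipeline consumes — binned ChIP/input coverage,
RNA counts, CpG methylation, motif files, variant lists and qPCR Ct tables —
for a 4-group atrial design (AF-LA, AF-RA, SR-LA, SR-RA) with known planted
signals, so every downstream stage can be scored against ground truth.

The defaults are the study conditions used throughout the test suite: two
1 Mb chromosomes at 200 bp bins, 5 samples per group, 6-fold H3K27ac
enrichment over ~10 reads/bin negative-binomial background, planted
log2FC = 2 expression changes, Δβ = 0.15 methylation shifts over runs of
3–6 CpGs, and qPCR tables consistent with the planted directions.  Bin counts
are negative-binomial rather than Poisson to emulate the donor-to-donor
heterogeneity bulk atrial tissue shows; planted regions are bin-aligned so
recovery scoring has no edge ambiguity.  One global seed fans out to
independent per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .tracks import CoverageTrack, RegionSet, StudyDesign

__all__ = [
    "SimConfig",
    "TruthTable",
    "Genome",
    "MethylationData",
    "make_design",
    "make_toy_genome",
    "plant_truth",
    "simulate_chip",
    "simulate_counts",
    "simulate_methylation",
    "simulate_qpcr",
    "simulate_region_sequences",
    "planted_pwm_matrix",
    "simulate_study",
    "write_fixture",
]

GROUPS = ["AF-LA", "AF-RA", "SR-LA", "SR-RA"]

# Planted transcription-factor motif: 8-bp consensus with a central CpG so a
# differentially methylated cytosine can fall inside a motif instance.
PLANTED_MOTIF_ID = "PLANTED.1"
PLANTED_CONSENSUS = "TGACGTCA"


@dataclass
class SimConfig:
    """Parameters of the toy study; defaults are the reference conditions."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    bin_size: int = 200
    samples_per_group: int = 5
    background_rate: float = 10.0      # reads per bin, ChIP and input baseline
    enrichment_fold: float = 6.0       # ChIP fold inside planted regions
    nb_dispersion: float = 0.1         # coverage NB dispersion (1/size)
    n_regions_per_group: int = 10
    region_length: int = 1000          # bp, bin-aligned
    n_genes: int = 240
    n_de_per_group: int = 10
    de_log2fc: float = 2.0
    de_dispersion: float = 0.05
    collocated_fraction: float = 0.7   # planted DE genes near same-group regions
    n_dmrs: int = 8
    dmr_delta_beta: float = 0.15
    beta_noise_sd: float = 0.05
    meth_n_per_status: int = 8         # AF vs SR methylation arms
    n_input_spikes: int = 2            # artifact regions present in all inputs
    qpcr_noise_sd: float = 0.25        # cycles
    qpcr_expression_log2fold: float = 2.0
    qpcr_chip_log2fold: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length % self.bin_size:
            raise ValueError("bin_size must divide chrom_length")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        for name in ("background_rate", "enrichment_fold", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.region_length % self.bin_size:
            raise ValueError("region_length must be bin-aligned")

    def child_rng(self, stage: str) -> np.random.Generator:
        """Per-stage generator: reproducible independently of other stages."""
        stages = ["genome", "truth", "chip", "counts", "methylation", "qpcr", "sequences"]
        idx = stages.index(stage)
        children = np.random.SeedSequence(self.seed).spawn(len(stages))
        return np.random.default_rng(children[idx])


@dataclass
class Genome:
    chrom_sizes: Dict[str, int]
    genes: pd.DataFrame      # gene, chrom, tss, strand, biotype
    cpgs: pd.DataFrame       # cpg, chrom, pos


@dataclass
class MethylationData:
    betas: pd.DataFrame      # CpGs x samples
    cpg_map: pd.DataFrame    # cpg, chrom, pos
    design: pd.DataFrame     # sample, disease


@dataclass
class TruthTable:
    """Ground truth of every planted signal."""

    regions: List[dict] = field(default_factory=list)       # chrom,start,end,group,fold
    de_genes: List[dict] = field(default_factory=list)      # gene,group,log2fc,collocated
    dmrs: List[dict] = field(default_factory=list)          # chrom,start,end,direction,delta_beta,cpgs
    motif_sites: List[dict] = field(default_factory=list)   # motif,chrom,start,end,strand,dmr_index
    qpcr_loci: List[dict] = field(default_factory=list)     # locus,gene,expected_up
    input_spikes: List[dict] = field(default_factory=list)  # chrom,start,end,fold

    def regions_for(self, group: str) -> RegionSet:
        rows = [(r["chrom"], r["start"], r["end"], r["fold"])
                for r in self.regions if r["group"] == group]
        return RegionSet.from_intervals(rows)

    def all_region_set(self) -> RegionSet:
        rows = [(r["chrom"], r["start"], r["end"], r["fold"]) for r in self.regions]
        return RegionSet.from_intervals(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_design(cfg: SimConfig) -> StudyDesign:
    rows = []
    donor = 0
    for group in GROUPS:
        disease, side = group.split("-")
        for i in range(cfg.samples_per_group):
            donor += 1
            rows.append({
                "sample": f"{group}_{i + 1}",
                "disease": disease,
                "side": side,
                "donor": f"D{donor}",
                "batch": 1 + (donor % 2),
            })
    return StudyDesign(pd.DataFrame(rows))


def make_toy_genome(cfg: SimConfig) -> Genome:
    """Chromosome sizes, genes with TSS/strand/biotype, and clustered CpGs."""
    rng = cfg.child_rng("genome")
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    chroms = list(chrom_sizes)

    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gene_rows = []
    gid = 0
    for chrom in chroms:
        tss = np.sort(rng.choice(cfg.chrom_length, size=per_chrom, replace=False))
        for t in tss:
            gid += 1
            gene_rows.append({
                "gene": f"G{gid:04d}",
                "chrom": chrom,
                "tss": int(t),
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": "protein_coding" if rng.random() < 0.9 else "lincRNA",
            })
    genes = pd.DataFrame(gene_rows)

    # CpGs come in clusters (array-like density): runs of 3-8 sites 20-400 bp
    # apart, separated by multi-kb gaps, so DMR-sized runs exist by design.
    cpg_rows = []
    cid = 0
    for chrom in chroms:
        pos = int(rng.integers(1000, 5000))
        while pos < cfg.chrom_length - 5000:
            k = int(rng.integers(3, 9))
            for _ in range(k):
                if pos >= cfg.chrom_length - 100:
                    break
                cid += 1
                cpg_rows.append({"cpg": f"cg{cid:06d}", "chrom": chrom, "pos": pos})
                pos += int(rng.integers(20, 401))
            pos += int(rng.integers(2000, 12000))
    cpgs = pd.DataFrame(cpg_rows)
    return Genome(chrom_sizes, genes, cpgs)


def plant_truth(cfg: SimConfig, genome: Genome) -> TruthTable:
    """Choose planted regions, DE genes, DMRs, motif sites and qPCR loci."""
    rng = cfg.child_rng("truth")
    truth = TruthTable()
    chroms = list(genome.chrom_sizes)

    # --- group-enriched regions: bin-aligned, well separated ---------------
    n_bins_region = cfg.region_length // cfg.bin_size
    taken: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def place(n: int, min_sep: int = 5000) -> List[Tuple[str, int, int]]:
        placed = []
        attempts = 0
        while len(placed) < n and attempts < 10000:
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            max_bin = genome.chrom_sizes[chrom] // cfg.bin_size - n_bins_region - 1
            b = int(rng.integers(5, max_bin))
            start = b * cfg.bin_size
            end = start + cfg.region_length
            if all(end + min_sep <= s or start >= e + min_sep for s, e in taken[chrom]):
                taken[chrom].append((start, end))
                placed.append((chrom, start, end))
        if len(placed) < n:
            raise RuntimeError("could not place planted intervals")
        return placed

    for group in GROUPS:
        for chrom, start, end in place(cfg.n_regions_per_group):
            truth.regions.append({"chrom": chrom, "start": start, "end": end,
                                  "group": group, "fold": cfg.enrichment_fold})

    for chrom, start, end in place(cfg.n_input_spikes):
        truth.input_spikes.append({"chrom": chrom, "start": start, "end": end, "fold": 4.0})

    # --- planted DE genes: a fraction collocated with same-group regions.
    # "Collocated" means the gene nearest a planted region of the group, so
    # the region falls inside the gene's basal+extension regulatory domain
    # and the Fisher integration has a positive signal to find.
    used_genes: set = set()
    for group in GROUPS:
        regs = [r for r in truth.regions if r["group"] == group]
        near_genes: List[str] = []
        for r in regs:
            sub = genome.genes[genome.genes["chrom"] == r["chrom"]]
            order_d = np.argsort(np.abs(sub["tss"].values - (r["start"] + r["end"]) // 2))
            for gi in order_d:
                g = str(sub.iloc[int(gi)]["gene"])
                if g not in used_genes and g not in near_genes:
                    near_genes.append(g)
                    break
        n_near = min(int(round(cfg.collocated_fraction * cfg.n_de_per_group)),
                     len(near_genes))
        chosen_near = near_genes[:n_near]
        used_genes.update(chosen_near)
        far_pool = [g for g in genome.genes["gene"]
                    if g not in used_genes and g not in near_genes]
        chosen_far = [str(g) for g in
                      rng.choice(far_pool, size=cfg.n_de_per_group - n_near, replace=False)]
        used_genes.update(chosen_far)
        for g in chosen_near + chosen_far:
            truth.de_genes.append({"gene": g, "group": group,
                                   "log2fc": cfg.de_log2fc,
                                   "collocated": g in chosen_near})

    # --- planted DMRs: runs of >=3 CpGs with gaps <= 500 bp ----------------
    runs = []
    for chrom in chroms:
        sub = genome.cpgs[genome.cpgs["chrom"] == chrom].reset_index(drop=True)
        pos = sub["pos"].values
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > 500:
                if i - start_i >= 3:
                    runs.append((chrom, start_i, i, sub))
                start_i = i
    order = rng.permutation(len(runs))
    directions = ["hyper", "hypo"] * (cfg.n_dmrs // 2 + 1)
    for k in range(cfg.n_dmrs):
        chrom, i0, i1, sub = runs[order[k]]
        take = min(i1 - i0, int(rng.integers(3, 7)))
        members = sub.iloc[i0:i0 + take]
        truth.dmrs.append({
            "chrom": chrom,
            "start": int(members["pos"].min()),
            "end": int(members["pos"].max()) + 2,
            "direction": directions[k],
            "delta_beta": cfg.dmr_delta_beta,
            "cpgs": list(members["cpg"]),
        })

    # --- motif sites: one planted instance per DMR covering a member CpG ---
    L = len(PLANTED_CONSENSUS)
    cg_offset = PLANTED_CONSENSUS.index("CG")  # CpG sits here within the motif
    cpg_pos = genome.cpgs.set_index("cpg")["pos"]
    for di, dmr in enumerate(truth.dmrs):
        cpg = dmr["cpgs"][len(dmr["cpgs"]) // 2]
        p = int(cpg_pos[cpg])
        truth.motif_sites.append({
            "motif": PLANTED_MOTIF_ID,
            "chrom": dmr["chrom"],
            "start": p - cg_offset,
            "end": p - cg_offset + L,
            "strand": "+",
            "dmr_index": di,
        })

    # --- qPCR loci: 8 AF-up and 5 SR-up, tied to planted DE genes ----------
    af_genes = [d["gene"] for d in truth.de_genes if d["group"].startswith("AF")]
    sr_genes = [d["gene"] for d in truth.de_genes if d["group"].startswith("SR")]
    for i, g in enumerate(af_genes[:8]):
        truth.qpcr_loci.append({"locus": f"L{i + 1:02d}", "gene": g, "expected_up": "AF"})
    for i, g in enumerate(sr_genes[:5]):
        truth.qpcr_loci.append({"locus": f"L{i + 9:02d}", "gene": g, "expected_up": "SR"})
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_chip(cfg: SimConfig, truth: TruthTable, genome: Genome,
                  design: Optional[StudyDesign] = None
                  ) -> Tuple[Dict[str, CoverageTrack], Dict[str, CoverageTrack]]:
    """Per-sample ChIP and input coverage tracks.

    ChIP bins inside a region planted for group *g* get ``background x fold``
    in group-*g* samples only; input tracks never receive the fold.  Input
    spikes (artifacts) raise both ChIP and input in every sample, emulating
    the signals a greylist is built to remove.
    """
    rng = cfg.child_rng("chip")
    design = design or make_design(cfg)
    n_bins = {c: size // cfg.bin_size for c, size in genome.chrom_sizes.items()}

    chips: Dict[str, CoverageTrack] = {}
    inputs: Dict[str, CoverageTrack] = {}
    for row in design.table.itertuples(index=False):
        group = f"{row.disease}-{row.side}"
        depth_factor = float(rng.uniform(0.8, 1.2))
        chip_counts, input_counts = {}, {}
        for chrom, nb in n_bins.items():
            chip_mean = np.full(nb, cfg.background_rate * depth_factor)
            input_mean = np.full(nb, cfg.background_rate * depth_factor)
            for r in truth.regions:
                if r["chrom"] == chrom and r["group"] == group:
                    b0, b1 = r["start"] // cfg.bin_size, r["end"] // cfg.bin_size
                    chip_mean[b0:b1] *= r["fold"]
            for sp in truth.input_spikes:
                if sp["chrom"] == chrom:
                    b0, b1 = sp["start"] // cfg.bin_size, sp["end"] // cfg.bin_size
                    chip_mean[b0:b1] *= sp["fold"]
                    input_mean[b0:b1] *= sp["fold"]
            chip_counts[chrom] = _nb_draw(rng, chip_mean, cfg.nb_dispersion)
            input_counts[chrom] = _nb_draw(rng, input_mean, cfg.nb_dispersion)
        chips[row.sample] = CoverageTrack(chip_counts, cfg.bin_size)
        inputs[row.sample] = CoverageTrack(input_counts, cfg.bin_size)
    return chips, inputs


def simulate_counts(cfg: SimConfig, truth: TruthTable, genome: Genome,
                    design: Optional[StudyDesign] = None) -> pd.DataFrame:
    """RNA read-count matrix (genes x samples), planted genes up in their group."""
    rng = cfg.child_rng("counts")
    design = design or make_design(cfg)
    genes = genome.genes["gene"].values
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(genes))
    lfc = {d["gene"]: (d["group"], d["log2fc"]) for d in truth.de_genes}

    cols = {}
    for row in design.table.itertuples(index=False):
        group = f"{row.disease}-{row.side}"
        depth = float(rng.uniform(0.8, 1.2))
        mean = base * depth
        bump = np.array([2.0 ** lfc[g][1] if g in lfc and lfc[g][0] == group else 1.0
                         for g in genes])
        cols[row.sample] = _nb_draw(rng, mean * bump, cfg.de_dispersion).astype(int)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def simulate_methylation(cfg: SimConfig, truth: TruthTable, genome: Genome) -> MethylationData:
    """Beta-value matrix over the genome's CpGs for an AF-vs-SR methylation arm."""
    rng = cfg.child_rng("methylation")
    samples = [f"M_AF_{i + 1}" for i in range(cfg.meth_n_per_status)] + \
              [f"M_SR_{i + 1}" for i in range(cfg.meth_n_per_status)]
    disease = ["AF"] * cfg.meth_n_per_status + ["SR"] * cfg.meth_n_per_status
    is_af = np.array([d == "AF" for d in disease], dtype=float)

    cpgs = genome.cpgs.reset_index(drop=True)
    n = len(cpgs)
    base = rng.uniform(0.15, 0.85, size=n)
    effect = np.zeros(n)
    cpg_index = {c: i for i, c in enumerate(cpgs["cpg"])}
    for dmr in truth.dmrs:
        sign = 1.0 if dmr["direction"] == "hyper" else -1.0
        for c in dmr["cpgs"]:
            i = cpg_index[c]
            base[i] = rng.uniform(0.3, 0.6)  # keep beta + delta inside [0, 1]
            effect[i] = sign * dmr["delta_beta"]

    noise = rng.normal(0.0, cfg.beta_noise_sd, size=(n, len(samples)))
    betas = np.clip(base[:, None] + effect[:, None] * is_af[None, :] + noise, 0.0, 1.0)
    return MethylationData(
        betas=pd.DataFrame(betas, index=pd.Index(cpgs["cpg"], name="cpg"), columns=samples),
        cpg_map=cpgs[["cpg", "chrom", "pos"]].copy(),
        design=pd.DataFrame({"sample": samples, "disease": disease}),
    )


def simulate_qpcr(cfg: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Ct tables for the replication cohort (RT and ChIP/input fractions).

    Ct = baseline - log2(relative abundance) + noise; the reference gene/locus
    has constant abundance in every sample, so planted fold changes move the
    target Ct only.  Two technical replicates per well.
    """
    rng = cfg.child_rng("qpcr")
    samples = [("V_AF_1", "AF"), ("V_AF_2", "AF"), ("V_AF_3", "AF"),
               ("V_SR_1", "SR"), ("V_SR_2", "SR")]
    rows = []

    def add(sample, group, target, fraction, ct):
        for rep in (1, 2):
            rows.append({"sample": sample, "group": group, "target": target,
                         "fraction": fraction, "ct": ct + rng.normal(0, cfg.qpcr_noise_sd),
                         "rep": rep})

    for sample, group in samples:
        add(sample, group, "TBP", "RT", 20.0)
        add(sample, group, "GAPDH_ref", "ChIP", 24.0)
        add(sample, group, "GAPDH_ref", "Input", 22.0)
        for locus in truth.qpcr_loci:
            up = locus["expected_up"] == group
            rt_ct = 25.0 - (cfg.qpcr_expression_log2fold if up else 0.0)
            add(sample, group, locus["gene"], "RT", rt_ct)
            for amp in ("a", "b"):
                chip_ct = 27.0 - (cfg.qpcr_chip_log2fold if up else 0.0)
                add(sample, group, f"{locus['locus']}_{amp}", "ChIP", chip_ct)
                add(sample, group, f"{locus['locus']}_{amp}", "Input", 26.0)
    return pd.DataFrame(rows)


def planted_pwm_matrix(p_consensus: float = 0.85) -> Tuple[str, np.ndarray]:
    """The planted motif as an (L, 4) probability matrix over A,C,G,T."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(PLANTED_CONSENSUS)
    mat = np.full((L, 4), (1.0 - p_consensus) / 3.0)
    for i, b in enumerate(PLANTED_CONSENSUS):
        mat[i, idx[b]] = p_consensus
    return PLANTED_MOTIF_ID, mat


def simulate_region_sequences(cfg: SimConfig, truth: TruthTable,
                              regions: RegionSet) -> Dict[str, str]:
    """Random sequences for a region set, with planted motif instances embedded
    wherever a planted motif site falls inside a region.  Keyed by
    ``chrom:start-end``."""
    rng = cfg.child_rng("sequences")
    bases = np.array(list("ACGT"))
    out: Dict[str, str] = {}
    for row in regions.df.itertuples(index=False):
        seq = list(rng.choice(bases, size=row.end - row.start))
        for site in truth.motif_sites:
            if site["chrom"] == row.chrom and site["start"] >= row.start \
                    and site["end"] <= row.end:
                off = site["start"] - row.start
                seq[off:off + len(PLANTED_CONSENSUS)] = list(PLANTED_CONSENSUS)
        out[f"{row.chrom}:{row.start}-{row.end}"] = "".join(seq)
    return out


def simulate_study(cfg: SimConfig) -> dict:
    """Run every generator once; the bundle feeds the pipeline and tests."""
    genome = make_toy_genome(cfg)
    truth = plant_truth(cfg, genome)
    design = make_design(cfg)
    chips, inputs = simulate_chip(cfg, truth, genome, design)
    counts = simulate_counts(cfg, truth, genome, design)
    meth = simulate_methylation(cfg, truth, genome)
    qpcr = simulate_qpcr(cfg, truth)
    return {"config": cfg, "genome": genome, "truth": truth, "design": design,
            "chips": chips, "inputs": inputs, "counts": counts,
            "methylation": meth, "qpcr": qpcr}


def write_fixture(bundle: dict, outdir) -> None:
    """Write the whole toy study as plain-text files (bedGraph/BED/TSV/JSON/MEME)."""
    import os

    from .motifs import PWM, write_meme

    os.makedirs(outdir, exist_ok=True)
    cfg: SimConfig = bundle["config"]
    genome: Genome = bundle["genome"]
    with open(os.path.join(outdir, "chrom_sizes.tsv"), "w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    genome.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    genome.cpgs.to_csv(os.path.join(outdir, "cpg_map.tsv"), sep="\t", index=False)
    bundle["design"].to_tsv(os.path.join(outdir, "design.tsv"))
    bundle["truth"].to_json(os.path.join(outdir, "truth.json"))
    bundle["truth"].all_region_set().to_bed(os.path.join(outdir, "planted_regions.bed"))
    for name, track in bundle["chips"].items():
        track.to_bedgraph(os.path.join(outdir, f"chip_{name}.bedgraph"))
    for name, track in bundle["inputs"].items():
        track.to_bedgraph(os.path.join(outdir, f"input_{name}.bedgraph"))
    bundle["counts"].to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    meth: MethylationData = bundle["methylation"]
    meth.betas.to_csv(os.path.join(outdir, "betas.tsv"), sep="\t")
    meth.design.to_csv(os.path.join(outdir, "meth_design.tsv"), sep="\t", index=False)
    bundle["qpcr"].to_csv(os.path.join(outdir, "qpcr_ct.tsv"), sep="\t", index=False)
    motif_id, mat = planted_pwm_matrix()
    write_meme([PWM(motif_id, mat)], os.path.join(outdir, "motifs.meme"))
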