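"""End-to-end orchestration of the toy-study pipeline.

``run_all`` chains every stage — simulation, depth normalisation,
greylisting, reference peaks, pairwise differential enrichment, replicate
voting, reference-overlap and uniqueness filters, region quantification,
differential expression, region-gene integration, EWAS/DMR calling, motif
enrichment and qPCR validation — deterministically from one config + seed,
and returns a result bundle with a manifest of the parameters used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import expression as de
from . import integration as integ
from . import methylation as meth_mod
from . import motifs as motif_mod
from . import peaks
from . import qpcr as qpcr_mod
from . import quantify
from . import simulate as sim
from .tracks import RegionSet

__all__ = ["PipelineConfig", "run_all", "recover_planted_regions", "region_recovery"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its conventional default."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    consensus: cns.ConsensusParams = field(default_factory=cns.ConsensusParams)
    association: integ.AssociationRule = field(default_factory=integ.AssociationRule)
    peak_p_thresh: float = 1e-5
    greylist_fraction: float = 0.5
    target_depth: float = 20_000_000
    de_fdr: float = 0.05
    dmr_max_gap: int = 500
    dmr_alpha: float = 0.05
    motif_p_max: float = 0.001
    qpcr_alpha: float = 0.2
    gwas_p_thresh: float = 1e-8   # applied by callers when filtering variants
    seed: int = 0

    def __post_init__(self):
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(seed=raw.get("seed", 0))
        for key, value in raw.items():
            if key in ("sim", "consensus", "association"):
                target = getattr(cfg, key)
                for k, v in value.items():
                    setattr(target, k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
        cfg.sim.__post_init__()
        return cfg

    def to_manifest(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "consensus": dataclasses.asdict(self.consensus),
            "association": dataclasses.asdict(self.association),
            "peak_p_thresh": self.peak_p_thresh,
            "greylist_fraction": self.greylist_fraction,
            "de_fdr": self.de_fdr,
            "dmr_max_gap": self.dmr_max_gap,
            "dmr_alpha": self.dmr_alpha,
            "motif_p_max": self.motif_p_max,
            "qpcr_alpha": self.qpcr_alpha,
            "seed": self.seed,
        }


def consensus_regions(bundle: dict, cfg: PipelineConfig) -> Dict[str, RegionSet]:
    """ChIP stages only: greylist, reference peaks, pairwise LLR, voting,
    reference-overlap filter, cross-category removal."""
    design = bundle["design"]
    chips = {s: peaks.normalize_depth(t, cfg.target_depth) for s, t in bundle["chips"].items()}
    inputs = {s: peaks.normalize_depth(t, cfg.target_depth) for s, t in bundle["inputs"].items()}

    greylist = peaks.compute_greylist(list(inputs.values()), cfg.greylist_fraction,
                                      p_thresh=cfg.peak_p_thresh)
    reference = {
        group: peaks.call_group_reference_peaks(
            [chips[s] for s in members], [inputs[s] for s in members],
            p_thresh=cfg.peak_p_thresh)
        for group, members in design.groups.items()
    }
    reference = {g: peaks.subtract_greylist(r, greylist) for g, r in reference.items()}

    results = [
        cns.pairwise_diff_enrich(chips[a], chips[b], cfg.consensus, pair=(a, b))
        for a, b in cns.enumerate_pairs(design)
    ]
    sets = cns.collect_directional_sets(results)
    raw = {g: cns.build_group_consensus(sets, design, g, cfg.consensus)
           for g in design.groups}
    filtered = {}
    for g, regions in raw.items():
        regions = peaks.subtract_greylist(regions, greylist, min_len=cfg.consensus.l)
        filtered[g] = cns.filter_by_reference_overlap(regions, reference[g],
                                                      cfg.consensus.ref_overlap_frac)
    unique = cns.remove_cross_category(filtered)
    unique["_greylist"] = greylist
    unique["_reference"] = reference
    unique["_directional_sets"] = sets
    return unique


def region_recovery(found: RegionSet, planted: RegionSet) -> Dict[str, float]:
    """Sensitivity / FDR of recovered regions against planted truth (>=1 bp)."""
    if len(planted) == 0:
        return {"sensitivity": np.nan, "fdr": np.nan, "n_found": len(found)}
    sens = float(planted.overlaps_any(found).mean()) if len(found) else 0.0
    fdr = float((~found.overlaps_any(planted)).mean()) if len(found) else 0.0
    return {"sensitivity": sens, "fdr": fdr, "n_found": len(found)}


def recover_planted_regions(cfg: PipelineConfig) -> Dict[str, Dict[str, float]]:
    """Simulate one study and score per-group consensus recovery."""
    bundle = sim.simulate_study(cfg.sim)
    out = consensus_regions(bundle, cfg)
    truth = bundle["truth"]
    return {g: region_recovery(out[g], truth.regions_for(g)) for g in sim.GROUPS}


def run_all(cfg: PipelineConfig, outdir: Optional[str] = None) -> dict:
    """Run the full pipeline on a simulated study; optionally write outputs."""
    bundle = sim.simulate_study(cfg.sim)
    design = bundle["design"]
    truth = bundle["truth"]
    results: dict = {"config": cfg, "truth": truth, "design": design}

    # --- enriched-region discovery ----------------------------------------
    groups_out = consensus_regions(bundle, cfg)
    region_sets = {g: groups_out[g] for g in sim.GROUPS}
    results["regions_by_group"] = region_sets
    results["greylist"] = groups_out["_greylist"]
    results["disease_consensus"] = cns.build_disease_consensus(
        groups_out["_directional_sets"], design, cfg.consensus)

    # --- quantification ----------------------------------------------------
    all_regions = RegionSet(pd.concat([r.df for r in region_sets.values()])
                            ) if any(len(r) for r in region_sets.values()) else RegionSet()
    if len(all_regions):
        chip_m = quantify.region_matrix(bundle["chips"], all_regions)
        input_m = quantify.region_matrix(bundle["inputs"], all_regions)
        ratio = quantify.input_normalize(chip_m, input_m)
        qn = quantify.quantile_normalize(ratio)
        log_m = np.log2(qn + 1e-6)
        results["coverage_matrix"] = log_m
        results["correlations"] = quantify.sample_correlations(log_m)
        results["pca"] = quantify.principal_components(log_m, k=2)
        region_ids = {g: [f"{r.chrom}:{r.start}-{r.end}"
                          for r in region_sets[g].df.itertuples(index=False)]
                      for g in region_sets}
        results["upward_shift"] = quantify.upward_shift_pvalues(
            log_m, region_ids, design.groups)

    # --- differential expression and integration ---------------------------
    genes = bundle["genome"].genes
    counts = de.filter_genes(bundle["counts"], genes)
    universe = set(counts.index)
    domains = integ.build_regulatory_domains(genes, bundle["genome"].chrom_sizes,
                                             cfg.association)
    de_results, fisher, candidates = {}, {}, {}
    contrast_for_group = {"AF-LA": ("AF-LA_vs_SR-LA", "up"),
                          "SR-LA": ("AF-LA_vs_SR-LA", "down"),
                          "AF-RA": ("AF-RA_vs_SR-RA", "up"),
                          "SR-RA": ("AF-RA_vs_SR-RA", "down")}
    for group, (contrast, direction) in contrast_for_group.items():
        if contrast not in de_results:
            de_results[contrast] = de.nb_wald_de(counts, design, contrast)
        d = de_results[contrast]
        assoc = integ.associate_regions_to_genes(region_sets[group], domains)
        near = {g for gs in assoc.values() for g in gs}
        sign = 1.0 if direction == "up" else -1.0
        de_up = {g for g, row in d.iterrows()
                 if np.isfinite(row["padj"]) and row["padj"] < cfg.de_fdr
                 and sign * row["log2fc"] > 0}
        odds, p, table = integ.fisher_overlap(near, de_up, universe)
        fisher[group] = {"odds": odds, "pvalue": p, "table": table}
        candidates[group] = integ.define_candidate_loci(assoc, d, direction, cfg.de_fdr)
    results["de"] = de_results
    results["fisher"] = fisher
    results["candidates"] = candidates
    results["domains"] = domains

    # --- methylation --------------------------------------------------------
    ew = meth_mod.ewas(bundle["methylation"], n_svs=2)
    windows = meth_mod.find_candidate_windows(ew, max_gap=cfg.dmr_max_gap)
    dmrs = meth_mod.dmr_statistics(windows, ew, alpha=cfg.dmr_alpha)
    results["ewas"] = ew
    results["dmrs"] = dmrs
    results["dmr_classes"] = meth_mod.classify_dmrs(dmrs)
    non_empty = [c for c in candidates.values() if len(c)]
    all_cands = pd.concat(non_empty) if non_empty else pd.DataFrame()
    if len(dmrs) and len(all_cands):
        results["dmr_links"] = meth_mod.link_dmrs_to_loci(
            dmrs[dmrs["significant"]], all_cands, domains, region_sets)

    # --- motifs --------------------------------------------------------------
    sig = dmrs[dmrs["significant"]] if len(dmrs) else dmrs
    if len(sig):
        dmr_regions = RegionSet.from_intervals(
            [(r["chrom"], r["start"], r["end"], 0.0) for _, r in sig.iterrows()])
        seqs = sim.simulate_region_sequences(cfg.sim, truth, dmr_regions)
        motif_id, mat = sim.planted_pwm_matrix()
        pwm = motif_mod.PWM(motif_id, mat)
        hits = motif_mod.scan_pwm(seqs, pwm, p_max=cfg.motif_p_max)
        results["motif_hits"] = hits

    # --- qPCR validation -----------------------------------------------------
    ct = bundle["qpcr"]
    rel = qpcr_mod.rt_relative_expression(ct, "TBP")
    enr = qpcr_mod.chip_qpcr_enrichment(ct, "GAPDH_ref")
    call_rows = []
    for locus in truth.qpcr_loci:
        sub = rel[rel["target"] == locus["gene"]]
        call = qpcr_mod.validate_target(sub["value"], sub["group"],
                                        locus["expected_up"], cfg.qpcr_alpha)
        call_rows.append({"assay": "RT", "category": locus["expected_up"],
                          "locus": locus["locus"], "amplicon": "rt",
                          "validated": call["validated"]})
        for amp in ("a", "b"):
            sub = enr[enr["target"] == f"{locus['locus']}_{amp}"]
            call = qpcr_mod.validate_target(sub["value"], sub["group"],
                                            locus["expected_up"], cfg.qpcr_alpha)
            call_rows.append({"assay": "ChIP", "category": locus["expected_up"],
                              "locus": locus["locus"], "amplicon": amp,
                              "validated": call["validated"]})
    calls = pd.DataFrame(call_rows)
    results["qpcr_calls"] = calls
    results["validation_rt"] = qpcr_mod.validation_summary(calls[calls["assay"] == "RT"])
    results["validation_chip"] = qpcr_mod.validation_summary(calls[calls["assay"] == "ChIP"])

    results["manifest"] = {"parameters": cfg.to_manifest()}
    if outdir is not None:
        _write_outputs(results, outdir)
    return results


def _digest(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def _write_outputs(results: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    written = []
    for group, regions in results["regions_by_group"].items():
        path = os.path.join(outdir, f"consensus_{group}.bed")
        regions.to_bed(path, name_prefix=group)
        written.append(path)
    if "coverage_matrix" in results:
        path = os.path.join(outdir, "coverage_log2.tsv")
        results["coverage_matrix"].to_csv(path, sep="\t")
        written.append(path)
    for contrast, d in results["de"].items():
        path = os.path.join(outdir, f"de_{contrast}.tsv")
        d.to_csv(path, sep="\t")
        written.append(path)
    if len(results["dmrs"]):
        path = os.path.join(outdir, "dmrs.tsv")
        results["dmrs"].drop(columns=["cpgs"]).to_csv(path, sep="\t", index=False)
        written.append(path)
    for name in ("validation_rt", "validation_chip"):
        path = os.path.join(outdir, f"{name}.tsv")
        results[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    manifest = dict(results["manifest"])
    manifest["outputs"] = {os.path.basename(p): _digest(p) for p in written}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
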