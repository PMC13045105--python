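"""Region-gene association and integration statistics.

Builds GREAT-style basal-plus-extension regulatory domains, associates
enriched regions with genes by domain overlap, tests the overlap between
near-region genes and upregulated genes with a one-sided Fisher's exact test
(all tested genes as background), defines candidate loci, and provides the
hypergeometric gene-set and variant-in-region enrichment tests plus a
length-preserving interval-shuffling empirical enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .tracks import RegionSet

__all__ = [
    "AssociationRule",
    "build_regulatory_domains",
    "associate_regions_to_genes",
    "fisher_overlap",
    "define_candidate_loci",
    "geneset_overrep",
    "variant_region_enrichment",
    "shuffle_enrichment",
]


@dataclass
class AssociationRule:
    """Basal-plus-extension gene-to-region association rule (GREAT defaults)."""

    basal_upstream: int = 5000
    basal_downstream: int = 1000
    max_extension: int = 1_000_000

    def __post_init__(self):
        if min(self.basal_upstream, self.basal_downstream, self.max_extension) < 0:
            raise ValueError("rule distances must be >= 0")
        if self.max_extension < max(self.basal_upstream, self.basal_downstream):
            raise ValueError("extension must be >= basal spans")


def build_regulatory_domains(genes: pd.DataFrame, chrom_sizes: Mapping[str, int],
                             rule: AssociationRule = AssociationRule()) -> pd.DataFrame:
    """Per-gene regulatory domain.

    The basal domain spans ``basal_upstream`` bp upstream and
    ``basal_downstream`` bp downstream of the TSS (oriented by strand); it is
    then extended in both directions up to ``max_extension`` bp but never
    into a neighbouring gene's basal domain, and clipped at chromosome ends.
    """
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("tss").reset_index(drop=True)
        size = chrom_sizes[chrom]
        basal = []
        for row in sub.itertuples(index=False):
            if row.strand == "+":
                b0 = row.tss - rule.basal_upstream
                b1 = row.tss + rule.basal_downstream
            else:
                b0 = row.tss - rule.basal_downstream
                b1 = row.tss + rule.basal_upstream
            basal.append((max(0, b0), min(size, b1)))
        for i, row in enumerate(sub.itertuples(index=False)):
            b0, b1 = basal[i]
            # extension stops at the nearest neighbouring basal domain; a
            # basal straddling this gene's basal edge blocks extension fully
            left_limit = max((min(e, b0) for j, (s, e) in enumerate(basal)
                              if j != i and s < b0), default=0)
            right_limit = min((max(s, b1) for j, (s, e) in enumerate(basal)
                               if j != i and e > b1), default=size)
            d0 = max(0, b0 - rule.max_extension, left_limit)
            d1 = min(size, b1 + rule.max_extension, right_limit)
            rows.append((row.gene, chrom, min(d0, b0), max(d1, b1), b0, b1))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "basal_start", "basal_end"])


def associate_regions_to_genes(regions: RegionSet, domains: pd.DataFrame
                               ) -> Dict[str, List[str]]:
    """Map each region (``chrom:start-end`` key) to every gene whose regulatory
    domain it overlaps by >= 1 bp."""
    out: Dict[str, List[str]] = {}
    by_chrom = {c: g.sort_values("start") for c, g in domains.groupby("chrom")}
    for row in regions.df.itertuples(index=False):
        key = f"{row.chrom}:{row.start}-{row.end}"
        hits = []
        sub = by_chrom.get(row.chrom)
        if sub is not None:
            mask = (sub["start"].values < row.end) & (sub["end"].values > row.start)
            hits = list(sub.loc[mask, "gene"])
        out[key] = hits
    return out


def fisher_overlap(region_genes: Set[str], de_genes: Set[str], universe: Set[str],
                   alternative: str = "greater") -> Tuple[float, float, np.ndarray]:
    """Fisher's exact test of the 2x2 near-region x DE table over the universe.

    One-sided (enrichment) by default.  Returns (odds ratio, p, table) with
    table rows = near-region yes/no, columns = DE yes/no.
    """
    region_genes = set(region_genes) & set(universe)
    de_genes = set(de_genes) & set(universe)
    a = len(region_genes & de_genes)
    b = len(region_genes - de_genes)
    c = len(de_genes - region_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p), table


def define_candidate_loci(association: Mapping[str, List[str]], de: pd.DataFrame,
                          direction: str = "up", fdr: float = 0.05) -> pd.DataFrame:
    """Candidate loci: genes both significantly DE in the right direction and
    associated with >= 1 group-enriched region.

    ``de`` is a `nb_wald_de` result (indexed by gene, with log2fc and padj);
    ``direction`` 'up' requires log2fc > 0, 'down' < 0.
    """
    near: Dict[str, List[str]] = {}
    for region, genes in association.items():
        for g in genes:
            near.setdefault(g, []).append(region)
    sign = 1.0 if direction == "up" else -1.0
    rows = []
    for gene, row in de.iterrows():
        de_hit = (np.isfinite(row["padj"]) and row["padj"] < fdr
                  and sign * row["log2fc"] > 0)
        if de_hit and gene in near:
            rows.append((gene, ";".join(near[gene]), row["log2fc"], row["padj"]))
    return pd.DataFrame(rows, columns=["gene", "regions", "log2fc", "padj"])


def geneset_overrep(candidates: Set[str], external_list: Set[str],
                    universe: Set[str]) -> Tuple[int, float]:
    """Hypergeometric over-representation of candidates in an external gene set.

    Returns (overlap, p) with p = P(overlap >= observed) when drawing
    ``len(candidates)`` genes from the universe containing
    ``len(external & universe)`` successes.
    """
    candidates = set(candidates) & set(universe)
    external = set(external_list) & set(universe)
    k = len(candidates & external)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(external), len(candidates)))
    return k, p


def variant_region_enrichment(variants: pd.DataFrame, target: RegionSet,
                              background: RegionSet) -> Tuple[float, float, int, int]:
    """Enrichment of variant positions in a target region set.

    Variants (columns chrom, pos) falling in the background are the draws;
    success states are the background bases also covered by the target.
    Returns (fold, p, n_in_target, n_in_background) with fold the ratio of the
    observed target fraction to the bp fraction expected at random.
    """
    bg_bp = background.total_bp()
    inter_bp = int(background.merge().overlap_lengths(target).sum())
    as_regions = RegionSet.from_intervals(
        [(row.chrom, int(row.pos), int(row.pos) + 1, 0.0)
         for row in variants.itertuples(index=False)], raw=True)
    in_bg = as_regions.overlaps_any(background)
    in_both = in_bg & as_regions.overlaps_any(target)
    n_bg, k = int(in_bg.sum()), int(in_both.sum())
    if n_bg == 0 or bg_bp == 0:
        raise ValueError("no variants fall in the background regions")
    p = float(stats.hypergeom.sf(k - 1, bg_bp, inter_bp, n_bg))
    expected_frac = inter_bp / bg_bp
    fold = (k / n_bg) / expected_frac if expected_frac > 0 else np.inf
    if k == 0:
        fold = 0.0
    return fold, p, k, n_bg


def shuffle_enrichment(target: RegionSet, catalog: RegionSet,
                       chrom_sizes: Mapping[str, int], n_shuffles: int = 200,
                       seed: int = 0) -> Tuple[int, float]:
    """Empirical enrichment of target-catalog overlap by interval shuffling.

    Target intervals are relocated uniformly within their own chromosome,
    preserving lengths; the statistic is total bp overlap with the catalog.
    Empirical p = (1 + #{shuffles with overlap >= observed}) / (1 + n).
    """
    rng = np.random.default_rng(seed)
    observed = int(target.overlap_lengths(catalog).sum())
    ge = 0
    lengths = {c: (target.by_chrom(c)["end"] - target.by_chrom(c)["start"]).values
               for c in target.chroms}
    for _ in range(n_shuffles):
        rows = []
        for chrom, lens in lengths.items():
            size = chrom_sizes[chrom]
            for L in lens:
                s = int(rng.integers(0, size - L + 1))
                rows.append((chrom, s, s + int(L), 0.0))
        shuffled = RegionSet.from_intervals(rows, raw=True)
        if int(shuffled.overlap_lengths(catalog).sum()) >= observed:
            ge += 1
    return observed, (1 + ge) / (1 + n_shuffles)
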