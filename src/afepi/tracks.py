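"""Core containers: binned coverage tracks, region sets and the study design.

Coordinates are 0-based half-open throughout.  Coverage is held at fixed bin
resolution per chromosome (the pipeline works from binned read counts, not
individual alignments); region sets wrap a :class:`pandas.DataFrame` with the
BED-like columns ``chrom, start, end, score`` plus free metadata columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = ["CoverageTrack", "RegionSet", "StudyDesign"]

REGION_COLUMNS = ["chrom", "start", "end", "score"]


@dataclass
class CoverageTrack:
    """Fixed-bin read coverage for one sequencing library.

    Parameters
    ----------
    counts
        Mapping chromosome -> per-bin read counts (floats after depth scaling).
    bin_size
        Bin width in bp, shared by all chromosomes.
    total_reads
        Library depth the counts represent.  Defaults to the sum of counts.
    meta
        Free-form provenance flags (e.g. ``depth_scaled``).
    """

    counts: Dict[str, np.ndarray]
    bin_size: int
    total_reads: float = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = {c: np.asarray(v, dtype=float) for c, v in self.counts.items()}
        for c, v in self.counts.items():
            if np.any(v < 0):
                raise ValueError(f"negative counts on {c}")
        if self.total_reads is None:
            self.total_reads = float(sum(v.sum() for v in self.counts.values()))

    @property
    def chroms(self) -> List[str]:
        return list(self.counts)

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) * self.bin_size for c, v in self.counts.items()}

    def same_binning(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.counts.items()},
            self.bin_size,
            self.total_reads,
            dict(self.meta),
        )

    # ---- bedGraph I/O -----------------------------------------------------
    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.counts:
                v = self.counts[chrom]
                for i, x in enumerate(v):
                    if x != 0:
                        fh.write(
                            f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{x:g}\n"
                        )

    @classmethod
    def from_bedgraph(cls, path, bin_size: int, chrom_sizes: Mapping[str, int]) -> "CoverageTrack":
        counts = {
            c: np.zeros(int(np.ceil(size / bin_size)), dtype=float)
            for c, size in chrom_sizes.items()
        }
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end, value = line.split()[:4]
                s, e, x = int(start), int(end), float(value)
                if (e - s) % bin_size or s % bin_size:
                    raise ValueError("bedGraph intervals must be bin-aligned")
                counts[chrom][s // bin_size : e // bin_size] = x
        return cls(counts, bin_size)


class RegionSet:
    """Sorted genomic intervals with scores and per-region metadata."""

    def __init__(self, df: Optional[pd.DataFrame] = None, raw: bool = False):
        if df is None or len(df) == 0:
            cols = REGION_COLUMNS if df is None else list(df.columns)
            for c in REGION_COLUMNS:
                if c not in cols:
                    cols.append(c)
            df = pd.DataFrame({c: [] for c in cols})
        df = df.copy()
        if "score" not in df.columns:
            df["score"] = 0.0
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and np.any(df["end"].values <= df["start"].values):
            raise ValueError("regions must satisfy start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self.df = df
        self.raw = raw  # raw sets may contain overlaps

    @classmethod
    def from_intervals(cls, rows: Iterable[tuple], columns: Optional[List[str]] = None,
                       raw: bool = False) -> "RegionSet":
        columns = columns or REGION_COLUMNS
        return cls(pd.DataFrame(list(rows), columns=columns), raw=raw)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    @property
    def chroms(self) -> List[str]:
        return sorted(self.df["chrom"].unique())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).values

    def total_bp(self) -> int:
        merged = self.merge(gap=0)
        return int(merged.lengths().sum())

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    # ---- set algebra ------------------------------------------------------
    def merge(self, gap: int = 0) -> "RegionSet":
        """Merge intervals with gaps <= ``gap``; scores aggregate by max."""
        rows = []
        for chrom in self.chroms:
            sub = self.by_chrom(chrom)
            s, e = iv.merge_intervals(sub["start"].values, sub["end"].values, gap=gap)
            # max score over source intervals falling in each merged interval
            for ms, me in zip(s, e):
                mask = (sub["start"].values < me) & (sub["end"].values > ms)
                score = float(sub["score"].values[mask].max()) if mask.any() else 0.0
                rows.append((chrom, int(ms), int(me), score))
        return RegionSet.from_intervals(rows)

    def subtract(self, other: "RegionSet", min_len: int = 1) -> "RegionSet":
        """Remove every base covered by ``other``; keep fragments >= ``min_len``."""
        rows = []
        extra_cols = [c for c in self.df.columns if c not in ("chrom", "start", "end")]
        for chrom in self.chroms:
            sub = self.by_chrom(chrom)
            o = other.by_chrom(chrom)
            os_, oe_ = iv.merge_intervals(o["start"].values, o["end"].values, gap=0)
            fs, fe, src = iv.subtract_intervals(sub["start"].values, sub["end"].values, os_, oe_)
            for s, e, i in zip(fs, fe, src):
                if e - s >= min_len:
                    rows.append((chrom, int(s), int(e)) + tuple(sub.iloc[i][c] for c in extra_cols))
        return RegionSet.from_intervals(rows, columns=["chrom", "start", "end"] + extra_cols)

    def overlap_lengths(self, other: "RegionSet") -> np.ndarray:
        """Per-region bp overlapped by ``other`` (merged before measuring)."""
        out = np.zeros(len(self), dtype=np.int64)
        merged = {c: iv.merge_intervals(other.by_chrom(c)["start"].values,
                                        other.by_chrom(c)["end"].values, gap=0)
                  for c in other.chroms}
        for i, row in enumerate(self.df.itertuples(index=False)):
            if row.chrom in merged:
                s, e = merged[row.chrom]
                out[i] = iv.overlap_length(int(row.start), int(row.end), s, e)
        return out

    def overlaps_any(self, other: "RegionSet") -> np.ndarray:
        return self.overlap_lengths(other) > 0

    # ---- I/O --------------------------------------------------------------
    def to_bed(self, path, name_prefix: str = "region", score_col: str = "score") -> None:
        """Write BED6; score column is -10*log10(p)-style, capped at 1000."""
        with open(path, "w") as fh:
            for i, row in enumerate(self.df.itertuples(index=False)):
                score = min(1000, int(round(float(getattr(row, score_col, 0.0)) * 10)))
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name_prefix}_{i}\t{score}\t.\n")

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                score = float(parts[4]) / 10 if len(parts) > 4 else 0.0
                rows.append((chrom, start, end, score))
        return cls.from_intervals(rows)


@dataclass
class StudyDesign:
    """Sample sheet: disease status (AF/SR), anatomical side (LA/RA), donor, batch."""

    table: pd.DataFrame  # columns: sample, disease, side, donor, batch

    def __post_init__(self):
        required = {"sample", "disease", "side"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        bad = set(self.table["disease"]) - {"AF", "SR"}
        if bad:
            raise ValueError(f"unknown disease levels: {bad}")
        bad = set(self.table["side"]) - {"LA", "RA"}
        if bad:
            raise ValueError(f"unknown side levels: {bad}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> List[str]:
        return list(self.table["sample"])

    def group_of(self, sample: str) -> str:
        row = self.table[self.table["sample"] == sample].iloc[0]
        return f"{row['disease']}-{row['side']}"

    @property
    def groups(self) -> Dict[str, List[str]]:
        g: Dict[str, List[str]] = {}
        for row in self.table.itertuples(index=False):
            g.setdefault(f"{row.disease}-{row.side}", []).append(row.sample)
        return g

    @property
    def disease_groups(self) -> Dict[str, List[str]]:
        g: Dict[str, List[str]] = {}
        for row in self.table.itertuples(index=False):
            g.setdefault(row.disease, []).append(row.sample)
        return g

    def subset(self, samples: Iterable[str]) -> "StudyDesign":
        keep = self.table[self.table["sample"].isin(list(samples))]
        return StudyDesign(keep.copy())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t"))
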