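"""Plain-text I/O: allele-depth TSV, BED, bedGraph and run configuration.

File conventions: the allele-depth TSV is 1-based (VCF-style positions) and
converted to the package's 0-based internal coordinates on read; BED and
bedGraph are 0-based half-open as usual.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .tracks import AlleleDepthTable, BinnedTrack, IntervalSet

__all__ = [
    "read_allele_depth_tsv",
    "write_allele_depth_tsv",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_TSV_COLUMNS = ["chrom", "pos", "mat_s", "pat_s", "mat_g1", "pat_g1"]


def read_allele_depth_tsv(path) -> AlleleDepthTable:
    """Read a phased allele-depth table (tab-separated, 1-based positions)."""
    df = pd.read_csv(path, sep="\t", comment=None, header=None, skiprows=_count_header(path),
                     names=_TSV_COLUMNS, dtype={"chrom": str})
    missing = df.columns[df.isna().any()].tolist()
    if missing:
        bad = int(df[df.isna().any(axis=1)].index[0]) + 1
        raise ValueError(f"malformed line {bad}: missing value in column(s) {missing}")
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    if (df["pos"] < 0).any():
        raise ValueError("position column must be 1-based (found 0)")
    if not df[["chrom", "pos"]].equals(df[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)):
        logger.warning("input not sorted; sorting by (chrom, pos)")
    return AlleleDepthTable(df)


def _count_header(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def write_allele_depth_tsv(table: AlleleDepthTable, path) -> None:
    """Write the table with 1-based positions and a '#'-prefixed header."""
    df = table.df.copy()
    df["pos"] = df["pos"] + 1
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


_BED_NAMES = ["chrom", "start", "end", "name", "score", "strand", "thickStart", "thickEnd", "itemRgb"]


def read_bed(path) -> IntervalSet:
    """Read BED3-BED9; track lines and '#' comments are skipped."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {ln}: fewer than 3 BED columns")
            rows.append(fields[:9])
    if not rows:
        return IntervalSet.empty()
    width = max(len(r) for r in rows)
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in rows], columns=_BED_NAMES[:width])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    df = intervals.df
    cols = [c for c in _BED_NAMES if c in df.columns]
    # BED columns are positional: stop at the first absent one
    out_cols = []
    for c in _BED_NAMES:
        if c in df.columns:
            out_cols.append(c)
        else:
            break
    df[out_cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(tracks: Mapping[str, BinnedTrack] | BinnedTrack, path) -> None:
    """Write covered bins as bedGraph, run-length merging equal neighbours."""
    if isinstance(tracks, BinnedTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom in tracks:
            t = tracks[chrom]
            w = t.bin_width
            cur = None  # (start_bin, end_bin, value)
            for i in np.flatnonzero(t.covered):
                v = t.values[i]
                if cur is not None and i == cur[1] and v == cur[2]:
                    cur = (cur[0], i + 1, v)
                else:
                    if cur is not None:
                        fh.write(f"{chrom}\t{cur[0] * w}\t{min(cur[1] * w, t.length)}\t{cur[2]:.10g}\n")
                    cur = (int(i), int(i) + 1, v)
            if cur is not None:
                fh.write(f"{chrom}\t{cur[0] * w}\t{min(cur[1] * w, t.length)}\t{cur[2]:.10g}\n")


def read_bedgraph(path, bin_width: int, chrom_lengths: Mapping[str, int]) -> dict:
    """Load a bedGraph into fixed-width tracks (records must align to bins)."""
    out = {c: BinnedTrack.empty(c, l, bin_width) for c, l in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     comment="#")
    for rec in df.itertuples(index=False):
        t = out[rec.chrom]
        lo, hi = rec.start // bin_width, -(-rec.end // bin_width)
        t.values[lo:hi] = rec.value
        t.covered[lo:hi] = True
    return out


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline parameters; serialized beside every run's outputs."""

    bin_width: int = 500
    sigma: float = 100_000.0
    scale_factor: float = 1.4
    diff_threshold: float = 0.02
    max_gap: int = 250_000
    min_size: int = 50_000
    core_threshold: float = 0.10
    core_max_gap: int = 50_000
    core_min_size: int = 50_000
    fdr: float = 0.05
    mean_depth: float = 25.0
    seed: int = 0
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)
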