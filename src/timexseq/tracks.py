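"""Core genomic containers: binned tracks, interval sets and allele-depth tables.

All coordinates are 0-based, half-open internally.  1-based positions appear
only at the TSV/VCF file boundary (see :mod:`timexseq.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["BinnedTrack", "IntervalSet", "AlleleDepthTable", "TrackDict"]

#: Multi-chromosome tracks are plain dicts keyed by chromosome name.
TrackDict = dict


@dataclass
class BinnedTrack:
    """A fixed-width binned numeric track on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    bin_width : int
        Width of each bin in base pairs.
    values : ndarray of float
        One value per bin.  Values of uncovered bins carry no meaning.
    covered : ndarray of bool
        Per-bin flag; ``False`` marks bins with no underlying data.
    """

    chrom: str
    bin_width: int
    values: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.values.shape != self.covered.shape or self.values.ndim != 1:
            raise ValueError("values and covered must be 1-D arrays of equal length")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def length(self) -> int:
        """Chromosome span covered by the binning, in bp."""
        return self.n_bins * self.bin_width

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return self.bin_starts() + self.bin_width / 2.0

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.chrom, self.bin_width, self.values.copy(), self.covered.copy())

    @classmethod
    def empty(cls, chrom: str, chrom_length: int, bin_width: int) -> "BinnedTrack":
        n = -(-int(chrom_length) // int(bin_width))  # ceil division
        return cls(chrom, bin_width, np.zeros(n), np.zeros(n, dtype=bool))


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class IntervalSet:
    """Sorted, strand-agnostic genomic intervals with optional name/score/strand.

    Intervals are stored 0-based half-open and kept sorted by
    ``(chrom, start, end)``.  Overlap queries run in ``O(n log m)`` against a
    merged copy of the other set.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires a '{col}' column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval coordinates")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"start >= end at {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str] | str,
        start: Sequence[int],
        end: Sequence[int],
        **extra,
    ) -> "IntervalSet":
        start = np.asarray(start, dtype=np.int64)
        if isinstance(chrom, str):
            chrom = np.repeat(chrom, start.size)
        data = {"chrom": np.asarray(chrom), "start": start, "end": np.asarray(end, dtype=np.int64)}
        for key, val in extra.items():
            if val is not None:
                data[key] = np.asarray(val)
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame({"chrom": [], "start": [], "end": []}))

    @classmethod
    def concat(cls, sets: Iterable["IntervalSet"]) -> "IntervalSet":
        frames = [s.df for s in sets]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator:
        return self.df.itertuples(index=False)

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def total_length(self) -> int:
        """Total bp covered, counting overlapping bases once."""
        merged = self.merged()
        return int((merged.ends - merged.starts).sum())

    # -- operations ---------------------------------------------------------
    def merged(self, gap: int = 0) -> "IntervalSet":
        """Union of intervals, merging any pair closer than ``gap`` bp."""
        if len(self) == 0:
            return IntervalSet.empty()
        rows = []
        for chrom, grp in self.df.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e + gap:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per own interval: does it overlap ``other`` by >= 1 bp?"""
        out = np.zeros(len(self), dtype=bool)
        if len(self) == 0 or len(other) == 0:
            return out
        merged = other.merged()
        by_chrom = {c: g for c, g in merged.df.groupby("chrom")}
        for chrom, grp in self.df.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            ostarts = by_chrom[chrom]["start"].to_numpy()
            oends = by_chrom[chrom]["end"].to_numpy()
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            # last other-interval starting before our end; overlap iff it ends after our start
            idx = np.searchsorted(ostarts, e, side="left") - 1
            hit = (idx >= 0) & (oends[np.clip(idx, 0, None)] > s)
            out[grp.index.to_numpy()] = hit
        return out

    def expand(self, pad: int, chrom_lengths: Mapping[str, int] | None = None) -> "IntervalSet":
        df = self.df.copy()
        df["start"] = np.maximum(df["start"] - pad, 0)
        df["end"] = df["end"] + pad
        if chrom_lengths is not None:
            caps = df["chrom"].map(chrom_lengths)
            df["end"] = np.minimum(df["end"], caps.astype(np.int64))
        return IntervalSet(df)

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self.df[np.asarray(mask, dtype=bool)])


@dataclass
class AlleleDepthTable:
    """Phased per-SNP read depths for both homologs in the S and G1 fractions.

    Wraps a DataFrame with columns ``chrom, pos, mat_s, pat_s, mat_g1, pat_g1``
    where ``pos`` is the 0-based SNP coordinate.  Depth columns may be floats
    (expected counts are used by the simulation benchmark).
    """

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("chrom", "pos", "mat_s", "pat_s", "mat_g1", "pat_g1")
    DEPTH_COLUMNS = ("mat_s", "pat_s", "mat_g1", "pat_g1")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"allele-depth table is missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise ValueError("negative SNP position")
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    @property
    def chrom_names(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def depth_column(self, homolog: str, fraction: str) -> str:
        hom = {"maternal": "mat", "paternal": "pat"}.get(homolog)
        if hom is None:
            raise ValueError(f"unknown homolog {homolog!r} (use 'maternal' or 'paternal')")
        frac = fraction.lower()
        if frac not in ("s", "g1"):
            raise ValueError(f"unknown fraction {fraction!r} (use 'S' or 'G1')")
        return f"{hom}_{frac}"

    def copy(self) -> "AlleleDepthTable":
        return AlleleDepthTable(self.df.copy())
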