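"""Build smoothed, scaled S/G1 replication-timing profiles from allele depths.

The pipeline follows the timing-by-copy-number logic: read depths of phased
heterozygous SNPs are summed in fixed windows (500 bp by default), each track
is normalized to its total read count, tracks are smoothed with a Gaussian
kernel (sigma = 100 kb by default), and the per-bin S/G1 ratio is scaled by
1.4 so that values land near the theoretical 1-2 range (G1 cells carry two
copies of every locus; S cells carry between two and four, in proportion to
how early the locus replicates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .tracks import AlleleDepthTable, BinnedTrack, IntervalSet

__all__ = [
    "TimexProfile",
    "bin_depths",
    "normalize_track",
    "normalize_tracks",
    "gaussian_smooth",
    "timex_ratio",
    "build_profile",
    "low_snp_mask",
    "apply_mask",
    "hires_profile",
    "saturate_outliers",
    "combine_homolog_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class TimexProfile:
    """Per-bin scaled S/G1 ratio with a coverage mask, one per homolog.

    ``tracks`` maps chromosome name to a :class:`BinnedTrack` of scaled
    ratios.  ``homolog`` is ``maternal``, ``paternal`` or ``combined``.
    """

    tracks: dict
    homolog: str
    sigma: float
    scale_factor: float = 1.4

    @property
    def bin_width(self) -> int:
        return next(iter(self.tracks.values())).bin_width

    def track(self, chrom: str) -> BinnedTrack:
        return self.tracks[chrom]

    def covered_values(self) -> np.ndarray:
        return np.concatenate([t.values[t.covered] for t in self.tracks.values()])


def bin_depths(
    table: AlleleDepthTable,
    homolog: str,
    fraction: str,
    bin_width: int,
    chrom_lengths: Mapping[str, int],
) -> dict:
    """Sum per-SNP depths into fixed-width bins; SNP-free bins are uncovered.

    A SNP at 0-based position p contributes to bin ``p // bin_width``
    (half-open window convention).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    col = table.depth_column(homolog, fraction)
    out = {}
    for chrom, length in chrom_lengths.items():
        track = BinnedTrack.empty(chrom, length, bin_width)
        sub = table.df[table.df["chrom"] == chrom]
        if len(sub):
            idx = (sub["pos"].to_numpy() // bin_width).astype(np.int64)
            if idx.max() >= track.n_bins:
                raise ValueError(f"SNP beyond end of {chrom}")
            track.values[:] = np.bincount(idx, weights=sub[col].to_numpy(), minlength=track.n_bins)
            track.covered[:] = np.bincount(idx, minlength=track.n_bins) > 0
        out[chrom] = track
    return out


def normalize_track(track: BinnedTrack) -> BinnedTrack:
    """Divide covered values by the track-wide total of covered values."""
    return normalize_tracks({track.chrom: track})[track.chrom]


def normalize_tracks(tracks: Mapping[str, BinnedTrack]) -> dict:
    """Normalize a multi-chromosome track to its genome-wide covered total."""
    total = sum(float(t.values[t.covered].sum()) for t in tracks.values())
    if total <= 0:
        raise ValueError("cannot normalize a track with zero total signal")
    out = {}
    for chrom, t in tracks.items():
        new = t.copy()
        new.values[new.covered] = new.values[new.covered] / total
        out[chrom] = new
    return out


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * sigma_bins))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    return np.exp(-(x**2) / (2.0 * sigma_bins**2))


def gaussian_smooth(track: BinnedTrack, sigma: float) -> BinnedTrack:
    """Gap-aware Gaussian smoothing.

    Each covered output bin is the weighted mean of covered input bins with
    weights exp(-d^2 / 2 sigma^2) on the genomic distance d between bin
    centers, truncated at 4 sigma and renormalized over covered bins only,
    so coverage gaps neither leak zeros into the average nor shrink it.
    Uncovered bins stay uncovered.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    kernel = _gaussian_kernel(sigma / track.bin_width)
    cov = track.covered.astype(np.float64)
    vals = np.where(track.covered, track.values, 0.0)
    num = signal.oaconvolve(vals, kernel, mode="same")
    den = signal.oaconvolve(cov, kernel, mode="same")
    out = track.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    out.values = np.where(track.covered, smoothed, 0.0)
    return out


def smooth_tracks(tracks: Mapping[str, BinnedTrack], sigma: float) -> dict:
    return {c: gaussian_smooth(t, sigma) for c, t in tracks.items()}


def timex_ratio(
    s: Mapping[str, BinnedTrack] | BinnedTrack,
    g1: Mapping[str, BinnedTrack] | BinnedTrack,
    scale_factor: float = 1.4,
    homolog: str = "combined",
    sigma: float = float("nan"),
) -> TimexProfile:
    """Per-bin scaled S/G1 ratio of two normalized, smoothed tracks.

    Bins covered in only one input, or with a zero G1 value, are uncovered
    in the output (SNP deserts make zero-G1 bins routine; they are masked
    with a warning rather than raising).
    """
    if isinstance(s, BinnedTrack):
        s = {s.chrom: s}
    if isinstance(g1, BinnedTrack):
        g1 = {g1.chrom: g1}
    out = {}
    n_zero = 0
    for chrom in s:
        st, gt = s[chrom], g1[chrom]
        if st.bin_width != gt.bin_width or st.n_bins != gt.n_bins:
            raise ValueError(f"S and G1 binning differs on {chrom}")
        covered = st.covered & gt.covered
        zero_g1 = covered & (gt.values == 0)
        n_zero += int(zero_g1.sum())
        covered = covered & ~zero_g1
        values = np.zeros(st.n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = st.values / gt.values
        values[covered] = scale_factor * ratio[covered]
        out[chrom] = BinnedTrack(chrom, st.bin_width, values, covered)
    if n_zero:
        logger.warning("masked %d bins with zero G1 signal", n_zero)
    return TimexProfile(out, homolog=homolog, sigma=sigma, scale_factor=scale_factor)


def build_profile(
    table: AlleleDepthTable,
    homolog: str,
    chrom_lengths: Mapping[str, int],
    bin_width: int = 500,
    sigma: float = 100_000.0,
    scale_factor: float = 1.4,
) -> TimexProfile:
    """Full allele-specific pipeline: bin, normalize, smooth, ratio, scale."""
    s = bin_depths(table, homolog, "S", bin_width, chrom_lengths)
    g1 = bin_depths(table, homolog, "G1", bin_width, chrom_lengths)
    s = smooth_tracks(normalize_tracks(s), sigma)
    g1 = smooth_tracks(normalize_tracks(g1), sigma)
    return timex_ratio(s, g1, scale_factor, homolog=homolog, sigma=sigma)


def low_snp_mask(
    positions: Mapping[str, np.ndarray] | np.ndarray,
    min_density: float,
    window: int,
    chrom_lengths: Mapping[str, int] | int,
    chrom: str = "chr1",
) -> IntervalSet:
    """Intervals where SNP density per ``window`` falls below ``min_density``.

    ``min_density`` is in SNPs per bp (e.g. 1/5000 for one SNP per 5 kb).
    Adjacent low-density windows are merged.
    """
    if isinstance(chrom_lengths, (int, np.integer)):
        chrom_lengths = {chrom: int(chrom_lengths)}
        positions = {chrom: np.asarray(positions)}
    pieces = []
    for chrom_name, length in chrom_lengths.items():
        pos = np.sort(np.asarray(positions.get(chrom_name, []), dtype=np.int64))
        n_win = -(-length // window)
        counts = np.bincount(pos // window, minlength=n_win)[:n_win]
        widths = np.full(n_win, window, dtype=np.int64)
        widths[-1] = length - (n_win - 1) * window
        low = counts / widths < min_density
        if low.any():
            idx = np.flatnonzero(low)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [idx.size - 1]])
            for a, b in zip(run_starts, run_ends):
                pieces.append((chrom_name, idx[a] * window, min((idx[b] + 1) * window, length)))
    if not pieces:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(pieces, columns=["chrom", "start", "end"]))


def apply_mask(tracks: Mapping[str, BinnedTrack], mask: IntervalSet) -> dict:
    """Uncover all bins intersecting the mask.  Values are left untouched."""
    out = {c: t.copy() for c, t in tracks.items()}
    for row in mask:
        track = out.get(row.chrom)
        if track is None:
            continue
        lo = row.start // track.bin_width
        hi = -(-row.end // track.bin_width)
        track.covered[lo:hi] = False
    return out


def hires_profile(
    s_reads: Mapping[str, BinnedTrack],
    g1_reads: Mapping[str, BinnedTrack],
    sigma: float = 20_000.0,
    outlier_ratio: float = 2.4,
    robust: bool = False,
) -> TimexProfile:
    """High-resolution non-allele-specific profile from 1 kb read tracks.

    Tracks are normalized to total reads, the raw per-bin S/G1 ratio is
    computed, bins with ratio above ``outlier_ratio`` are dropped, the ratio
    track is Gaussian-smoothed (sigma = 20 kb) and finally indexed so the
    covered minimum maps to 1 and the maximum to 2.  With ``robust`` the
    0.1/99.9 covered percentiles anchor the indexing instead of min/max.
    """
    s = normalize_tracks(s_reads)
    g1 = normalize_tracks(g1_reads)
    raw = timex_ratio(s, g1, scale_factor=1.0, sigma=sigma)
    for chrom, t in raw.tracks.items():
        t.covered &= ~(t.covered & (t.values > outlier_ratio))
    smooth = {c: gaussian_smooth(t, sigma) for c, t in raw.tracks.items()}
    allv = np.concatenate([t.values[t.covered] for t in smooth.values()])
    if allv.size == 0:
        raise ValueError("no covered bins left after outlier removal")
    if robust:
        lo, hi = np.percentile(allv, [0.1, 99.9])
    else:
        lo, hi = float(allv.min()), float(allv.max())
    if hi <= lo:
        raise ValueError("cannot index a constant profile between 1 and 2")
    for t in smooth.values():
        t.values[t.covered] = 1.0 + (t.values[t.covered] - lo) / (hi - lo)
        np.clip(t.values, 1.0, 2.0, out=t.values)
    return TimexProfile(smooth, homolog="combined", sigma=sigma, scale_factor=1.0)


def saturate_outliers(track: BinnedTrack, n_sd: float = 3.0) -> BinnedTrack:
    """Cap covered values at mean + ``n_sd`` standard deviations."""
    vals = track.values[track.covered]
    if vals.size < 2:
        raise ValueError("need at least two covered bins")
    cap = float(vals.mean() + n_sd * vals.std(ddof=0))
    out = track.copy()
    out.values[out.covered & (out.values > cap)] = cap
    return out


def combine_homolog_tables(tables: Sequence[AlleleDepthTable]) -> AlleleDepthTable:
    """Sum per-SNP depths across individuals (outer union of SNP positions)."""
    if not tables:
        raise ValueError("no tables to combine")
    for t in tables:
        if t.df.duplicated(["chrom", "pos"]).any():
            raise ValueError("conflicting duplicate positions within one table")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    combined = df.groupby(["chrom", "pos"], as_index=False, sort=True)[
        list(AlleleDepthTable.DEPTH_COLUMNS)
    ].sum()
    return AlleleDepthTable(combined)
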