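"""Nascent-strand peak post-processing and genomic-feature association.

Replication-origin peak sets (e.g. from nascent-strand sequencing) are
width-normalized and rank-pruned, then scored for association with feature
windows (CpG islands as given; 1 kb windows on transcription start sites;
400 bp windows on G-quadruplex and DNase-hypersensitive-site midpoints).
A peak is associated with a feature when they overlap by at least one base
pair.  Enrichment is quantified against bootstrap placements of the peaks
inside a stated territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ards import ArdRecord
from .ripples import randomize_intervals
from .tracks import BinnedTrack, IntervalSet

__all__ = [
    "FeatureWindows",
    "make_feature_windows",
    "normalize_peak_widths",
    "top_n_peaks",
    "percent_associated",
    "bootstrap_enrichment",
    "fraction_origin_stats",
    "gc_repeat_content",
    "repeat_content",
    "ard_allele_ns_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureWindows:
    """Feature sets converted to the window conventions used for association."""

    cpg: IntervalSet | None = None
    tss: IntervalSet | None = None
    g4: IntervalSet | None = None
    dhs: IntervalSet | None = None

    def items(self):
        return [(k, v) for k, v in vars(self).items() if v is not None]


def _centered_windows(
    intervals: IntervalSet, width: int, chrom_lengths: Mapping[str, int] | None
) -> IntervalSet:
    mid = (intervals.starts + intervals.ends) // 2
    start = np.maximum(mid - width // 2, 0)
    end = mid + (width - width // 2)
    out = IntervalSet.from_arrays(intervals.chroms, start, end)
    if chrom_lengths is not None:
        df = out.df
        caps = df["chrom"].map(chrom_lengths).astype(np.int64)
        df["end"] = np.minimum(df["end"], caps)
        out = IntervalSet(df[df["start"] < df["end"]])
    return out


def make_feature_windows(
    cpg: IntervalSet | None = None,
    tss: IntervalSet | None = None,
    g4: IntervalSet | None = None,
    dhs: IntervalSet | None = None,
    tss_width: int = 1000,
    motif_width: int = 400,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureWindows:
    """Build association windows: CpG intervals as given, 1 kb on TSS,
    400 bp centered on G4/DHS midpoints, clipped to chromosome bounds."""
    return FeatureWindows(
        cpg=cpg,
        tss=None if tss is None else _centered_windows(tss, tss_width, chrom_lengths),
        g4=None if g4 is None else _centered_windows(g4, motif_width, chrom_lengths),
        dhs=None if dhs is None else _centered_windows(dhs, motif_width, chrom_lengths),
    )


def normalize_peak_widths(peaks: IntervalSet, width: int = 400) -> IntervalSet:
    """Replace each peak by a fixed-width window on its midpoint, then merge.

    Merging collapses nearby peaks into one window, which is why width
    normalization reduces the peak count (about half in dense peak sets).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    return _centered_windows(peaks, width, None).merged()


def top_n_peaks(peaks: IntervalSet, n: int = 100_000) -> IntervalSet:
    """Highest-scoring n peaks; ties broken stably by genomic position."""
    if "score" not in peaks.df.columns:
        raise ValueError("peaks need a 'score' column")
    df = peaks.df.sort_values(["chrom", "start", "end"], kind="stable")
    df = df.sort_values("score", ascending=False, kind="stable")
    return IntervalSet(df.head(n))


def percent_associated(peaks: IntervalSet, features: IntervalSet) -> float:
    """Percent of peaks overlapping any feature window by >= 1 bp."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    return 100.0 * float(peaks.overlaps_any(features).mean())


def bootstrap_enrichment(
    peaks: IntervalSet,
    features: IntervalSet,
    territory: IntervalSet,
    iters: int = 100,
    seed: int = 0,
) -> dict:
    """Observed association vs the average over random peak placements.

    Each iteration re-places the peaks uniformly within the territory
    (widths preserved) and records the percent associated; the enrichment
    fold is observed / mean(random).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    observed = percent_associated(peaks, features)
    rng = np.random.default_rng(seed)
    random_pcts = [
        percent_associated(randomize_intervals(peaks, territory, rng), features)
        for _ in range(iters)
    ]
    mean_random = float(np.mean(random_pcts))
    if mean_random == 0:
        logger.warning("no random placement hit a feature; enrichment fold undefined")
        fold = float("nan")
    else:
        fold = observed / mean_random
    return {
        "observed_pct": observed,
        "random_pct_mean": mean_random,
        "random_pct_sd": float(np.std(random_pcts, ddof=1)) if iters > 1 else float("nan"),
        "fold": fold,
        "iters": iters,
    }


def fraction_origin_stats(
    ns_reads: Mapping[str, BinnedTrack],
    ns_peaks: IntervalSet,
    fractions: Sequence[IntervalSet],
    density_window: int = 5000,
) -> pd.DataFrame:
    """Per-S-fraction origin statistics.

    For each fraction (S1..Sk): mean nascent-strand reads per
    ``density_window``, number of peaks with their per-Mb rate, mean peak
    area (score column if present, else width), and the median gap between
    consecutive peaks.  Fractions with fewer than two peaks get NaN for the
    inter-peak distance.
    """
    rows = []
    for i, frac in enumerate(fractions, start=1):
        frac_len = frac.total_length()
        # read density: mean over fraction bins, scaled to the window
        tot_reads, tot_bins = 0.0, 0
        for iv in frac:
            track = ns_reads.get(iv.chrom)
            if track is None:
                continue
            lo, hi = iv.start // track.bin_width, -(-iv.end // track.bin_width)
            cov = track.covered[lo:hi]
            tot_reads += float(track.values[lo:hi][cov].sum())
            tot_bins += int(cov.sum())
        density = (
            tot_reads / tot_bins * (density_window / next(iter(ns_reads.values())).bin_width)
            if tot_bins
            else float("nan")
        )
        inside = ns_peaks.subset(ns_peaks.overlaps_any(frac))
        n_peaks = len(inside)
        if "area" in inside.df.columns and n_peaks:
            mean_area = float(inside.df["area"].mean())
        elif "score" in inside.df.columns and n_peaks:
            mean_area = float(inside.df["score"].mean())
        else:
            mean_area = float(inside.widths().mean()) if n_peaks else float("nan")
        gaps = []
        for _, grp in inside.df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts.size >= 2:
                gaps.extend((starts[1:] - ends[:-1]).tolist())
        median_gap = float(np.median(gaps)) if gaps else float("nan")
        rows.append(
            {
                "fraction": f"S{i}",
                "length_bp": frac_len,
                "mean_reads_per_window": density,
                "n_peaks": n_peaks,
                "peaks_per_mb": n_peaks / frac_len * 1e6 if frac_len else float("nan"),
                "mean_peak_area": mean_area,
                "median_interpeak_bp": median_gap,
            }
        )
    return pd.DataFrame(rows)


def gc_repeat_content(
    sequence: str,
    window: int = 100_000,
    step: int = 10_000,
    chrom: str = "chr1",
) -> BinnedTrack:
    """Sliding-window percent G+C of a sequence, evaluated every ``step`` bp.

    The value at step i is the GC percentage of the ``window``-bp window
    centered on the step midpoint, truncated at the sequence ends.
    """
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_gc = np.isin(seq, [b"G", b"C"]).astype(np.float64)
    is_base = np.isin(seq, [b"A", b"C", b"G", b"T"]).astype(np.float64)
    cum_gc = np.concatenate([[0.0], np.cumsum(is_gc)])
    cum_base = np.concatenate([[0.0], np.cumsum(is_base)])
    n = len(seq)
    n_steps = -(-n // step)
    values = np.zeros(n_steps)
    covered = np.zeros(n_steps, dtype=bool)
    for i in range(n_steps):
        mid = i * step + step // 2
        lo = max(mid - window // 2, 0)
        hi = min(mid + window // 2, n)
        bases = cum_base[hi] - cum_base[lo]
        if bases > 0:
            values[i] = 100.0 * (cum_gc[hi] - cum_gc[lo]) / bases
            covered[i] = True
    return BinnedTrack(chrom, step, values, covered)


def repeat_content(
    repeats: IntervalSet,
    chrom_length: int,
    window: int = 100_000,
    step: int = 10_000,
    chrom: str = "chr1",
) -> BinnedTrack:
    """Percent of repeat-masked bases per sliding window."""
    cover = np.zeros(chrom_length + 1)
    sub = repeats.df[repeats.df["chrom"] == chrom]
    for s, e in zip(sub["start"], sub["end"]):
        cover[min(s, chrom_length)] += 1
        cover[min(e, chrom_length)] -= 1
    depth = np.clip(np.cumsum(cover[:-1]), 0, 1)
    cum = np.concatenate([[0.0], np.cumsum(depth)])
    n_steps = -(-chrom_length // step)
    values = np.zeros(n_steps)
    for i in range(n_steps):
        mid = i * step + step // 2
        lo = max(mid - window // 2, 0)
        hi = min(mid + window // 2, chrom_length)
        values[i] = 100.0 * (cum[hi] - cum[lo]) / (hi - lo)
    return BinnedTrack(chrom, step, values, np.ones(n_steps, dtype=bool))


def ard_allele_ns_ratio(
    ards: Sequence[ArdRecord],
    ns_mat_reads: Sequence[float],
    ns_pat_reads: Sequence[float],
) -> tuple:
    """Per-ARD maternal/paternal nascent-strand read ratio vs signed delay.

    ARDs with a zero paternal count are skipped with a warning.  Returns
    (DataFrame with ratio and delay_minutes columns, Pearson r).
    """
    if not (len(ards) == len(ns_mat_reads) == len(ns_pat_reads)):
        raise ValueError("one count pair per ARD required")
    rows = []
    for ard, m, p in zip(ards, ns_mat_reads, ns_pat_reads):
        if p <= 0 or m <= 0:
            logger.warning("skipping ARD %s:%d-%d with non-positive NS count", ard.chrom, ard.start, ard.end)
            continue
        rows.append({"chrom": ard.chrom, "start": ard.start, "end": ard.end,
                     "ratio": m / p, "delay_minutes": ard.delay_minutes})
    df = pd.DataFrame(rows)
    if len(df) >= 3 and df["ratio"].nunique() > 1 and df["delay_minutes"].nunique() > 1:
        r = float(stats.pearsonr(df["ratio"], df["delay_minutes"])[0])
    else:
        r = float("nan")
    return df, r
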