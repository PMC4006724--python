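"""Synthetic phased allele-depth data and the binomial spike-in simulator.

The generator emulates the statistical structure that the S/G1 timing method
assumes: heterogeneous SNP density (haplotype blocks of high and low
heterozygosity), megabase-scale replication-timing domains with values in the
theoretical 1-2 range (1 = latest, 2 = earliest replication), and
Poisson-distributed per-SNP sequencing depth in each cell-cycle fraction.

Asynchrony is introduced exactly the way the in-silico spike-in study defines
it: the total (S+G1) read count of each SNP inside a spiked region on one
homolog is inflated by a fixed percentage, the extra reads are assigned to
the S fraction, and every SNP (spiked or not) is then passed through a
binomial resampler parameterised by its (S, S+G1) counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .tracks import AlleleDepthTable, BinnedTrack, IntervalSet

__all__ = [
    "SyntheticGenomeSpec",
    "SpikeRegionSpec",
    "gen_snp_positions",
    "gen_timing_landscape",
    "gen_depths",
    "control_pair",
    "resample_binomial",
    "spike_regions",
    "expected_spiked_depths",
    "place_random_regions",
]

logger = logging.getLogger(__name__)

# Sub-stream identifiers so each generator stage draws from its own
# reproducible stream derived from the single user-facing seed.
_STAGE_POSITIONS = 1
_STAGE_LANDSCAPE = 2
_STAGE_DEPTHS = 3
_STAGE_SPIKE = 4
_STAGE_PLACE = 5


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stage,)))


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome.

    ``snp_density_range`` is expressed as (min, max) base pairs per SNP;
    the default 500-5000 bp matches the spacing of informative heterozygous
    SNPs in a phased human genome.  ``mean_depth`` is the expected read depth
    per SNP, per homolog, per cell-cycle fraction.  ``timing_domain_scale``
    sets the autocorrelation length of the timing landscape.
    """

    chrom_lengths: Sequence[tuple] = (("chr1", 50_000_000),)
    snp_density_range: tuple = (500, 5000)
    mean_depth: float = 25.0
    timing_domain_scale: int = 1_500_000
    bin_width: int = 500
    seed: int = 0
    # density blocks mimic haplotype structure: within a block the SNP
    # spacing is roughly constant, between blocks it jumps.
    density_block_range: tuple = (100_000, 1_000_000)

    def __post_init__(self) -> None:
        lo, hi = self.snp_density_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid snp_density_range {self.snp_density_range}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @property
    def chrom_dict(self) -> dict:
        return {name: int(length) for name, length in self.chrom_lengths}


@dataclass
class SpikeRegionSpec:
    """Regions to be made asynchronous, with the S-phase read excess to apply."""

    intervals: IntervalSet
    excess_fraction: float
    target_homolog: str = "maternal"

    def __post_init__(self) -> None:
        if self.excess_fraction < 0:
            raise ValueError("excess_fraction must be >= 0")
        if self.target_homolog not in ("maternal", "paternal"):
            raise ValueError(f"unknown homolog {self.target_homolog!r}")
        merged = self.intervals.merged()
        if len(merged) != len(self.intervals):
            raise ValueError("spike intervals must be non-overlapping")


def gen_snp_positions(spec: SyntheticGenomeSpec) -> dict:
    """Generate sorted SNP coordinates per chromosome.

    The chromosome is carved into blocks of 100 kb - 1 Mb; each block draws a
    characteristic spacing uniformly between the configured bounds and SNPs
    are laid down with gaps jittered around that spacing (clamped to the
    bounds), so local density varies block-to-block the way heterozygosity
    does along real haplotypes while never leaving the configured range.
    """
    rng = _stage_rng(spec.seed, _STAGE_POSITIONS)
    lo, hi = spec.snp_density_range
    blo, bhi = spec.density_block_range
    out = {}
    for chrom, length in spec.chrom_lengths:
        positions = []
        block_start = 0
        while block_start < length:
            block_len = int(rng.integers(blo, bhi + 1))
            block_end = min(block_start + block_len, length)
            spacing = float(rng.uniform(lo, hi))
            # gaps jittered +/-25% around the block spacing, clamped to bounds
            gap_lo = max(lo, 0.75 * spacing)
            gap_hi = min(hi, 1.25 * spacing)
            n_max = int((block_end - block_start) / gap_lo) + 2
            gaps = rng.uniform(gap_lo, gap_hi, size=n_max)
            pos = block_start + np.cumsum(gaps)
            positions.append(pos[pos < block_end])
            block_start = block_end
        pos = np.unique(np.concatenate(positions).astype(np.int64))
        out[chrom] = pos[pos < length]
    return out


def gen_timing_landscape(
    spec: SyntheticGenomeSpec, constant: float | None = None
) -> dict:
    """Generate a true replication-timing landscape per chromosome.

    Values live in [1, 2]: 2 = earliest-replicating, 1 = latest.  The
    landscape is a stationary Gaussian random field mapped through the normal
    CDF so that values fill the theoretical range with uniform marginals,
    autocorrelated at ``timing_domain_scale`` (the genomic distance at which
    the autocorrelation of the underlying field drops to exp(-1/2)).

    With ``constant`` set, every bin takes that value (useful for calibration
    tests).
    """
    rng = _stage_rng(spec.seed, _STAGE_LANDSCAPE)
    out = {}
    for chrom, length in spec.chrom_lengths:
        n = -(-length // spec.bin_width)
        if constant is not None:
            if not (1.0 <= constant <= 2.0):
                raise ValueError("constant timing value must lie in [1, 2]")
            values = np.full(n, float(constant))
        else:
            # smoothing white noise with a Gaussian kernel of sd L/sqrt(2)
            # yields a Gaussian autocorrelation that hits exp(-1/2) at lag L
            sigma_bins = spec.timing_domain_scale / spec.bin_width / np.sqrt(2.0)
            pad = int(4 * sigma_bins) + 1
            white = rng.standard_normal(n + 2 * pad)
            smooth = ndimage.gaussian_filter1d(white, sigma_bins, mode="reflect")[pad:-pad]
            sd = smooth.std()
            if sd == 0:
                raise ValueError("degenerate landscape: zero variance")
            values = 1.0 + ndtr(smooth / sd)
        out[chrom] = BinnedTrack(chrom, spec.bin_width, values, np.ones(n, dtype=bool))
    return out


def _timing_at(positions: np.ndarray, track: BinnedTrack) -> np.ndarray:
    idx = positions // track.bin_width
    if idx.size and idx.max() >= track.n_bins:
        raise ValueError("SNP position outside the timing landscape")
    return track.values[idx]


def landscape_mean(timing: Mapping[str, BinnedTrack]) -> float:
    """Genome-wide mean of the true timing landscape over covered bins."""
    tot, n = 0.0, 0
    for track in timing.values():
        tot += track.values[track.covered].sum()
        n += int(track.covered.sum())
    return tot / n


def gen_depths(
    positions: Mapping[str, np.ndarray],
    timing: Mapping[str, BinnedTrack],
    spec: SyntheticGenomeSpec,
) -> AlleleDepthTable:
    """Draw per-SNP read depths for both homologs and fractions.

    G1 depth is Poisson(mean_depth) for each homolog.  S depth is
    Poisson(mean_depth * t / t_mean) where t is the local timing value, so
    that the normalized S/G1 ratio recovers the landscape shape.  Both
    homologs share the same t; asynchrony is introduced only by
    :func:`spike_regions`.
    """
    rng = _stage_rng(spec.seed, _STAGE_DEPTHS)
    tbar = landscape_mean(timing)
    frames = []
    for chrom, pos in positions.items():
        t = _timing_at(pos, timing[chrom])
        lam_s = spec.mean_depth * t / tbar
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "mat_s": rng.poisson(lam_s),
                    "pat_s": rng.poisson(lam_s),
                    "mat_g1": rng.poisson(spec.mean_depth, size=pos.size),
                    "pat_g1": rng.poisson(spec.mean_depth, size=pos.size),
                }
            )
        )
    return AlleleDepthTable(pd.concat(frames, ignore_index=True))


def control_pair(table: AlleleDepthTable, source_homolog: str = "maternal") -> AlleleDepthTable:
    """Duplicate one homolog's observed counts onto both homologs.

    The spike-in study builds its simulated maternal and paternal control
    tracks by resampling the *same* observed track, so that the two controls
    differ only by resampling noise and the homolog-contrast test is exactly
    calibrated.  This helper prepares that configuration: pass the result to
    :func:`spike_regions`, which draws independent binomial resamples for
    the two homologs (and adds the spike to one of them).
    """
    df = table.df.copy()
    src = "mat" if source_homolog == "maternal" else "pat"
    dst = "pat" if src == "mat" else "mat"
    df[f"{dst}_s"] = df[f"{src}_s"]
    df[f"{dst}_g1"] = df[f"{src}_g1"]
    return AlleleDepthTable(df)


def resample_binomial(
    s_depth, total_depth, rng: np.random.Generator | int
) -> np.ndarray:
    """Binomially resample S counts given per-SNP (S, S+G1) totals.

    Draws Binomial(n=total, p=S/total) per SNP; the matching G1 resample is
    ``total - draw``.  Vectorised over arrays.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    s = np.atleast_1d(np.asarray(s_depth))
    n = np.atleast_1d(np.asarray(total_depth))
    if np.any(s < 0) or np.any(n < 0):
        raise ValueError("negative read counts")
    if np.any(s > n):
        raise ValueError("s_depth exceeds total_depth")
    n_int = np.round(n).astype(np.int64)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, s / np.where(n > 0, n, 1), 0.0)
    draw = rng.binomial(n_int, p)
    return draw if np.ndim(s_depth) else int(draw[0])


def spike_regions(
    table: AlleleDepthTable,
    spike: SpikeRegionSpec,
    seed: int,
) -> AlleleDepthTable:
    """Inflate S-phase reads inside spiked regions, then resample everything.

    For SNPs of the target homolog inside a spike interval the total count is
    inflated to ``round(total * (1 + excess))`` with all extra reads assigned
    to S; every SNP of both homologs is then passed through the binomial
    resampler so spiked and unspiked SNPs carry identical sampling noise.
    """
    rng = _stage_rng(seed, _STAGE_SPIKE)
    df = table.df.copy()
    target = "mat" if spike.target_homolog == "maternal" else "pat"
    snps = IntervalSet.from_arrays(df["chrom"].to_numpy(), df["pos"].to_numpy(), df["pos"].to_numpy() + 1)
    in_spike = snps.overlaps_any(spike.intervals)
    for hom in ("mat", "pat"):
        s = df[f"{hom}_s"].to_numpy().astype(np.float64)
        g1 = df[f"{hom}_g1"].to_numpy().astype(np.float64)
        total = s + g1
        if hom == target and spike.excess_fraction > 0:
            inflated = np.round(total * (1.0 + spike.excess_fraction))
            extra = inflated - total
            s = np.where(in_spike, s + extra, s)
            total = np.where(in_spike, inflated, total)
        new_s = resample_binomial(s, total, rng)
        df[f"{hom}_s"] = new_s
        df[f"{hom}_g1"] = np.round(total).astype(np.int64) - new_s
    return AlleleDepthTable(df)


def expected_spiked_depths(
    table: AlleleDepthTable, spike: SpikeRegionSpec
) -> AlleleDepthTable:
    """Expected (noise-free) depths after spiking and binomial resampling.

    The binomial resampler preserves expectations, so the expected table is
    the input with the spike inflation applied deterministically.  Used by
    the benchmark to compute the timing differential a spike truly induces.
    """
    df = table.df.copy()
    target = "mat" if spike.target_homolog == "maternal" else "pat"
    snps = IntervalSet.from_arrays(df["chrom"].to_numpy(), df["pos"].to_numpy(), df["pos"].to_numpy() + 1)
    in_spike = snps.overlaps_any(spike.intervals)
    s = df[f"{target}_s"].to_numpy().astype(np.float64)
    g1 = df[f"{target}_g1"].to_numpy().astype(np.float64)
    total = s + g1
    inflated = np.round(total * (1.0 + spike.excess_fraction))
    df[f"{target}_s"] = np.where(in_spike, s + (inflated - total), s)
    return AlleleDepthTable(df)


def place_random_regions(
    n: int,
    size_choices: Sequence[int],
    genome: Mapping[str, int] | Sequence[tuple],
    seed: int,
    max_tries_per_region: int = 1000,
) -> IntervalSet:
    """Place ``n`` mutually non-overlapping regions uniformly on the genome.

    Sizes are drawn uniformly from ``size_choices``; chromosomes are chosen
    with probability proportional to their placeable length.  Placement uses
    rejection sampling; an error is raised if a region cannot be placed
    within the retry budget (genome too crowded).
    """
    rng = _stage_rng(seed, _STAGE_PLACE)
    chrom_lengths = dict(genome) if not isinstance(genome, Mapping) else dict(genome)
    sizes = np.asarray(size_choices, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("region sizes must be positive")
    chroms = list(chrom_lengths)
    placed: dict = {c: [] for c in chroms}
    rows = []
    for _ in range(n):
        size = int(rng.choice(sizes))
        lengths = np.array([max(chrom_lengths[c] - size, 0) for c in chroms], dtype=np.float64)
        if lengths.sum() == 0:
            raise ValueError(f"no chromosome can host a {size} bp region")
        probs = lengths / lengths.sum()
        for attempt in range(max_tries_per_region):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            start = int(rng.integers(0, chrom_lengths[chrom] - size + 1))
            end = start + size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append((chrom, start, end, size))
                break
        else:
            raise RuntimeError(
                f"could not place region {len(rows) + 1}/{n} of {size} bp "
                f"after {max_tries_per_region} tries"
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "size"])
    return IntervalSet(df[["chrom", "start", "end"]].assign(size=df["size"]))
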