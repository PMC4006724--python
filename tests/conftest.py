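import numpy as np
import pandas as pd
import pytest

from timexseq import (
    AlleleDepthTable,
    BinnedTrack,
    IntervalSet,
    SyntheticGenomeSpec,
    build_profile,
    gen_depths,
    gen_snp_positions,
    gen_timing_landscape,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    return SyntheticGenomeSpec(chrom_lengths=[("chr1", 5_000_000)], mean_depth=25.0, seed=7)


def make_track(values, covered=None, bin_width=500, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    if covered is None:
        covered = np.ones(values.size, dtype=bool)
    return BinnedTrack(chrom, bin_width, values, np.asarray(covered, dtype=bool))


def make_table(pos, mat_s, pat_s, mat_g1, pat_g1, chrom="chr1"):
    return AlleleDepthTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "mat_s": mat_s,
                "pat_s": pat_s,
                "mat_g1": mat_g1,
                "pat_g1": pat_g1,
            }
        )
    )


@pytest.fixture(scope="session")
def unspiked_sim():
    """A 40 Mb unspiked synthetic genome with its maternal/paternal profiles."""
    spec = SyntheticGenomeSpec(chrom_lengths=[("chr1", 40_000_000)], mean_depth=25.0, seed=11)
    positions = gen_snp_positions(spec)
    timing = gen_timing_landscape(spec)
    table = gen_depths(positions, timing, spec)
    mat = build_profile(table, "maternal", spec.chrom_dict)
    pat = build_profile(table, "paternal", spec.chrom_dict)
    return dict(spec=spec, positions=positions, timing=timing, table=table, mat=mat, pat=pat)
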