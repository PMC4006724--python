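import numpy as np
import pytest
from scipy import stats

from timexseq import (
    IntervalSet,
    IslandParams,
    SpikeRegionSpec,
    ard_overlap,
    bh_qvalues,
    call_ards,
    delay_minutes,
    difference_track,
    excess_to_minutes,
    find_islands,
    gene_rank_enrichment,
    island_chisq,
    place_random_regions,
    spike_regions,
)
from timexseq.ards import ArdRecord, ards_to_intervals
from timexseq.profiles import TimexProfile, build_profile
from timexseq.synthio import SyntheticGenomeSpec, control_pair, gen_depths, gen_snp_positions, gen_timing_landscape

from .conftest import make_track


def profile_from(values, covered=None, bin_width=500):
    tr = make_track(values, covered, bin_width)
    return TimexProfile({"chr1": tr}, homolog="maternal", sigma=100_000)


class TestDifferenceTrack:
    def test_identical_profiles_zero(self):
        p = profile_from([1.4, 1.5, 1.6])
        diff = difference_track(p, profile_from([1.4, 1.5, 1.6]))["chr1"]
        np.testing.assert_array_equal(diff.values, 0.0)

    def test_antisymmetry(self, rng):
        a = profile_from(rng.random(50))
        b = profile_from(rng.random(50))
        d1 = difference_track(a, b)["chr1"].values
        d2 = difference_track(b, a)["chr1"].values
        np.testing.assert_allclose(d1, -d2)

    def test_gap_propagates(self):
        a = profile_from([1.0, 1.0], covered=[True, False])
        b = profile_from([1.0, 1.0])
        diff = difference_track(a, b)["chr1"]
        assert diff.covered[0] and not diff.covered[1]

    def test_mismatched_bin_width_rejected(self):
        a = profile_from([1.0], bin_width=500)
        b = profile_from([1.0], bin_width=1000)
        with pytest.raises(ValueError):
            difference_track(a, b)


class TestFindIslands:
    params = IslandParams(0.02, 250_000, 50_000)

    def test_single_run_above_threshold(self):
        values = np.zeros(400)
        values[100:220] = 0.05  # 120 bins = 60 kb
        islands = find_islands(make_track(values), self.params)
        assert len(islands) == 1
        row = islands.df.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (50_000, 110_000, "+")

    def test_runs_beyond_max_gap_stay_separate(self):
        values = np.zeros(2000)
        values[0:120] = 0.05
        values[720:840] = 0.05  # 300 kb gap > 250 kb
        islands = find_islands(make_track(values), self.params)
        assert len(islands) == 2

    def test_runs_within_max_gap_merge(self):
        values = np.zeros(2000)
        values[0:120] = 0.05
        values[520:640] = 0.05  # 200 kb gap
        islands = find_islands(make_track(values), self.params)
        assert len(islands) == 1
        assert islands.df.iloc[0]["end"] - islands.df.iloc[0]["start"] == 320_000

    def test_subthreshold_track_yields_nothing(self):
        islands = find_islands(make_track(np.full(1000, 0.01)), self.params)
        assert len(islands) == 0

    def test_opposite_signs_never_merge(self):
        values = np.zeros(1000)
        values[0:120] = 0.05
        values[130:260] = -0.05
        values[270:400] = 0.05
        islands = find_islands(make_track(values), self.params)
        strands = sorted(islands.df["strand"])
        assert strands == ["+", "-"]
        plus = islands.df[islands.df["strand"] == "+"].iloc[0]
        assert plus["end"] - plus["start"] == 200_000  # merged across the negative gap

    def test_min_size_filter(self):
        values = np.zeros(400)
        values[10:80] = 0.05  # 35 kb < 50 kb
        assert len(find_islands(make_track(values), self.params)) == 0


class TestIslandChisq:
    def test_balanced_table_p_one(self):
        assert island_chisq(100, 100, 100, 100) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        obs = np.array([[150.0, 100.0], [100.0, 100.0]])
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p_oracle = stats.chi2.sf(chi2, df=1)
        assert island_chisq(150, 100, 100, 100) == pytest.approx(p_oracle, rel=1e-12)

    def test_row_swap_symmetry(self):
        assert island_chisq(150, 100, 90, 110) == pytest.approx(island_chisq(90, 110, 150, 100))

    def test_zero_marginal_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert island_chisq(0, 0, 10, 10) == 1.0


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        # q_k = min over i>=k of m*p_(i)/i
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p(self, rng):
        p = rng.random(200)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)

    def test_oracle_on_random_values(self, rng):
        p = rng.random(50)
        order = np.argsort(p)
        m = p.size
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_qvalues(p), oracle, rtol=1e-12)


class TestDelayConversions:
    def test_delay_formula(self):
        assert delay_minutes(0.0) == 0.0
        assert delay_minutes(0.12) == pytest.approx(0.12 * 480 / 1.2)
        assert delay_minutes(0.12) == pytest.approx(48.0)

    def test_delay_linear_and_signed(self):
        assert delay_minutes(0.2) == pytest.approx(2 * delay_minutes(0.1))
        assert delay_minutes(-0.1) == pytest.approx(-delay_minutes(0.1))

    def test_delay_multiply_switch(self):
        assert delay_minutes(0.1, multiply=True) == pytest.approx(0.1 * 480 * 1.2)

    def test_excess_conversion(self):
        assert excess_to_minutes(0.10) == pytest.approx(48.0)
        assert excess_to_minutes(0.15) == pytest.approx(72.0)
        assert excess_to_minutes(0.20) == pytest.approx(96.0)
        assert excess_to_minutes(0.0) == 0.0


@pytest.fixture(scope="module")
def spiked_run():
    spec = SyntheticGenomeSpec(chrom_lengths=[("chr1", 40_000_000)], mean_depth=12.5, seed=21)
    positions = gen_snp_positions(spec)
    timing = gen_timing_landscape(spec)
    base = control_pair(gen_depths(positions, timing, spec))
    truth = IntervalSet.from_arrays("chr1", [15_000_000], [17_000_000])
    table = spike_regions(base, SpikeRegionSpec(truth, 0.50, "maternal"), seed=21)
    mat = build_profile(table, "maternal", spec.chrom_dict)
    pat = build_profile(table, "paternal", spec.chrom_dict)
    return dict(truth=truth, ards=call_ards(mat, pat, table))


class TestCallArds:
    def test_spiked_region_detected(self, spiked_run):
        det = ards_to_intervals(spiked_run["ards"])
        assert len(det) >= 1
        assert spiked_run["truth"].overlaps_any(det).all()

    def test_spiked_sign_is_paternal_delayed(self, spiked_run):
        hits = ards_to_intervals(spiked_run["ards"]).overlaps_any(spiked_run["truth"])
        for ard, hit in zip(spiked_run["ards"], hits):
            if hit:
                assert ard.sign == "paternal-delayed"
                assert ard.delay_minutes > 0
                assert ard.cores, "a 50% spike must contain a core"

    def test_records_satisfy_contracts(self, spiked_run):
        prev_end = {}
        for ard in spiked_run["ards"]:
            assert ard.q_value < 0.05
            assert ard.q_value >= ard.p_value
            assert ard.length >= 50_000
            assert 0.0 <= ard.coverage <= 1.0
            for cs, ce, _ in ard.cores:
                assert ard.start <= cs < ce <= ard.end
            key = (ard.chrom, ard.sign)
            assert ard.start >= prev_end.get(key, -1)
            prev_end[key] = ard.end


class TestArdOverlap:
    def _records(self, spans, sign="paternal-delayed"):
        return [
            ArdRecord("chr1", s, e, sign, (1, 1, 1, 1), 0.01, 0.02, 1.0, 0.1, 40.0)
            for s, e in spans
        ]

    def test_identical_lists_all_overlap(self):
        a = self._records([(0, 100), (200, 300)])
        assert ard_overlap(a, a) == [(0, 0), (1, 1)]

    def test_disjoint_lists_none(self):
        a = self._records([(0, 100)])
        b = self._records([(100, 200)])
        assert ard_overlap(a, b) == []

    def test_symmetric_counts(self):
        a = self._records([(0, 100), (500, 600)])
        b = self._records([(50, 120), (550, 650)])
        ab = ard_overlap(a, b)
        ba = ard_overlap(b, a)
        assert len(ab) == len(ba) == 2


class TestGeneRankEnrichment:
    def _ards(self, n, p_values):
        return [
            ArdRecord("chr1", i * 1_000_000, i * 1_000_000 + 500_000, "paternal-delayed",
                      (1, 1, 1, 1), p, p, 1.0, 0.1, 40.0)
            for i, p in zip(range(n), p_values)
        ]

    def test_empty_gene_set(self):
        ards = self._ards(50, np.linspace(0.001, 0.05, 50))
        obs, p = gene_rank_enrichment(ards, IntervalSet.empty(), top_n=40, n_rand=100, seed=0)
        assert obs == 0 and p == 1.0

    def test_every_ard_near_gene(self):
        ards = self._ards(50, np.linspace(0.001, 0.05, 50))
        genes = IntervalSet.from_arrays("chr1", [i * 1_000_000 for i in range(50)],
                                        [i * 1_000_000 + 100 for i in range(50)])
        obs, p = gene_rank_enrichment(ards, genes, top_n=40, n_rand=100, seed=0)
        assert obs == 40 and p == 1.0

    def test_matches_hypergeometric_tail(self):
        # 100 ARDs, 10 gene-associated, all 10 among the top 40 by p-value
        p_values = np.concatenate([np.full(10, 1e-6), np.linspace(0.01, 0.9, 90)])
        ards = self._ards(100, p_values)
        genes = IntervalSet.from_arrays("chr1", [i * 1_000_000 + 100 for i in range(10)],
                                        [i * 1_000_000 + 200 for i in range(10)])
        obs, p = gene_rank_enrichment(ards, genes, top_n=40, n_rand=20_000, seed=1)
        assert obs == 10
        p_exact = stats.hypergeom.sf(9, 100, 10, 40)
        assert p == pytest.approx(p_exact, abs=3 * np.sqrt(p_exact * (1 - p_exact) / 20_000))

    def test_requires_enough_ards(self):
        with pytest.raises(ValueError):
            gene_rank_enrichment(self._ards(5, [0.01] * 5), IntervalSet.empty(), top_n=40)
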