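"""Simulator: renewal process statistics, thinning, maps, selection, VCF I/O."""

import time

import numpy as np
import pytest
from scipy import stats

from xover.genome import GenomeMap, default_genome, distal_elevated_map, uniform_map
from xover.genotypes import read_calls
from xover.simulate import (
    CALL_MISSING,
    MeiosisModel,
    ObservationModel,
    PopulationCalls,
    SelectionModel,
    TrueGamete,
    genetic_to_physical,
    make_gamete,
    observe_gamete,
    sample_chromatids,
    simulate_bundle_crossovers,
    simulate_population,
    thin_to_chromatid,
    write_population_vcf,
)


def _bundles(nu, G, n, seed):
    rng = np.random.default_rng(seed)
    return [simulate_bundle_crossovers(nu, G, rng) for _ in range(n)]


class TestBundleRenewal:
    def test_zero_length_is_empty(self):
        assert len(simulate_bundle_crossovers(1.0, 0.0, 0)) == 0
        assert len(simulate_bundle_crossovers(7.0, 0.0, 0)) == 0

    def test_invalid_nu_rejected(self):
        with pytest.raises(ValueError):
            simulate_bundle_crossovers(0.0, 1.0, 0)
        with pytest.raises(ValueError):
            MeiosisModel(nu=-1.0)

    def test_poisson_limit_mean_count(self):
        # at nu = 1 the process is Poisson with rate 2/Morgan: G = 2 -> mean 4
        counts = [len(b) for b in _bundles(1.0, 2.0, 10_000, 1)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 4.0) < 3 * se

    @pytest.mark.parametrize("nu", [0.5, 1.0, 5.0])
    def test_stationarity_along_interval(self, nu):
        # equilibrium start => equal mean counts in the two interval halves
        G = 2.0
        first, second = [], []
        for b in _bundles(nu, G, 10_000, 2):
            first.append(np.sum(b < G / 2))
            second.append(np.sum(b >= G / 2))
        diff = np.array(first) - np.array(second)
        se = np.std(diff, ddof=1) / np.sqrt(len(diff))
        assert abs(np.mean(diff)) < 3 * se

    def test_interference_shrinks_gap_variance(self):
        gaps1 = np.concatenate([np.diff(b) for b in _bundles(1.0, 2.0, 10_000, 3) if len(b) > 1])
        gaps10 = np.concatenate([np.diff(b) for b in _bundles(10.0, 2.0, 10_000, 4) if len(b) > 1])
        assert np.var(gaps10) < np.var(gaps1)

    def test_nu1_gaps_are_exponential(self):
        # long interval so window truncation of the pooled gaps is negligible
        gaps = np.concatenate([np.diff(b) for b in _bundles(1.0, 100.0, 60, 5)])
        assert len(gaps) > 10_000
        p = stats.kstest(gaps, "expon", args=(0, 0.5)).pvalue
        assert p > 0.001


class TestThinning:
    def test_empty(self):
        assert len(thin_to_chromatid(np.empty(0), 0)) == 0

    def test_halves_intensity(self):
        rng = np.random.default_rng(6)
        counts = [
            len(thin_to_chromatid(simulate_bundle_crossovers(1.0, 2.0, rng), rng))
            for _ in range(10_000)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_retention_independent_of_position(self):
        rng = np.random.default_rng(7)
        pos, kept = [], []
        for _ in range(4000):
            b = simulate_bundle_crossovers(1.0, 2.0, rng)
            c = thin_to_chromatid(b, rng)
            pos.extend(b / 2.0)
            kept.extend(np.isin(b, c))
        quart = np.minimum((np.asarray(pos) * 4).astype(int), 3)
        table = np.array([np.bincount(quart[np.asarray(kept) == k], minlength=4) for k in (0, 1)])
        p = stats.chi2_contingency(table)[1]
        assert p > 0.001

    def test_batch_sampler_matches_scalar_mean(self):
        rng = np.random.default_rng(8)
        counts = [len(c) for c in sample_chromatids(1.0, 2.0, 10_000, rng)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se


class TestGeneticToPhysical:
    def _genome(self, kind):
        maps = {"uniform": uniform_map, "distal": distal_elevated_map}
        return GenomeMap(
            chromosomes={"c1": 600_000_000},
            genetic_maps={"c1": maps[kind](600_000_000, 1.0)},
        )

    def test_uniform_midpoint(self):
        g = self._genome("uniform")
        assert genetic_to_physical([0.5], g, "c1")[0] == pytest.approx(300e6)

    def test_empty_identity(self):
        assert len(genetic_to_physical([], self._genome("uniform"), "c1")) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            genetic_to_physical([1.5], self._genome("uniform"), "c1")

    def test_distal_map_depletes_chromosome_middle(self):
        g = self._genome("distal")
        rng = np.random.default_rng(9)
        pos = []
        for chromatid in sample_chromatids(1.0, 1.0, 10_000, rng):
            pos.extend(genetic_to_physical(chromatid, g, "c1"))
        pos = np.asarray(pos)
        middle = ((pos > 0.3 * 600e6) & (pos < 0.7 * 600e6)).mean()
        assert middle < 0.15


class TestMakeGamete:
    def test_zero_crossovers_single_origin(self, small_genome):
        model = MeiosisModel(nu=1.0, genetic_length=0.0)
        g = make_gamete(small_genome, model, rng=np.random.default_rng(0))
        for chrom in small_genome.names:
            assert len(g.crossovers[chrom]) == 0
            parents = g.parent_at(chrom, [1, small_genome.length(chrom) // 2])
            assert len(set(parents.tolist())) == 1

    def test_haplotype_alternates_at_crossovers(self, small_genome):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = make_gamete(small_genome, MeiosisModel(nu=2.0), rng=rng)
            for chrom, xo in g.crossovers.items():
                for x in xo:
                    before, after = g.parent_at(chrom, [x - 1, x + 1])
                    assert before != after

    def test_selection_hits_target_transmission(self):
        genome = GenomeMap(
            chromosomes={"c1": 600_000_000},
            genetic_maps={"c1": distal_elevated_map(600_000_000, 1.0)},
        )
        locus, linked = 30_000_000, 35_000_000  # distal, 5 Mbp apart
        sel = SelectionModel(loci=(("c1", locus, 0.9),))
        rng = np.random.default_rng(2)
        at_locus, at_linked = [], []
        for _ in range(5000):
            g = make_gamete(genome, MeiosisModel(nu=1.0), sel, rng)
            at_locus.append(int(g.parent_at("c1", locus)) == 1)
            at_linked.append(int(g.parent_at("c1", linked)) == 1)
        f = np.mean(at_locus)
        se = np.sqrt(0.9 * 0.1 / 5000)
        assert abs(f - 0.9) < 3 * se
        # linked marker decays toward 0.5 with the recombination fraction
        fl = np.mean(at_linked)
        se_l = np.sqrt(fl * (1 - fl) / 5000)
        assert 0.5 + 3 * se_l < fl < 0.9 - 3 * se_l

    def test_neutral_transmission_balanced(self, small_genome):
        rng = np.random.default_rng(3)
        hits = [
            int(make_gamete(small_genome, MeiosisModel(nu=1.0), rng=rng).parent_at("c1", 10e6)) == 1
            for _ in range(2000)
        ]
        assert abs(np.mean(hits) - 0.5) < 3 * np.sqrt(0.25 / 2000)


class TestObservation:
    def test_perfect_observation_equals_truth(self, small_genome):
        rng = np.random.default_rng(4)
        g = make_gamete(small_genome, MeiosisModel(nu=2.0), rng=rng)
        obs = ObservationModel(detect_prob=1.0, error_rate=0.0, bad_region_frac=0.0)
        calls = observe_gamete(g, small_genome, obs, rng)
        for chrom in small_genome.names:
            truth = g.parent_at(chrom, small_genome.markers[chrom]["pos"].to_numpy())
            assert np.array_equal(calls[chrom], truth)

    def test_zero_detection_all_missing(self, small_genome):
        rng = np.random.default_rng(5)
        g = make_gamete(small_genome, MeiosisModel(nu=2.0), rng=rng)
        calls = observe_gamete(g, small_genome, ObservationModel(detect_prob=0.0), rng)
        assert all(np.all(v == CALL_MISSING) for v in calls.values())

    def test_detection_fraction(self, small_genome):
        rng = np.random.default_rng(6)
        g = make_gamete(small_genome, MeiosisModel(nu=2.0), rng=rng)
        obs = ObservationModel(detect_prob=0.3, error_rate=0.0, bad_region_frac=0.0)
        calls = observe_gamete(g, small_genome, obs, rng)
        flat = np.concatenate(list(calls.values()))
        frac = (flat != CALL_MISSING).mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(flat))


class TestVcfRoundTrip:
    def test_roundtrip(self, small_genome, tmp_path):
        _, calls = simulate_population(
            small_genome,
            MeiosisModel(nu=2.0),
            ObservationModel(detect_prob=0.5, error_rate=0.01),
            n_samples=8,
            seed=10,
        )
        path = tmp_path / "pop.vcf"
        write_population_vcf(calls, small_genome, path)
        back, stats_ = read_calls(path, small_genome)
        assert back.samples == calls.samples
        for chrom in small_genome.names:
            assert np.array_equal(back.calls[chrom], calls.calls[chrom])
        assert stats_["dropped_allele_mismatch"] == 0

    def test_empty_population_header_only(self, small_genome, tmp_path):
        calls = PopulationCalls(
            samples=["only"],
            calls={
                c: np.full((1, len(small_genome.markers[c])), CALL_MISSING, np.int8)
                for c in small_genome.names
            },
        )
        path = tmp_path / "empty.vcf"
        write_population_vcf(calls, small_genome, path)
        back, _ = read_calls(path, small_genome)
        assert all(np.all(v == CALL_MISSING) for v in back.calls.values())

    def test_parse_speed_40x10k(self, tmp_path):
        genome = default_genome(
            lengths={"c1": 1_000_000_000},
            marker_spacing=100_000,
            gap_size=0,
            gap_centers=(),
            map_kind="uniform",
            seed=1,
        )
        _, calls = simulate_population(
            genome, MeiosisModel(nu=1.0), ObservationModel(detect_prob=0.3), n_samples=40, seed=2
        )
        path = tmp_path / "big.vcf"
        write_population_vcf(calls, genome, path)
        t0 = time.time()
        read_calls(path, genome)
        assert time.time() - t0 < 5.0
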