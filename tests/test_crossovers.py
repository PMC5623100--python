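"""Flip-rate curation, event detection (with brute-force oracle), summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tests.conftest import make_matrix
from xover.crossovers import (
    chi2_goodness_of_fit,
    count_per_chromosome,
    curate,
    detect_events,
    detect_events_vector,
    mask_singletons,
    mean_events_per_sample,
    singleton_flip_rate,
)
from xover.genotypes import CODE_MISSING, bin_consensus
from xover.simulate import MeiosisModel, ObservationModel, simulate_population

NA = -1


def oracle_events(codes):
    """Brute-force reference: sign changes of the informative subsequence."""
    idx = [i for i, c in enumerate(codes) if c != NA]
    out = []
    for a, b in zip(idx, idx[1:]):
        if codes[a] != codes[b]:
            out.append((a, b))
    return out


class TestFlipRate:
    def test_motif_examples(self):
        m = make_matrix({"c1": [[0, 2, 0], [0, 0, 0]]})
        rates = singleton_flip_rate(m)
        assert rates["c1"].tolist() == [0.0, 0.5, 0.0]

    def test_constant_vectors_zero(self):
        m = make_matrix({"c1": [[2, 2, 2, 2], [0, 0, 0, 0]]})
        assert np.all(singleton_flip_rate(m)["c1"] == 0)

    def test_missing_bins_bridged(self):
        m = make_matrix({"c1": [[0, NA, 2, NA, 0], [0, 0, 0, 0, 0]]})
        rates = singleton_flip_rate(m)
        assert rates["c1"][2] == 0.5
        assert rates["c1"][[0, 1, 3, 4]].tolist() == [0.0] * 4


class TestCurate:
    def test_clean_simulation_untouched(self, small_genome):
        _, calls = simulate_population(
            small_genome,
            MeiosisModel(nu=2.0),
            ObservationModel(detect_prob=0.5, error_rate=0.0, bad_region_frac=0.0),
            n_samples=12,
            seed=5,
        )
        matrix = bin_consensus(calls, small_genome)
        _, report = curate(matrix, max_flip_rate=0.1)
        assert report.n_removed() == 0

    def test_threshold_is_strict(self):
        rows = [[0, 2, 0]] * 5 + [[0, 0, 0]] * 35  # flip rate 0.125
        curated, report = curate(make_matrix({"c1": rows}), max_flip_rate=0.1)
        assert report.removed["c1"].tolist() == [1_000_000]
        assert np.all(curated.codes["c1"][:, 1] == CODE_MISSING)
        _, report_loose = curate(make_matrix({"c1": rows}), max_flip_rate=1.0)
        assert report_loose.n_removed() == 0

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        rows = rng.choice([0, 2, NA], size=(20, 30), p=[0.45, 0.45, 0.1]).tolist()
        once, _ = curate(make_matrix({"c1": rows}), max_flip_rate=0.05)
        twice, report2 = curate(once, max_flip_rate=0.05)
        assert report2.n_removed() == 0
        assert np.array_equal(once.codes["c1"], twice.codes["c1"])

    def test_curation_never_increases_event_count(self):
        rng = np.random.default_rng(7)
        rows = rng.choice([0, 2, NA], size=(10, 25), p=[0.4, 0.4, 0.2]).tolist()
        m = make_matrix({"c1": rows})
        before = len(detect_events(m))
        curated, _ = curate(m, max_flip_rate=0.15)
        assert len(detect_events(curated)) <= before


class TestMaskSingletons:
    def test_single_sample_flip_removed(self):
        m = make_matrix({"c1": [[0, 0, 2, 0, 0], [0, 0, 0, 0, 0]]})
        masked, n = mask_singletons(m)
        assert n == 1
        assert len(detect_events(masked)) == 0

    def test_real_crossover_run_kept(self):
        m = make_matrix({"c1": [[0, 0, 2, 2, 0, 0], [0, 0, 0, 0, 0, 0]]})
        masked, n = mask_singletons(m)
        assert n == 0
        assert len(detect_events(masked)) == 2


class TestDetectEvents:
    def test_simple_transition(self):
        m = make_matrix({"c1": [[0, 0, 0, 2, 2, 2]]})
        ev = detect_events(m)
        assert len(ev) == 1
        e = ev.iloc[0]
        assert (e.left, e.right, e.left_code, e.right_code) == (3_000_000, 3_000_000, 0, 2)

    def test_constant_and_missing_vectors(self):
        m = make_matrix({"c1": [[0, 0, 0], [NA, NA, NA], [2, 2, 2]]})
        assert len(detect_events(m)) == 0

    def test_gap_spanning_event(self):
        m = make_matrix({"c1": [[0, NA, NA, 2]]})
        ev = detect_events(m)
        assert len(ev) == 1
        e = ev.iloc[0]
        assert (e.left, e.right) == (1_000_000, 3_000_000)
        assert e.midpoint == 2_000_000

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 2, NA]), min_size=1, max_size=12))
    def test_matches_oracle(self, codes):
        starts = np.arange(len(codes), dtype=np.int64) * 10
        ends = starts + 10
        got = detect_events_vector(np.asarray(codes, np.int8), starts, ends)
        want = oracle_events(codes)
        assert [(left // 10 - 1, right // 10) for left, right, _, _ in got] == want

    def test_alternation(self):
        rng = np.random.default_rng(8)
        rows = rng.choice([0, 2, NA], size=(30, 40)).tolist()
        ev = detect_events(make_matrix({"c1": rows}))
        for _, grp in ev.groupby("sample"):
            codes = list(zip(grp["left_code"], grp["right_code"]))
            for (l1, r1), (l2, r2) in zip(codes, codes[1:]):
                assert (l2, r2) == (r1, l1)


class TestCountSummary:
    def test_single_sample_no_events(self):
        ev = pd.DataFrame(columns=["sample", "chrom", "midpoint"])
        s = count_per_chromosome(ev, ["s0"], ["c1"])
        assert s.class_freq.loc[0, "pooled"] == 1.0
        assert s.total_events == 0

    def test_brute_force_recount(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(15)]
        chroms = ["c1", "c2"]
        rows = []
        for s in samples:
            for c in chroms:
                for _ in range(rng.integers(0, 4)):
                    rows.append({"sample": s, "chrom": c, "midpoint": float(rng.integers(1, 100))})
        ev = pd.DataFrame(rows)
        summary = count_per_chromosome(ev, samples, chroms)
        for c in chroms:
            for k in summary.class_counts.index:
                manual = sum(
                    1
                    for s in samples
                    if ((ev["sample"] == s) & (ev["chrom"] == c)).sum() == k
                )
                assert summary.class_counts.loc[k, c] == manual
        assert summary.total_events == len(ev)
        assert summary.mean_per_sample == len(ev) / len(samples)

    def test_mean_requires_samples(self):
        with pytest.raises(ValueError):
            mean_events_per_sample(10, 0)


class TestChi2GoodnessOfFit:
    def test_identical_distributions(self):
        stat, p = chi2_goodness_of_fit([10, 20, 30], [10, 20, 30])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        stat, _ = chi2_goodness_of_fit([10, 30], [50, 50])
        assert stat == pytest.approx(10.0)

    def test_null_p_values_uniform(self):
        # goodness-of-fit treats the reference proportions as fixed, so the
        # null calibration holds when the reference sample dominates
        rng = np.random.default_rng(10)
        probs = np.array([0.15, 0.4, 0.3, 0.1, 0.05])
        pvals = []
        for _ in range(500):
            a = rng.multinomial(280, probs)
            b = rng.multinomial(100_000, probs)
            pvals.append(chi2_goodness_of_fit(a, b)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi2_goodness_of_fit([0, 0], [1, 1])
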