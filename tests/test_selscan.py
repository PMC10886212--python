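"""Windowed FST / θπ scan, min–max scaling, quantile sweep calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from selsig import (
    SimParams,
    call_sweeps,
    merge_windows,
    minmax_scale,
    scan_windows,
    simulate_genotypes,
    window_fst,
    window_pi,
    window_starts,
)
from selsig.selscan import nearest_rank_quantile

from conftest import make_matrix


def two_pop(calls_p1, calls_p2, positions=None, chroms=None):
    calls = np.array(calls_p1 + calls_p2, dtype=np.int8)
    pops = ["p1"] * len(calls_p1) + ["p2"] * len(calls_p2)
    return make_matrix(calls, positions=positions, chroms=chroms, populations=pops)


class TestWindowBookkeeping:
    @pytest.mark.parametrize(
        "L,window,step,expected",
        [(10_000_000, 5_000_000, 100_000, 51), (1_000_000, 1_000_000, 100_000, 1),
         (999_999, 1_000_000, 100_000, 0), (1_200_000, 1_000_000, 100_000, 3)],
    )
    def test_window_count_formula(self, L, window, step, expected):
        starts = window_starts(L, window, step)
        assert len(starts) == expected
        if expected:
            assert starts[0] == 1 and starts[-1] + window - 1 <= L

    def test_snp_to_window_assignment_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 100_001), size=60, replace=False))
        calls_p1 = [rng.integers(0, 3, size=60).tolist() for _ in range(4)]
        calls_p2 = [rng.integers(0, 3, size=60).tolist() for _ in range(4)]
        g = two_pop(calls_p1, calls_p2, positions=pos.tolist())
        window, step = 10_000, 2_000
        w = scan_windows(g, "p1", "p2", window=window, step=step,
                         chrom_lengths={"1": 100_000})
        for row in w.itertuples(index=False):
            expect = sum(1 for p in pos if row.start <= p <= row.end)
            assert row.n_snps == expect


class TestWindowFST:
    def test_identical_frequencies_give_zero(self):
        rows = [[0, 1, 2, 1]] * 4
        g = two_pop(rows[:2], rows[2:])
        w = window_fst(g, "p1", "p2", window=10_000, step=10_000,
                       chrom_lengths={"1": 10_000})
        assert w["fst"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_alleles_give_one(self):
        g = two_pop([[0], [0]], [[2], [2]])
        w = window_fst(g, "p1", "p2", window=10_000, step=10_000,
                       chrom_lengths={"1": 10_000})
        assert w["fst"].iloc[0] == pytest.approx(1.0)

    def test_single_snp_formula_evaluation(self):
        # p1_hat = 0.9 (dosages 2,2,2,2,1 over 5 samples), p2_hat = 0.1
        # Hs = (2*.09 + 2*.09)/2 = 0.18; Ht = 2*.5*.5 = 0.5; FST = 0.64
        g = two_pop([[2], [2], [2], [2], [1]], [[0], [0], [0], [0], [1]])
        w = window_fst(g, "p1", "p2", window=10_000, step=10_000,
                       chrom_lengths={"1": 10_000})
        assert w["fst"].iloc[0] == pytest.approx(0.64)

    def test_identical_population_labels_rejected(self, two_pop_matrix):
        with pytest.raises(ValueError, match="differ"):
            scan_windows(two_pop_matrix, "hl", "hl")

    def test_merged_identical_populations_fst_zero(self):
        # the same pool of genotypes split arbitrarily into two labels with
        # identical composition per variant
        rows = [[0, 1], [1, 2], [0, 1], [1, 2]]
        g = two_pop(rows[:2], rows[2:])
        w = window_fst(g, "p1", "p2", window=10_000, step=10_000,
                       chrom_lengths={"1": 10_000})
        assert abs(w["fst"].iloc[0]) < 1e-12


class TestWindowPi:
    def test_monomorphic_window_has_zero_pi(self):
        g = two_pop([[0], [0]], [[0], [0]])
        w = window_pi(g, "p1", window=1_000, step=1_000,
                      chrom_lengths={"1": 1_000})
        assert w["pi"].iloc[0] == 0.0

    def test_single_snp_unbiased_formula(self):
        # p_hat = 0.5 over n_c = 4 alleles: pi = (4/3) * 2*0.5*0.5 / 1000
        g = two_pop([[1], [1]], [[0], [0]], positions=[500])
        w = window_pi(g, "p1", window=1_000, step=1_000,
                      chrom_lengths={"1": 1_000})
        assert w["pi"].iloc[0] == pytest.approx((4 / 3) * 0.5 / 1_000)

    def test_matches_allele_pair_mismatch_oracle(self):
        # oracle: average fraction of differing allele pairs over all
        # distinct pairs of sample-chromosomes, per site, summed / length
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(6, 8), dtype=np.int8)
        pos = sorted(rng.choice(np.arange(1, 2_000), size=8, replace=False))
        g = two_pop(calls[:4].tolist(), calls[4:].tolist(), positions=pos)
        w = window_pi(g, "p1", window=2_000, step=2_000,
                      chrom_lengths={"1": 2_000})

        total = 0.0
        for j in range(8):
            alleles = []
            for d in calls[:4, j]:
                alleles += [1] * d + [0] * (2 - d)
            diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
            total += np.mean(diffs)
        assert w["pi"].iloc[0] == pytest.approx(total / 2_000, rel=1e-9)

    def test_unknown_population_rejected(self, two_pop_matrix):
        with pytest.raises(KeyError):
            window_pi(two_pop_matrix, "nope")


class TestMinMaxScale:
    def test_direct_formula(self):
        np.testing.assert_allclose(minmax_scale([2, 4, 6]), [0, 0.5, 1])

    def test_endpoints_forced(self):
        x = np.array([3.2, -1.0, 7.5, 2.2])
        y = minmax_scale(x)
        assert y[np.argmin(x)] == 0 and y[np.argmax(x)] == 1

    def test_rank_preserving(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        np.testing.assert_array_equal(np.argsort(minmax_scale(x)), np.argsort(x))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            minmax_scale([1.0, 1.0, 1.0])


def synthetic_windows(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": 1 + 100_000 * np.arange(n),
            "end": 100_000 * np.arange(n) + 1_000_000,
            "n_snps": rng.integers(5, 30, size=n),
            "fst": rng.beta(1, 20, size=n),
            "pi_p1": rng.uniform(1e-4, 1e-3, size=n),
            "pi_p2": rng.uniform(1e-4, 1e-3, size=n),
            "pi_ratio": rng.lognormal(0, 0.3, size=n),
        }
    )


class TestCallSweeps:
    def test_constructed_extreme_window_is_the_sole_pop1_call(self):
        w = synthetic_windows(n=100)
        w.loc[42, "fst"] = 0.99
        w.loc[42, "pi_ratio"] = 1e-4
        calls = call_sweeps(w, top_frac=0.01)
        assert len(calls.windows_pop1_selected) == 1
        assert calls.windows_pop1_selected["start"].iloc[0] == w.loc[42, "start"]

    def test_degenerate_distribution_calls_nothing(self):
        w = synthetic_windows(n=100)
        w["fst"] = 0.1
        w["pi_ratio"] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            calls = call_sweeps(w)
        assert calls.windows_pop1_selected.empty
        assert calls.windows_pop2_selected.empty

    def test_few_windows_warns_about_quantile_resolution(self):
        with pytest.warns(UserWarning, match="usable windows"):
            call_sweeps(synthetic_windows(n=50))

    def test_direction_mapping_low_ratio_means_numerator_sweep(self):
        w = synthetic_windows(n=200)
        w.loc[10, ["fst", "pi_ratio"]] = [0.95, 1e-5]  # depleted numerator
        w.loc[20, ["fst", "pi_ratio"]] = [0.95, 1e5]  # depleted denominator
        calls = call_sweeps(w)
        assert w.loc[10, "start"] in set(calls.windows_pop1_selected["start"])
        assert w.loc[20, "start"] in set(calls.windows_pop2_selected["start"])

    def test_min_snps_windows_excluded_from_quantiles(self):
        w = synthetic_windows(n=200)
        w.loc[0, "n_snps"] = 1
        w.loc[0, "fst"] = 0.999  # extreme but unusable
        calls = call_sweeps(w, min_snps=2)
        assert w.loc[0, "start"] not in set(calls.windows_pop1_selected["start"])
        assert w.loc[0, "start"] not in set(calls.windows_pop2_selected["start"])

    def test_scaled_and_raw_thresholding_select_identical_windows(self):
        w = synthetic_windows(n=300, seed=7)
        raw = call_sweeps(w)
        scaled = w.copy()
        scaled["fst"] = minmax_scale(w["fst"].to_numpy())
        scaled["pi_ratio"] = minmax_scale(w["pi_ratio"].to_numpy())
        sc = call_sweeps(scaled)
        for ours, theirs in [
            (raw.windows_pop1_selected, sc.windows_pop1_selected),
            (raw.windows_pop2_selected, sc.windows_pop2_selected),
        ]:
            assert list(ours["start"]) == list(theirs["start"])

    def test_candidate_snps_lie_inside_regions(self):
        params = SimParams(seed=2)
        g, _ = simulate_genotypes(params)
        w = scan_windows(g, "highland", "lowland", window=1_000_000, step=100_000)
        calls = call_sweeps(w, g, pop1="highland", pop2="lowland")
        regions = pd.concat([calls.regions_pop1.assign(direction="highland"),
                             calls.regions_pop2.assign(direction="lowland")])
        for snp in calls.candidate_snps.itertuples(index=False):
            inside = regions[
                (regions["direction"] == snp.direction)
                & (regions["chrom"] == snp.chrom)
                & (regions["start"] <= snp.pos)
                & (regions["end"] >= snp.pos)
            ]
            assert len(inside) >= 1

    def test_nearest_rank_quantile_inclusive_tie_selection(self):
        w = synthetic_windows(n=200)
        thr = nearest_rank_quantile(w["fst"].to_numpy(), 0.99)
        calls = call_sweeps(w)
        # everything >= threshold that also clears a ratio criterion appears
        sel = pd.concat([calls.windows_pop1_selected, calls.windows_pop2_selected])
        assert (sel["fst"] >= thr).all()


class TestMergeWindows:
    def test_overlapping_and_adjacent_merge(self):
        w = pd.DataFrame(
            {
                "chrom": ["1", "1", "1", "2"],
                "start": [1, 50_001, 200_001, 1],
                "end": [100_000, 150_000, 300_000, 100_000],
            }
        )
        merged = merge_windows(w)
        assert merged.values.tolist() == [
            ["1", 1, 150_000], ["1", 200_001, 300_000], ["2", 1, 100_000],
        ]

    def test_bookended_intervals_merge(self):
        w = pd.DataFrame({"chrom": ["1", "1"], "start": [1, 101], "end": [100, 200]})
        assert merge_windows(w).values.tolist() == [["1", 1, 200]]
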