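"""Coverage counting, normalizations, ratios, profiles, deviations."""

import numpy as np
import pandas as pd
import pytest

from chromtraj.intervals import GenomicInterval, overlaps
from chromtraj.signal import (
    FragmentSet,
    SignalMatrix,
    accessibility_ratio,
    count_coverage,
    heatmap_matrix,
    motif_deviation,
    normalize_fpkpm,
    quantile_normalize,
)


def frag(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestCountCoverage:
    def test_counts_only_overlapping(self):
        loci = [GenomicInterval("chr1", 100, 300)]
        fs = FragmentSet("s", [frag("chr1", 120, 180), frag("chr1", 250, 320),
                               frag("chr1", 290, 340), frag("chr1", 500, 600),
                               frag("chr2", 120, 180)])
        assert count_coverage(loci, fs).tolist() == [3]

    def test_half_open_fragment_not_counted(self):
        loci = [GenomicInterval("chr1", 100, 300)]
        fs = FragmentSet("s", [frag("chr1", 50, 100)])
        assert count_coverage(loci, fs).tolist() == [0]

    def test_matches_bruteforce_oracle(self, rng):
        loci = [GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 400)))
                for s in rng.integers(0, 5000, size=30)]
        frags = [frag("chr1", int(s), int(s) + int(rng.integers(30, 200)))
                 for s in rng.integers(0, 5000, size=200)]
        fs = FragmentSet("s", frags)
        brute = [sum(overlaps(l, f) for f in frags) for l in loci]
        assert count_coverage(loci, fs).tolist() == brute


class TestFpkpm:
    def test_arithmetic(self):
        assert normalize_fpkpm(50, 2000, 10_000_000) == pytest.approx(2.5)

    def test_zero_count(self):
        assert normalize_fpkpm(0, 500, 1_000_000) == 0.0

    def test_doubling_library_halves_signal(self):
        one = normalize_fpkpm(40, 1000, 1_000_000)
        two = normalize_fpkpm(40, 1000, 2_000_000)
        assert one == pytest.approx(2 * two)

    @pytest.mark.parametrize("length,lib", [(0, 1000), (100, 0)])
    def test_degenerate_inputs_rejected(self, length, lib):
        with pytest.raises(ValueError):
            normalize_fpkpm(10, length, lib)


def reference_quantile_normalize(x):
    """Sort-and-average oracle, coded independently (no tie handling)."""
    x = np.asarray(x, dtype=float)
    mean_sorted = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j])
        for rank, row in enumerate(order):
            out[row, j] = mean_sorted[rank]
    return out


class TestQuantileNormalize:
    def test_identical_columns_shift_by_pseudocount(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 7.0], "b": [3.0, 1.0, 7.0]})
        out = quantile_normalize(SignalMatrix(df), pseudo_count=1)
        np.testing.assert_allclose(out.values.to_numpy(), df.to_numpy() + 1)
        assert out.normalization == "quantile"

    def test_permuted_columns_share_multiset(self, rng):
        col = rng.random(20)
        df = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = quantile_normalize(SignalMatrix(df)).values
        assert sorted(out["a"]) == pytest.approx(sorted(out["b"]))

    def test_matches_independent_reference(self, rng):
        x = rng.random((40, 4)) * 100  # continuous: ties have measure zero
        df = pd.DataFrame(x, columns=list("wxyz"))
        out = quantile_normalize(SignalMatrix(df), pseudo_count=1).values.to_numpy()
        np.testing.assert_allclose(out, reference_quantile_normalize(x + 1), atol=1e-9)

    def test_small_instance_frozen_values(self):
        # oracle by hand: +1 then sorted cols (2,3,6) & (2,4,9) -> ref (2, 3.5, 7.5)
        df = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [3.0, 8.0, 1.0]})
        out = quantile_normalize(SignalMatrix(df), pseudo_count=1).values
        np.testing.assert_allclose(out["a"], [2.0, 7.5, 3.5])
        np.testing.assert_allclose(out["b"], [3.5, 7.5, 2.0])

    def test_columns_share_sorted_vector_when_tie_free(self, rng):
        x = rng.permuted(np.tile(np.arange(25, dtype=float), (3, 1)).T, axis=0)
        out = quantile_normalize(SignalMatrix(pd.DataFrame(x))).values.to_numpy()
        for j in range(1, 3):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]))

    def test_tie_averaging_keeps_rank_order_and_totals(self, rng):
        # ties take the mean of the reference over their rank range: output
        # stays monotone in the input within each column, and column totals
        # stay close to the reference total (exact only without ties)
        x = rng.integers(0, 5, size=(30, 3)).astype(float)
        out = quantile_normalize(SignalMatrix(pd.DataFrame(x))).values.to_numpy()
        for j in range(3):
            order = np.argsort(x[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12)
            tied = x[:, j][:, None] == x[:, j][None, :]
            assert np.all(tied == (np.abs(out[:, j][:, None] - out[:, j][None, :]) < 1e-12))
        reference_total = np.sort(x + 1, axis=0).mean(axis=1).sum()
        np.testing.assert_allclose(out.sum(axis=0), reference_total, rtol=0.05)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(SignalMatrix(pd.DataFrame({"a": [1.0, 2.0]})))


class TestAccessibilityRatio:
    def test_equal_signals_give_one(self):
        np.testing.assert_allclose(accessibility_ratio([2.0, 5.0], [2.0, 5.0]), 1.0)

    def test_zero_mef_is_finite(self):
        r = accessibility_ratio([4.0], [0.0], epsilon=0.1)
        assert np.isfinite(r[0]) and r[0] > 1

    def test_strictly_monotone_in_day_signal(self):
        days = np.linspace(0, 10, 50)
        r = accessibility_ratio(days, np.full(50, 2.0))
        assert np.all(np.diff(r) > 0)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            accessibility_ratio([-1.0], [1.0])


class TestHeatmapMatrix:
    def test_single_fragment_at_rep_pos_hits_center_bin(self):
        loci = [GenomicInterval("chr1", 4900, 5100)]  # rep 5000
        fs = FragmentSet("s", [frag("chr1", 4995, 5005)], library_size=1)
        prof = heatmap_matrix(loci, fs, window=2000, n_bins=20)  # 100bp bins
        nz = np.nonzero(prof[0])[0]
        assert nz.tolist() == [9, 10]  # fragment straddles the center boundary

    def test_uniform_carpet_is_flat(self, rng):
        loci = [GenomicInterval("chr1", 10_000, 10_400)]
        frags = [frag("chr1", int(s), int(s) + 50)
                 for s in rng.integers(8000, 12_000, size=4000)]
        fs = FragmentSet("s", frags)
        prof = heatmap_matrix(loci, fs, window=2000, n_bins=10)[0]
        assert prof.std() / prof.mean() < 0.2

    def test_window_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix([], FragmentSet("s", [frag("chr1", 0, 10)]),
                           window=2000, n_bins=3)

    def test_left_edge_bins_zero(self):
        loci = [GenomicInterval("chr1", 0, 100)]  # rep 50, window extends to -950
        fs = FragmentSet("s", [frag("chr1", 10, 60)], library_size=1)
        prof = heatmap_matrix(loci, fs, window=2000, n_bins=20)[0]
        assert prof[:9].sum() == 0
        assert prof.sum() > 0


class TestMotifDeviation:
    def make_counts(self):
        return pd.DataFrame(
            {"s1": [10.0, 20.0, 30.0], "s2": [20.0, 40.0, 60.0]},
            index=["p1", "p2", "p3"],
        )

    def test_proportional_columns_give_zero_raw(self):
        out = motif_deviation(self.make_counts(), {"m": ["p1", "p2"]}, seed=0)
        np.testing.assert_allclose(out["raw_deviation"], 0.0, atol=1e-12)

    def test_all_peaks_set_raw_is_zero(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, size=(20, 3)).astype(float),
                              index=[f"p{i}" for i in range(20)])
        out = motif_deviation(counts, {"all": [f"p{i}" for i in range(20)]}, seed=0)
        np.testing.assert_allclose(out["raw_deviation"], 0.0, atol=1e-12)

    def test_hand_computed_raw(self):
        counts = pd.DataFrame({"s1": [10.0, 5.0, 5.0], "s2": [10.0, 15.0, 15.0]},
                              index=["p1", "p2", "p3"])
        out = motif_deviation(counts, {"m": ["p1"]}, seed=0).set_index("sample")
        # T_p1=20, N_s1=20, N=60 -> E=20*20/60=6.667; X=10 -> raw=0.5
        assert out.loc["s1", "raw_deviation"] == pytest.approx(0.5)
        assert out.loc["s2", "raw_deviation"] == pytest.approx(-0.25)

    def test_seeded_reproducibility(self, rng):
        counts = pd.DataFrame(rng.integers(1, 60, size=(40, 4)).astype(float),
                              index=[f"p{i}" for i in range(40)])
        sets = {"m": [f"p{i}" for i in range(0, 10)]}
        a = motif_deviation(counts, sets, seed=42)
        b = motif_deviation(counts, sets, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_opening_pattern_ranks_by_z(self, rng):
        # 30 marked peaks opened only in condition A; backgrounds flat
        n = 120
        idx = [f"p{i}" for i in range(n)]
        base = rng.integers(8, 12, size=n).astype(float)
        counts = pd.DataFrame({
            "MEF": base,
            "A": base + np.where(np.arange(n) < 30, 40.0, 0.0),
            "B": base + rng.integers(0, 2, size=n),
        }, index=idx)
        out = motif_deviation(counts, {"marked": idx[:30]}, seed=7).set_index("sample")
        assert out.loc["A", "z"] > 0
        assert out.loc["A", "z"] == out["z"].max()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_deviation(self.make_counts(), {"m": []}, seed=0)
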