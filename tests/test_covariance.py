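"""Correlation structure, distance binning, slope, and shuffle null."""

import math

import numpy as np
import pytest

from numchan import (CorrMatrix, DistanceBins, WfMatrix,
                     binned_correlation_curve, distance_slope,
                     numerical_distance, shuffle_null, wf_correlation_matrix)


def pearson_brute(x, y):
    """Textbook two-pass Pearson r, independent of numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def corr_from_targets(targets, values):
    """CorrMatrix with given off-diagonal generator values(d) applied."""
    t = np.asarray(targets, dtype=float)
    M = np.ones((t.size, t.size))
    for i in range(t.size):
        for j in range(t.size):
            if i != j:
                M[i, j] = values(numerical_distance(t[i], t[j]))
    return CorrMatrix(targets=t, values=M)


class TestNumericalDistance:
    def test_octave_pairs(self):
        assert numerical_distance(8, 32) == pytest.approx(math.log10(4))
        assert numerical_distance(32, 8) == pytest.approx(math.log10(4))

    def test_zero_iff_equal(self):
        assert numerical_distance(14, 14) == 0.0
        assert numerical_distance(14, 16) == pytest.approx(0.05799, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            numerical_distance(0, 8)


class TestCorrelationMatrix:
    def test_identical_rows_correlate_perfectly(self):
        base = np.array([[0.1, 0.1, 0.3], [0.2, 0.2, 0.1],
                         [0.3, 0.3, 0.2], [0.15, 0.15, 0.4]])
        wfm = WfMatrix(participants=list("abcd"), targets=[8, 16, 32],
                       values=base)
        corr = wf_correlation_matrix(wfm)
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        wfm = WfMatrix(participants=list("abc"), targets=[8.0, 16.0],
                       values=np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        corr = wf_correlation_matrix(wfm)
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self, small_wfm):
        corr = wf_correlation_matrix(small_wfm)
        X = small_wfm.values
        for i in range(4):
            for j in range(4):
                expected = pearson_brute(list(X[:, i]), list(X[:, j]))
                assert corr.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_target_named_in_error(self):
        wfm = WfMatrix(participants=list("abc"), targets=[8.0, 16.0],
                       values=np.array([[0.2, 0.1], [0.2, 0.2], [0.2, 0.3]]))
        with pytest.raises(ValueError, match="8"):
            wf_correlation_matrix(wfm)

    def test_csv_round_trip(self, tmp_path, small_wfm):
        corr = wf_correlation_matrix(small_wfm)
        corr.to_csv(tmp_path / "c.csv")
        back = CorrMatrix.from_csv(tmp_path / "c.csv")
        np.testing.assert_allclose(back.values, corr.values, atol=1e-12)


class TestDistanceBins:
    def test_printed_edges_partition_the_55_pairs(self):
        targets = np.array([8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32], float)
        corr = corr_from_targets(targets, lambda d: 0.5)
        curve = binned_correlation_curve(corr)
        assert curve["n_pairs"].sum() == 55  # 11 choose 2
        assert len(curve) == 6

    def test_pair_8_10_lands_in_second_bin(self):
        bins = DistanceBins()
        d = numerical_distance(8, 10)  # 0.0969
        assert d == pytest.approx(0.09691, abs=1e-4)
        assert bins.assign([d])[0] == 1
        assert bins.labels()[1] == "0.08-0.14"

    def test_edges_are_half_open(self):
        bins = DistanceBins()
        assert bins.assign([0.08])[0] == 1   # [0.08, 0.14)
        assert bins.assign([0.079999])[0] == 0
        assert bins.assign([0.39])[0] == 5   # last bin [0.39, inf)

    def test_constant_matrix_gives_constant_curve(self):
        targets = np.geomspace(8, 32, 11)
        corr = corr_from_targets(targets, lambda d: 0.37)
        curve = binned_correlation_curve(corr)
        filled = curve.dropna(subset=["mean_r"])
        assert np.allclose(filled["mean_r"], 0.37)

    def test_empty_bins_reported_not_dropped(self):
        corr = corr_from_targets([8.0, 9.0], lambda d: 0.5)  # d = 0.051
        curve = binned_correlation_curve(corr)
        assert curve["n_pairs"].tolist() == [1, 0, 0, 0, 0, 0]
        assert curve["mean_r"].isna().tolist() == [False] + [True] * 5

    def test_binning_matches_brute_force(self, small_wfm):
        corr = wf_correlation_matrix(small_wfm)
        curve = binned_correlation_curve(corr)
        bins = DistanceBins()
        edges = (0.0,) + bins.inner_edges + (np.inf,)
        t = corr.targets
        for k in range(6):
            rs = [corr.values[i, j]
                  for i in range(len(t)) for j in range(i + 1, len(t))
                  if edges[k] <= numerical_distance(t[i], t[j]) < edges[k + 1]]
            if rs:
                assert curve["mean_r"].iloc[k] == pytest.approx(
                    np.mean(rs), abs=1e-12)
            else:
                assert np.isnan(curve["mean_r"].iloc[k])

    def test_curve_invariant_to_target_relabelling(self, small_wfm):
        corr = wf_correlation_matrix(small_wfm)
        # permute targets and participants' columns consistently
        perm = [2, 0, 3, 1]
        order = np.argsort(small_wfm.targets[perm])
        shuffled = WfMatrix(
            participants=small_wfm.participants,
            targets=small_wfm.targets[perm][order],
            values=small_wfm.values[:, perm][:, order],
            condition="fast")
        c2 = wf_correlation_matrix(shuffled)
        a = binned_correlation_curve(corr)
        b = binned_correlation_curve(c2)
        np.testing.assert_allclose(a["mean_r"], b["mean_r"], atol=1e-12)


class TestDistanceSlope:
    def test_constant_correlations_give_zero_slope(self):
        corr = corr_from_targets(np.geomspace(8, 32, 6), lambda d: 0.4)
        assert distance_slope(corr).slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_construction_recovered_exactly(self):
        corr = corr_from_targets(np.geomspace(8, 32, 6), lambda d: 1.0 - d)
        fit = distance_slope(corr)
        assert fit.slope == pytest.approx(-1.0, abs=1e-10)
        assert fit.stderr == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_design_rejected(self):
        corr = corr_from_targets([8.0, 16.0], lambda d: 0.5)
        with pytest.raises(ValueError):
            distance_slope(corr)


class TestShuffleNull:
    def test_same_seed_reproduces_null(self, small_wfm):
        a = shuffle_null(small_wfm, n_iter=50, seed=9)
        b = shuffle_null(small_wfm, n_iter=50, seed=9)
        np.testing.assert_array_equal(a.slopes, b.slopes)
        np.testing.assert_allclose(a.bin_means, b.bin_means, equal_nan=True)

    def test_permutation_preserves_row_multisets(self):
        # permuted() on axis 1 must keep each participant's Wf multiset
        rng = np.random.default_rng(0)
        X = np.arange(20.0).reshape(4, 5)
        Xp = rng.permuted(X, axis=1)
        for row, prow in zip(X, Xp):
            assert sorted(row) == sorted(prow)
        assert not np.array_equal(X, Xp)

    def test_null_slope_centred_on_zero(self, small_wfm):
        null = shuffle_null(small_wfm, n_iter=2000, seed=1)
        assert abs(null.slope_mean) < 3 * null.slopes.std(ddof=1) / np.sqrt(2000)

    def test_null_preserves_grand_mean_correlation(self):
        rng = np.random.default_rng(3)
        wfm = WfMatrix(participants=[f"S{i}" for i in range(25)],
                       targets=np.geomspace(8, 32, 8),
                       values=0.1 + 0.1 * rng.random((25, 8)))
        observed = wf_correlation_matrix(wfm).mean_offdiag()
        null = shuffle_null(wfm, n_iter=2000, seed=4)
        se = null.mean_offdiag.std(ddof=1) / np.sqrt(null.n_iter)
        assert abs(null.mean_offdiag.mean() - observed) < 4 * se + 0.01

    def test_detects_real_structure(self, low_noise_two_channel):
        from numchan import simulate_cohort
        wfm = simulate_cohort(low_noise_two_channel, 30, seed=6)
        null = shuffle_null(wfm, n_iter=500, seed=7)
        assert null.observed_slope < null.slope_band()[0]
        assert null.p_value < 0.01
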