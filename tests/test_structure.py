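"""Clustering, contiguity control, components, and tuning fits."""

import numpy as np
import pytest

from numchan import (ChannelModelConfig, WfMatrix, contiguity_null,
                     factor_solution, hierarchical_clusters, is_contiguous,
                     loggaussian_fit, simulate_cohort, zscore_targets)
from numchan.structure import _loggauss


@pytest.fixture
def two_channel_cohort(low_noise_two_channel):
    return simulate_cohort(low_noise_two_channel, 30, seed=100)


class TestZScore:
    def test_small_column(self):
        wfm = WfMatrix(participants=list("abc"), targets=[8.0, 16.0],
                       values=np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 9.0]]))
        Xz = zscore_targets(wfm)
        assert Xz[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_columns_standardized(self, small_wfm):
        Xz = zscore_targets(small_wfm)
        assert Xz.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert Xz.std(axis=0, ddof=1) == pytest.approx(np.ones(4), abs=1e-12)

    def test_idempotent(self, small_wfm):
        Xz = zscore_targets(small_wfm)
        again = zscore_targets(WfMatrix(participants=small_wfm.participants,
                                        targets=small_wfm.targets,
                                        values=Xz - Xz.min() + 0.1))
        np.testing.assert_allclose(again, Xz, atol=1e-10)

    def test_zero_variance_target_rejected_by_name(self):
        wfm = WfMatrix(participants=list("abc"), targets=[8.0, 16.0],
                       values=np.array([[0.2, 0.1], [0.2, 0.2], [0.2, 0.3]]))
        with pytest.raises(ValueError, match="8"):
            zscore_targets(wfm)


class TestHierarchicalClusters:
    def test_identical_targets_merge_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        col = rng.random(10)
        other = rng.random((10, 2))
        values = np.column_stack([col, col, other])
        wfm = WfMatrix(participants=[f"S{i}" for i in range(10)],
                       targets=[8.0, 9.0, 16.0, 32.0], values=values)
        res = hierarchical_clusters(wfm)
        assert res.linkage[0, 0] == 0 and res.linkage[0, 1] == 1
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_contiguous_two_cluster_split(self, two_channel_cohort):
        res = hierarchical_clusters(two_channel_cohort)
        assert res.n_clusters == 2
        assert is_contiguous(res.labels)
        low, high = res.clusters()
        assert 8.0 in low and 32.0 in high

    def test_merge_heights_monotone(self, two_channel_cohort):
        res = hierarchical_clusters(two_channel_cohort)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_explicit_cluster_count_override(self, two_channel_cohort):
        res = hierarchical_clusters(two_channel_cohort, n_clusters=3)
        assert res.n_clusters == 3

    def test_participant_order_irrelevant(self, two_channel_cohort):
        perm = np.random.default_rng(1).permutation(
            two_channel_cohort.n_participants)
        shuffled = WfMatrix(
            participants=[two_channel_cohort.participants[i] for i in perm],
            targets=two_channel_cohort.targets,
            values=two_channel_cohort.values[perm],
            condition="sim")
        a = hierarchical_clusters(two_channel_cohort)
        b = hierarchical_clusters(shuffled)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_assignments_partition_targets(self, two_channel_cohort):
        res = hierarchical_clusters(two_channel_cohort)
        assert sorted(t for c in res.clusters() for t in c) == \
            sorted(two_channel_cohort.targets)

    def test_too_few_targets_rejected(self):
        wfm = WfMatrix(participants=list("abcd"), targets=[8.0, 16.0],
                       values=np.random.default_rng(2).random((4, 2)))
        with pytest.raises(ValueError):
            hierarchical_clusters(wfm)

    def test_newick_export_parses(self, two_channel_cohort):
        nwk = hierarchical_clusters(two_channel_cohort).to_newick()
        assert nwk.endswith(";")
        for t in two_channel_cohort.targets:
            assert f"{t:g}" in nwk


class TestIsContiguous:
    def test_interval_split_is_contiguous(self):
        targets = [8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32]
        labels = [1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2]
        assert is_contiguous(labels, targets)

    def test_extremes_in_one_cluster_is_not(self):
        targets = [8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32]
        labels = [1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 1]
        assert not is_contiguous(labels, targets)

    def test_single_cluster_is_contiguous(self):
        assert is_contiguous([1, 1, 1], [8, 16, 32])

    def test_dict_input(self):
        assert is_contiguous({8: 1, 10: 1, 16: 2, 32: 2})
        assert not is_contiguous({8: 1, 10: 2, 16: 1, 32: 2})


class TestContiguityNull:
    def test_seeded_reproducibility(self, two_channel_cohort):
        a = contiguity_null(two_channel_cohort, n_iter=100, seed=5)
        b = contiguity_null(two_channel_cohort, n_iter=100, seed=5)
        assert a.proportion_contiguous == b.proportion_contiguous

    def test_contiguity_rare_under_permutation(self, flat_config):
        wfm = simulate_cohort(flat_config, 30, seed=6)
        null = contiguity_null(wfm, n_iter=1000, seed=7)
        assert null.proportion_contiguous < 0.05

    def test_real_structure_is_contiguous_across_cohorts(
            self, well_separated_two_channel):
        hits = 0
        for rep in range(20):
            wfm = simulate_cohort(well_separated_two_channel, 30,
                                  seed=200 + rep)
            res = hierarchical_clusters(wfm)
            hits += is_contiguous(res.labels)
        assert hits >= 19  # >= 95% of simulated cohorts


class TestFactorSolution:
    def test_two_channels_give_two_components(self, two_channel_cohort):
        sol = factor_solution(two_channel_cohort)
        assert sol.n_components == 2
        # each component dominates one flank of the target range
        lead = np.abs(sol.loadings).argmax(axis=0)
        peaks = sorted(two_channel_cohort.targets[lead])
        assert peaks[0] <= 14 and peaks[1] >= 19

    def test_equicorrelated_data_gives_one_component(self, flat_config):
        # flat model: a single shared factor; eigenstructure of an
        # equicorrelation matrix has one eigenvalue 1+(T-1)r > 1, rest 1-r
        cfg = flat_config.with_(noise_sd=0.04)
        wfm = simulate_cohort(cfg, 200, seed=8, mode="analytic")
        sol = factor_solution(wfm)
        assert sol.n_components == 1
        assert np.all(sol.loadings[:, 0] > 0)

    def test_variance_explained_matches_eigenvalues(self, two_channel_cohort):
        sol = factor_solution(two_channel_cohort)
        expected = sol.eigenvalues[:2] / two_channel_cohort.n_targets
        assert sol.variance_explained == pytest.approx(expected)
        assert 0 < sol.total_variance_explained <= 1

    def test_promax_and_varimax_agree_on_dominant_structure(
            self, two_channel_cohort):
        p = factor_solution(two_channel_cohort, rotation="promax")
        v = factor_solution(two_channel_cohort, rotation="varimax")
        # same target-to-component assignment after sign/order alignment
        assign_p = np.abs(p.loadings).argmax(axis=1)
        assign_v = np.abs(v.loadings).argmax(axis=1)
        agree = (assign_p == assign_v).mean()
        assert agree == 1.0 or agree == pytest.approx(1.0, abs=0.1)

    def test_rotation_none_returns_principal_axes(self, two_channel_cohort):
        sol = factor_solution(two_channel_cohort, rotation="none")
        R = np.corrcoef(zscore_targets(two_channel_cohort), rowvar=False)
        recon = sol.loadings @ sol.loadings.T
        # rank-2 eigendecomposition reproduces the dominant structure
        assert np.abs(R - recon)[np.triu_indices(11, 1)].mean() < 0.2


class TestLogGaussianFit:
    def test_exact_recovery_from_generated_profile(self):
        targets = np.array([8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32], float)
        y = _loggauss(targets, a=0.9, peak=11.0, width=0.25)
        fit = loggaussian_fit(y, targets)
        assert fit.peak == pytest.approx(11.0, abs=1e-6)
        assert fit.width == pytest.approx(0.25, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_profile_does_not_crash(self):
        targets = np.geomspace(8, 32, 6)
        fit = loggaussian_fit(np.full(6, 0.5), targets)
        assert np.isfinite(fit.peak) and fit.width > 0
        assert fit.r2 <= 1.0

    def test_negative_loadings_permitted(self):
        targets = np.geomspace(8, 32, 8)
        y = _loggauss(targets, a=0.8, peak=28.0, width=0.2) - 0.1
        fit = loggaussian_fit(y, targets)
        assert fit.r2 > 0.5

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError):
            loggaussian_fit([0.1, 0.2, 0.3], [8, 16, 32])

    def test_component_peaks_recover_generating_channels(
            self, well_separated_two_channel):
        # peaks of the two rotated components straddle the geometric mean
        # of the generating channels (~16.1) and land within +/-25% of the
        # generating 10 / 26; channels must lie inside the probed range for
        # this to be identifiable (edge channels give flank-plateau
        # loadings whose fitted peak is the flank centre)
        gen_lo, gen_hi = well_separated_two_channel.peaks
        mid = np.sqrt(gen_lo * gen_hi)
        hits = 0
        for rep in range(20):
            wfm = simulate_cohort(well_separated_two_channel, 30,
                                  seed=300 + rep)
            sol = factor_solution(wfm)
            if sol.n_components != 2:
                continue
            peaks = sorted(loggaussian_fit(sol.loadings[:, k], wfm.targets).peak
                           for k in range(2))
            if (0.75 * gen_lo <= peaks[0] <= 1.25 * gen_lo
                    and 0.75 * gen_hi <= peaks[1] <= 1.25 * gen_hi):
                assert peaks[0] < mid < peaks[1]
                hits += 1
        assert hits >= 18  # >= 90% of cohorts
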