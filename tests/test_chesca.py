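import math

import numpy as np
import pandas as pd
import pytest

from allokin import (
    CommunityMap,
    CorrelationMatrix,
    cluster_residues,
    community_correlation,
    correlation_matrix,
    correlation_scores,
    filter_responsive_residues,
    project_trajectory,
)
from allokin.errors import ConfigError, DomainError, InsufficientDataError
from allokin.shift_io import ShiftTable

from conftest import STATES, brute_force_abs_pearson, make_table

# two exactly orthogonal (after centering) latent patterns over four states
PATTERN_A = np.array([0.0, 0.45, 0.55, 1.0])
PATTERN_B = np.array([0.0, 1.0, 1.0, 0.0])


def table_from_patterns(blocks, scale=0.5):
    """blocks: {residue_id: (pattern, amplitude)} → ShiftTable with δN static."""
    traj = {}
    for rid, (pattern, amp) in blocks.items():
        traj[rid] = [(8.0 + amp * scale * p, 119.0) for p in pattern]
    return make_table(traj)


class TestInclusionFilter:
    def test_shift_exceeding_mean_linewidth_included(self):
        # Δδ_H = 0.10 ppm against linewidths 0.04/0.04 → 0.10 > 0.04
        traj = {1: [(8.0, 119.0), (8.0, 119.0), (8.0, 119.0), (8.10, 119.0)],
                2: [(8.0, 119.0)] * 4,
                3: [(8.0, 119.0)] * 4}
        t = make_table(traj, lw=(0.04, 0.4))
        assert filter_responsive_residues(t) == [1]

    def test_static_residue_excluded(self):
        t = make_table({1: [(8.0, 119.0)] * 4}, lw=(0.01, 0.1))
        assert filter_responsive_residues(t) == []

    def test_missing_linewidths_use_fallback_with_warning(self):
        t = make_table({1: [(8.0, 119.0)] * 3 + [(8.5, 119.0)]})
        df = t.records.drop(columns=["lw_H", "lw_N"])
        t2 = ShiftTable(df, states=STATES)
        with pytest.warns(UserWarning, match="fallback"):
            assert filter_responsive_residues(t2) == [1]

    def test_missing_linewidths_without_fallback_is_error(self):
        t = make_table({1: [(8.0, 119.0)] * 4})
        df = t.records.drop(columns=["lw_H", "lw_N"])
        t2 = ShiftTable(df, states=STATES)
        with pytest.raises(ConfigError):
            filter_responsive_residues(t2, fallback_lw=None)

    def test_noiseless_network_recovered_exactly(self, noiseless_dataset):
        table, _, truth = noiseless_dataset
        assert filter_responsive_residues(table) == sorted(truth.network_members)


class TestProjectTrajectory:
    def test_collinear_points_have_infinite_linearity(self):
        pts = np.array([[8.0 + 0.1 * k, 119.0 + 0.5 * k] for k in range(4)])
        traj = project_trajectory(pts)
        assert math.isinf(traj.linearity)
        # trace reproduces signed distances along the line
        seg = np.diff(traj.projected_trace)
        step = np.hypot(0.1, 0.154 * 0.5)
        np.testing.assert_allclose(np.abs(seg), step, atol=1e-12)

    def test_isotropic_square_has_unit_linearity(self):
        # four points on a square in weighted shift space
        w = 0.154
        pts = np.array([[1.0, 0.0], [0.0, 1.0 / w], [-1.0, 0.0], [0.0, -1.0 / w]])
        traj = project_trajectory(pts)
        assert traj.linearity == pytest.approx(1.0, abs=1e-9)

    def test_linearity_matches_covariance_eigen_oracle(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([
            8.0 + 0.1 * PATTERN_A + rng.normal(0, 0.01, 4),
            119.0 + 1.0 * PATTERN_A + rng.normal(0, 0.05, 4),
        ])
        traj = project_trajectory(pts)
        scaled = pts * np.array([1.0, 0.154])
        c = scaled - scaled.mean(axis=0)
        a, b, d = c[:, 0] @ c[:, 0], c[:, 0] @ c[:, 1], c[:, 1] @ c[:, 1]
        half = math.sqrt((a - d) ** 2 + 4 * b * b) / 2.0
        eig1, eig2 = (a + d) / 2.0 + half, (a + d) / 2.0 - half
        assert traj.linearity == pytest.approx(math.sqrt(eig1 / eig2), rel=1e-10)

    def test_fewer_than_three_states_rejected(self):
        with pytest.raises(InsufficientDataError):
            project_trajectory(np.array([[8.0, 119.0], [8.1, 119.5]]))


class TestCorrelationMatrix:
    def test_anticollinear_traces_correlate_fully(self):
        t = table_from_patterns({1: (PATTERN_A, 1.0), 2: (PATTERN_A, -2.0)})
        m = correlation_matrix(t, residues=[1, 2])
        assert m.value(1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_traces_uncorrelated(self):
        t = table_from_patterns({1: (PATTERN_A, 1.0), 2: (PATTERN_B, 1.0)})
        m = correlation_matrix(t, residues=[1, 2])
        assert m.value(1, 2) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_network_fully_correlated(self, noiseless_dataset):
        table, _, truth = noiseless_dataset
        m = correlation_matrix(table, residues=truth.network_members)
        assert np.allclose(m.R, 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed,n", [(0, 8), (1, 12), (2, 20)])
    def test_oracle_equivalence_on_small_fixtures(self, seed, n):
        from allokin.synthetic import SyntheticShiftConfig, generate_shift_dataset
        cfg = SyntheticShiftConfig(
            n_residues=n, networked_fraction=1.0,
            noise_sd_H=0.02, noise_sd_N=0.15, seed=seed)
        table, _, _ = generate_shift_dataset(cfg)
        residues = table.residues
        m = correlation_matrix(table, residues=residues)
        traces = np.array([
            project_trajectory(table.trajectory(r)).projected_trace
            for r in m.residues
        ])
        np.testing.assert_allclose(m.R, brute_force_abs_pearson(traces), atol=1e-12)

    def test_zero_variance_residue_dropped_with_warning(self):
        t = table_from_patterns({1: (PATTERN_A, 1.0), 2: (PATTERN_A, 2.0),
                                 3: (PATTERN_A, 0.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            m = correlation_matrix(t, residues=[1, 2, 3])
        assert m.residues == [1, 2]

    def test_fewer_than_four_states_rejected(self):
        t = make_table({1: [(8, 119)] * 3, 2: [(8.1, 119)] * 3},
                       states=["apo", "ADP", "ATPgN"])
        with pytest.raises(InsufficientDataError):
            correlation_matrix(t, residues=[1, 2])

    def test_permutation_safety(self, noisy_dataset):
        table, _, _ = noisy_dataset
        shuffled = ShiftTable(table.records.sample(frac=1.0, random_state=2),
                              states=table.states)
        m1 = correlation_matrix(table)
        m2 = correlation_matrix(shuffled)
        s1 = correlation_scores(m1).scores
        s2 = correlation_scores(m2).scores
        assert s1 == s2


class TestCorrelationScores:
    def _matrix(self, n, pairs, residues=None):
        R = np.eye(n)
        for i, j, v in pairs:
            R[i, j] = R[j, i] = v
        return CorrelationMatrix(residues=residues or list(range(1, n + 1)), R=R)

    def test_seven_partners_over_350(self):
        m = self._matrix(9, [(0, j, 0.99) for j in range(1, 8)])
        prof = correlation_scores(m, denominator=350)
        assert prof.scores[1] == pytest.approx(7 / 350)
        assert prof.scores[1] == pytest.approx(0.02)

    def test_isolated_residue_scores_zero(self):
        m = self._matrix(3, [(0, 1, 0.99)])
        assert correlation_scores(m).scores[3] == 0.0

    def test_complete_network_scores(self):
        m = self._matrix(10, [(i, j, 1.0) for i in range(10) for j in range(i + 1, 10)])
        prof = correlation_scores(m, denominator=10)
        assert all(v == pytest.approx(9 / 10) for v in prof.scores.values())

    def test_bad_denominator(self):
        m = self._matrix(2, [])
        with pytest.raises(DomainError):
            correlation_scores(m, denominator=0)

    def test_scores_monotone_in_cutoff(self, noisy_dataset):
        table, _, _ = noisy_dataset
        m = correlation_matrix(table)
        prev = None
        for cutoff in (0.5, 0.7, 0.9, 0.98):
            scores = correlation_scores(m, cutoff=cutoff).scores
            if prev is not None:
                assert all(scores[r] <= prev[r] + 1e-15 for r in scores)
            prev = scores


class TestClustering:
    def test_two_independent_networks_give_two_clusters(self):
        blocks = {r: (PATTERN_A, 1.0 + 0.2 * r) for r in (1, 2, 3)}
        blocks.update({r: (PATTERN_B, 1.0 + 0.2 * r) for r in (4, 5, 6)})
        m = correlation_matrix(table_from_patterns(blocks), residues=list(range(1, 7)))
        labels = cluster_residues(m)
        assert labels[1] == labels[2] == labels[3] != 0
        assert labels[4] == labels[5] == labels[6] != 0
        assert labels[1] != labels[4]

    def test_uncorrelated_matrix_gives_singletons(self):
        R = np.full((4, 4), 0.1)
        np.fill_diagonal(R, 1.0)
        m = CorrelationMatrix(residues=[1, 2, 3, 4], R=R)
        assert set(cluster_residues(m).values()) == {0}

    def test_single_network_single_cluster(self, noiseless_dataset):
        table, _, truth = noiseless_dataset
        m = correlation_matrix(table, residues=truth.network_members)
        labels = cluster_residues(m)
        assert set(labels.values()) == {1}


class TestCommunityCorrelation:
    def _fixture_matrix(self):
        # residues 1,2 in X; 3,4,5 in Y; exactly 3 qualifying cross pairs
        R = np.eye(5)
        qualifying = [(0, 2), (0, 3), (1, 2)]
        for i in range(5):
            for j in range(i + 1, 5):
                v = 0.9 if (i, j) in qualifying else 0.3
                R[i, j] = R[j, i] = v
        m = CorrelationMatrix(residues=[1, 2, 3, 4, 5], R=R, cutoff=0.98)
        cmap = CommunityMap(assignments={1: "X", 2: "X", 3: "Y", 4: "Y", 5: "Y"})
        return m, cmap

    def test_partial_cross_block(self):
        m, cmap = self._fixture_matrix()
        cm = community_correlation(m, cmap, r_cutoff=0.8)
        assert cm.value("X", "Y") == pytest.approx(3 / 6)
        assert cm.value("Y", "X") == cm.value("X", "Y")
        assert cm.value("X", "X") == 0.0  # no within-X qualifying pair
        assert cm.n == {"X": 2, "Y": 3}

    def test_bounds(self, noiseless_dataset):
        table, cmap, truth = noiseless_dataset
        m = correlation_matrix(table, residues=truth.network_members)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cm = community_correlation(m, cmap)
        vals = cm.R.to_numpy()
        finite = vals[np.isfinite(vals)]
        # noiseless single network: every defined entry is exactly 1
        assert np.allclose(finite, 1.0)

    def test_no_qualifying_pairs_is_zero(self):
        R = np.full((4, 4), 0.1)
        np.fill_diagonal(R, 1.0)
        m = CorrelationMatrix(residues=[1, 2, 3, 4], R=R)
        cmap = CommunityMap(assignments={1: "X", 2: "X", 3: "Y", 4: "Y"})
        cm = community_correlation(m, cmap)
        assert cm.value("X", "Y") == 0.0

    def test_single_member_community_undefined(self):
        R = np.eye(2)
        m = CorrelationMatrix(residues=[1, 2], R=R)
        cmap = CommunityMap(assignments={1: "X", 2: "Y"})
        with pytest.warns(UserWarning, match="undefined"):
            cm = community_correlation(m, cmap)
        assert math.isnan(cm.value("X", "X"))

    def test_community_matrix_monotone_in_cutoff(self, noisy_dataset):
        table, cmap, _ = noisy_dataset
        m = correlation_matrix(table)
        import warnings
        prev = None
        for cutoff in (0.5, 0.8, 0.95):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                cm = community_correlation(m, cmap, r_cutoff=cutoff)
            vals = cm.R.fillna(0.0)
            if prev is not None:
                assert (vals.to_numpy() <= prev.to_numpy() + 1e-15).all()
            prev = vals
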