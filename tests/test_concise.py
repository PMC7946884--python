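import math

import numpy as np
import pytest

from allokin import (
    ShiftTable,
    SyntheticShiftConfig,
    community_concise,
    concise_scores,
    ddg_from_closure,
    free_energy_map,
    generate_shift_dataset,
    percent_closed,
)
from allokin.errors import DomainError, InsufficientDataError

from conftest import STATES, make_table

LAMBDAS = [0.0, 0.45, 0.55, 1.0]


def expected_standardized_lambdas():
    lam = np.array(LAMBDAS)
    return (lam - lam.mean()) / lam.std(ddof=1)


class TestConciseScores:
    def test_state_means_follow_lambda_exactly_without_noise(self, noiseless_dataset):
        table, _, _ = noiseless_dataset
        res = concise_scores(table)
        means = [res.mean_pc[s] for s in STATES]
        assert means == sorted(means)
        # every networked residue's standardized trace equals the standardized
        # λ pattern, so the pooled means match it too
        np.testing.assert_allclose(means, expected_standardized_lambdas(), atol=1e-9)
        assert all(res.sd_pc[s] == pytest.approx(0.0, abs=1e-9) for s in STATES)

    def test_identical_states_coincide(self):
        cfg = SyntheticShiftConfig(
            n_residues=30,
            state_lambdas={"apo": 0.0, "ADP": 0.5, "ATPgN": 0.5, "ATPgN+PKI": 1.0},
            noise_sd_H=0.0, noise_sd_N=0.0, seed=4,
        )
        table, _, _ = generate_shift_dataset(cfg)
        res = concise_scores(table)
        assert abs(res.mean_pc["ADP"] - res.mean_pc["ATPgN"]) < 1e-9

    def test_circular_trajectories_rejected_by_linearity(self):
        # four states on a circle in weighted shift space: s1/s2 = 1 < 3
        w = 0.154
        traj = {}
        for r in range(1, 6):
            a = 0.1 * r
            traj[r] = [(8.0 + a, 119.0), (8.0, 119.0 + a / w),
                       (8.0 - a, 119.0), (8.0, 119.0 - a / w)]
        with pytest.raises(InsufficientDataError):
            concise_scores(make_table(traj))

    def test_axis_oriented_apo_low(self, noisy_dataset):
        table, _, _ = noisy_dataset
        res = concise_scores(table)
        assert res.mean_pc["apo"] < res.mean_pc["ATPgN+PKI"]
        assert res.mean_pc["apo"] == min(res.mean_pc.values())

    def test_affine_invariance_of_scores(self, noiseless_dataset):
        table, _, truth = noiseless_dataset
        res1 = concise_scores(table)
        shifted = table.records.copy()
        target = truth.network_members[0]
        mask = shifted["residue_id"] == target
        shifted.loc[mask, "delta_H"] += 3.0
        shifted.loc[mask, "delta_N"] += 7.0
        res2 = concise_scores(ShiftTable(shifted, states=table.states))
        np.testing.assert_allclose(res1.scores.loc[target], res2.scores.loc[target],
                                   atol=1e-9)


class TestCommunityConcise:
    def test_homogeneous_network_gives_uniform_community_positions(self, noiseless_dataset):
        table, cmap, _ = noiseless_dataset
        global_res = concise_scores(table)
        per_comm = community_concise(table, cmap)
        defined = {c: r for c, r in per_comm.items() if r is not None}
        assert defined
        for res in defined.values():
            for s in STATES:
                assert res.mean_pc[s] == pytest.approx(global_res.mean_pc[s], abs=1e-9)

    def test_partially_closing_community_detected(self):
        # one community stops at λ = 0.75 in the ternary state
        cfg = SyntheticShiftConfig(
            n_residues=90, networked_fraction=1.0, community_count=3,
            noise_sd_H=0.0, noise_sd_N=0.0, seed=9,
            community_lambdas={"ComB": {"ATPgN+PKI": 0.75}},
        )
        table, cmap, _ = generate_shift_dataset(cfg)
        per_comm = community_concise(table, cmap)
        tern = {c: r.mean_pc["ATPgN+PKI"] for c, r in per_comm.items()}
        assert tern["ComB"] < tern["ComA"]
        assert tern["ComB"] < tern["ComC"]

    def test_tiny_community_undefined(self, noiseless_dataset):
        table, _, _ = noiseless_dataset
        from allokin import CommunityMap
        residues = table.residues
        cmap = CommunityMap(assignments={residues[0]: "Tiny", residues[1]: "Tiny",
                                         **{r: "Rest" for r in residues[2:]}})
        with pytest.warns(UserWarning, match="Tiny"):
            out = community_concise(table, cmap)
        assert out["Tiny"] is None


class TestClosureMapping:
    MEANS = {"apo": -1.2, "mid": 0.05, "closed": 1.3}

    def test_anchors(self):
        pct = percent_closed(self.MEANS, "apo", "closed")
        assert pct["apo"] == 0.0
        assert pct["closed"] == 100.0

    def test_midpoint(self):
        pct = percent_closed({"a": 0.0, "m": 0.5, "b": 1.0}, "a", "b")
        assert pct["m"] == pytest.approx(50.0)

    def test_degenerate_references(self):
        with pytest.raises(DomainError):
            percent_closed({"a": 1.0, "b": 1.0}, "a", "b")
        with pytest.raises(DomainError):
            percent_closed(self.MEANS, "apo", "apo")

    def test_out_of_range_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="outside"):
            pct = percent_closed({"a": 0.0, "x": -0.2, "b": 1.0}, "a", "b")
        assert pct["x"] == pytest.approx(-20.0)

    @pytest.mark.parametrize("pct,expected", [(0.0, 0.0), (100.0, -15.0), (50.0, -7.5)])
    def test_ddg_affine_map(self, pct, expected):
        assert ddg_from_closure(pct, ddg_closed=-15.0) == pytest.approx(expected)

    def test_free_energy_map_anchors_and_error(self, noisy_dataset):
        table, _, _ = noisy_dataset
        res = concise_scores(table)
        fmap = free_energy_map(res, ddg_closed=-15.0)
        assert fmap.ddg["apo"] == pytest.approx(0.0)
        assert fmap.ddg["ATPgN+PKI"] == pytest.approx(-15.0)
        # ΔΔG is affine in percent-closed
        for s in res.states:
            assert fmap.ddg[s] == pytest.approx(-15.0 * fmap.percent_closed[s] / 100.0)
        # uncertainty scales as SD × |ΔΔG span| / |<PC> span|
        span = res.mean_pc["ATPgN+PKI"] - res.mean_pc["apo"]
        for s in res.states:
            assert fmap.ddg_sd[s] == pytest.approx(res.sd_pc[s] * 15.0 / abs(span))
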