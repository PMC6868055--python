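"""Bead-spring dynamics and crosslink kinetics."""

import numpy as np
import pytest

from kinetoforge import (PolymerParams, init_chain, rdna_only_params,
                         run_trajectory, snapshot_to_fluorophores,
                         step_dynamics, update_crosslinks)
from kinetoforge.polymer_model import PolymerState


def quiet_params(**kw):
    """No thermal noise, no crosslinking, loose tether by default."""
    defaults = dict(n_beads=10, n_rdna_beads=5, kT=0.0, k_on=0.0,
                    tether_spring_constant=0.0)
    defaults.update(kw)
    return PolymerParams(**defaults)


class TestInitChain:
    def test_default_genome_bead_counts(self):
        params = PolymerParams()
        state = init_chain(params, seed=1)
        assert len(state.positions) == 2803
        assert len(params.rdna_indices) == 361

    def test_all_beads_inside_confinement(self):
        params = PolymerParams(n_beads=500, n_rdna_beads=100)
        state = init_chain(params, seed=2)
        r = np.linalg.norm(state.positions, axis=1)
        assert (r <= params.confinement_radius + 1e-9).all()

    def test_same_seed_same_chain(self):
        params = quiet_params()
        a = init_chain(params, seed=3).positions
        b = init_chain(params, seed=3).positions
        np.testing.assert_array_equal(a, b)

    def test_oversized_rest_length_rejected(self):
        with pytest.raises(ValueError, match="rest_length"):
            PolymerParams(rest_length=5000.0, confinement_radius=100.0)


class TestStepDynamics:
    def test_straight_chain_at_rest_is_fixed_point(self):
        params = quiet_params(n_beads=5, n_rdna_beads=2)
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5) * params.rest_length
        state = PolymerState(pos.copy())
        step_dynamics(state, params, np.random.default_rng(0))
        np.testing.assert_allclose(state.positions, pos, atol=1e-9)

    def test_stretched_bond_contracts(self):
        params = quiet_params(n_beads=2, n_rdna_beads=1)
        pos = np.array([[0.0, 0.0, 0.0], [150.0, 0.0, 0.0]])
        state = PolymerState(pos.copy())
        step_dynamics(state, params, np.random.default_rng(0))
        new_dist = np.linalg.norm(state.positions[1] - state.positions[0])
        assert new_dist < 150.0

    def test_free_bead_diffusion_obeys_einstein_relation(self):
        # 500 independent beads (no springs): displacement variance per
        # axis over T seconds must be 2*kT*T/drag within 10%
        params = quiet_params(n_beads=500, n_rdna_beads=1, kT=4.1,
                              spring_constant=0.0,
                              confinement_radius=1e7, rest_length=50.0)
        state = init_chain(params, seed=4)
        start = state.positions.copy()
        rng = np.random.default_rng(5)
        n_steps = 2000
        for _ in range(n_steps):
            step_dynamics(state, params, rng)
        t = n_steps * params.dt
        msd = ((state.positions - start)**2).sum(axis=1).mean()
        expected = 6.0 * params.kT / params.drag * t
        assert msd == pytest.approx(expected, rel=0.10)

    def test_non_finite_coordinates_raise_naming_dt(self):
        params = quiet_params(n_beads=2, n_rdna_beads=1)
        state = PolymerState(np.array([[0.0, 0.0, 0.0], [np.inf, 0.0, 0.0]]))
        with pytest.raises(RuntimeError, match=str(params.dt)):
            step_dynamics(state, params, np.random.default_rng(0))


class TestUpdateCrosslinks:
    def clustered_state(self, params, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 10.0, size=(params.n_beads, 3))
        return PolymerState(pos)

    def test_zero_on_rate_never_links(self):
        params = quiet_params(n_beads=30, n_rdna_beads=30, k_on=0.0)
        state = self.clustered_state(params)
        for _ in range(50):
            update_crosslinks(state, params, np.random.default_rng(1))
        assert state.links == {}

    def test_zero_capture_radius_never_links(self):
        params = quiet_params(n_beads=30, n_rdna_beads=30, k_on=100.0,
                              capture_radius=0.0)
        state = self.clustered_state(params)
        update_crosslinks(state, params, np.random.default_rng(2))
        assert state.links == {}

    def test_lifetimes_are_exponential_with_mean_mu(self):
        mu = 0.19
        params = quiet_params(n_beads=40, n_rdna_beads=40, k_on=500.0,
                              capture_radius=100.0, mu=mu)
        state = self.clustered_state(params, seed=3)
        rng = np.random.default_rng(4)
        while len(state.completed_lifetimes) < 10_000:
            update_crosslinks(state, params, rng, elapsed=1e-3)
            state.clock += 1.0   # long stride so most links complete
        lifetimes = np.array(state.completed_lifetimes[:10_000])
        se = mu / np.sqrt(len(lifetimes))
        assert abs(lifetimes.mean() - mu) < 3 * se
        # exponential: variance == mu^2 (checked loosely at n=1e4)
        assert lifetimes.var() == pytest.approx(mu**2, rel=0.1)

    def test_links_are_unique_undirected_pairs(self):
        params = quiet_params(n_beads=50, n_rdna_beads=50, k_on=200.0, mu=5.0)
        state = self.clustered_state(params, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(20):
            update_crosslinks(state, params, rng, elapsed=1e-2)
            state.clock += 1e-2
        pairs = list(state.links)
        assert all(i < j for i, j in pairs)
        assert all(j - i > 1 for i, j in pairs)
        assert len(pairs) == len(set(pairs))

    def test_expired_links_are_removed(self):
        params = quiet_params(n_beads=30, n_rdna_beads=30, k_on=500.0, mu=0.01)
        state = self.clustered_state(params, seed=7)
        rng = np.random.default_rng(8)
        update_crosslinks(state, params, rng, elapsed=1e-2)
        assert len(state.links) > 0
        state.clock += 100.0   # far beyond every expiry
        update_crosslinks(state, params, rng, elapsed=1e-2)
        expired_still_present = [p for p, (t, _) in state.links.items()
                                 if t <= state.clock]
        assert expired_still_present == []


class TestRunTrajectory:
    def test_snapshot_count(self):
        params = quiet_params(n_beads=20, n_rdna_beads=10, kT=4.1)
        traj = run_trajectory(params, total_steps=1000, sample_every=100,
                              seed=9)
        assert traj.rdna_positions.shape == (10, 10, 3)

    def test_same_seed_identical_trajectory(self):
        params = rdna_only_params(n_beads=60, n_rdna_beads=60)
        a = run_trajectory(params, 500, 100, seed=10)
        b = run_trajectory(params, 500, 100, seed=10)
        np.testing.assert_array_equal(a.rdna_positions, b.rdna_positions)

    def test_confinement_holds_across_snapshots(self):
        params = rdna_only_params(n_beads=80, n_rdna_beads=80)
        traj = run_trajectory(params, 1000, 200, seed=11)
        r = np.linalg.norm(traj.rdna_positions, axis=2)
        assert (r <= params.confinement_radius + 1e-6).all()
        assert np.isfinite(traj.rdna_positions).all()

    def test_chain_integrity(self):
        params = rdna_only_params(n_beads=80, n_rdna_beads=80)
        traj = run_trajectory(params, 1000, 1000, seed=12)
        bonds = np.linalg.norm(np.diff(traj.rdna_positions[-1], axis=0),
                               axis=1)
        assert np.isfinite(bonds).all()
        assert bonds.mean() < 5 * params.rest_length

    def test_longer_crosslink_duration_compacts_rdna(self):
        # ensemble Rg must be non-increasing across mu = 0.09 / 0.19 / 1.6 s
        mean_rg = {}
        for mu in (0.09, 0.19, 1.6):
            rgs = []
            for seed in (13, 14):
                traj = run_trajectory(rdna_only_params(mu=mu),
                                      total_steps=2500, sample_every=1250,
                                      seed=seed, burn_in_steps=30_000)
                rgs.append(traj.radius_of_gyration().mean())
            mean_rg[mu] = np.mean(rgs)
        assert mean_rg[0.09] >= mean_rg[0.19] >= mean_rg[1.6]

    def test_snapshot_converts_to_red_fluorophores(self):
        params = rdna_only_params(n_beads=50, n_rdna_beads=50)
        traj = run_trajectory(params, 200, 100, seed=15)
        fl = snapshot_to_fluorophores(traj, 0)
        assert len(fl) == 50
        assert set(fl.channels) == {"red"}
        np.testing.assert_allclose(fl.xyz.mean(axis=0), 0.0, atol=1e-9)
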