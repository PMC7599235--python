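"""Metropolis engine: acceptance law, Boltzmann sampling, protocol contracts."""

import math

import numpy as np
import pytest

from dimerlab.constants import kbt
from dimerlab.energy import EnergyModel, build_energy_model
from dimerlab.mc import (SimulationConfig, _Engine, _signed_singular_sum,
                         metropolis_accept, run_native_ensemble, run_pulling)
from dimerlab.structure import (AtomRecord, DimerConformation, MonomerStructure,
                                ResidueRecord, backbone_rmsd)

KBT = kbt(300.0)


class TestMetropolisAccept:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-x, KBT, rng) for x in (0.0, 0.1, 5.0, 1e6))

    def test_acceptance_fraction_at_one_kbt(self):
        """ΔE = k_BT is accepted with long-run frequency e⁻¹ (±3σ binomial)."""
        rng = np.random.default_rng(7)
        n = 100_000
        acc = sum(metropolis_accept(KBT, KBT, rng) for _ in range(n))
        p = math.exp(-1.0)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * sigma

    def test_non_finite_rejected_with_warning(self, rng):
        with pytest.warns(UserWarning, match="non-finite"):
            assert not metropolis_accept(float("nan"), KBT, rng)


class TestBoltzmannSampling:
    def test_two_state_occupancy(self):
        """Two levels (0, ε): occupancy ratio e^(−ε/k_BT) within 3σ at 10⁵ steps."""
        rng = np.random.default_rng(3)
        eps = KBT  # ε = k_BT
        n = 100_000
        state = 0
        count_high = 0
        for _ in range(n):
            delta = eps if state == 0 else -eps
            if metropolis_accept(delta, KBT, rng):
                state = 1 - state
            count_high += state
        p_expected = math.exp(-1.0) / (1.0 + math.exp(-1.0))
        sigma = math.sqrt(p_expected * (1 - p_expected) / n) * 3  # τ ≈ 1 here
        assert abs(count_high / n - p_expected) < 3 * sigma

    def test_three_state_stationary_distribution(self):
        """Enumerable 3-state chain matches Boltzmann weights at 10⁶ steps."""
        rng = np.random.default_rng(11)
        energies = np.array([0.0, 0.5, 1.2])
        n = 1_000_000
        proposals = rng.integers(1, 3, size=n)  # offset to one of the others
        us = rng.random(n)
        state = 0
        counts = np.zeros(3, dtype=int)
        for k in range(n):
            cand = (state + proposals[k]) % 3
            delta = energies[cand] - energies[state]
            if delta <= 0.0 or us[k] < math.exp(-delta / KBT):
                state = cand
            counts[state] += 1
        w = np.exp(-energies / KBT)
        p = w / w.sum()
        for i in range(3):
            sigma = math.sqrt(p[i] * (1 - p[i]) / n)
            # 3σ with a small inflation for the chain's autocorrelation
            assert abs(counts[i] / n - p[i]) < 3 * 3 * sigma


class TestSignedSingularSum:
    def test_matches_numpy_svd(self, rng):
        for _ in range(300):
            m = rng.normal(size=(3, 3)) * 10.0 ** rng.integers(-2, 3)
            s = np.linalg.svd(m, compute_uv=False).copy()
            if np.linalg.det(m) < 0:
                s[-1] = -s[-1]
            assert _signed_singular_sum(m) == pytest.approx(float(s.sum()),
                                                            rel=1e-8, abs=1e-10)


class TestSimulationConfig:
    def test_published_protocol_stride(self):
        cfg = SimulationConfig(n_cycles=500_000, burn_in=200_000, n_snapshots=3000)
        assert cfg.snapshot_stride == 100

    def test_invalid_burn_in(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cycles=1000, burn_in=1000)

    def test_too_many_snapshots(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cycles=1000, burn_in=900, n_snapshots=200)


def _harmonic_two_site_model(r0=10.0, k_bond=5.0):
    def mono(chain, x):
        res = (ResidueRecord(index=1, aa="A",
                             atoms=(AtomRecord("CA", "C", np.array([x, 0.0, 0.0])),)),)
        return MonomerStructure(chain_id=chain, residues=res)
    ref = DimerConformation(monomer_a=mono("A", 0.0), monomer_b=mono("B", r0))
    coords = np.array([[0.0, 0, 0], [r0, 0, 0]])
    return EnergyModel(
        reference=ref, ref_coords=coords, site_monomer=np.array([0, 1]),
        restraint_sites=(np.array([0]), np.array([1])),
        bonds=np.array([[0, 1]]), bond_r0=np.array([r0]),
        native_pairs=np.empty((0, 2), dtype=int), native_r0=np.empty(0),
        native_eps=np.empty(0), repulsive_pairs=np.empty((0, 2), dtype=int),
        bond_k=k_bond, k_rmsd=0.0, force_pn=0.0, anchors=(0, 1))


class TestEngine:
    def test_same_seed_identical_snapshots(self, small_dimer):
        model = build_energy_model(small_dimer.conformation, site_level="heavy")
        cfg = SimulationConfig(n_cycles=60, burn_in=20, n_snapshots=4, n_runs=2, seed=9)
        a = run_native_ensemble(model, cfg)
        b = run_native_ensemble(model, cfg)
        for run_a, run_b in zip(a, b):
            for s_a, s_b in zip(run_a, run_b):
                np.testing.assert_array_equal(s_a.all_coords(), s_b.all_coords())
        # and the runs themselves differ from each other
        assert not np.array_equal(a[0][0].all_coords(), a[1][0].all_coords())

    def test_incremental_energy_matches_full_recompute(self, small_dimer):
        """Cached energy drifts < 1e-6 kcal/mol from the full recomputation."""
        model = build_energy_model(small_dimer.conformation, site_level="heavy",
                                   force_pn=150.0)
        cfg = SimulationConfig(n_cycles=3000, burn_in=0, n_snapshots=1, n_runs=1,
                               seed=2, check_interval=500)
        rng = np.random.default_rng(4)
        eng = _Engine(model, cfg, rng)
        for _ in range(3000):
            eng.run_cycle()
        assert eng.max_drift < 1e-6

    def test_restraint_keeps_monomers_native_like(self, small_dimer):
        """Unforced run: 95th-percentile backbone RMSD stays under 2.5 Å."""
        model = build_energy_model(small_dimer.conformation, site_level="heavy")
        cfg = SimulationConfig(n_cycles=2000, burn_in=400, n_snapshots=40,
                               n_runs=1, seed=5)
        runs = run_native_ensemble(model, cfg)
        rmsds = [backbone_rmsd(s.monomer_a, small_dimer.conformation.monomer_a)
                 for s in runs[0]]
        assert np.percentile(rmsds, 95) < 2.5
        assert np.mean(rmsds) > 0.2  # and it does fluctuate

    def test_snapshot_count_and_stride(self, small_dimer):
        model = build_energy_model(small_dimer.conformation, site_level="heavy")
        cfg = SimulationConfig(n_cycles=300, burn_in=100, n_snapshots=10,
                               n_runs=1, seed=1)
        runs = run_native_ensemble(model, cfg)
        assert len(runs[0]) == 10

    def test_harmonic_equipartition(self):
        """2-site harmonic toy: var(r) = k_BT / (2·k_bond) within 5%."""
        model = _harmonic_two_site_model(r0=10.0, k_bond=5.0)
        cfg = SimulationConfig(n_cycles=1, burn_in=0, n_snapshots=1, n_runs=1, seed=8)
        rng = np.random.default_rng(8)
        eng = _Engine(model, cfg, rng)
        n_cycles = 100_000
        rs = np.empty(n_cycles)
        for i in range(n_cycles):
            eng.run_cycle()
            rs[i] = np.linalg.norm(eng.coords[0] - eng.coords[1])
        expected = kbt(300.0) / (2.0 * 5.0)
        assert np.var(rs[1000:]) == pytest.approx(expected, rel=0.05)


class TestPulling:
    def test_zero_force_short_run_censored(self, small_dimer):
        model = build_energy_model(small_dimer.conformation, site_level="heavy",
                                   force_pn=0.0)
        cfg = SimulationConfig(n_cycles=200, burn_in=0, n_snapshots=1, n_runs=1, seed=3)
        traj = run_pulling(model, cfg, d_threshold=41.0)[0]
        assert not traj.dissociated and traj.t_dis is None

    def test_strong_force_dissociates_with_first_passage(self, small_dimer):
        from dimerlab.dissociation import first_passage_time
        model = build_energy_model(small_dimer.conformation, site_level="heavy",
                                   force_pn=500.0, native_cutoff=4.5,
                                   well_width=0.3)
        cfg = SimulationConfig(n_cycles=20_000, burn_in=0, n_snapshots=1,
                               n_runs=1, seed=6, rigid_trans_amplitude=0.3)
        traj = run_pulling(model, cfg, d_threshold=20.0)[0]
        assert traj.dissociated
        # recorded series agrees with the reported first-passage time
        assert first_passage_time(traj.cycles, traj.d_ca, 20.0) == traj.t_dis
        assert np.all(np.diff(traj.cycles) > 0)

    def test_trajectory_invariants(self):
        from dimerlab.mc import PullingTrajectory
        with pytest.raises(ValueError):
            PullingTrajectory(cycles=np.array([1]), d_ca=np.array([1.0]),
                              energy=np.array([0.0]), dissociated=True, t_dis=None)
        with pytest.raises(ValueError):
            PullingTrajectory(cycles=np.array([1]), d_ca=np.array([1.0]),
                              energy=np.array([0.0]), dissociated=False, t_dis=5)
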