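"""Langevin engine: thermostats, determinism, energies, campaigns."""

import numpy as np
import pytest

from dyn2lattice import (
    ForceField,
    SimParams,
    SimulationError,
    run_campaign,
    run_simulation,
    total_energy,
)
from dyn2lattice.bead_model import BeadModel
from dyn2lattice.engine import Trajectory
from dyn2lattice.params import (
    debye_huckel_energy,
    excluded_volume_energy,
    gaussian_contact_energy,
)


def _beads(positions, charges=None, bonds=None, chains=None,
           native=None, native_r0=None):
    n = len(positions)
    return BeadModel(
        chain_id=list(chains) if chains else ["T"] * n,
        residue_index=np.arange(1, n + 1, dtype=np.int64),
        residue_name=["GLY"] * n,
        positions=np.asarray(positions, dtype=float),
        charges=np.asarray(charges if charges is not None else np.zeros(n), dtype=float),
        group=["tail"] * n,
        bonds=(np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
               if bonds is not None else np.zeros((0, 2), dtype=np.int64)),
        native_contacts=(np.asarray(native, dtype=np.int64).reshape(-1, 2)
                         if native is not None else np.zeros((0, 2), dtype=np.int64)),
        native_r0=(np.asarray(native_r0, dtype=float)
                   if native_r0 is not None else np.zeros(0)),
    )


class TestIntegrator:
    def test_zero_temperature_zero_force_fixed_point(self):
        system = _beads([[0, 0, 0], [8, 0, 0]], chains=["A", "B"])
        params = SimParams(temperature=0.0, n_steps=1000, burn_in_steps=0,
                           output_stride=100)
        traj = run_simulation(system, params, ForceField())
        assert np.abs(traj.com_low - traj.com_low[0]).max() < 1e-14

    def test_equipartition_in_harmonic_well(self):
        """A single restrained bead samples positional variance kB·T/k
        per axis (within 5%)."""
        ff = ForceField(restraint_k=25.0)
        system = _beads([[0, 0, 0]])
        params = SimParams(n_steps=400_000, burn_in_steps=0, output_stride=20,
                           seed=11)
        traj = run_simulation(system, params, ff, restrain_beads=[0])
        x = traj.com_low[1000:]  # discard equilibration
        var = x.var(axis=0).mean()
        assert var == pytest.approx(params.kT / ff.restraint_k, rel=0.05)

    def test_energy_conservation_in_verlet_limit(self):
        """Friction 0, temperature 0: windowed-mean total energy drifts
        by < 1e-4 (relative) over 10^4 steps.  The initial condition is
        a native pair displaced from its well minimum, so the system
        oscillates with nonzero total energy."""
        system = _beads([[0, 0, 0], [0.7, 0, 0]], chains=["A", "B"],
                        native=[[0, 1]], native_r0=[1.0])
        params = SimParams(temperature=0.0, friction=0.0, n_steps=10_000,
                           burn_in_steps=0, output_stride=10, timestep=0.01)
        traj = run_simulation(system, params, ForceField())
        e = traj.energies
        assert abs(e[:100].mean()) > 1e-3  # genuinely oscillating
        drift = abs(e[-100:].mean() - e[:100].mean()) / abs(e[:100].mean())
        assert drift < 1e-4

    def test_seed_determinism(self, toy_system_y, ff):
        params = SimParams(n_steps=3000, burn_in_steps=0, output_stride=100, seed=5)
        t1 = run_simulation(toy_system_y.copy(), params, ff)
        t2 = run_simulation(toy_system_y.copy(), params, ff)
        np.testing.assert_array_equal(t1.com_low, t2.com_low)
        params2 = SimParams(n_steps=3000, burn_in_steps=0, output_stride=100, seed=6)
        t3 = run_simulation(toy_system_y.copy(), params2, ff)
        assert not np.array_equal(t1.com_low, t3.com_low)

    def test_escape_beyond_box_bound_aborts_with_step(self):
        """Two overlapping beads repel and, without friction, fly past
        the abort bound; the failure reports the step index."""
        system = _beads([[0, 0, 0], [0.55, 0, 0]], chains=["A", "B"])
        params = SimParams(temperature=0.0, friction=0.0, n_steps=50_000,
                           burn_in_steps=0, output_stride=10)
        with pytest.raises(SimulationError, match="step"):
            run_simulation(system, params, ForceField())

    def test_rigid_head_keeps_shape(self, toy_system_y, ff):
        params = SimParams(n_steps=2000, burn_in_steps=0, output_stride=100,
                           seed=3)
        traj = run_simulation(toy_system_y.copy(), params, ff,
                              store_full_stride=1000)
        model = traj.model
        head = model.chain_beads("ML")
        mobpos = {int(b): k for k, b in enumerate(traj.mobile_idx)}
        sel = [mobpos[int(i)] for i in head]
        first = traj.full_positions[0][sel]
        last = traj.full_positions[-1][sel]
        d_first = np.linalg.norm(first[:, None] - first[None, :], axis=2)
        d_last = np.linalg.norm(last[:, None] - last[None, :], axis=2)
        np.testing.assert_allclose(d_first, d_last, atol=1e-8)


class TestTotalEnergy:
    def test_distant_neutral_beads_no_nonbonded(self):
        system = _beads([[0, 0, 0], [10, 0, 0]], chains=["A", "B"])
        e = total_energy(system, SimParams(), ForceField())
        for term in ("electrostatic", "excluded", "native", "bonded", "tether"):
            assert e[term] == 0.0

    def test_three_bead_system_matches_pairwise_oracle(self):
        """Charged pair + native pair reproduced by summing the
        closed-form pair energies independently."""
        params = SimParams()
        ff = ForceField()
        pos = [[0.0, 0, 0], [0.8, 0, 0], [0.0, 0.9, 0]]
        system = _beads(pos, charges=[1, -1, 0], chains=["A", "B", "C"],
                        native=[[0, 2]], native_r0=[0.9])
        e = total_energy(system, params, ff)
        r01, r02, r12 = 0.8, 0.9, np.linalg.norm(np.subtract(pos[1], pos[2]))
        assert e["electrostatic"] == pytest.approx(
            debye_huckel_energy(1, -1, r01, params), rel=1e-9)
        assert e["native"] == pytest.approx(
            gaussian_contact_energy(r02, 0.9, ff.go_epsilon, ff.contact_width),
            rel=1e-9)
        expected_ev = sum(
            excluded_volume_energy(r, ff.excluded_sigma, ff.excluded_epsilon,
                                   ff.excluded_cutoff)
            for r in (r01, r02, r12)
        )
        assert e["excluded"] == pytest.approx(expected_ev, rel=1e-9)
        assert e["total"] == pytest.approx(sum(
            v for k, v in e.items() if k != "total"), rel=1e-12)

    def test_translation_invariance(self, toy_system_y, ff):
        params = SimParams()
        e1 = total_energy(toy_system_y, params, ff)
        shifted = toy_system_y.copy()
        shifted.positions = shifted.positions + np.array([1.7, -2.3, 0.9])
        e2 = total_energy(shifted, params, ff)
        assert e1["total"] == pytest.approx(e2["total"], rel=1e-9)

    def test_overlapping_beads_rejected(self):
        system = _beads([[0, 0, 0], [0, 0, 0]], chains=["A", "B"])
        with pytest.raises(Exception, match="overlap|unique"):
            total_energy(system, SimParams(), ForceField())


class TestCampaign:
    def test_counts_and_unique_seeds(self):
        params = SimParams(n_steps=2000, burn_in_steps=500, output_stride=100)
        trajs, manifest = run_campaign(states=("Y",), positions=(2,),
                                       n_seeds=2, params=params, base_seed=42)
        assert len(trajs) == 2
        assert len(set(manifest["seeds"])) == 2
        assert manifest["seeds"][0] == 42
        assert all(t.metadata["tail_state"] == "Y" for t in trajs)

    def test_full_matrix_counts(self):
        params = SimParams(n_steps=1000, burn_in_steps=100, output_stride=100)
        trajs, manifest = run_campaign(states=("Y", "dY"), positions=(1, 2, 3),
                                       n_seeds=1, params=params)
        assert len(trajs) == 6
        assert len(set(manifest["seeds"])) == 6

    def test_invalid_n_seeds(self):
        with pytest.raises(Exception):
            run_campaign(n_seeds=0)


class TestTrajectoryIO:
    def test_tsv_roundtrip(self, tmp_path):
        steps = np.arange(100, 600, 100, dtype=np.int64)
        com = np.random.default_rng(0).normal(0, 1, (5, 3))
        traj = Trajectory(metadata={"seed": 1}, steps=steps, com_low=com)
        path = tmp_path / "com.tsv"
        traj.to_tsv(path)
        back = Trajectory.from_tsv(path, metadata={"seed": 1})
        np.testing.assert_array_equal(back.steps, steps)
        np.testing.assert_allclose(back.com_low, com, atol=1e-6)

    def test_dcd_export_roundtrip(self, toy_system_y, ff, tmp_path):
        import mdtraj as md

        params = SimParams(n_steps=1000, burn_in_steps=0, output_stride=100)
        traj = run_simulation(toy_system_y.copy(), params, ff,
                              store_full_stride=500)
        dcd = tmp_path / "run.dcd"
        pdb = tmp_path / "top.pdb"
        traj.to_dcd(dcd)
        traj.model.to_pdb(pdb)
        loaded = md.load_dcd(str(dcd), top=str(pdb))
        assert loaded.n_frames == len(traj.full_positions)
        assert loaded.n_atoms == traj.model.n_beads
        # mobile bead coordinates round-trip (DCD stores float32)
        got = loaded.xyz[0][traj.mobile_idx]
        np.testing.assert_allclose(got, traj.full_positions[0], atol=1e-3)

    def test_steps_strictly_increasing_enforced(self):
        with pytest.raises(Exception):
            Trajectory(metadata={}, steps=np.array([2, 1]),
                       com_low=np.zeros((2, 3))).validate()
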