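import numpy as np
import pytest

from thermoidp.constants import KB_KCAL, KCAL_TO_INTERNAL
from thermoidp.engine import (
    DENSITY_AMU_NM3,
    EngineError,
    NeighborList,
    SimSystem,
    Trajectory,
    _chains_to_system,
    build_single_chain,
    build_slab,
    compute_forces,
    rg_series,
    run_langevin,
)
from thermoidp.sequences import build_chain


def make_gas(ff, sequence, n_chains, box, seed=0, nonbonded=False):
    """Independent, non-interacting copies of one chain (for ideal checks)."""
    rng = np.random.default_rng(seed)
    chains = [build_chain(sequence, ff.residues) for _ in range(n_chains)]
    coords = []
    for _ in range(n_chains):
        origin = rng.uniform(0, box, size=3)
        pts = [origin]
        for _ in range(len(sequence) - 1):
            v = rng.normal(size=3)
            pts.append(pts[-1] + ff.residues.bond_r0 * v / np.linalg.norm(v))
        coords.append(np.array(pts))
    return _chains_to_system(
        chains, np.concatenate(coords), np.full(3, float(box)), ff, 300.0,
        include_nonbonded=nonbonded,
    )


class TestBuilders:
    def test_single_chain_counts_and_overlap(self, ff):
        system = build_single_chain("VPGVG" * 4, ff, 300.0, 50.0, seed=1)
        assert system.n_beads == 20
        assert len(system.bond_i) == 19
        d = np.linalg.norm(
            system.coords[:, None, :] - system.coords[None, :, :], axis=-1
        )
        iu = np.triu_indices(20, k=2)  # beyond bonded neighbors
        min_sigma = system.pair_sigma.min()
        assert d[iu].min() > 0.7 * min_sigma

    def test_box_smaller_than_contour_rejected(self, ff):
        with pytest.raises(EngineError, match="contour"):
            build_single_chain("V" * 100, ff, 300.0, 10.0)

    def test_seeded_determinism(self, ff):
        a = build_single_chain("VPGVG", ff, 300.0, 30.0, seed=5)
        b = build_single_chain("VPGVG", ff, 300.0, 30.0, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_slab_replicate_rule_short(self, ff):
        system = build_slab("VPGVG" * 20, ff, 320.0, 50.0, seed=2, relax_steps=0)
        assert len(system.chains) == 64  # 100 residues < 190

    def test_slab_replicate_rule_boundary(self, ff):
        system = build_slab("VPGVG" * 38, ff, 320.0, 50.0, seed=2, relax_steps=0)
        assert len(system.chains) == 27  # 190 residues: 3x3x3

    def test_slab_concentration_postcondition(self, ff):
        target = 75.0  # g/L
        system = build_slab("VPGVG" * 8, ff, 320.0, target, seed=3, relax_steps=0)
        conc = system.masses.sum() / np.prod(system.box) / DENSITY_AMU_NM3 * 1e3
        assert conc == pytest.approx(target, rel=1e-3)

    def test_excessive_concentration_rejected(self, ff):
        with pytest.raises(EngineError, match="concentration"):
            build_slab("VPGVG" * 8, ff, 320.0, 2000.0, dense_density=0.8, relax_steps=0)


class TestDynamics:
    def test_zero_steps_returns_initial_frame_only(self, ff):
        system = build_single_chain("VPGVG", ff, 300.0, 30.0, seed=1)
        traj = run_langevin(system, 300.0, n_steps=0, seed=1)
        assert traj.n_frames == 1
        assert traj.times[0] == 0.0

    def test_seeded_trajectories_are_bitwise_identical(self, ff):
        s1 = build_single_chain("VPGVG" * 2, ff, 300.0, 30.0, seed=1)
        s2 = build_single_chain("VPGVG" * 2, ff, 300.0, 30.0, seed=1)
        t1 = run_langevin(s1, 300.0, n_steps=500, seed=9, sample_every=100)
        t2 = run_langevin(s2, 300.0, n_steps=500, seed=9, sample_every=100)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.potential, t2.potential)

    def test_energy_conservation_without_thermostat(self, ff):
        system = build_single_chain("VPGVG" * 2, ff, 300.0, 30.0, seed=2)
        run_langevin(system, 300.0, n_steps=200, seed=3, sample_every=200)
        traj = run_langevin(
            system, 300.0, n_steps=10_000, dt_fs=1.0, seed=4,
            sample_every=100, thermostat=False,
        )
        etot = traj.potential + traj.kinetic
        assert np.ptp(etot) / abs(etot.mean()) < 1e-4

    def test_free_particle_diffusion_einstein_relation(self, ff):
        system = make_gas(ff, "G", 128, box=100.0, seed=3)
        traj = run_langevin(
            system, 300.0, n_steps=10_000, seed=9, sample_every=100, damping_ps=5.0,
        )
        m = system.masses[0]
        d_expected = KB_KCAL * 300.0 * KCAL_TO_INTERNAL / (m * 0.2)  # nm^2/ps
        disp = ((traj.frames - traj.frames[0]) ** 2).sum(axis=2).mean(axis=1)
        slope = np.polyfit(traj.times[20:], disp[20:], 1)[0]
        assert slope == pytest.approx(6 * d_expected, rel=0.05)

    def test_overlapping_beads_reported(self, ff):
        system = build_single_chain("VV", ff, 300.0, 30.0, seed=1)
        system.coords[1] = system.coords[0]
        with pytest.raises(EngineError, match="beads"):
            compute_forces(system)


class TestNeighborList:
    def test_matches_all_pairs_forces_exactly(self, ff):
        system = build_slab("VPGVG" * 2, ff, 320.0, 100.0, seed=4, relax_steps=20)
        nl = NeighborList(system)
        nl.build(system.coords)
        ap = NeighborList(system)
        ap.all_pairs(system.coords)
        e1, f1 = compute_forces(system, system.coords, nl)
        e2, f2 = compute_forces(system, system.coords, ap)
        assert e1 == e2
        assert np.array_equal(f1, f2)

    def test_bonded_pairs_are_excluded(self, ff):
        system = build_single_chain("VPGVG", ff, 300.0, 30.0, seed=1)
        nl = NeighborList(system)
        nl.build(system.coords)
        i, j = nl.pairs
        bonded = set(zip(system.bond_i.tolist(), system.bond_j.tolist()))
        assert all((a, b) not in bonded for a, b in zip(i.tolist(), j.tolist()))


class TestObservables:
    def _system_with_coords(self, ff, sequence, coords, box=50.0):
        chain = build_chain(sequence, ff.residues)
        return _chains_to_system([chain], coords, np.full(3, box), ff, 300.0)

    def _traj(self, coords):
        c = np.asarray(coords, dtype=float)[None]
        z = np.zeros(1)
        return Trajectory(np.zeros(1), c, z, z, z)

    def test_coincident_beads_have_zero_rg(self, ff):
        coords = np.zeros((3, 3)) + 5.0
        system = self._system_with_coords(ff, "GGG", coords)
        assert rg_series(self._traj(coords), system)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_mass_beads_one_nm_apart(self, ff):
        coords = np.array([[5.0, 5, 5], [6.0, 5, 5]])
        system = self._system_with_coords(ff, "GG", coords)
        assert rg_series(self._traj(coords), system)[0] == pytest.approx(0.5)

    def test_rigid_rod_discrete_formula(self, ff):
        n, a = 11, 0.38
        coords = np.zeros((n, 3))
        coords[:, 2] = np.arange(n) * a + 1.0
        system = self._system_with_coords(ff, "G" * n, coords)
        expected = a * np.sqrt((n**2 - 1) / 12.0)
        assert rg_series(self._traj(coords), system)[0] == pytest.approx(expected, rel=1e-12)

    def test_rg_unwraps_across_periodic_boundary(self, ff):
        box = 10.0
        coords = np.array([[9.8, 5, 5], [0.2, 5, 5]])  # split by the boundary
        system = self._system_with_coords(ff, "GG", coords, box=box)
        assert rg_series(self._traj(coords), system)[0] == pytest.approx(0.2)

    def test_chain_index_out_of_range(self, ff):
        coords = np.zeros((2, 3))
        system = self._system_with_coords(ff, "GG", coords)
        with pytest.raises(IndexError):
            rg_series(self._traj(coords), system, chain_index=3)
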