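"""Integrator contracts: free flight, NVE limit, thermostat, determinism,
periodic wrapping, and invariant preservation over long runs."""

import numpy as np
import pytest

from ringcrowd import (
    CylinderGeometry,
    SystemSpec,
    apply_periodic,
    integrate,
    kinetic_temperature,
    make_fixture,
)
from ringcrowd.dynamics import draw_maxwell_boltzmann, kinetic_energy
from ringcrowd.params import DynamicsParams, MONOMER, ParticleState


def _nve(spec):
    spec.dynamics = DynamicsParams(gamma=0.0)
    return spec


class TestFreeFlight:
    def test_position_advances_by_v_dt(self):
        state, spec, _ = make_fixture("dimer")
        spec = _nve(spec)
        # separate the pair beyond the cutoff: no forces at all
        state.positions[1] += np.array([1.0, 0.0, 0.0])
        state.velocities[:] = [[0.1, -0.2, 0.3], [0.0, 0.1, -0.1]]
        v0 = state.velocities.copy()
        x0 = state.positions.copy()
        traj = integrate(state, spec, n_steps=1, sample_stride=1, seed=0)
        out = traj.frames[-1]
        assert np.allclose(out.positions, x0 + v0 * spec.dynamics.dt, atol=1e-14)
        assert np.allclose(out.velocities, v0, atol=1e-14)


class TestNVE:
    def test_energy_conserved_without_thermostat(self, ring20):
        state, spec, _ = ring20
        spec = _nve(SystemSpec.from_dict(spec.to_dict()))
        work = state.copy()
        draw_maxwell_boltzmann(work, DynamicsParams(), np.random.default_rng(7))
        traj = integrate(work, spec, n_steps=10_000, sample_stride=500, seed=1)
        total = [
            kinetic_energy(f) + sum(e.values())
            for f, e in zip(traj.frames, traj.energies)
        ]
        drift = (max(total) - min(total)) / abs(total[0])
        assert drift < 1e-3


class TestThermostat:
    def test_kinetic_temperature_reaches_target(self, ring20_crowders):
        # total kinetic energy decorrelates only on the 1/gamma timescale,
        # so average over replicates to resolve the 2% tolerance
        state, spec, _ = ring20_crowders
        means = []
        for seed in (5, 6, 7):
            traj = integrate(
                state.copy(), spec, n_steps=300_000, sample_stride=100, seed=seed
            )
            temps = [kinetic_temperature(f) for f in traj.frames[1000:]]
            means.append(np.mean(temps))
        assert np.mean(means) == pytest.approx(1.0, abs=0.02)

    def test_kinetic_temperature_conventions(self):
        state, _, _ = make_fixture("dimer")
        assert kinetic_temperature(state) == 0.0
        state.velocities[:] = [[1.0, 0, 0], [0, 1.0, 0]]
        t1 = kinetic_temperature(state)
        state.velocities *= 2.0
        assert kinetic_temperature(state) == pytest.approx(4.0 * t1)

    def test_maxwell_boltzmann_draw_matches_temperature(self, rng):
        state, spec, _ = make_fixture("ring20")
        reps = [
            kinetic_temperature(
                (draw_maxwell_boltzmann(state, spec.dynamics, rng), state)[1]
            )
            for _ in range(400)
        ]
        assert np.mean(reps) == pytest.approx(1.0, abs=0.02)


class TestDeterminism:
    def test_same_seed_identical_trajectories(self, ring20):
        state, spec, _ = ring20
        t1 = integrate(state.copy(), spec, n_steps=2000, sample_stride=500, seed=42)
        t2 = integrate(state.copy(), spec, n_steps=2000, sample_stride=500, seed=42)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.positions, f2.positions)
            assert np.array_equal(f1.velocities, f2.velocities)

    def test_different_seed_diverges(self, ring20):
        state, spec, _ = ring20
        t1 = integrate(state.copy(), spec, n_steps=2000, sample_stride=2000, seed=1)
        t2 = integrate(state.copy(), spec, n_steps=2000, sample_stride=2000, seed=2)
        assert not np.allclose(t1.frames[-1].positions, t2.frames[-1].positions)

    def test_zero_steps_returns_single_frame(self, ring20):
        state, spec, _ = ring20
        traj = integrate(state.copy(), spec, n_steps=0, sample_stride=100, seed=0)
        assert traj.n_frames == 1
        assert np.array_equal(traj.frames[0].positions, state.positions)


class TestPeriodicWrap:
    GEO = CylinderGeometry(diameter=5.0, length=10.0)

    def test_wrap_above_and_below(self):
        state = ParticleState.create(
            [[0, 0, 10.3], [0, 0, -0.1]], [MONOMER, MONOMER]
        )
        apply_periodic(state, self.GEO)
        assert state.positions[0, 2] == pytest.approx(0.3)
        assert state.images[0] == 1
        assert state.positions[1, 2] == pytest.approx(9.9)
        assert state.images[1] == -1

    def test_round_trip_unwrap_identity(self, rng):
        z = rng.uniform(-30.0, 30.0, 64)
        state = ParticleState.create(
            np.column_stack([np.zeros(64), np.zeros(64), z]), [MONOMER] * 64
        )
        apply_periodic(state, self.GEO)
        assert np.all(state.positions[:, 2] >= 0)
        assert np.all(state.positions[:, 2] < self.GEO.length)
        assert np.allclose(state.unwrapped_z(self.GEO.length), z, atol=1e-12)

    def test_capped_mode_rejected(self):
        state = ParticleState.create([[0, 0, 1.0]], [MONOMER])
        capped = CylinderGeometry(diameter=5.0, length=10.0, mode="capped")
        with pytest.raises(ValueError):
            apply_periodic(state, capped)


class TestLongRunInvariants:
    def test_bonds_and_containment_hold(self, ring20):
        state, spec, topo = ring20
        work = state.copy()
        draw_maxwell_boltzmann(work, spec.dynamics, np.random.default_rng(3))
        traj = integrate(work, spec, n_steps=100_000, sample_stride=2000, seed=9)
        radius = spec.geometry.radius
        for frame in traj.frames:
            rho = np.hypot(frame.positions[:, 0], frame.positions[:, 1])
            assert np.all(rho < radius + 1.0)  # never past the wall surface
            d = np.diff(
                np.vstack([frame.positions, frame.positions[:1]]), axis=0
            )
            d[:, 2] -= spec.geometry.length * np.round(
                d[:, 2] / spec.geometry.length
            )
            assert np.linalg.norm(d, axis=1).max() < spec.bonds.r0
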