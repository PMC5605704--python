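"""Langevin dynamics: velocity-Verlet with a BAOAB-split thermostat.

One time step is B(dt/2) A(dt/2) O A(dt/2) B(dt/2): half-kick, half-drift,
exact Ornstein-Uhlenbeck velocity refresh, half-drift, half-kick.  The OU
step uses v <- c1 v + sqrt(kT/m (1 - c1^2)) xi with c1 = exp(-gamma dt),
which realizes the fluctuation-dissipation balance of the noise contract
<W_i(t).W_j(t')> = 6 gamma kT m_i delta_ij delta(t-t') exactly at the
stationary point: the kinetic temperature equilibrates to kT with no
O(gamma dt) bias.  At gamma = 0 the step reduces identically to symplectic
velocity-Verlet.

Forces are evaluated once per step; the longitudinal coordinate is wrapped
into [0, L) after every drift in periodic mode, with integer image counters
keeping unwrapped coordinates exactly recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .forces import (
    STATUS_OK,
    _build_pairs,
    _forces_kernel,
    _kernel_args,
    _pair_list_forces,
    _raise_for_status,
)
from .params import CylinderGeometry, ParticleState, SystemSpec, WALL


class IntegrationFailure(RuntimeError):
    """Integrator hit an unstable configuration (overstretch/escape)."""

    def __init__(self, message: str, step: int, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.step = step
        self.trajectory = trajectory


@dataclass
class Trajectory:
    """Ordered snapshots of a run, sampled every ``sample_stride`` steps."""

    frames: list[ParticleState] = field(default_factory=list)
    step_indices: list[int] = field(default_factory=list)
    sample_stride: int = 1000
    rng_seed: int = 0
    energies: list[dict[str, float]] = field(default_factory=list)

    def append(self, state: ParticleState, step: int, energy: dict | None = None) -> None:
        if self.step_indices and step <= self.step_indices[-1]:
            raise ValueError("step indices must be strictly increasing")
        if self.frames and state.n != self.frames[0].n:
            raise ValueError("particle count must be constant across frames")
        self.frames.append(state)
        self.step_indices.append(step)
        if energy is not None:
            self.energies.append(energy)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def kinetic_temperature(state: ParticleState, mass: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Instantaneous kinetic temperature (1/3n) sum m v^2 in eps/k_B."""
    mobile = state.species != WALL
    m = np.asarray(mass)[state.species[mobile]]
    v2 = np.sum(state.velocities[mobile] ** 2, axis=1)
    n = int(np.sum(mobile))
    if n == 0:
        return 0.0
    return float(np.sum(m * v2) / (3.0 * n))


def kinetic_energy(state: ParticleState, mass: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    mobile = state.species != WALL
    m = np.asarray(mass)[state.species[mobile]]
    return float(0.5 * np.sum(m * np.sum(state.velocities[mobile] ** 2, axis=1)))


def apply_periodic(state: ParticleState, geometry: CylinderGeometry) -> ParticleState:
    """Wrap longitudinal coordinates into [0, L), updating image counters."""
    if geometry.mode != "periodic":
        raise ValueError("apply_periodic requires periodic geometry")
    wraps = np.floor(state.positions[:, 2] / geometry.length).astype(np.int64)
    state.positions[:, 2] -= wraps * geometry.length
    state.images += wraps
    return state


def draw_maxwell_boltzmann(
    state: ParticleState, dynamics, rng: np.random.Generator
) -> None:
    """Draw velocities from the Maxwell-Boltzmann distribution in place."""
    m = np.asarray(dynamics.mass)[state.species]
    sigma_v = np.sqrt(dynamics.temperature / m)
    state.velocities[:] = rng.standard_normal(state.positions.shape) * sigma_v[:, None]
    state.velocities[state.species == WALL] = 0.0


#: Verlet-list skin in units of a; pairs are collected to cutoff + skin and
#: the list is rebuilt when any particle moves more than skin/2.
PAIR_SKIN = 0.25


@njit(cache=True, fastmath=True)
def _baoab_chunk(
    pos,
    vel,
    images,
    species,
    n_mono,
    n_crowd,
    sig,
    eps,
    bond_k,
    bond_r0,
    length,
    periodic,
    radius,
    capped,
    smooth_wall,
    masses,
    dt,
    c1,
    kT,
    noise,
    forces,
    pairs,
    pair_state,
    pos_ref,
    skin,
):
    """Advance noise.shape[0] BAOAB steps.

    Returns (status, steps_done, e_pair, e_bond, e_wall).  ``pairs`` /
    ``pair_state`` / ``pos_ref`` persist across calls: pair_state[0] is the
    current pair count (-1 forces a rebuild).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    half = 0.5 * dt
    noise_amp = np.sqrt(kT * (1.0 - c1 * c1))
    trigger = 0.25 * skin * skin
    half_l = 0.5 * length
    e_pair = 0.0
    e_bond = 0.0
    e_wall = 0.0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            if species[i] == WALL:
                continue
            vf = half / masses[species[i]]
            vel[i, 0] += vf * forces[i, 0]
            vel[i, 1] += vf * forces[i, 1]
            vel[i, 2] += vf * forces[i, 2]
        # A: half drift (+ wrap)
        for i in range(n):
            if species[i] == WALL:
                continue
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
            if periodic:
                w = math.floor(pos[i, 2] / length)
                if w != 0:
                    pos[i, 2] -= w * length
                    images[i] += w
        # O: Ornstein-Uhlenbeck velocity refresh
        if c1 < 1.0:
            for i in range(n):
                if species[i] == WALL:
                    continue
                amp = noise_amp / np.sqrt(masses[species[i]])
                vel[i, 0] = c1 * vel[i, 0] + amp * noise[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + amp * noise[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + amp * noise[step, i, 2]
        # A: half drift (+ wrap)
        for i in range(n):
            if species[i] == WALL:
                continue
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
            if periodic:
                w = math.floor(pos[i, 2] / length)
                if w != 0:
                    pos[i, 2] -= w * length
                    images[i] += w
        # pair-list freshness: rebuild when anything moved > skin/2
        rebuild = pair_state[0] < 0
        if not rebuild:
            for i in range(n):
                dx = pos[i, 0] - pos_ref[i, 0]
                dy = pos[i, 1] - pos_ref[i, 1]
                dz = pos[i, 2] - pos_ref[i, 2]
                if periodic:
                    if dz > half_l:
                        dz -= length
                    elif dz < -half_l:
                        dz += length
                if dx * dx + dy * dy + dz * dz > trigger:
                    rebuild = True
                    break
        if rebuild:
            np_new = _build_pairs(
                pos, species, n_mono, n_crowd, sig, skin, length, periodic,
                radius, pairs,
            )
            while np_new < 0:  # buffer full: grow and retry
                pairs = np.empty((pairs.shape[0] * 2, 2), dtype=np.int64)
                np_new = _build_pairs(
                    pos, species, n_mono, n_crowd, sig, skin, length,
                    periodic, radius, pairs,
                )
            pair_state[0] = np_new
            pos_ref[:] = pos
        # force refresh + B: half kick
        status, e_pair, e_bond, e_wall = _pair_list_forces(
            pos, species, pairs, pair_state[0], n_mono, sig, eps, bond_k,
            bond_r0, length, periodic, radius, capped, smooth_wall, forces,
        )
        if status != STATUS_OK:
            return status, step, e_pair, e_bond, e_wall, pairs
        for i in range(n):
            if species[i] == WALL:
                continue
            vf = half / masses[species[i]]
            vel[i, 0] += vf * forces[i, 0]
            vel[i, 1] += vf * forces[i, 1]
            vel[i, 2] += vf * forces[i, 2]
    return STATUS_OK, n_steps, e_pair, e_bond, e_wall, pairs


def langevin_step(
    state: ParticleState, spec: SystemSpec, rng_seed: int | None = None
) -> ParticleState:
    """Advance exactly one BAOAB time step (thin wrapper over the chunk kernel).

    Deterministic given (state, rng_seed); pass rng_seed=None for gamma = 0
    runs where no noise is consumed.
    """
    traj = integrate(state, spec, n_steps=1, sample_stride=1, seed=rng_seed or 0)
    return traj.frames[-1]


def integrate(
    state: ParticleState,
    spec: SystemSpec,
    n_steps: int,
    sample_stride: int = 1000,
    seed: int = 0,
    record_energy: bool = True,
) -> Trajectory:
    """Run Langevin dynamics, sampling every ``sample_stride`` steps.

    The initial state is recorded as frame 0.  The random stream is seeded
    once from ``seed``, so identical (state, spec, seed) give bit-identical
    trajectories.  On instability the exception carries the trajectory of
    all frames sampled before the failure.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    sample_stride = max(1, int(sample_stride))
    dyn = spec.dynamics
    geo = spec.geometry
    work = state.copy()
    if geo.mode == "periodic":
        apply_periodic(work, geo)

    args = _kernel_args(work, spec)
    traj = Trajectory(sample_stride=sample_stride, rng_seed=seed)

    forces = np.zeros_like(work.positions)
    status, e_pair, e_bond, e_wall = _forces_kernel(*args, forces)
    _raise_for_status(status)
    traj.append(work.copy(), 0, {"pair": e_pair, "bond": e_bond, "wall": e_wall})
    if n_steps == 0:
        return traj

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    c1 = math.exp(-dyn.gamma * dyn.dt)
    masses = np.asarray(dyn.mass)
    n = work.n
    # Verlet-list workspace persists across chunks
    cap = 60 * n + 2000
    pairs = np.empty((cap, 2), dtype=np.int64)
    pair_state = np.array([-1], dtype=np.int64)
    pos_ref = np.zeros_like(work.positions)
    # sub-chunk size keeps the pregenerated noise block modest (~8 MB)
    nsub_max = max(1, 2_000_000 // max(3 * n, 1))

    step = 0
    while step < n_steps:
        chunk = min(sample_stride, n_steps - step)
        done_in_chunk = 0
        while done_in_chunk < chunk:
            nsub = min(nsub_max, chunk - done_in_chunk)
            noise = rng.standard_normal((nsub, n, 3), dtype=np.float32)
            status, done, e_pair, e_bond, e_wall, pairs = _baoab_chunk(
                work.positions, work.velocities, work.images, work.species,
                args[2], args[3], args[4], args[5], args[6], args[7],
                args[8], args[9], args[10], args[11], args[12],
                masses, dyn.dt, c1, dyn.temperature, noise, forces,
                pairs, pair_state, pos_ref, PAIR_SKIN,
            )
            if status != STATUS_OK:
                fail_step = step + done_in_chunk + done
                try:
                    _raise_for_status(status, step=fail_step)
                except Exception as exc:  # noqa: BLE001 - re-wrap with context
                    raise IntegrationFailure(str(exc), fail_step, traj) from exc
            done_in_chunk += nsub
        step += chunk
        energy = {"pair": e_pair, "bond": e_bond, "wall": e_wall} if record_energy else None
        traj.append(work.copy(), step, energy)
    return traj
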