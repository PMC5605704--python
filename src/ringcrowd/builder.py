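"""Initial-condition construction: helical ring, random crowders, wall beads.

The ring starts as a folded helix — the chain winds up the cylinder at a
fixed angular step and back down, which closes the ring exactly and keeps
every bond near its rest length.  Crowders are inserted uniformly at random
in the accessible volume with hard-overlap rejection; above phi_c = 0.25,
where random sequential insertion stalls, they are inserted at reduced
diameter and inflated to full size over a short relaxation run.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    CROWDER,
    MONOMER,
    WALL,
    WCA_CUT,
    CylinderGeometry,
    InteractionTable,
    ParticleState,
    RingTopology,
    SystemSpec,
)


class ConstructionError(RuntimeError):
    """The requested geometry cannot accommodate the requested ring."""


class PackingError(RuntimeError):
    """Crowder insertion failed before reaching the requested count."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


#: Relaxed longitudinal chain size R0 = R(phi_c = 0) by (N, D), in a.
#: The (135, 5) entry is the literature value for this model; the others were
#: measured once with this package's engine (long crowder-free periodic runs,
#: 4 replicates) and are used to set box lengths L = x * R0.
R0_TABLE: dict[tuple[int, float], float] = {
    (135, 5.0): 26.0,
    (135, 4.0): 34.0,
    (135, 3.0): 39.4,
    (60, 5.0): 13.2,
    (40, 5.0): 8.8,
    (20, 5.0): 4.3,
}


def equilibrium_span(n_monomers: int, diameter: float) -> float:
    """R0 lookup with a blob-scaling fallback R0 ~ N a (a/D)^(2/3)."""
    key = (int(n_monomers), float(diameter))
    if key in R0_TABLE:
        return R0_TABLE[key]
    return 26.0 * (n_monomers / 135.0) * (5.0 / diameter) ** (2.0 / 3.0)


def build_ring(
    n: int,
    geometry: CylinderGeometry,
    bond_length: float = 0.97,
    sigma: float = 1.0,
) -> np.ndarray:
    """Closed ring of ``n`` beads folded compactly inside the cylinder.

    Tiny rings that fit become a flat regular polygon.  Larger rings use an
    accordion fold: the chain runs up and down M columns placed on a circle
    around the axis (winding once around it per circuit), with vertical bead
    spacing and column spacing both near ``bond_length``.  The fold is
    deterministic, keeps every bond in [0.9, 1.1] bond lengths, every
    non-bonded pair at >= 0.85 sigma, and fits boxes down to the shortest
    capped cylinders the study uses.
    """
    if n < 3:
        raise ConstructionError("a ring needs at least 3 monomers")
    radius = geometry.radius
    free_r = radius - 0.13 * sigma  # wall force-free zone for centers

    # flat regular polygon, if it fits
    circum = bond_length / (2.0 * math.sin(math.pi / n))
    if circum <= free_r:
        ang = 2.0 * math.pi * np.arange(n) / n
        pos = np.column_stack(
            [circum * np.cos(ang), circum * np.sin(ang), np.zeros(n)]
        )
        pos[:, 2] += geometry.length / 2.0
        return pos

    d_col = 0.96 * bond_length  # horizontal turn-bond length
    if 2.0 * free_r < d_col:
        raise ConstructionError("cylinder too narrow for the requested bond length")
    # largest even column count whose circle fits inside the free radius
    m_max = int(math.pi / math.asin(min(1.0, d_col / (2.0 * free_r))))
    m_max -= m_max % 2
    m = max(2, min(m_max, (n // 3) - (n // 3) % 2))

    z_margin = 0.3 * sigma if geometry.mode == "capped" else min(
        0.3 * sigma, 0.05 * geometry.length
    )

    for m_try in range(m, 1, -2):
        pos = _accordion_positions(
            n, m_try, d_col, bond_length, free_r, geometry, z_margin, sigma
        )
        if pos is not None and _ring_is_valid(pos, bond_length, sigma, geometry):
            return pos
    raise ConstructionError(
        f"no feasible fold for N = {n} in D = {geometry.diameter}, L = {geometry.length}"
    )


def _accordion_positions(
    n, m, d_col, bond_length, free_r, geometry, z_margin, sigma
):
    """Bead coordinates of the accordion fold, or None if infeasible."""
    q, rem = divmod(n, m)
    v_bead = bool(rem % 2)  # odd remainder: one extra bead in a bottom turn
    rem -= rem % 2
    # column heights; top-turn partners (2p, 2p+1) must match heights
    heights = np.full(m, q, dtype=int)
    for p in range(rem // 2):
        heights[2 * p] += 1
        heights[2 * p + 1] += 1
    if heights.min() < 2:
        return None

    v_drop = math.sqrt(max(bond_length**2 - (d_col / 2.0) ** 2, 0.0))
    avail = geometry.length - 2.0 * z_margin - (v_drop if v_bead else 0.0)
    s_z = min(bond_length, avail / max(heights.max() - 1, 1))
    if s_z < 0.9 * sigma:
        return None

    r_c = d_col / (2.0 * math.sin(math.pi / m))
    if r_c > free_r:
        return None
    z0 = z_margin + (v_drop if v_bead else 0.0)
    total_h = (heights.max() - 1) * s_z
    z0 += 0.5 * max(geometry.length - 2.0 * z_margin - total_h - (v_drop if v_bead else 0.0), 0.0)

    coords = []
    for i in range(m):
        phi = 2.0 * math.pi * i / m
        x, y = r_c * math.cos(phi), r_c * math.sin(phi)
        levels = range(heights[i]) if i % 2 == 0 else range(heights[i] - 1, -1, -1)
        for j in levels:
            coords.append((x, y, z0 + j * s_z))
    if v_bead:
        # extra bead in the closing bottom turn, midway and below
        phi_a = 2.0 * math.pi * (m - 1) / m
        xa, ya = r_c * math.cos(phi_a), r_c * math.sin(phi_a)
        xb, yb = r_c, 0.0
        coords.append(((xa + xb) / 2.0, (ya + yb) / 2.0, z0 - v_drop))
    return np.array(coords)


def _ring_is_valid(
    pos: np.ndarray, bond_length: float, sigma: float, geometry: CylinderGeometry
) -> bool:
    n = len(pos)
    nxt = np.roll(pos, -1, axis=0)
    d = nxt - pos
    if geometry.mode == "periodic":
        d[:, 2] -= geometry.length * np.round(d[:, 2] / geometry.length)
    bonds = np.linalg.norm(d, axis=1)
    if bonds.min() < 0.9 * sigma or bonds.max() > 1.1 * sigma:
        return False
    # non-bonded separation
    diff = pos[:, None, :] - pos[None, :, :]
    if geometry.mode == "periodic":
        diff[:, :, 2] -= geometry.length * np.round(diff[:, :, 2] / geometry.length)
    dist = np.linalg.norm(diff, axis=2)
    ring = np.arange(n)
    sep = np.abs(ring[:, None] - ring[None, :])
    sep = np.minimum(sep, n - sep)
    nonbonded = dist[sep >= 2]
    return bool(nonbonded.size == 0 or nonbonded.min() >= 0.85 * sigma)


def crowder_count(phi_c: float, geometry: CylinderGeometry, a_c: float) -> int:
    """N_c from the nominal cylinder volume pi (D/2)^2 L."""
    if not 0.0 <= phi_c <= 0.4:
        raise ValueError("phi_c must lie in [0, 0.4]")
    v_cyl = math.pi * geometry.radius**2 * geometry.length
    v_crowder = math.pi * a_c**3 / 6.0
    return round(phi_c * v_cyl / v_crowder)


def place_crowders(
    n: int,
    geometry: CylinderGeometry,
    existing_positions: np.ndarray,
    rng: np.random.Generator,
    a_c: float = 0.3,
    a: float = 1.0,
    max_attempts_per_crowder: int = 2000,
) -> np.ndarray:
    """Insert ``n`` crowder centers uniformly in the accessible volume.

    A candidate is rejected if it sits closer than 0.9x the WCA contact
    distance to any existing particle (monomers at (a + a_c)/2, crowders at
    a_c) or inside the wall's repulsive zone.  Uses a spatial hash so cost
    stays near-linear in n.
    """
    if n == 0:
        return np.zeros((0, 3))
    sig_mc = 0.5 * (a + a_c)
    r_acc = geometry.radius - (WCA_CUT - 1.0) * sig_mc * 0.5  # conservative margin
    min_cc = 0.9 * a_c
    min_mc = 0.9 * sig_mc
    length = geometry.length
    periodic = geometry.mode == "periodic"
    z_lo, z_hi = (0.0, length) if periodic else (0.15, length - 0.15)

    cell = max(min_cc, 1e-9)
    grid: dict[tuple[int, int, int], list[int]] = {}
    accepted = np.empty((n, 3))
    n_acc = 0

    existing = np.asarray(existing_positions, dtype=float)

    def key(p):
        return (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))

    nz_cells = max(1, int(length // cell))
    for _ in range(n * max_attempts_per_crowder):
        if n_acc == n:
            break
        u = rng.random()
        rho = r_acc * math.sqrt(rng.random())
        theta = 2.0 * math.pi * rng.random()
        z = z_lo + (z_hi - z_lo) * u
        cand = np.array([rho * math.cos(theta), rho * math.sin(theta), z])

        # monomers: few, direct check
        if len(existing):
            d = existing - cand
            if periodic:
                d[:, 2] -= length * np.round(d[:, 2] / length)
            if np.min(np.einsum("ij,ij->i", d, d)) < min_mc**2:
                continue
        # crowders: spatial hash over neighbor cells
        kx, ky, kz = key(cand)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    kz2 = kz + dz
                    if periodic:
                        kz2 = kz2 % nz_cells
                    for idx in grid.get((kx + dx, ky + dy, kz2), ()):
                        d = accepted[idx] - cand
                        if periodic:
                            d[2] -= length * round(d[2] / length)
                        if d @ d < min_cc**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        accepted[n_acc] = cand
        kz_wrapped = kz % nz_cells if periodic else kz
        grid.setdefault((kx, ky, kz_wrapped), []).append(n_acc)
        n_acc += 1

    if n_acc < n:
        raise PackingError(
            f"inserted only {n_acc}/{n} crowders before the attempt budget", n_acc
        )
    return accepted


def build_wall_beads(geometry: CylinderGeometry, sigma13: float = 1.0, a: float = 1.0) -> np.ndarray:
    """Explicit wall: rings of beads on the cylinder of radius D/2 + sigma13.

    Bead centers sit where the smooth wall places its contact surface, so
    monomer centers are bounded near rho = D/2 in both wall models.  The
    lattice spacing (arc and axial) is ``geometry.wall_bead_spacing``.
    """
    r_w = geometry.radius + sigma13
    spacing = geometry.wall_bead_spacing
    n_arc = max(6, int(round(2.0 * math.pi * r_w / spacing)))
    n_z = max(1, int(round(geometry.length / spacing)))
    dz = geometry.length / n_z
    rows = []
    for iz in range(n_z):
        # stagger alternate rings by half a site to close gaps
        phase = math.pi / n_arc * (iz % 2)
        ang = 2.0 * math.pi * np.arange(n_arc) / n_arc + phase
        ring = np.column_stack(
            [r_w * np.cos(ang), r_w * np.sin(ang), np.full(n_arc, (iz + 0.5) * dz)]
        )
        rows.append(ring)
    return np.vstack(rows)


def build_system(
    spec: SystemSpec, rng: np.random.Generator | None = None
) -> tuple[ParticleState, RingTopology]:
    """Assemble the full initial state: helical ring + crowders (+ wall beads).

    Velocities are drawn Maxwell-Boltzmann at the working temperature from
    the spec seed.  Crowded systems above phi_c = 0.25 are packed by the
    reduced-diameter inflation protocol.
    """
    from .dynamics import draw_maxwell_boltzmann, integrate

    geo = spec.geometry
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    ring = build_ring(spec.n_monomers, geo, sigma=spec.monomer_diameter)
    topology = RingTopology(spec.n_monomers)
    n_c = crowder_count(spec.phi_c, geo, spec.crowder_diameter)

    inflate = spec.phi_c > 0.25 and n_c > 0
    if inflate:
        scale0 = (0.25 / spec.phi_c) ** (1.0 / 3.0)
        a_c_eff = spec.crowder_diameter * scale0
    else:
        a_c_eff = spec.crowder_diameter

    crowders = place_crowders(
        n_c, geo, ring, rng, a_c=a_c_eff, a=spec.monomer_diameter
    )
    positions = np.vstack([ring, crowders])
    species = np.concatenate(
        [np.full(len(ring), MONOMER), np.full(len(crowders), CROWDER)]
    ).astype(np.int64)

    if geo.wall_model == "beads":
        wall = build_wall_beads(
            geo, sigma13=spec.interactions.sigma[MONOMER, WALL], a=spec.monomer_diameter
        )
        positions = np.vstack([positions, wall])
        species = np.concatenate([species, np.full(len(wall), WALL)]).astype(np.int64)

    state = ParticleState.create(positions, species)

    if inflate:
        # grow crowders back to full size over a short damped relaxation
        n_stages = 14
        for stage in range(1, n_stages + 1):
            frac = stage / n_stages
            a_c_stage = a_c_eff + (spec.crowder_diameter - a_c_eff) * frac
            stage_spec = SystemSpec(
                n_monomers=spec.n_monomers,
                monomer_diameter=spec.monomer_diameter,
                crowder_diameter=a_c_stage,
                phi_c=0.0,  # bookkeeping only; particles are already placed
                interactions=InteractionTable.create(
                    a=spec.monomer_diameter,
                    a_c=a_c_stage,
                    eps13=spec.interactions.eps13,
                ),
                bonds=spec.bonds,
                dynamics=type(spec.dynamics)(
                    dt=0.0005, gamma=1.0, temperature=spec.dynamics.temperature,
                    mass=spec.dynamics.mass,
                ),
                geometry=geo,
                seed=spec.seed,
            )
            draw_maxwell_boltzmann(state, stage_spec.dynamics, rng)
            traj = integrate(
                state, stage_spec, n_steps=700, sample_stride=700,
                seed=int(rng.integers(2**31 - 1)), record_energy=False,
            )
            state = traj.frames[-1]

    draw_maxwell_boltzmann(state, spec.dynamics, rng)
    return state, topology


# ---------------------------------------------------------------------------
# deterministic test fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str) -> tuple[ParticleState, SystemSpec, RingTopology | None]:
    """Small frozen systems used throughout the test suite.

    - "dimer": two unbonded monomers at contact separation.
    - "triangle-ring": N = 3 flat ring.
    - "ring20": N = 20 helical ring, D = 5a.
    - "ring20+crowders": the same ring plus 50 crowders (seeded placement).
    """
    if name == "dimer":
        geo = CylinderGeometry(diameter=5.0, length=10.0)
        spec = SystemSpec(n_monomers=3, geometry=geo)  # table only; no ring built
        pos = np.array([[0.0, 0.0, 4.5], [1.0, 0.0, 4.5]])
        state = ParticleState.create(pos, [MONOMER, MONOMER])
        return state, spec, None

    if name == "triangle-ring":
        geo = CylinderGeometry(diameter=5.0, length=10.0)
        spec = SystemSpec(n_monomers=3, geometry=geo)
        pos = build_ring(3, geo)
        state = ParticleState.create(pos, [MONOMER] * 3)
        return state, spec, RingTopology(3)

    if name == "ring20":
        geo = CylinderGeometry(diameter=5.0, length=20.0)
        spec = SystemSpec(n_monomers=20, geometry=geo)
        pos = build_ring(20, geo)
        state = ParticleState.create(pos, [MONOMER] * 20)
        return state, spec, RingTopology(20)

    if name == "ring20+crowders":
        geo = CylinderGeometry(diameter=5.0, length=20.0)
        spec = SystemSpec(n_monomers=20, geometry=geo, phi_c=0.05)
        ring = build_ring(20, geo)
        rng = np.random.default_rng(12345)
        crowders = place_crowders(50, geo, ring, rng)
        pos = np.vstack([ring, crowders])
        species = np.array([MONOMER] * 20 + [CROWDER] * 50, dtype=np.int64)
        state = ParticleState.create(pos, species)
        return state, spec, RingTopology(20)

    raise KeyError(f"unknown fixture {name!r}")
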