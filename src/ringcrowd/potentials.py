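"""Pair and wall potentials: purely repulsive WCA pairs, FENE bonds, and the
smooth cylindrical wall.

These scalar/vector routines are the readable reference used by the
brute-force oracle and by tests; the production force loop in
:mod:`ringcrowd.forces` reimplements the same expressions in compiled kernels.
"""

from __future__ import annotations

import numpy as np

from .params import WCA_CUT, CylinderGeometry, InteractionTable, BondParams


class BondOverstretchError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension r0."""


class WallEscapeError(RuntimeError):
    """A particle center moved past the confining wall surface."""


def wca_energy(r: float, i: int, j: int, table: InteractionTable) -> float:
    """WCA energy for a center-to-center distance ``r`` between species i, j.

    U(r) = 4 eps_ij [ (sigma_ij/r)^12 - (sigma_ij/r)^6 + 1/4 ]  for
    r < 2^(1/6) sigma_ij, and exactly 0 beyond (truncated-and-shifted LJ).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sigma = table.sigma[i, j]
    if r >= WCA_CUT * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * table.epsilon[i, j] * (sr6 * sr6 - sr6 + 0.25)


def wca_force(r_vec: np.ndarray, i: int, j: int, table: InteractionTable) -> np.ndarray:
    """Force on the particle at +r_vec from its partner at the origin.

    Equals -grad U_WCA; repulsive, so it points along +r_vec inside the
    cutoff and vanishes at and beyond it.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    if r2 == 0.0:
        raise ValueError("zero-length pair displacement")
    sigma = table.sigma[i, j]
    if r2 >= (WCA_CUT * sigma) ** 2:
        return np.zeros(3)
    sr6 = (sigma * sigma / r2) ** 3
    # -dU/dr / r = 24 eps (2 sr12 - sr6) / r^2
    coeff = 24.0 * table.epsilon[i, j] * (2.0 * sr6 * sr6 - sr6) / r2
    return coeff * r_vec


def fene_energy(r: float, bonds: BondParams) -> float:
    """FENE bond energy -(1/2) k r0^2 ln[1 - (r/r0)^2]."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= bonds.r0:
        raise BondOverstretchError(f"bond length {r:.4f} >= r0 = {bonds.r0}")
    x = (r / bonds.r0) ** 2
    return -0.5 * bonds.k * bonds.r0 ** 2 * np.log1p(-x)


def fene_force(r_vec: np.ndarray, bonds: BondParams) -> np.ndarray:
    """Force on the particle at +r_vec from its bonded partner at the origin.

    Attractive toward the partner with magnitude k r / (1 - (r/r0)^2).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    if r2 >= bonds.r0 ** 2:
        raise BondOverstretchError(
            f"bond length {np.sqrt(r2):.4f} >= r0 = {bonds.r0}"
        )
    return -bonds.k / (1.0 - r2 / bonds.r0 ** 2) * r_vec


def wall_interaction(
    position: np.ndarray,
    species: int,
    geometry: CylinderGeometry,
    table: InteractionTable,
    radial: bool = True,
) -> tuple[float, np.ndarray]:
    """Smooth-wall energy and force for one particle.

    The WCA law with parameters (eps_i3, sigma_i3) acts on the radial gap
    d = (D/2 + sigma_i3) - rho, so a particle center at rho = D/2 sits at
    pair contact d = sigma_i3 and the force-free region extends to
    rho = D/2 + sigma_i3 (1 - 2^(1/6)), just inside D/2.  In capped mode the
    same law acts on the axial gaps z + sigma_i3 and (L - z) + sigma_i3.
    """
    position = np.asarray(position, dtype=float)
    from .params import WALL

    sigma = table.sigma[species, WALL]
    eps = table.epsilon[species, WALL]
    radius = geometry.radius
    x, y, z = position
    rho = np.hypot(x, y)

    energy = 0.0
    force = np.zeros(3)

    if radial:
        d = radius + sigma - rho
        if d <= 0:
            raise WallEscapeError(f"particle at rho = {rho:.4f} outside cylinder")
        if d < WCA_CUT * sigma:
            sr6 = (sigma / d) ** 6
            energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
            mag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d  # -dU/dd > 0
            if rho > 0:
                force[0] -= mag * x / rho
                force[1] -= mag * y / rho

    if geometry.mode == "capped":
        for gap, sign in ((z + sigma, +1.0), (geometry.length - z + sigma, -1.0)):
            if gap <= 0:
                raise WallEscapeError(f"particle at z = {z:.4f} outside caps")
            if gap < WCA_CUT * sigma:
                sr6 = (sigma / gap) ** 6
                energy += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                force[2] += sign * 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / gap

    return energy, force
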