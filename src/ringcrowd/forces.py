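"""Force evaluation: O(n^2) reference oracle and compiled production path.

The oracle (`brute_force_forces`) is written for clarity on top of
:mod:`ringcrowd.potentials` and is the ground truth in tests.  The production
path (`compute_forces`) evaluates the identical model with compiled kernels:
monomers (few) via a direct pair loop, crowders (many) via a linked-cell list
sized to the crowder-crowder cutoff, and monomer-crowder pairs by querying
that cell list over enough shells to cover the mixed cutoff.  Only the
longitudinal direction is periodic, so the minimum-image convention applies
to z alone.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (
    CROWDER,
    MONOMER,
    WALL,
    WCA_CUT,
    ParticleState,
    RingTopology,
    SystemSpec,
)
from .potentials import (
    BondOverstretchError,
    WallEscapeError,
    fene_force,
    fene_energy,
    wall_interaction,
    wca_energy,
    wca_force,
)

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_ESCAPE = 2


# ---------------------------------------------------------------------------
# reference oracle
# ---------------------------------------------------------------------------

def _min_image_dz(dz: float, length: float, periodic: bool) -> float:
    if periodic:
        dz -= length * np.round(dz / length)
    return dz


def brute_force_forces(
    state: ParticleState, spec: SystemSpec, topology: RingTopology | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """All-pairs force sum with a per-component potential-energy breakdown.

    Returns ``(forces, {"pair": U_pair, "bond": U_bond, "wall": U_wall})``.
    Wall-bead (species 2) pairs with each other are skipped: wall beads are
    frozen scaffolding, not dynamical particles.
    """
    geo = spec.geometry
    table = spec.interactions
    periodic = geo.mode == "periodic"
    pos = state.positions
    spc = state.species
    n = state.n
    forces = np.zeros((n, 3))
    energy = {"pair": 0.0, "bond": 0.0, "wall": 0.0}

    bonded = set()
    if topology is None and state.n_monomers >= 3:
        topology = RingTopology(state.n_monomers)
    if topology is not None:
        for a, b in topology.bonds:
            bonded.add((int(a), int(b)))

    for i in range(n):
        for j in range(i + 1, n):
            if spc[i] == WALL and spc[j] == WALL:
                continue
            d = pos[j] - pos[i]
            d[2] = _min_image_dz(d[2], geo.length, periodic)
            r = float(np.linalg.norm(d))
            energy["pair"] += wca_energy(r, spc[i], spc[j], table)
            f = wca_force(d, spc[i], spc[j], table)
            forces[j] += f
            forces[i] -= f

    for a, b in bonded:
        d = pos[b] - pos[a]
        d[2] = _min_image_dz(d[2], geo.length, periodic)
        r = float(np.linalg.norm(d))
        energy["bond"] += fene_energy(r, spec.bonds)
        f = fene_force(d, spec.bonds)
        forces[b] += f
        forces[a] -= f

    smooth = geo.wall_model == "smooth"
    if smooth or geo.mode == "capped":
        # caps are always the smooth axial law, even with a bead side wall
        for i in range(n):
            if spc[i] == WALL:
                continue
            u, f = wall_interaction(pos[i], int(spc[i]), geo, table, radial=smooth)
            energy["wall"] += u
            forces[i] += f

    return forces, energy


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _pair_accum(forces, pos, i, j, dz_shift, sigma, eps):
    """Accumulate WCA force/energy for one pair; returns pair energy."""
    dx = pos[j, 0] - pos[i, 0]
    dy = pos[j, 1] - pos[i, 1]
    dz = pos[j, 2] - pos[i, 2] + dz_shift
    r2 = dx * dx + dy * dy + dz * dz
    cut2 = (WCA_CUT * sigma) ** 2
    if r2 >= cut2 or r2 == 0.0:
        return 0.0
    sr6 = (sigma * sigma / r2) ** 3
    coeff = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
    forces[j, 0] += coeff * dx
    forces[j, 1] += coeff * dy
    forces[j, 2] += coeff * dz
    forces[i, 0] -= coeff * dx
    forces[i, 1] -= coeff * dy
    forces[i, 2] -= coeff * dz
    return 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)


@njit(cache=True, fastmath=True)
def _forces_kernel(
    pos,
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
    forces,
):
    """Full force evaluation. Returns (status, U_pair, U_bond, U_wall)."""
    n = pos.shape[0]
    forces[:] = 0.0
    e_pair = 0.0
    e_bond = 0.0
    e_wall = 0.0

    # --- monomer-monomer and everything involving wall beads
    # non-crowders occupy [0, n_mono) and [n_mono + n_crowd, n)
    n_tail = n - n_mono - n_crowd
    half_l = 0.5 * length
    if n_tail > 0:
        # bead-built wall present (fidelity option): plain direct loop
        n_direct = n_mono + n_tail
        for a in range(n_direct):
            i = a if a < n_mono else a + n_crowd
            si = species[a if a < n_mono else a + n_crowd]
            for b in range(a + 1, n_direct):
                j = b if b < n_mono else b + n_crowd
                sj = species[j]
                if si == WALL and sj == WALL:
                    continue
                dz_shift = 0.0
                if periodic:
                    dz = pos[j, 2] - pos[i, 2]
                    if dz > half_l:
                        dz_shift = -length
                    elif dz < -half_l:
                        dz_shift = length
                e_pair += _pair_accum(
                    forces, pos, i, j, dz_shift, sig[si, sj], eps[si, sj]
                )
    elif n_mono > 0:
        # monomer-monomer via 1D z-bins of width >= the monomer cutoff:
        # the chain spreads along the axis, so z separates most pairs
        sig_mm = sig[MONOMER, MONOMER]
        eps_mm = eps[MONOMER, MONOMER]
        cut_mm = WCA_CUT * sig_mm
        if periodic:
            nbz = max(3, int(length / cut_mm))
            binw = length / nbz
            blo = 0.0
        else:
            nbz = max(1, int((length + 2.0) / cut_mm))
            binw = (length + 2.0) / nbz
            blo = -1.0
        mhead = np.full(nbz, -1, dtype=np.int64)
        mnxt = np.full(n_mono, -1, dtype=np.int64)
        mbin = np.empty(n_mono, dtype=np.int64)
        for i in range(n_mono):
            bz = int((pos[i, 2] - blo) / binw)
            if periodic:
                bz = bz % nbz
            else:
                if bz < 0:
                    bz = 0
                if bz >= nbz:
                    bz = nbz - 1
            mbin[i] = bz
            mnxt[i] = mhead[bz]
            mhead[bz] = i
        for i in range(n_mono):
            for dzb in range(-1, 2):
                bz = mbin[i] + dzb
                dz_shift = 0.0
                if periodic:
                    wrapped = bz % nbz
                    dz_shift = length * ((bz - wrapped) // nbz)
                    bz = wrapped
                elif bz < 0 or bz >= nbz:
                    continue
                j = mhead[bz]
                while j >= 0:
                    if j > i:
                        e_pair += _pair_accum(
                            forces, pos, i, j, dz_shift, sig_mm, eps_mm
                        )
                    j = mnxt[j]

    # --- crowders via linked-cell list
    if n_crowd > 0:
        c0 = n_mono
        c1 = n_mono + n_crowd
        cut_cc = WCA_CUT * sig[CROWDER, CROWDER]
        cut_mc = WCA_CUT * sig[MONOMER, CROWDER]
        span = 2.0 * (radius + 1.0)
        ncx = max(1, int(span / cut_cc))
        cellx = span / ncx
        if periodic:
            ncz = max(3, int(length / cut_cc))
            cellz = length / ncz
        else:
            ncz = max(1, int((length + 2.0) / cut_cc))
            cellz = (length + 2.0) / ncz
        zlo = 0.0 if periodic else -1.0

        ncell = ncx * ncx * ncz
        head = np.full(ncell, -1, dtype=np.int64)
        nxt = np.full(n_crowd, -1, dtype=np.int64)
        cx = np.empty(n_crowd, dtype=np.int64)
        cy = np.empty(n_crowd, dtype=np.int64)
        cz = np.empty(n_crowd, dtype=np.int64)
        for kk in range(n_crowd):
            p = c0 + kk
            ix = int((pos[p, 0] + radius + 1.0) / cellx)
            iy = int((pos[p, 1] + radius + 1.0) / cellx)
            iz = int((pos[p, 2] - zlo) / cellz)
            if ix < 0:
                ix = 0
            if ix >= ncx:
                ix = ncx - 1
            if iy < 0:
                iy = 0
            if iy >= ncx:
                iy = ncx - 1
            if periodic:
                iz = iz % ncz
            else:
                if iz < 0:
                    iz = 0
                if iz >= ncz:
                    iz = ncz - 1
            cx[kk] = ix
            cy[kk] = iy
            cz[kk] = iz
            cell = (iz * ncx + iy) * ncx + ix
            nxt[kk] = head[cell]
            head[cell] = kk

        # crowder-crowder: 27-cell stencil, each pair counted once (ll > kk);
        # dz_shift moves the *partner* image next to kk across the boundary
        for kk in range(n_crowd):
            p = c0 + kk
            for dznb in range(-1, 2):
                iz = cz[kk] + dznb
                dz_shift = 0.0
                if periodic:
                    wrapped = iz % ncz
                    dz_shift = length * ((iz - wrapped) // ncz)
                    iz = wrapped
                elif iz < 0 or iz >= ncz:
                    continue
                for dynb in range(-1, 2):
                    iy = cy[kk] + dynb
                    if iy < 0 or iy >= ncx:
                        continue
                    for dxnb in range(-1, 2):
                        ix = cx[kk] + dxnb
                        if ix < 0 or ix >= ncx:
                            continue
                        cell = (iz * ncx + iy) * ncx + ix
                        ll = head[cell]
                        while ll >= 0:
                            if ll > kk:
                                e_pair += _pair_accum(
                                    forces, pos, p, c0 + ll, dz_shift,
                                    sig[CROWDER, CROWDER], eps[CROWDER, CROWDER],
                                )
                            ll = nxt[ll]

        # monomer/wall-bead vs crowder: shells covering the mixed cutoff
        sxy = int(cut_mc / cellx) + 1
        sz = int(cut_mc / cellz) + 1
        for i in range(n):
            si = species[i]
            if si == CROWDER:
                continue
            sig_mc = sig[si, CROWDER]
            eps_mc = eps[si, CROWDER]
            ix0 = int((pos[i, 0] + radius + 1.0) / cellx)
            iy0 = int((pos[i, 1] + radius + 1.0) / cellx)
            iz0 = int((pos[i, 2] - zlo) / cellz)
            for dznb in range(-sz, sz + 1):
                iz = iz0 + dznb
                dz_shift = 0.0
                if periodic:
                    wrapped = iz % ncz
                    dz_shift = length * ((iz - wrapped) // ncz)
                    iz = wrapped
                elif iz < 0 or iz >= ncz:
                    continue
                for dynb in range(-sxy, sxy + 1):
                    iy = iy0 + dynb
                    if iy < 0 or iy >= ncx:
                        continue
                    for dxnb in range(-sxy, sxy + 1):
                        ix = ix0 + dxnb
                        if ix < 0 or ix >= ncx:
                            continue
                        cell = (iz * ncx + iy) * ncx + ix
                        ll = head[cell]
                        while ll >= 0:
                            e_pair += _pair_accum(
                                forces, pos, i, c0 + ll, dz_shift, sig_mc, eps_mc
                            )
                            ll = nxt[ll]

    # --- FENE ring bonds (a ring needs >= 3 beads; fewer means no bonds)
    n_bonded = n_mono if n_mono >= 3 else 0
    for i in range(n_bonded):
        j = i + 1
        if j == n_bonded:
            j = 0
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if periodic:
            if dz > 0.5 * length:
                dz -= length
            elif dz < -0.5 * length:
                dz += length
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= bond_r0 * bond_r0:
            return STATUS_OVERSTRETCH, e_pair, e_bond, e_wall
        x = r2 / (bond_r0 * bond_r0)
        e_bond += -0.5 * bond_k * bond_r0 * bond_r0 * np.log(1.0 - x)
        coeff = -bond_k / (1.0 - x)
        forces[j, 0] += coeff * dx
        forces[j, 1] += coeff * dy
        forces[j, 2] += coeff * dz
        forces[i, 0] -= coeff * dx
        forces[i, 1] -= coeff * dy
        forces[i, 2] -= coeff * dz

    # --- smooth wall (radial, plus caps when capped)
    if smooth_wall or capped:
        for i in range(n):
            si = species[i]
            if si == WALL:
                continue
            sw = sig[si, WALL]
            ew = eps[si, WALL]
            rho = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            if smooth_wall:
                d = radius + sw - rho
                if d <= 0.0:
                    return STATUS_ESCAPE, e_pair, e_bond, e_wall
                if d < WCA_CUT * sw:
                    sr6 = (sw / d) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    mag = 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / d
                    if rho > 0.0:
                        forces[i, 0] -= mag * pos[i, 0] / rho
                        forces[i, 1] -= mag * pos[i, 1] / rho
            elif rho >= radius + 0.5:
                # past the bead-wall shell: containment lost
                return STATUS_ESCAPE, e_pair, e_bond, e_wall
            if capped:
                glo = pos[i, 2] + sw
                ghi = length - pos[i, 2] + sw
                if glo <= 0.0 or ghi <= 0.0:
                    return STATUS_ESCAPE, e_pair, e_bond, e_wall
                if glo < WCA_CUT * sw:
                    sr6 = (sw / glo) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    forces[i, 2] += 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / glo
                if ghi < WCA_CUT * sw:
                    sr6 = (sw / ghi) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    forces[i, 2] -= 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / ghi

    return STATUS_OK, e_pair, e_bond, e_wall


# ---------------------------------------------------------------------------
# Verlet pair list (production integrator path)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _build_pairs(pos, species, n_mono, n_crowd, sig, skin, length, periodic, radius, pairs):
    """Collect all pairs within cutoff + skin into ``pairs``.

    Non-crowder pairs by direct loop (few particles); crowders via a cell
    grid sized to the crowder cutoff, searched over enough shells to cover
    each pair type's cutoff + skin.  Returns the pair count, or -1 if the
    buffer is full.
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    count = 0
    half_l = 0.5 * length

    n_tail = n - n_mono - n_crowd
    n_direct = n_mono + n_tail
    for a in range(n_direct):
        i = a if a < n_mono else a + n_crowd
        si = species[i]
        for b in range(a + 1, n_direct):
            j = b if b < n_mono else b + n_crowd
            sj = species[j]
            if si == WALL and sj == WALL:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if periodic:
                if dz > half_l:
                    dz -= length
                elif dz < -half_l:
                    dz += length
            cut = WCA_CUT * sig[si, sj] + skin
            if dx * dx + dy * dy + dz * dz < cut * cut:
                if count >= cap:
                    return -1
                pairs[count, 0] = i
                pairs[count, 1] = j
                count += 1

    if n_crowd > 0:
        c0 = n_mono
        cut_cc = WCA_CUT * sig[CROWDER, CROWDER]
        span = 2.0 * (radius + 1.0)
        ncx = max(1, int(span / cut_cc))
        cellx = span / ncx
        if periodic:
            ncz = max(3, int(length / cut_cc))
            cellz = length / ncz
        else:
            ncz = max(1, int((length + 2.0) / cut_cc))
            cellz = (length + 2.0) / ncz
        zlo = 0.0 if periodic else -1.0

        ncell = ncx * ncx * ncz
        head = np.full(ncell, -1, dtype=np.int64)
        nxt = np.full(n_crowd, -1, dtype=np.int64)
        cx = np.empty(n_crowd, dtype=np.int64)
        cy = np.empty(n_crowd, dtype=np.int64)
        cz = np.empty(n_crowd, dtype=np.int64)
        for kk in range(n_crowd):
            p = c0 + kk
            ix = min(max(int((pos[p, 0] + radius + 1.0) / cellx), 0), ncx - 1)
            iy = min(max(int((pos[p, 1] + radius + 1.0) / cellx), 0), ncx - 1)
            iz = int((pos[p, 2] - zlo) / cellz)
            if periodic:
                iz = iz % ncz
            else:
                iz = min(max(iz, 0), ncz - 1)
            cx[kk] = ix
            cy[kk] = iy
            cz[kk] = iz
            cell = (iz * ncx + iy) * ncx + ix
            nxt[kk] = head[cell]
            head[cell] = kk

        cut_l = cut_cc + skin
        sxy_c = int(cut_l / cellx) + 1
        sz_c = int(cut_l / cellz) + 1
        cut_l2 = cut_l * cut_l
        for kk in range(n_crowd):
            p = c0 + kk
            for dznb in range(-sz_c, sz_c + 1):
                iz = cz[kk] + dznb
                dz_shift = 0.0
                if periodic:
                    wrapped = iz % ncz
                    dz_shift = length * ((iz - wrapped) // ncz)
                    iz = wrapped
                elif iz < 0 or iz >= ncz:
                    continue
                for dynb in range(-sxy_c, sxy_c + 1):
                    iy = cy[kk] + dynb
                    if iy < 0 or iy >= ncx:
                        continue
                    for dxnb in range(-sxy_c, sxy_c + 1):
                        ix = cx[kk] + dxnb
                        if ix < 0 or ix >= ncx:
                            continue
                        cell = (iz * ncx + iy) * ncx + ix
                        ll = head[cell]
                        while ll >= 0:
                            if ll > kk:
                                dx = pos[c0 + ll, 0] - pos[p, 0]
                                dy = pos[c0 + ll, 1] - pos[p, 1]
                                dzv = pos[c0 + ll, 2] - pos[p, 2] + dz_shift
                                if dx * dx + dy * dy + dzv * dzv < cut_l2:
                                    if count >= cap:
                                        return -1
                                    pairs[count, 0] = p
                                    pairs[count, 1] = c0 + ll
                                    count += 1
                            ll = nxt[ll]

        for i in range(n):
            si = species[i]
            if si == CROWDER:
                continue
            cut_m = WCA_CUT * sig[si, CROWDER] + skin
            cut_m2 = cut_m * cut_m
            sxy = int(cut_m / cellx) + 1
            sz = int(cut_m / cellz) + 1
            ix0 = int((pos[i, 0] + radius + 1.0) / cellx)
            iy0 = int((pos[i, 1] + radius + 1.0) / cellx)
            iz0 = int((pos[i, 2] - zlo) / cellz)
            for dznb in range(-sz, sz + 1):
                iz = iz0 + dznb
                dz_shift = 0.0
                if periodic:
                    wrapped = iz % ncz
                    dz_shift = length * ((iz - wrapped) // ncz)
                    iz = wrapped
                elif iz < 0 or iz >= ncz:
                    continue
                for dynb in range(-sxy, sxy + 1):
                    iy = iy0 + dynb
                    if iy < 0 or iy >= ncx:
                        continue
                    for dxnb in range(-sxy, sxy + 1):
                        ix = ix0 + dxnb
                        if ix < 0 or ix >= ncx:
                            continue
                        cell = (iz * ncx + iy) * ncx + ix
                        ll = head[cell]
                        while ll >= 0:
                            dx = pos[c0 + ll, 0] - pos[i, 0]
                            dy = pos[c0 + ll, 1] - pos[i, 1]
                            dzv = pos[c0 + ll, 2] - pos[i, 2] + dz_shift
                            if dx * dx + dy * dy + dzv * dzv < cut_m2:
                                if count >= cap:
                                    return -1
                                pairs[count, 0] = i
                                pairs[count, 1] = c0 + ll
                                count += 1
                            ll = nxt[ll]
    return count


@njit(cache=True, fastmath=True)
def _pair_list_forces(
    pos, species, pairs, npairs, n_mono, sig, eps, bond_k, bond_r0,
    length, periodic, radius, capped, smooth_wall, forces,
):
    """Forces/energies from a prebuilt pair list + bonds + wall.

    Identical physics to _forces_kernel; used inside the integrator where
    the pair list amortizes neighbor search over many steps.
    """
    n = pos.shape[0]
    forces[:] = 0.0
    e_pair = 0.0
    e_bond = 0.0
    e_wall = 0.0
    half_l = 0.5 * length
    for k in range(npairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dz_shift = 0.0
        if periodic:
            dz = pos[j, 2] - pos[i, 2]
            if dz > half_l:
                dz_shift = -length
            elif dz < -half_l:
                dz_shift = length
        si = species[i]
        sj = species[j]
        e_pair += _pair_accum(forces, pos, i, j, dz_shift, sig[si, sj], eps[si, sj])

    n_bonded = n_mono if n_mono >= 3 else 0
    for i in range(n_bonded):
        j = i + 1
        if j == n_bonded:
            j = 0
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if periodic:
            if dz > half_l:
                dz -= length
            elif dz < -half_l:
                dz += length
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= bond_r0 * bond_r0:
            return STATUS_OVERSTRETCH, e_pair, e_bond, e_wall
        x = r2 / (bond_r0 * bond_r0)
        e_bond += -0.5 * bond_k * bond_r0 * bond_r0 * np.log(1.0 - x)
        coeff = -bond_k / (1.0 - x)
        forces[j, 0] += coeff * dx
        forces[j, 1] += coeff * dy
        forces[j, 2] += coeff * dz
        forces[i, 0] -= coeff * dx
        forces[i, 1] -= coeff * dy
        forces[i, 2] -= coeff * dz

    if smooth_wall or capped:
        for i in range(n):
            si = species[i]
            if si == WALL:
                continue
            sw = sig[si, WALL]
            ew = eps[si, WALL]
            rho = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            if smooth_wall:
                d = radius + sw - rho
                if d <= 0.0:
                    return STATUS_ESCAPE, e_pair, e_bond, e_wall
                if d < WCA_CUT * sw:
                    sr6 = (sw / d) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    mag = 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / d
                    if rho > 0.0:
                        forces[i, 0] -= mag * pos[i, 0] / rho
                        forces[i, 1] -= mag * pos[i, 1] / rho
            elif rho >= radius + 0.5:
                # past the bead-wall shell: containment lost
                return STATUS_ESCAPE, e_pair, e_bond, e_wall
            if capped:
                glo = pos[i, 2] + sw
                ghi = length - pos[i, 2] + sw
                if glo <= 0.0 or ghi <= 0.0:
                    return STATUS_ESCAPE, e_pair, e_bond, e_wall
                if glo < WCA_CUT * sw:
                    sr6 = (sw / glo) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    forces[i, 2] += 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / glo
                if ghi < WCA_CUT * sw:
                    sr6 = (sw / ghi) ** 6
                    e_wall += 4.0 * ew * (sr6 * sr6 - sr6 + 0.25)
                    forces[i, 2] -= 24.0 * ew * (2.0 * sr6 * sr6 - sr6) / ghi

    return STATUS_OK, e_pair, e_bond, e_wall


def _kernel_args(state: ParticleState, spec: SystemSpec):
    geo = spec.geometry
    n_crowd = int(np.sum(state.species == CROWDER))
    return (
        state.positions,
        state.species,
        state.n_monomers,
        n_crowd,
        spec.interactions.sigma,
        spec.interactions.epsilon,
        spec.bonds.k,
        spec.bonds.r0,
        geo.length,
        geo.mode == "periodic",
        geo.radius,
        geo.mode == "capped",
        geo.wall_model == "smooth",
    )


def compute_forces(state: ParticleState, spec: SystemSpec) -> np.ndarray:
    """Production force evaluation; identical to the oracle to ~1e-10."""
    forces = np.zeros_like(state.positions)
    status, *_ = _forces_kernel(*_kernel_args(state, spec), forces)
    _raise_for_status(status)
    return forces


def potential_energy(state: ParticleState, spec: SystemSpec) -> dict[str, float]:
    """Per-component potential energy via the production kernel."""
    forces = np.zeros_like(state.positions)
    status, e_pair, e_bond, e_wall = _forces_kernel(*_kernel_args(state, spec), forces)
    _raise_for_status(status)
    return {"pair": e_pair, "bond": e_bond, "wall": e_wall}


def _raise_for_status(status: int, step: int | None = None) -> None:
    where = "" if step is None else f" at step {step}"
    if status == STATUS_OVERSTRETCH:
        raise BondOverstretchError(f"FENE bond reached maximum extension{where}")
    if status == STATUS_ESCAPE:
        raise WallEscapeError(f"particle escaped the confining wall{where}")
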