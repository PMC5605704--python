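"""Initial-condition construction: ring geometry, crowder counts and
placement statistics, full-system assembly."""

import numpy as np
import pytest
from scipy import stats

from ringcrowd import (
    CylinderGeometry,
    SystemSpec,
    build_ring,
    build_system,
    crowder_count,
    make_fixture,
    place_crowders,
)
from ringcrowd.builder import ConstructionError, R0_TABLE, equilibrium_span
from ringcrowd.params import CROWDER, MONOMER, RingTopology


def _check_ring(pos, geo, n):
    assert len(pos) == n
    nxt = np.roll(pos, -1, axis=0)
    d = nxt - pos
    if geo.mode == "periodic":
        d[:, 2] -= geo.length * np.round(d[:, 2] / geo.length)
    bonds = np.linalg.norm(d, axis=1)
    assert bonds.min() >= 0.9 and bonds.max() <= 1.1
    rho = np.hypot(pos[:, 0], pos[:, 1])
    assert rho.max() < geo.radius
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    ring = np.arange(n)
    sep = np.minimum(
        np.abs(ring[:, None] - ring[None, :]),
        n - np.abs(ring[:, None] - ring[None, :]),
    )
    nb = dist[sep >= 2]
    if nb.size:
        assert nb.min() >= 0.85


class TestBuildRing:
    def test_triangle_is_equilateral(self):
        geo = CylinderGeometry(diameter=5.0, length=10.0)
        pos = build_ring(3, geo)
        d01 = np.linalg.norm(pos[0] - pos[1])
        d12 = np.linalg.norm(pos[1] - pos[2])
        d20 = np.linalg.norm(pos[2] - pos[0])
        assert d01 == pytest.approx(d12) == pytest.approx(d20)

    @pytest.mark.parametrize(
        "n,diameter,length,mode",
        [
            (135, 5.0, 78.0, "periodic"),
            (135, 3.0, 20.0, "capped"),
            (135, 4.0, 16.0, "capped"),
            (135, 5.0, 13.0, "capped"),
            (40, 5.0, 13.0, "periodic"),
            (20, 5.0, 20.0, "periodic"),
        ],
    )
    def test_postconditions_across_geometries(self, n, diameter, length, mode):
        geo = CylinderGeometry(diameter=diameter, length=length, mode=mode)
        pos = build_ring(n, geo)
        _check_ring(pos, geo, n)
        if mode == "capped":
            assert pos[:, 2].min() > 0.0
            assert pos[:, 2].max() < length

    def test_deterministic(self):
        geo = CylinderGeometry(diameter=5.0, length=78.0)
        assert np.array_equal(build_ring(135, geo), build_ring(135, geo))

    def test_impossible_geometry_raises(self):
        geo = CylinderGeometry(diameter=2.2, length=3.0, mode="capped")
        with pytest.raises(ConstructionError):
            build_ring(500, geo)


class TestCrowderCount:
    GEO = CylinderGeometry(diameter=5.0, length=78.0)

    def test_zero_phi(self):
        assert crowder_count(0.0, self.GEO, 0.3) == 0

    def test_frozen_arithmetic(self):
        # round(0.3 * pi (2.5)^2 * 78 / ((pi/6) 0.3^3)) computed by hand
        assert crowder_count(0.3, self.GEO, 0.3) == 32500

    def test_linear_in_length(self):
        double = CylinderGeometry(diameter=5.0, length=156.0)
        n1 = crowder_count(0.2, self.GEO, 0.3)
        n2 = crowder_count(0.2, double, 0.3)
        assert abs(n2 - 2 * n1) <= 1

    def test_monotone_in_phi(self):
        counts = [crowder_count(p, self.GEO, 0.3) for p in np.linspace(0, 0.35, 15)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPlaceCrowders:
    GEO = CylinderGeometry(diameter=5.0, length=20.0)

    def test_empty_request(self, rng):
        assert place_crowders(0, self.GEO, np.zeros((0, 3)), rng).shape == (0, 3)

    def test_no_overlaps_with_ring(self, rng):
        ring = build_ring(20, self.GEO)
        crowders = place_crowders(300, self.GEO, ring, rng)
        d = np.linalg.norm(
            crowders[:, None, :] - ring[None, :, :], axis=2
        )
        assert d.min() >= 0.9 * 0.65
        dcc = np.linalg.norm(crowders[:, None, :] - crowders[None, :, :], axis=2)
        np.fill_diagonal(dcc, np.inf)
        assert dcc.min() >= 0.9 * 0.3

    def test_radial_uniformity_chi_squared(self, rng):
        """Single-crowder marginal is uniform over the cross-section area.

        Draws are independent single placements (no mutual exclusion, which
        would physically enhance the density at the sampling boundary).
        """
        empty = np.zeros((0, 3))
        pts = np.vstack(
            [place_crowders(1, self.GEO, empty, rng) for _ in range(10_000)]
        )
        rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        # 20 equal-area radial bins over the sampled disk
        edges = np.linspace(0.0, rho2.max() * (1 + 1e-12), 21)
        counts, _ = np.histogram(rho2, bins=edges)
        chi2, p = stats.chisquare(counts)
        assert p > 0.01


class TestBuildSystem:
    def test_monomers_only_at_zero_phi(self):
        spec = SystemSpec(
            n_monomers=20,
            geometry=CylinderGeometry(diameter=5.0, length=20.0),
            phi_c=0.0,
            seed=1,
        )
        state, topo = build_system(spec)
        assert state.n == 20
        assert np.all(state.species == MONOMER)

    def test_counts_match_crowder_count(self):
        geo = CylinderGeometry(diameter=5.0, length=15.0)
        spec = SystemSpec(n_monomers=20, geometry=geo, phi_c=0.1, seed=2)
        state, topo = build_system(spec)
        expected = crowder_count(0.1, geo, 0.3)
        assert int(np.sum(state.species == CROWDER)) == expected
        # containment and bond invariants before step 0
        rho = np.hypot(state.positions[:, 0], state.positions[:, 1])
        assert rho.max() < geo.radius + 0.01

    def test_high_phi_inflation_protocol(self):
        geo = CylinderGeometry(diameter=5.0, length=6.0)
        spec = SystemSpec(n_monomers=20, geometry=geo, phi_c=0.3, seed=3)
        state, topo = build_system(spec)
        n_c = int(np.sum(state.species == CROWDER))
        assert n_c == crowder_count(0.3, geo, 0.3)
        # post-inflation: no deep hard overlaps at full diameter
        crowders = state.positions[state.species == CROWDER]
        diff = crowders[:, None, :] - crowders[None, :, :]
        diff[:, :, 2] -= geo.length * np.round(diff[:, :, 2] / geo.length)
        d = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.6 * 0.3

    def test_capped_fig5_setting(self):
        r0 = equilibrium_span(135, 3.0)
        geo = CylinderGeometry(diameter=3.0, length=0.6 * r0, mode="capped")
        spec = SystemSpec(n_monomers=135, geometry=geo, phi_c=0.0, seed=4)
        state, _ = build_system(spec)
        assert state.positions[:, 2].min() > 0.0
        assert state.positions[:, 2].max() < geo.length


class TestTopologyAndFixtures:
    def test_arm_pairing_odd_n(self):
        topo = RingTopology(135)
        assert len(topo.bonds) == 135
        # split monomers 0 and 67 never appear in arm pairs
        assert 0 not in topo.arm_pairs
        assert 67 not in topo.arm_pairs
        assert len(topo.arm_pairs) == 66
        flat = topo.arm_pairs.ravel()
        assert len(set(flat.tolist())) == len(flat)
        for left, right in topo.arm_pairs:
            assert left + right == 135

    def test_bond_degrees(self):
        topo = RingTopology(20)
        degree = np.zeros(20, int)
        for a, b in topo.bonds:
            degree[a] += 1
            degree[b] += 1
        assert np.all(degree == 2)

    def test_fixtures_frozen(self):
        s1, _, _ = make_fixture("ring20+crowders")
        s2, _, _ = make_fixture("ring20+crowders")
        assert np.array_equal(s1.positions, s2.positions)
        dimer, _, _ = make_fixture("dimer")
        assert np.linalg.norm(dimer.positions[1] - dimer.positions[0]) == 1.0
        with pytest.raises(KeyError):
            make_fixture("nonesuch")

    def test_r0_lookup_and_fallback(self):
        assert equilibrium_span(135, 5.0) == R0_TABLE[(135, 5.0)]
        # fallback uses blob scaling, must stay positive and D-decreasing
        assert equilibrium_span(100, 4.0) > equilibrium_span(100, 6.0) > 0
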