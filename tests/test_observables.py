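"""Observable definitions against closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringcrowd import (
    CylinderGeometry,
    arm_correlation,
    bimodality_indicator,
    classify_state,
    ensemble_average,
    longitudinal_span,
    mean_sq_radial,
    projected_profile,
)
from ringcrowd.observables import (
    FrameObservables,
    RunSummary,
    UnwrapError,
    replicate_summary,
)
from ringcrowd.params import MONOMER, ParticleState, RingTopology

GEO = CylinderGeometry(diameter=5.0, length=40.0)


def _frame(positions):
    positions = np.asarray(positions, dtype=float)
    return ParticleState.create(positions, [MONOMER] * len(positions))


def _ring_frame(n, rng=None, radius=1.0, z_spread=5.0):
    rng = rng or np.random.default_rng(0)
    ang = np.cumsum(rng.uniform(0.2, 0.5, n))
    pos = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.linspace(10, 10 + z_spread, n)]
    )
    return _frame(pos)


class TestLongitudinalSpan:
    def test_coplanar_ring_has_zero_span(self):
        topo = RingTopology(8)
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pos = np.column_stack([np.cos(ang), np.sin(ang), np.full(8, 7.0)])
        assert longitudinal_span(_frame(pos), topo, GEO) == 0.0

    def test_translation_invariance(self):
        topo = RingTopology(12)
        frame = _ring_frame(12)
        r1 = longitudinal_span(frame, topo, GEO)
        shifted = _frame(frame.positions + np.array([0, 0, 3.7]))
        assert longitudinal_span(shifted, topo, GEO) == pytest.approx(r1)

    def test_boundary_straddle_matches_recentered(self):
        """Wrapping a chain across z = 0 must not change its span."""
        topo = RingTopology(12)
        frame = _ring_frame(12, z_spread=4.0)
        r_ref = longitudinal_span(frame, topo, GEO)
        shifted = frame.positions.copy()
        shifted[:, 2] = (shifted[:, 2] + GEO.length - 12.0) % GEO.length
        assert longitudinal_span(_frame(shifted), topo, GEO) == pytest.approx(r_ref)

    def test_self_wrapping_chain_raises(self):
        # a "ring" marching straight around the periodic box cannot unwrap
        topo = RingTopology(40)
        z = np.arange(40) * (GEO.length / 40.0)
        pos = np.column_stack([np.zeros(40), np.zeros(40), z])
        with pytest.raises(UnwrapError):
            longitudinal_span(_frame(pos), topo, GEO)


class TestMeanSqRadial:
    def test_axis_and_wall_limits(self):
        on_axis = _frame([[0, 0, 1], [0, 0, 2]])
        assert mean_sq_radial(on_axis, GEO) == 0.0
        at_wall = _frame([[2.5, 0, 1], [0, -2.5, 2]])
        assert mean_sq_radial(at_wall, GEO) == pytest.approx(1.0)

    def test_uniform_disk_gives_half(self, rng):
        """<r^2> = 1/2 for points uniform over the cross-section."""
        n = 1_000_000
        rho = GEO.radius * np.sqrt(rng.random(n))
        ang = rng.uniform(0, 2 * np.pi, n)
        pos = np.column_stack([rho * np.cos(ang), rho * np.sin(ang), np.zeros(n)])
        assert mean_sq_radial(_frame(pos), GEO) == pytest.approx(0.5, abs=0.002)

    def test_rotation_invariance(self, rng):
        frame = _ring_frame(20, rng)
        v1 = mean_sq_radial(frame, GEO)
        c, s = np.cos(1.1), np.sin(1.1)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        assert mean_sq_radial(
            _frame(frame.positions @ rot.T), GEO
        ) == pytest.approx(v1)


class TestArmCorrelation:
    def _paired_frame(self, left_xy, right_xy, n=10):
        """n monomers per arm; pair (i, N-i) at given transverse offsets."""
        topo = RingTopology(2 * n)
        pos = np.zeros((2 * n, 3))
        for i in range(1, n):
            pos[i, :2] = left_xy
            pos[2 * n - i, :2] = right_xy
        pos[0, :2] = left_xy
        pos[n, :2] = right_xy
        return _frame(pos), topo

    def test_opposite_at_wall_gives_minus_one(self):
        frame, topo = self._paired_frame([2.5, 0.0], [-2.5, 0.0])
        assert arm_correlation(frame, topo, GEO) == pytest.approx(-1.0)

    def test_coincident_at_wall_gives_plus_one(self):
        frame, topo = self._paired_frame([0.0, 2.5], [0.0, 2.5])
        assert arm_correlation(frame, topo, GEO) == pytest.approx(1.0)

    def test_independent_angles_average_to_zero(self, rng):
        """Pairs at fixed radius with independent angles decorrelate."""
        n = 60
        topo = RingTopology(n)
        vals = []
        for _ in range(500):
            ang = rng.uniform(0, 2 * np.pi, n)
            pos = np.column_stack(
                [2.0 * np.cos(ang), 2.0 * np.sin(ang), np.zeros(n)]
            )
            vals.append(arm_correlation(_frame(pos), topo, GEO))
        assert np.mean(vals) == pytest.approx(0.0, abs=0.01)

    def test_arm_swap_invariance(self, rng):
        n = 20
        topo = RingTopology(n)
        frame = _ring_frame(n, rng)
        v = arm_correlation(frame, topo, GEO)
        swapped = frame.positions.copy()
        # reversing ring orientation swaps the two arms
        swapped = swapped[::-1]
        swapped = np.roll(swapped, 1, axis=0)  # keep monomer 0 at the split
        assert arm_correlation(_frame(swapped), topo, GEO) == pytest.approx(v)


class TestProjectedProfile:
    def test_uniform_cylinder_projects_to_semicircle(self, rng):
        """Uniform points in the cylinder -> (2/pi) sqrt(1-x^2) marginal."""
        n = 100_000
        rho = GEO.radius * np.sqrt(rng.random(n))
        ang = rng.uniform(0, 2 * np.pi, n)
        frame = _frame(
            np.column_stack([rho * np.cos(ang), rho * np.sin(ang), np.zeros(n)])
        )
        prof = projected_profile([frame], n_bins=41, geometry=GEO)
        # bin-averaged closed form from the semicircle CDF
        # F(x) = (asin x + x sqrt(1-x^2)) / pi + 1/2
        edges = np.clip(prof.bin_edges, -1.0, 1.0)
        cdf = (np.arcsin(edges) + edges * np.sqrt(1 - edges**2)) / np.pi + 0.5
        width = prof.bin_edges[1] - prof.bin_edges[0]
        p_bin = np.diff(cdf)
        expected = p_bin / width
        # per-bin binomial noise on 2n projected samples
        sd = np.sqrt(p_bin * (1 - p_bin) / (2 * n)) / width
        assert np.all(np.abs(prof.density - expected) <= 3.0 * sd + 1e-9)

    def test_thin_shell_projects_to_two_peaks(self, rng):
        n = 50_000
        ang = rng.uniform(0, 2 * np.pi, n)
        r = 0.8 * GEO.radius
        frame = _frame(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)]))
        prof = projected_profile([frame], n_bins=41, geometry=GEO)
        bimodal, dip = bimodality_indicator(prof)
        assert bimodal
        peaks = prof.bin_centers[prof.density == prof.density.max()]
        assert np.all(np.abs(np.abs(peaks) - 0.8) < 0.1)

    def test_normalized_and_even(self, rng):
        frame = _ring_frame(500, rng, radius=1.5)
        prof = projected_profile([frame], n_bins=20, geometry=GEO)
        width = prof.bin_edges[1] - prof.bin_edges[0]
        assert prof.density.sum() * width == pytest.approx(1.0)
        assert prof.folded_density.sum() * (
            prof.folded_edges[1] - prof.folded_edges[0]
        ) == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            projected_profile([_frame([[0, 0, 0]])], n_bins=3, geometry=GEO)


class TestClassifier:
    def _summary(self, msr, ac):
        return RunSummary(
            R=10.0, R_sem=0.0, mean_sq_r=msr, mean_sq_r_sem=0.0,
            arm_corr=ac, arm_corr_sem=0.0, n_replicates=4,
        )

    @pytest.mark.parametrize(
        "msr,ac,label",
        [
            (0.95, 0.0, "iii"),       # intermingled at the wall
            (0.5, 0.3, "iv"),         # arms collapsed together
            (0.4, -0.1, "i"),         # weak crowding baseline
            (0.9, -0.4, "ii"),        # separated arms at the wall
            (0.4, 0.05, "iii_prime"), # centrally organized, uncorrelated
        ],
    )
    def test_regime_examples(self, msr, ac, label):
        assert classify_state(self._summary(msr, ac)) == label

    @settings(max_examples=200, derandomize=True)
    @given(
        msr=st.floats(min_value=0.0, max_value=1.1),
        ac=st.floats(min_value=-1.0, max_value=1.0),
    )
    def test_total_and_deterministic(self, msr, ac):
        label = classify_state(self._summary(msr, ac))
        assert label in ("i", "ii", "iii", "iii_prime", "iv")
        assert classify_state(self._summary(msr, ac)) == label

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            classify_state(self._summary(float("nan"), 0.0))


class TestEnsembleAverage:
    def test_single_replicate_flagged(self):
        rep = FrameObservables(R=10.0, mean_sq_r=0.4, arm_corr=-0.05)
        summary = ensemble_average([rep])
        assert summary.single_replicate
        assert summary.R == 10.0
        assert summary.R_sem == 0.0

    def test_identical_replicates_zero_sem(self):
        rep = FrameObservables(R=10.0, mean_sq_r=0.4, arm_corr=-0.05)
        summary = ensemble_average([rep, rep, rep])
        assert summary.R_sem == 0.0

    def test_hand_computed_mean_and_sem(self):
        reps = [
            FrameObservables(R=10.0, mean_sq_r=0.4, arm_corr=0.0),
            FrameObservables(R=12.0, mean_sq_r=0.5, arm_corr=-0.1),
            FrameObservables(R=14.0, mean_sq_r=0.6, arm_corr=-0.2),
        ]
        s = ensemble_average(reps, r0=10.0)
        assert s.R == pytest.approx(12.0)
        # SEM = sd(10,12,14)/sqrt(3) = 2/sqrt(3)
        assert s.R_sem == pytest.approx(2.0 / np.sqrt(3.0))
        assert s.R_over_R0 == pytest.approx(1.2)

    def test_replicate_summary_is_frame_mean(self):
        obs = [
            FrameObservables(R=1.0, mean_sq_r=0.2, arm_corr=0.1),
            FrameObservables(R=3.0, mean_sq_r=0.4, arm_corr=-0.3),
        ]
        rep = replicate_summary(obs)
        assert rep.R == 2.0
        assert rep.mean_sq_r == pytest.approx(0.3)
        assert rep.arm_corr == pytest.approx(-0.1)
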