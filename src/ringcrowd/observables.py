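"""Chain-organization observables and the organization-state classifier.

Three scalars characterize the confined ring per frame: the longitudinal
span R (length of the imaginary tube enclosing the ring), the mean-squared
radial position <r^2> of monomers with the transverse position rescaled by
D/2 (0.5 for a cross-sectionally uniform distribution, -> 1 for a
wall-adsorbed chain), and the opposing-arm angular correlation <r_L . r_R>
(-1: arms on opposite sides at the wall; +1: arms collapsed together at the
wall).  A binned projection of the transverse coordinate onto a plane
through the cylinder axis gives the radial density profile whose "M" shape
signals arm separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CylinderGeometry, ParticleState, RingTopology


class UnwrapError(RuntimeError):
    """The bonded path winds the periodic box; the span is ill-defined."""


@dataclass
class FrameObservables:
    R: float
    mean_sq_r: float
    arm_corr: float


@dataclass
class RunSummary:
    """Ensemble means and standard errors over replicates."""

    R: float
    R_sem: float
    mean_sq_r: float
    mean_sq_r_sem: float
    arm_corr: float
    arm_corr_sem: float
    n_replicates: int
    discard_fraction: float = 0.2
    R_over_R0: float | None = None
    single_replicate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class TransverseProfile:
    """Normalized histogram of the rescaled in-plane transverse coordinate."""

    bin_edges: np.ndarray
    density: np.ndarray
    folded_edges: np.ndarray = field(default=None)  # type: ignore[assignment]
    folded_density: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


ORGANIZATION_STATES = ("i", "ii", "iii", "iii_prime", "iv")

#: Classifier thresholds; the regime boundaries are smooth crossovers and
#: model-dependent, so these are deliberately config-exposed.
DEFAULT_THRESHOLDS = {
    "arm_corr_pos": 0.1,
    "arm_corr_neg": -0.2,
    "msr_high": 0.8,
    "msr_low": 0.6,
}


def unwrapped_monomer_positions(
    frame: ParticleState, topology: RingTopology, geometry: CylinderGeometry
) -> np.ndarray:
    """Monomer positions with z unwrapped along the bonded path.

    Walks the ring accumulating minimum-image bond vectors; a nonzero net
    winding after closing the ring means the chain wraps the box and the
    span is undefined.
    """
    pos = frame.monomer_positions().copy()
    if geometry.mode != "periodic":
        return pos
    length = geometry.length
    z = pos[:, 2]
    dz = np.diff(z, append=z[0])
    dz -= length * np.round(dz / length)
    if abs(dz.sum()) > 1e-6 * length:
        raise UnwrapError("ring winds the periodic box; cannot unwrap")
    pos[:, 2] = z[0] + np.concatenate([[0.0], np.cumsum(dz[:-1])])
    return pos


def longitudinal_span(
    frame: ParticleState, topology: RingTopology, geometry: CylinderGeometry
) -> float:
    """R = max(z) - min(z) over monomers after unwrapping along the ring."""
    z = unwrapped_monomer_positions(frame, topology, geometry)[:, 2]
    return float(z.max() - z.min())


def mean_sq_radial(frame: ParticleState, geometry: CylinderGeometry) -> float:
    """<r^2> with the transverse position rescaled by D/2."""
    xy = frame.monomer_positions()[:, :2]
    return float(np.mean(np.sum(xy**2, axis=1)) / geometry.radius**2)


def arm_correlation(
    frame: ParticleState, topology: RingTopology, geometry: CylinderGeometry
) -> float:
    """<r_L . r_R>: angular correlation of the two arms.

    r_L and r_R are averaged independently over the monomers of each arm
    (the two split monomers belong to both arms and are excluded), so the
    statistic is the dot product of the two arm-centroid transverse
    positions, rescaled by D/2.  Equivalent to the mean of r_i . r_j over
    all cross-arm monomer pairs; bounded in [-1, 1].
    """
    if len(topology.arm_pairs) == 0:
        raise ValueError("topology has no arm pairs")
    xy = frame.monomer_positions()[:, :2] / geometry.radius
    left = xy[topology.arm_pairs[:, 0]].mean(axis=0)
    right = xy[topology.arm_pairs[:, 1]].mean(axis=0)
    return float(left @ right)


def frame_observables(
    frame: ParticleState, topology: RingTopology, geometry: CylinderGeometry
) -> FrameObservables:
    return FrameObservables(
        R=longitudinal_span(frame, topology, geometry),
        mean_sq_r=mean_sq_radial(frame, geometry),
        arm_corr=arm_correlation(frame, topology, geometry),
    )


def projected_profile(
    frames, n_bins: int = 41, geometry: CylinderGeometry | None = None
) -> TransverseProfile:
    """Monomer density projected onto a plane containing the cylinder axis.

    By azimuthal symmetry every monomer contributes both its x- and its
    y-coordinate (rescaled by D/2) as samples of the signed in-plane
    transverse coordinate on [-1, 1].  A uniform cross-sectional
    distribution projects to the semicircle density (2/pi) sqrt(1 - x^2);
    a wall-hugging chain projects to two peaks near +-1 (the "M" shape).
    A folded |x| variant is attached as well.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    if geometry is None:
        raise ValueError("geometry is required for rescaling")
    samples = []
    for frame in frames:
        xy = frame.monomer_positions()[:, :2] / geometry.radius
        samples.append(xy[:, 0])
        samples.append(xy[:, 1])
    x = np.concatenate(samples)
    if x.size == 0:
        raise ValueError("no frames given")
    density, edges = np.histogram(x, bins=n_bins, range=(-1.0, 1.0), density=True)
    fdensity, fedges = np.histogram(
        np.abs(x), bins=max(4, n_bins // 2), range=(0.0, 1.0), density=True
    )
    return TransverseProfile(
        bin_edges=edges, density=density, folded_edges=fedges, folded_density=fdensity
    )


def bimodality_indicator(
    profile: TransverseProfile, dip_threshold: float = 0.05
) -> tuple[bool, float]:
    """Operational "M-shape" test on a signed transverse profile.

    True when the global maxima sit off-center and the density at the axis
    dips below the peak by at least ``dip_threshold`` of the peak height.
    Returns (is_bimodal, central_dip_fraction).
    """
    density = profile.density
    centers = profile.bin_centers
    peak = float(density.max())
    if peak <= 0:
        return False, 0.0
    center_idx = np.argmin(np.abs(centers))
    central = float(density[center_idx])
    dip = (peak - central) / peak
    peak_positions = centers[density == peak]
    off_center = bool(np.all(np.abs(peak_positions) > 0.2))
    return bool(off_center and dip >= dip_threshold), dip


def classify_state(
    summary: RunSummary, thresholds: dict | None = None
) -> str:
    """Map (mean_sq_r, arm_corr) to an organization-state label.

    iv: arms collapsed together (positive correlation); ii: arms separated
    against the wall; iii: arms intermingled at the wall; iii': centrally
    organized with uncorrelated arms; i: weak-crowding default.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    msr, ac = summary.mean_sq_r, summary.arm_corr
    if msr is None or ac is None or np.isnan(msr) or np.isnan(ac):
        raise ValueError("summary is missing mean_sq_r or arm_corr")
    if ac > th["arm_corr_pos"]:
        return "iv"
    if ac < th["arm_corr_neg"] and msr > th["msr_high"]:
        return "ii"
    # strictly-inside band: a correlation sitting on the threshold is still
    # "weakly negative", i.e. state (i)
    if abs(ac) < th["arm_corr_pos"] and msr > th["msr_high"]:
        return "iii"
    if abs(ac) < th["arm_corr_pos"] and msr < th["msr_low"]:
        return "iii_prime"
    return "i"


def trajectory_observables(
    traj, topology: RingTopology, geometry: CylinderGeometry, discard_fraction: float = 0.2
):
    """Per-frame observables after discarding the equilibration prefix.

    Returns (steps, list[FrameObservables]) for frames past the discard
    fraction of the run.
    """
    n = traj.n_frames
    start = int(np.ceil(discard_fraction * n))
    if start >= n:
        start = n - 1
    obs = []
    steps = []
    for frame, step in zip(traj.frames[start:], traj.step_indices[start:]):
        obs.append(frame_observables(frame, topology, geometry))
        steps.append(step)
    return steps, obs


def replicate_summary(observables: list[FrameObservables]) -> FrameObservables:
    """Frame-average of one replicate."""
    return FrameObservables(
        R=float(np.mean([o.R for o in observables])),
        mean_sq_r=float(np.mean([o.mean_sq_r for o in observables])),
        arm_corr=float(np.mean([o.arm_corr for o in observables])),
    )


def ensemble_average(
    replicates: list[FrameObservables],
    discard_fraction: float = 0.2,
    r0: float | None = None,
) -> RunSummary:
    """Mean and standard error across replicate frame-averages."""
    if not replicates:
        raise ValueError("need at least one replicate")
    n = len(replicates)
    single = n == 1

    def stats(values):
        mean = float(np.mean(values))
        sem = 0.0 if single else float(np.std(values, ddof=1) / np.sqrt(n))
        return mean, sem

    r_mean, r_sem = stats([r.R for r in replicates])
    m_mean, m_sem = stats([r.mean_sq_r for r in replicates])
    a_mean, a_sem = stats([r.arm_corr for r in replicates])
    return RunSummary(
        R=r_mean, R_sem=r_sem,
        mean_sq_r=m_mean, mean_sq_r_sem=m_sem,
        arm_corr=a_mean, arm_corr_sem=a_sem,
        n_replicates=n,
        discard_fraction=discard_fraction,
        R_over_R0=(r_mean / r0) if r0 else None,
        single_replicate=single,
    )
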