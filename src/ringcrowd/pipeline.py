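"""Run orchestration: single experiments, phi_c x eps13 sweeps, capped-box
profiles, and the resulting organization-state table.

Two scale presets are shipped.  "paper" is the full study protocol (N = 135,
L = 3 R0, 5e7 steps, 16 replicates) and is cluster-scale; "desk" keeps the
physics (same densities, interaction strengths and geometry ratios) at sizes
a single CPU handles: N = 135 for crowder-free runs, N <= 60 with L = 1.5 R0
when crowders are present, 2e6 / 5e5 steps, 4 replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import build_system, equilibrium_span
from .dynamics import integrate
from .observables import (
    RunSummary,
    bimodality_indicator,
    classify_state,
    ensemble_average,
    projected_profile,
    replicate_summary,
    trajectory_observables,
)
from .params import CylinderGeometry, SystemSpec
from .xyzio import write_trajectory

log = logging.getLogger("ringcrowd")

PRESETS = {
    "paper": {
        "n_monomers": 135, "n_steps": 50_000_000, "sample_stride": 1000,
        "replicates": 16, "l_over_r0": 3.0, "n_monomers_crowded": 135,
    },
    "desk": {
        "n_monomers": 135, "n_steps": 2_000_000, "sample_stride": 1000,
        "replicates": 4, "l_over_r0": 3.0, "n_monomers_crowded": 40,
        "n_steps_crowded": 500_000, "l_over_r0_crowded": 1.5,
    },
}


@dataclass
class SweepSpec:
    phi_c_values: list = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35])
    eps13_values: list = field(default_factory=lambda: [1.0, 1.5, 2.0, 2.5, 3.0])
    replicates: int = 16
    n_steps: int = 50_000_000
    n_steps_crowded: int | None = None  # defaults to n_steps
    sample_stride: int = 1000
    scale_preset: str = "paper"
    diameter: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not self.phi_c_values or not self.eps13_values:
            raise ValueError("sweep grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SweepSpec":
        p = PRESETS[name]
        kw = dict(
            replicates=p["replicates"], n_steps=p["n_steps"],
            n_steps_crowded=p.get("n_steps_crowded"),
            sample_stride=p["sample_stride"], scale_preset=name,
        )
        kw.update(overrides)
        return cls(**kw)


def make_spec(
    phi_c: float = 0.0,
    eps13: float = 1.0,
    preset: str = "desk",
    diameter: float = 5.0,
    seed: int = 0,
    n_monomers: int | None = None,
    length: float | None = None,
) -> SystemSpec:
    """SystemSpec for one sweep cell under a scale preset.

    Box length defaults to l_over_r0 * R0(N, D) with R0 from the cached
    lookup; crowded desk cells use the reduced chain and box.
    """
    p = PRESETS[preset]
    crowded = phi_c > 0
    if n_monomers is None:
        n_monomers = p["n_monomers_crowded"] if crowded else p["n_monomers"]
    if length is None:
        ratio = p.get("l_over_r0_crowded", p["l_over_r0"]) if crowded else p["l_over_r0"]
        length = ratio * equilibrium_span(n_monomers, diameter)
    geometry = CylinderGeometry(diameter=diameter, length=length)
    spec = SystemSpec(
        n_monomers=n_monomers, phi_c=phi_c, geometry=geometry, seed=seed
    )
    return spec.with_eps13(eps13)


def run_replicate(
    spec: SystemSpec,
    n_steps: int,
    sample_stride: int,
    seed: int,
    discard_fraction: float = 0.2,
):
    """Build, integrate, and frame-average one replicate.

    Returns (replicate FrameObservables, trajectory, per-frame table).
    """
    rng = np.random.default_rng(seed)
    state, topology = build_system(spec, rng)
    traj = integrate(state, spec, n_steps=n_steps, sample_stride=sample_stride, seed=seed)
    steps, obs = trajectory_observables(traj, topology, spec.geometry, discard_fraction)
    table = pd.DataFrame(
        {
            "step": steps,
            "R": [o.R for o in obs],
            "mean_sq_r": [o.mean_sq_r for o in obs],
            "arm_corr": [o.arm_corr for o in obs],
        }
    )
    return replicate_summary(obs), traj, table


def run_experiment(
    spec: SystemSpec,
    out_dir,
    n_steps: int = 2_000_000,
    sample_stride: int = 1000,
    replicates: int = 4,
    discard_fraction: float = 0.2,
    r0: float | None = None,
    save_trajectory: bool = True,
) -> RunSummary:
    """Replicate ensemble for one parameter point, with a full run bundle.

    Writes observables.csv (per frame, per replicate), summary.json, the
    echoed spec (spec.yaml), and the first replicate's trajectory.  Replicate
    k uses seed spec.seed + k, so reruns are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if r0 is None:
        r0 = equilibrium_span(spec.n_monomers, spec.geometry.diameter)

    reps = []
    tables = []
    for k in range(replicates):
        seed = spec.seed + k
        log.info("replicate %d/%d (seed %d)", k + 1, replicates, seed)
        rep, traj, table = run_replicate(
            spec, n_steps, sample_stride, seed, discard_fraction
        )
        table.insert(0, "replicate", k)
        tables.append(table)
        reps.append(rep)
        if save_trajectory and k == 0:
            write_trajectory(traj, out_dir / "trajectory.xyz", spec.geometry)

    summary = ensemble_average(reps, discard_fraction, r0=r0)
    pd.concat(tables, ignore_index=True).to_csv(out_dir / "observables.csv", index=False)
    spec.to_yaml(out_dir / "spec.yaml")
    payload = summary.to_dict()
    payload["state"] = classify_state(summary)
    payload["n_steps"] = n_steps
    payload["sample_stride"] = sample_stride
    payload["seed"] = spec.seed
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return summary


def run_sweep(sweep: SweepSpec, out_dir) -> pd.DataFrame:
    """phi_c x eps13 grid of replicate ensembles -> organization-state table.

    Each cell writes its own bundle under out_dir/phi<..>_eps<..>; completed
    cells (summary.json present) are skipped on rerun, so an interrupted
    sweep resumes to the identical table.  Per-cell failures are recorded and
    the sweep continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for phi_c in sweep.phi_c_values:
        for eps13 in sweep.eps13_values:
            cell_dir = out_dir / f"phi{phi_c:g}_eps{eps13:g}"
            summary_path = cell_dir / "summary.json"
            row = {"phi_c": phi_c, "eps13": eps13}
            if summary_path.exists():
                with open(summary_path) as fh:
                    payload = json.load(fh)
            else:
                spec = make_spec(
                    phi_c=phi_c, eps13=eps13, preset=sweep.scale_preset,
                    diameter=sweep.diameter,
                    seed=sweep.seed + hash((round(phi_c, 6), round(eps13, 6))) % 100_000,
                )
                n_steps = (
                    (sweep.n_steps_crowded or sweep.n_steps)
                    if phi_c > 0 else sweep.n_steps
                )
                try:
                    run_experiment(
                        spec, cell_dir, n_steps=n_steps,
                        sample_stride=sweep.sample_stride,
                        replicates=sweep.replicates, save_trajectory=False,
                    )
                except Exception as exc:  # noqa: BLE001 - sweep must continue
                    log.error("cell phi=%g eps13=%g failed: %s", phi_c, eps13, exc)
                    row["error"] = str(exc)
                    rows.append(row)
                    continue
                with open(summary_path) as fh:
                    payload = json.load(fh)
            row.update(
                {
                    k: payload[k]
                    for k in (
                        "R", "R_sem", "R_over_R0", "mean_sq_r", "mean_sq_r_sem",
                        "arm_corr", "arm_corr_sem", "state", "n_replicates",
                    )
                }
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "phase_table.csv", index=False)
    return table


def capped_cylinder_experiment(
    diameter: float,
    l_over_r0: float,
    n_monomers: int = 135,
    out_dir=None,
    n_steps: int = 1_000_000,
    sample_stride: int = 1000,
    replicates: int = 2,
    seed: int = 0,
    n_bins: int = 41,
    discard_fraction: float = 0.2,
    wall_model: str = "beads",
) -> dict:
    """Crowder-free ring in a finite capped cylinder: transverse profile.

    The box length is l_over_r0 * R0(N, D); pass numpy.inf for the open
    (periodic, L = 3 R0) limit.  Returns the profile, the two-peak
    indicator, and the central-dip fraction.

    The side wall defaults to the explicit bead-built wall: the wall-layering
    that produces the narrow-channel "M" profile is sensitive to the wall's
    sub-σ corrugation, which the smooth wall lacks.  Caps use the smooth
    axial law in either case.
    """
    r0 = equilibrium_span(n_monomers, diameter)
    if np.isinf(l_over_r0):
        geometry = CylinderGeometry(
            diameter=diameter, length=3.0 * r0, mode="periodic",
            wall_model=wall_model,
        )
    else:
        geometry = CylinderGeometry(
            diameter=diameter, length=l_over_r0 * r0, mode="capped",
            wall_model=wall_model,
        )
    spec = SystemSpec(n_monomers=n_monomers, phi_c=0.0, geometry=geometry, seed=seed)

    frames = []
    for k in range(replicates):
        rng = np.random.default_rng(seed + k)
        state, _ = build_system(spec, rng)
        traj = integrate(
            state, spec, n_steps=n_steps, sample_stride=sample_stride, seed=seed + k
        )
        start = int(np.ceil(discard_fraction * traj.n_frames))
        frames.extend(traj.frames[start:])

    profile = projected_profile(frames, n_bins=n_bins, geometry=geometry)
    bimodal, dip = bimodality_indicator(profile)
    result = {
        "diameter": diameter,
        "l_over_r0": None if np.isinf(l_over_r0) else l_over_r0,
        "profile": profile,
        "bimodal": bimodal,
        "central_dip": dip,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"bin_center": profile.bin_centers, "density": profile.density}
        ).to_csv(out_dir / "profile.csv", index=False)
        pd.DataFrame(
            {
                "bin_center": 0.5 * (profile.folded_edges[:-1] + profile.folded_edges[1:]),
                "density": profile.folded_density,
            }
        ).to_csv(out_dir / "profile_folded.csv", index=False)
        spec.to_yaml(out_dir / "spec.yaml")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(
                {k: v for k, v in result.items() if k != "profile"},
                fh, indent=2, sort_keys=True,
            )
    return result
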