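"""Extended-XYZ trajectory I/O.

Grammar per frame::

    <natoms>
    key=value metadata: Step=<int> Lattice="ax 0 0 0 ay 0 0 0 az" Properties=species:S:1:pos:R:3:image:I:1
    <species> <x> <y> <z> <image>     (natoms lines; species column first)

Species labels are M (monomer), C (crowder), W (wall bead).  The image
column is the longitudinal wrap counter, so unwrapped coordinates are
exactly recoverable.  The lattice is a bounding box carrying D and L; only
z is periodic.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .params import CROWDER, MONOMER, WALL, CylinderGeometry, ParticleState

SPECIES_LABELS = {MONOMER: "M", CROWDER: "C", WALL: "W"}
LABEL_SPECIES = {v: k for k, v in SPECIES_LABELS.items()}


class XYZParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_trajectory(traj: Trajectory, path, geometry: CylinderGeometry) -> None:
    path = Path(path)
    d, length = geometry.diameter, geometry.length
    with open(path, "w") as fh:
        for frame, step in zip(traj.frames, traj.step_indices):
            fh.write(f"{frame.n}\n")
            fh.write(
                f'Step={step} Stride={traj.sample_stride} Seed={traj.rng_seed} '
                f'Lattice="{d} 0 0 0 {d} 0 0 0 {length}" Mode={geometry.mode} '
                f'Properties=species:S:1:pos:R:3:image:I:1\n'
            )
            for i in range(frame.n):
                x, y, z = frame.positions[i]
                fh.write(
                    f"{SPECIES_LABELS[int(frame.species[i])]} "
                    f"{x:.10f} {y:.10f} {z:.10f} {int(frame.images[i])}\n"
                )


_KV = re.compile(r'(\w+)=("(?:[^"]*)"|\S+)')


def read_trajectory(path) -> tuple[Trajectory, CylinderGeometry]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError("empty trajectory file", 1)
    traj = None
    geometry = None
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError("expected atom count", ln + 1) from None
        if natoms <= 0:
            raise XYZParseError("frame must contain at least one atom", ln + 1)
        if ln + 1 >= len(lines):
            raise XYZParseError("missing comment line", ln + 2)
        meta = {k: v.strip('"') for k, v in _KV.findall(lines[ln + 1])}
        step = int(meta.get("Step", 0))
        if geometry is None:
            try:
                lattice = [float(v) for v in meta["Lattice"].split()]
                geometry = CylinderGeometry(
                    diameter=lattice[0], length=lattice[8],
                    mode=meta.get("Mode", "periodic"),
                )
            except (KeyError, IndexError, ValueError) as exc:
                raise XYZParseError(f"bad or missing Lattice: {exc}", ln + 2) from None
        if traj is None:
            traj = Trajectory(
                sample_stride=int(meta.get("Stride", 1000)),
                rng_seed=int(meta.get("Seed", 0)),
            )
        if ln + 2 + natoms > len(lines):
            raise XYZParseError("truncated frame", len(lines))
        pos = np.empty((natoms, 3))
        species = np.empty(natoms, dtype=np.int64)
        images = np.zeros(natoms, dtype=np.int64)
        for k in range(natoms):
            row = lines[ln + 2 + k].split()
            if len(row) < 4:
                raise XYZParseError("expected: species x y z [image]", ln + 3 + k)
            if row[0] not in LABEL_SPECIES:
                raise XYZParseError(f"unknown species label {row[0]!r}", ln + 3 + k)
            species[k] = LABEL_SPECIES[row[0]]
            pos[k] = [float(row[1]), float(row[2]), float(row[3])]
            if len(row) > 4:
                images[k] = int(row[4])
        state = ParticleState.create(pos, species)
        state.images = images
        traj.append(state, step)
        ln += 2 + natoms
    if traj is None:
        raise XYZParseError("no frames found", 1)
    return traj, geometry
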