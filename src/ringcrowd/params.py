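"""Physical parameter types for the confined ring-polymer model.

All quantities are in reduced units: lengths in the monomer diameter ``a``
(= the WCA ``sigma`` of a monomer pair), energies in ``eps`` (the
monomer-monomer WCA strength, with k_B T = eps at the working temperature),
and times in ``tau0 = sigma * sqrt(m / eps)``.

Species are indexed 0 = monomer, 1 = crowder, 2 = wall bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import yaml

MONOMER = 0
CROWDER = 1
WALL = 2

#: WCA cutoff factor: the potential minimum, 2^(1/6).
WCA_CUT = 2.0 ** (1.0 / 6.0)


class ConfigError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class InteractionTable:
    """Symmetric 3x3 tables of WCA diameters and strengths.

    sigma[0][0] = a (monomer), sigma[1][1] = a_c (crowder), wall beads share
    the monomer diameter; cross terms follow the additive mixing rule
    sigma_ij = (sigma_ii + sigma_jj) / 2.  epsilon[0][0] = 1 by definition of
    the energy unit; the monomer-wall strength eps13 is the experimentally
    varied knob; every other entry defaults to 1.
    """

    sigma: np.ndarray
    epsilon: np.ndarray

    @classmethod
    def create(cls, a: float = 1.0, a_c: float = 0.3, eps13: float = 1.0) -> "InteractionTable":
        d = np.array([a, a_c, a])
        sigma = 0.5 * (d[:, None] + d[None, :])
        epsilon = np.ones((3, 3))
        epsilon[MONOMER, WALL] = epsilon[WALL, MONOMER] = eps13
        return cls(sigma=sigma, epsilon=epsilon)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.sigma.shape != (3, 3) or self.epsilon.shape != (3, 3):
            raise ConfigError("interaction tables must be 3x3")
        if not (np.allclose(self.sigma, self.sigma.T) and np.allclose(self.epsilon, self.epsilon.T)):
            raise ConfigError("interaction tables must be symmetric")
        if np.any(self.sigma <= 0) or np.any(self.epsilon <= 0):
            raise ConfigError("interaction parameters must be positive")
        mixed = 0.5 * (self.sigma[0, 0] + self.sigma[1, 1])
        if not np.isclose(self.sigma[0, 1], mixed):
            raise ConfigError("sigma12 must equal (sigma11 + sigma22)/2")

    @property
    def eps13(self) -> float:
        return float(self.epsilon[MONOMER, WALL])

    def cutoff(self, i: int, j: int) -> float:
        return WCA_CUT * float(self.sigma[i, j])


@dataclass
class BondParams:
    """FENE bond constants (Kremer-Grest defaults)."""

    k: float = 30.0          # eps / sigma^2
    r0: float = 1.5          # sigma; maximum extension

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError("FENE k must be positive")
        if self.r0 <= WCA_CUT:
            raise ConfigError("FENE r0 must exceed the WCA minimum 2^(1/6) sigma")


@dataclass
class DynamicsParams:
    """Langevin integration constants.

    dt is in tau0, gamma in 1/tau0, temperature in eps/k_B.  mass is
    per-species in units of the monomer mass m; equilibrium averages do not
    depend on it, so all species default to 1.
    """

    dt: float = 0.002
    gamma: float = 0.1
    temperature: float = 1.0
    mass: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.gamma < 0:
            raise ConfigError("gamma must be non-negative")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        self.mass = tuple(float(m) for m in self.mass)
        if any(m <= 0 for m in self.mass):
            raise ConfigError("masses must be positive")


@dataclass
class CylinderGeometry:
    """Confining cylinder.

    ``diameter`` bounds particle *centers*: the smooth wall applies the WCA
    law to the gap d = (D/2 + sigma_i3) - rho, so pair contact (U = eps at
    d = sigma_i3) happens exactly when a center reaches rho = D/2.  In
    ``capped`` mode the same law acts on the axial gaps at z = 0 and z = L;
    in ``periodic`` mode the longitudinal direction wraps with period L.
    ``beads`` wall mode replaces the smooth radial law by an explicit
    cylindrical lattice of wall beads (fidelity-check option).
    """

    diameter: float = 5.0
    length: float = 78.0
    mode: Literal["periodic", "capped"] = "periodic"
    wall_model: Literal["smooth", "beads"] = "smooth"
    wall_bead_spacing: float = 1.0   # only used by the beads wall

    def __post_init__(self) -> None:
        if self.diameter <= 2.0:
            raise ConfigError("cylinder diameter must exceed 2a")
        if self.length <= 0:
            raise ConfigError("cylinder length must be positive")
        if self.mode not in ("periodic", "capped"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.wall_model not in ("smooth", "beads"):
            raise ConfigError(f"unknown wall model {self.wall_model!r}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class SystemSpec:
    """Complete description of one simulated system."""

    n_monomers: int = 135
    monomer_diameter: float = 1.0
    crowder_diameter: float = 0.3
    phi_c: float = 0.0
    interactions: InteractionTable = None  # type: ignore[assignment]
    bonds: BondParams = field(default_factory=BondParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 3:
            raise ConfigError("a ring needs at least 3 monomers")
        if not 0.0 <= self.phi_c <= 0.4:
            raise ConfigError("phi_c must lie in [0, 0.4]")
        if self.crowder_diameter > self.monomer_diameter:
            raise ConfigError("crowders must not be larger than monomers")
        if self.interactions is None:
            self.interactions = InteractionTable.create(
                a=self.monomer_diameter, a_c=self.crowder_diameter
            )

    def with_eps13(self, eps13: float) -> "SystemSpec":
        table = InteractionTable.create(
            a=self.monomer_diameter, a_c=self.crowder_diameter, eps13=eps13
        )
        return SystemSpec(
            n_monomers=self.n_monomers,
            monomer_diameter=self.monomer_diameter,
            crowder_diameter=self.crowder_diameter,
            phi_c=self.phi_c,
            interactions=table,
            bonds=self.bonds,
            dynamics=self.dynamics,
            geometry=self.geometry,
            seed=self.seed,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interactions"] = {
            "sigma": self.interactions.sigma.tolist(),
            "epsilon": self.interactions.epsilon.tolist(),
        }
        d["dynamics"]["mass"] = list(self.dynamics.mass)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        d = dict(d)
        if "interactions" in d and d["interactions"] is not None:
            d["interactions"] = InteractionTable(
                sigma=np.array(d["interactions"]["sigma"]),
                epsilon=np.array(d["interactions"]["epsilon"]),
            )
        if "bonds" in d:
            d["bonds"] = BondParams(**d["bonds"])
        if "dynamics" in d:
            dyn = dict(d["dynamics"])
            if "mass" in dyn:
                dyn["mass"] = tuple(dyn["mass"])
            d["dynamics"] = DynamicsParams(**dyn)
        if "geometry" in d:
            d["geometry"] = CylinderGeometry(**d["geometry"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SystemSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RingTopology:
    """Ring bond list and opposing-arm pairing.

    The ring is split into two arms at monomer 0 and monomer floor(N/2);
    monomer i on the left arm (1 <= i <= floor(N/2) - 1) pairs with monomer
    N - i on the right arm.  The two split monomers sit on both arms at once
    and are excluded from the pairing.
    """

    n: int
    bonds: np.ndarray = field(init=False)
    arm_pairs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = int(self.n)
        if n < 3:
            raise ConfigError("a ring needs at least 3 monomers")
        self.bonds = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
        half = n // 2
        left = np.arange(1, half)
        self.arm_pairs = np.column_stack([left, n - left])


@dataclass
class ParticleState:
    """Positions, velocities, species labels and longitudinal wrap counters."""

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    images: np.ndarray

    @classmethod
    def create(cls, positions, species, velocities=None) -> "ParticleState":
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        species = np.asarray(species, dtype=np.int64)
        if velocities is None:
            velocities = np.zeros((n, 3))
        return cls(
            positions=positions,
            velocities=np.asarray(velocities, dtype=float),
            species=species,
            images=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_monomers(self) -> int:
        return int(np.sum(self.species == MONOMER))

    def monomer_positions(self) -> np.ndarray:
        return self.positions[self.species == MONOMER]

    def unwrapped_z(self, length: float) -> np.ndarray:
        return self.positions[:, 2] + self.images * length

    def copy(self) -> "ParticleState":
        return ParticleState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            images=self.images.copy(),
        )
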