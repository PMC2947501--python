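"""Minimal bead-spring MD engine: NVE velocity-Verlet plus Langevin equilibration.

The engine stands in, at desk scale, for the full atomistic engine a pulling
protocol would normally drive.  It supports three bonded terms — harmonic,
Morse, and an irreversibly breakable harmonic whose rupture force k·r_break is
known in closed form — and nothing else (no nonbonded terms, no constraints).
Breakable bonds give synthetic systems an exact ground-truth rupture force
against which the protocol's force estimates can be validated.

Integration conventions
-----------------------
* Positions Å, velocities Å/ps, masses Da, time ps; API durations/timesteps
  are stated in fs (the natural scale for a 1 fs step) and converted once.
* ``nve_step``/``run_nve``/``langevin_equilibrate`` advance the system
  **in place** and return it; callers that need the original state should
  ``system.copy()`` first.  Higher-level drivers (``run_puff``) copy for you.
* The Langevin integrator is the BAOAB splitting; with a fixed seed it is
  bit-reproducible on a given platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    IntegrationBlowupError,
    InvalidArgumentError,
    SingularGeometryError,
)
from .units import BOLTZMANN, FORCE_PN_PER_DA_ACCEL

__all__ = [
    "HarmonicBond",
    "MorseBond",
    "BreakableBond",
    "ParticleSystem",
    "EquilibrationParams",
    "EnergyTrace",
    "compute_forces",
    "nve_step",
    "run_nve",
    "langevin_equilibrate",
    "max_restoring_force",
]

_R_SINGULAR = 1e-10  # Å; below this the bond direction is undefined


@dataclass
class HarmonicBond:
    """V(r) = ½ k (r − r0)²  — unbreakable; k in Da/ps², r0 in Å."""

    i: int
    j: int
    k: float
    r0: float

    def __post_init__(self) -> None:
        _check_bond(self.i, self.j, k=self.k, r0=self.r0)


@dataclass
class MorseBond:
    """V(r) = D (1 − exp(−a(r − r0)))²  — D in Da·Å²/ps², a in 1/Å, r0 in Å.

    The restoring force peaks at the inflection point with magnitude a·D/2.
    """

    i: int
    j: int
    depth: float
    width: float
    r0: float

    def __post_init__(self) -> None:
        _check_bond(self.i, self.j, depth=self.depth, width=self.width, r0=self.r0)


@dataclass
class BreakableBond:
    """Harmonic up to extension ``r_break``, then irreversibly broken.

    Rupture is triggered the first time the instantaneous extension
    r − r0 exceeds ``r_break`` during a force evaluation; afterwards the
    bond exerts zero force for the rest of the run.  The rupture force is
    exactly k·r_break (in internal units).
    """

    i: int
    j: int
    k: float
    r0: float
    r_break: float
    intact: bool = True

    def __post_init__(self) -> None:
        _check_bond(self.i, self.j, k=self.k, r0=self.r0, r_break=self.r_break)


Bond = HarmonicBond | MorseBond | BreakableBond


def _check_bond(i: int, j: int, **params: float) -> None:
    if i == j:
        raise InvalidArgumentError(f"bond endpoints must differ, got i = j = {i}")
    for name, value in params.items():
        if value <= 0:
            raise InvalidArgumentError(f"bond parameter {name} must be > 0, got {value}")


@dataclass
class ParticleSystem:
    """The simulated state: masses, positions, velocities, time and bonds."""

    masses: np.ndarray  # (n,) Da
    positions: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/ps
    time: float = 0.0  # ps
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        n = self.masses.shape[0]
        if n < 2:
            raise InvalidArgumentError("a ParticleSystem needs at least 2 particles")
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise InvalidArgumentError(
                "positions and velocities must both have shape (n, 3)"
            )
        if np.any(self.masses <= 0):
            raise InvalidArgumentError("masses must be strictly positive")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise InvalidArgumentError("positions and velocities must be finite")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise InvalidArgumentError(f"bond ({b.i}, {b.j}) references a missing particle")

    @property
    def n(self) -> int:
        return int(self.masses.shape[0])

    def copy(self) -> "ParticleSystem":
        import copy as _copy

        return ParticleSystem(
            masses=self.masses.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            time=self.time,
            bonds=[_copy.copy(b) for b in self.bonds],
        )


@dataclass
class EquilibrationParams:
    """Langevin equilibration settings.

    ``gamma`` is the friction coefficient in 1/ps (the conventional MD input
    unit).  ``snapshot_times`` asks for copies of the state at those times,
    usable as independent starting points for repeat pulling runs.
    """

    temperature: float = 300.0  # K
    duration: float = 100.0  # ps
    gamma: float = 5.0  # 1/ps
    timestep: float = 1.0  # fs
    seed: int = 0
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be > 0")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be > 0")
        if self.timestep <= 0:
            raise InvalidArgumentError("timestep must be > 0")
        for t in self.snapshot_times:
            if not (0.0 <= t <= self.duration):
                raise InvalidArgumentError(
                    f"snapshot time {t} outside [0, {self.duration}] ps"
                )


@dataclass
class EnergyTrace:
    """Per-step energy bookkeeping from an NVE segment (index 0 = initial state)."""

    times: np.ndarray  # ps
    kinetic: np.ndarray  # Da·Å²/ps²
    potential: np.ndarray  # Da·Å²/ps²

    @property
    def total(self) -> np.ndarray:
        return self.kinetic + self.potential


def _bond_force_scalar(bond: Bond, r: float) -> float:
    """dV/dr for an intact bond at separation r (Da·Å/ps²)."""
    if isinstance(bond, HarmonicBond):
        return bond.k * (r - bond.r0)
    if isinstance(bond, MorseBond):
        e = math.exp(-bond.width * (r - bond.r0))
        return 2.0 * bond.width * bond.depth * (1.0 - e) * e
    if isinstance(bond, BreakableBond):
        return bond.k * (r - bond.r0)
    raise InvalidArgumentError(f"unknown bond type {type(bond).__name__}")


def _bond_energy(bond: Bond, r: float) -> float:
    if isinstance(bond, (HarmonicBond, BreakableBond)):
        d = r - bond.r0
        return 0.5 * bond.k * d * d
    e = 1.0 - math.exp(-bond.width * (r - bond.r0))
    return bond.depth * e * e


def compute_forces(system: ParticleSystem) -> tuple[np.ndarray, float]:
    """Analytic forces (Da·Å/ps²) and total potential energy (Da·Å²/ps²).

    Breakable bonds whose instantaneous extension exceeds their rupture
    threshold are flipped to broken here (irreversibly) and contribute
    nothing from that evaluation onwards.

    Raises
    ------
    SingularGeometryError
        If two bonded particles coincide (undefined bond direction).
    """
    forces = np.zeros_like(system.positions)
    potential = 0.0
    pos = system.positions
    for bond in system.bonds:
        if isinstance(bond, BreakableBond) and not bond.intact:
            continue
        d = pos[bond.j] - pos[bond.i]
        r = float(np.sqrt(d @ d))
        if r < _R_SINGULAR:
            raise SingularGeometryError(
                f"particles {bond.i} and {bond.j} coincide (r = {r:.3g} Å)"
            )
        if isinstance(bond, BreakableBond) and (r - bond.r0) > bond.r_break:
            bond.intact = False
            continue
        dvdr = _bond_force_scalar(bond, r)
        fvec = (-dvdr / r) * d  # force on particle j
        forces[bond.j] += fvec
        forces[bond.i] -= fvec
        potential += _bond_energy(bond, r)
    return forces, potential


def _check_finite(forces: np.ndarray) -> None:
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0][0])
        raise IntegrationBlowupError(
            f"non-finite force on particle {bad}", particle=bad
        )


def nve_step(system: ParticleSystem, dt_fs: float = 1.0) -> ParticleSystem:
    """One velocity-Verlet step of ``dt_fs`` femtoseconds, in place."""
    if dt_fs <= 0:
        raise InvalidArgumentError("dt must be > 0")
    dt = dt_fs * 1e-3
    inv_m = 1.0 / system.masses[:, None]
    f0, _ = compute_forces(system)
    _check_finite(f0)
    a0 = f0 * inv_m
    system.positions += system.velocities * dt + 0.5 * a0 * dt * dt
    f1, _ = compute_forces(system)
    _check_finite(f1)
    system.velocities += 0.5 * (a0 + f1 * inv_m) * dt
    system.time += dt
    return system


def run_nve(
    system: ParticleSystem, duration_fs: float, dt_fs: float = 1.0
) -> tuple[ParticleSystem, EnergyTrace]:
    """Constant-energy segment of ``duration_fs`` at timestep ``dt_fs``, in place.

    ``duration_fs`` must be a non-negative integer multiple of ``dt_fs``;
    a duration of 0 returns the system unchanged with a single-entry trace.
    The force at the end of one step is reused at the start of the next, so
    the cost is one force evaluation per step.
    """
    if dt_fs <= 0:
        raise InvalidArgumentError("dt must be > 0")
    n_steps = int(round(duration_fs / dt_fs))
    if abs(n_steps * dt_fs - duration_fs) > 1e-9 * max(1.0, dt_fs) or duration_fs < 0:
        raise InvalidArgumentError(
            f"duration {duration_fs} fs is not a multiple of dt {dt_fs} fs"
        )
    dt = dt_fs * 1e-3
    masses = system.masses
    inv_m = 1.0 / masses[:, None]
    pos, vel = system.positions, system.velocities

    times = np.empty(n_steps + 1)
    kinetic = np.empty(n_steps + 1)
    potential = np.empty(n_steps + 1)

    f, pe = compute_forces(system)
    _check_finite(f)
    times[0] = system.time
    kinetic[0] = 0.5 * float(np.sum(masses * np.sum(vel * vel, axis=1)))
    potential[0] = pe
    for step in range(1, n_steps + 1):
        a = f * inv_m
        pos += vel * dt + 0.5 * a * dt * dt
        f, pe = compute_forces(system)
        _check_finite(f)
        vel += 0.5 * (a + f * inv_m) * dt
        system.time += dt
        times[step] = system.time
        kinetic[step] = 0.5 * float(np.sum(masses * np.sum(vel * vel, axis=1)))
        potential[step] = pe
    return system, EnergyTrace(times=times, kinetic=kinetic, potential=potential)


def langevin_equilibrate(
    system: ParticleSystem, params: EquilibrationParams
) -> tuple[ParticleSystem, list[ParticleSystem]]:
    """Equilibrate with a BAOAB Langevin integrator, in place.

    Returns the final system and copies of the state at each requested
    snapshot time (in the order given), usable as repeat starting points.
    A snapshot time of 0 captures the initial state.  Identical seeds give
    identical trajectories and snapshots.
    """
    dt = params.timestep * 1e-3
    n_steps = int(round(params.duration / dt))
    snap_steps = [int(round(t / dt)) for t in params.snapshot_times]
    rng = np.random.default_rng(params.seed)

    masses = system.masses
    inv_m = 1.0 / masses[:, None]
    c1 = math.exp(-params.gamma * dt)
    # thermal velocity scale per particle; zero-temperature limit damps to rest
    sigma = np.sqrt(BOLTZMANN * params.temperature / masses)[:, None]
    c2 = math.sqrt(1.0 - c1 * c1)

    snapshots: dict[int, ParticleSystem] = {}
    if 0 in snap_steps:
        snapshots[0] = system.copy()

    pos, vel = system.positions, system.velocities
    f, _ = compute_forces(system)
    _check_finite(f)
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * f * inv_m  # B
        pos += 0.5 * dt * vel  # A
        noise = rng.standard_normal(size=vel.shape)
        vel *= c1  # O
        vel += c2 * sigma * noise
        pos += 0.5 * dt * vel  # A
        f, _ = compute_forces(system)
        _check_finite(f)
        vel += 0.5 * dt * f * inv_m  # B
        system.time += dt
        if step in snap_steps:
            snapshots[step] = system.copy()
    return system, [snapshots[s] for s in snap_steps]


def max_restoring_force(bond: Bond) -> float:
    """Maximum restoring force |dV/dr| over r ≥ r0, in pN.

    Closed forms: a·D/2 for a Morse bond (at its inflection point),
    k·r_break for a breakable-harmonic bond.  An unbreakable harmonic
    bond has no maximum and returns ``math.inf``.
    """
    if isinstance(bond, HarmonicBond):
        return math.inf
    if isinstance(bond, BreakableBond):
        return bond.k * bond.r_break * FORCE_PN_PER_DA_ACCEL
    if isinstance(bond, MorseBond):
        return 0.5 * bond.width * bond.depth * FORCE_PN_PER_DA_ACCEL
    raise InvalidArgumentError(f"unknown bond type {type(bond).__name__}")
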