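"""The constant-momentum (PUFF) pulling controller and an SMD baseline.

The protocol alternates instantaneous velocity resets with short unmodified
NVE segments.  Each cycle: (1) the pre-pulse relative axis velocity and anchor
separation are recorded; (2) system velocities are rescaled to the thermostat
temperature (centre-of-mass motion removed first); (3) the relative velocity
of the two anchor groups along their centre-of-mass axis is reset to the
target value by adding ±½·ΔV to every atom of the two groups; (4) the system
relaxes for one pulse length of constant-energy dynamics.

Because the reset is instantaneous, the injected momentum change
ΔP = M·ΔV (M the combined anchor mass) is booked as the applied force
F = M·ΔV, with M expressed in pN·ps²/Å.  The reset caps the applied force at
2·M·V_target: a system reflecting off a barrier arrives at the pulse boundary
with axis velocity near −V_target, so ΔV ≤ 2·V_target.

Ordering note: velocities are rescaled *before* the impulse, so the thermostat
never distorts the freshly reset pulling velocity, while the *recorded*
pre-pulse velocity is sampled before the rescale so that it reflects the raw
dynamical response of the previous relaxation.  ΔV (and hence the booked
force) is computed from the post-rescale velocity — that is the change the
controller actually applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import ParticleSystem, run_nve
from .errors import (
    DegenerateAxisError,
    IntegrationBlowupError,
    InvalidArgumentError,
)
from .units import kinetic_temperature, mass_to_force_units

__all__ = [
    "AnchorSpec",
    "PuffParams",
    "PulseRecord",
    "TrajectoryResult",
    "SmdResult",
    "pulling_axis",
    "relative_axis_velocity",
    "apply_impulse",
    "rescale_to_temperature",
    "run_puff",
    "theoretical_max_force",
    "per_pulse_displacement",
    "run_smd_baseline",
]

_AXIS_SINGULAR = 1e-8  # Å


@dataclass(frozen=True)
class AnchorSpec:
    """Two disjoint particle groups defining the pulling axis.

    The combined pulling mass M = M1 + M2 (both groups summed) enters the
    force bookkeeping F = M·ΔV.
    """

    group1: tuple[int, ...]
    group2: tuple[int, ...]

    def __post_init__(self) -> None:
        g1, g2 = tuple(self.group1), tuple(self.group2)
        object.__setattr__(self, "group1", g1)
        object.__setattr__(self, "group2", g2)
        if not g1 or not g2:
            raise InvalidArgumentError("anchor groups must be non-empty")
        if set(g1) & set(g2):
            raise InvalidArgumentError("anchor groups must be disjoint")
        if len(set(g1)) != len(g1) or len(set(g2)) != len(g2):
            raise InvalidArgumentError("anchor groups must not repeat indices")

    def group_masses(self, system: ParticleSystem) -> tuple[float, float]:
        m = system.masses
        return float(m[list(self.group1)].sum()), float(m[list(self.group2)].sum())

    def pulling_mass(self, system: ParticleSystem) -> float:
        """Combined anchor mass M1 + M2 in Da."""
        m1, m2 = self.group_masses(system)
        return m1 + m2


@dataclass
class PuffParams:
    """Controller settings.

    ``rescale_temp=None`` disables the inter-pulse thermostat entirely —
    useful when the protocol's bookkeeping is being examined in isolation
    (e.g. a free pair, where rescaling would renormalise the pulling
    velocity itself).  ``remove_com_drift`` optionally subtracts the net
    momentum the ±½·ΔV scheme injects when the two anchor groups have
    unequal masses (off by default: the faithful scheme applies equal and
    opposite *accelerations*, not impulses).
    """

    v_target: float  # Å/ps
    n_pulses: int
    pulse_fs: float = 100.0
    dt_fs: float = 1.0
    rescale_temp: float | None = 300.0
    seed: int = 0
    remove_com_drift: bool = False

    def __post_init__(self) -> None:
        if self.v_target < 0:
            raise InvalidArgumentError("v_target must be >= 0")
        if self.n_pulses < 0:
            raise InvalidArgumentError("n_pulses must be >= 0")
        if self.dt_fs <= 0 or self.pulse_fs <= 0:
            raise InvalidArgumentError("pulse_fs and dt_fs must be > 0")
        n = round(self.pulse_fs / self.dt_fs)
        if abs(n * self.dt_fs - self.pulse_fs) > 1e-9:
            raise InvalidArgumentError("pulse_fs must be a multiple of dt_fs")
        if self.rescale_temp is not None and self.rescale_temp < 0:
            raise InvalidArgumentError("rescale_temp must be >= 0 or None")


@dataclass
class PulseRecord:
    """Per-pulse log entry.

    ``pre_pulse_velocity`` is the relative axis velocity at the end of the
    preceding relaxation (before thermostatting); ``delta_v`` is the reset
    actually applied; ``applied_force`` = mass_to_force_units(M)·delta_v, pN.
    """

    index: int
    time_ps: float
    pre_pulse_velocity: float
    delta_v: float
    applied_force: float
    separation: float
    axis: np.ndarray


@dataclass
class TrajectoryResult:
    """Output of a constant-momentum run."""

    params: PuffParams
    anchors: AnchorSpec
    pulses: list[PulseRecord]
    final_system: ParticleSystem
    snapshots: list[ParticleSystem] = field(default_factory=list)
    error: str | None = None  # set if the run aborted mid-way

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_ps for p in self.pulses])

    @property
    def separations(self) -> np.ndarray:
        return np.array([p.separation for p in self.pulses])

    @property
    def pre_pulse_velocities(self) -> np.ndarray:
        return np.array([p.pre_pulse_velocity for p in self.pulses])

    @property
    def applied_forces(self) -> np.ndarray:
        return np.array([p.applied_force for p in self.pulses])

    def pulling_mass(self) -> float:
        return self.anchors.pulling_mass(self.final_system)


def _group_com(system: ParticleSystem, group: tuple[int, ...], what: np.ndarray) -> np.ndarray:
    idx = list(group)
    m = system.masses[idx]
    return m @ what[idx] / m.sum()


def pulling_axis(system: ParticleSystem, anchors: AnchorSpec) -> tuple[np.ndarray, float]:
    """Unit vector from group1's COM to group2's COM, and their separation in Å."""
    c1 = _group_com(system, anchors.group1, system.positions)
    c2 = _group_com(system, anchors.group2, system.positions)
    d = c2 - c1
    sep = float(np.linalg.norm(d))
    if sep < _AXIS_SINGULAR:
        raise DegenerateAxisError("anchor-group centres of mass coincide")
    return d / sep, sep


def relative_axis_velocity(system: ParticleSystem, anchors: AnchorSpec) -> float:
    """(V2 − V1)·N12 in Å/ps; positive when the groups are separating."""
    axis, _ = pulling_axis(system, anchors)
    v1 = _group_com(system, anchors.group1, system.velocities)
    v2 = _group_com(system, anchors.group2, system.velocities)
    return float((v2 - v1) @ axis)


def apply_impulse(
    system: ParticleSystem,
    anchors: AnchorSpec,
    v_target: float,
    remove_com_drift: bool = False,
) -> PulseRecord:
    """Reset the relative axis velocity to ``v_target`` in place.

    Every atom of group2 gains +½·ΔV·N12 and every atom of group1 gains
    −½·ΔV·N12, where ΔV = v_target − V12,axis.  Immediately afterwards the
    relative axis velocity equals ``v_target`` exactly (to rounding).  The
    returned record carries the velocity found, the reset applied and the
    booked force; ``index``/``time_ps`` are filled by the caller
    (time_ps defaults to the system clock).
    """
    if v_target < 0:
        raise InvalidArgumentError("v_target must be >= 0")
    axis, sep = pulling_axis(system, anchors)
    v12 = relative_axis_velocity(system, anchors)
    delta_v = v_target - v12
    kick = 0.5 * delta_v * axis
    g1, g2 = list(anchors.group1), list(anchors.group2)
    system.velocities[g2] += kick
    system.velocities[g1] -= kick
    if remove_com_drift:
        m1, m2 = anchors.group_masses(system)
        net = 0.5 * delta_v * (m2 - m1) * axis  # injected momentum, Da·Å/ps
        system.velocities -= net / system.masses.sum()
    m = anchors.pulling_mass(system)
    force = mass_to_force_units(m) * delta_v
    return PulseRecord(
        index=-1,
        time_ps=system.time,
        pre_pulse_velocity=v12,
        delta_v=delta_v,
        applied_force=force,
        separation=sep,
        axis=axis,
    )


def rescale_to_temperature(system: ParticleSystem, temp_K: float) -> float:
    """Scale all velocities so the COM-free kinetic temperature equals ``temp_K``.

    The mass-weighted COM velocity is removed first (and stays removed), so
    drift injected by earlier impulses is not counted as heat.  If the system
    has zero kinetic energy and ``temp_K`` > 0 the rescale is impossible; a
    warning is issued and the system is left untouched.  Returns the scale
    factor applied (1.0 for the no-op cases).
    """
    if temp_K < 0:
        raise InvalidArgumentError("temperature must be >= 0")
    com_v = system.masses @ system.velocities / system.masses.sum()
    system.velocities -= com_v
    t_now = kinetic_temperature(system.velocities, system.masses, remove_com=False)
    # COM already removed; use the 3N-3 dof count by hand
    t_now *= (3 * system.n) / (3 * system.n - 3)
    if t_now == 0.0:
        if temp_K > 0.0:
            warnings.warn(
                "cannot rescale a system with zero kinetic energy; velocities unchanged",
                stacklevel=2,
            )
        return 1.0
    factor = float(np.sqrt(temp_K / t_now))
    system.velocities *= factor
    return factor


def run_puff(
    system: ParticleSystem,
    anchors: AnchorSpec,
    params: PuffParams,
    snapshot_every: int | None = None,
) -> TrajectoryResult:
    """Run the full pulse/relax cycle for ``params.n_pulses`` pulses.

    The input system is copied; the caller's state is untouched.  Each cycle
    records the pre-pulse state, thermostats (unless disabled), resets the
    pulling velocity, then relaxes for ``pulse_fs`` of NVE dynamics.  If the
    integrator blows up, the partial trajectory is returned with ``error``
    set instead of raising.
    """
    work = system.copy()
    pulses: list[PulseRecord] = []
    snapshots: list[ParticleSystem] = []
    error: str | None = None
    for k in range(params.n_pulses):
        try:
            if params.rescale_temp is not None:
                pre_v = relative_axis_velocity(work, anchors)
                rescale_to_temperature(work, params.rescale_temp)
                record = apply_impulse(
                    work, anchors, params.v_target, params.remove_com_drift
                )
                record.pre_pulse_velocity = pre_v
            else:
                record = apply_impulse(
                    work, anchors, params.v_target, params.remove_com_drift
                )
            record.index = k
            record.time_ps = work.time
            pulses.append(record)
            run_nve(work, params.pulse_fs, params.dt_fs)
        except IntegrationBlowupError as exc:
            error = str(exc)
            break
        if snapshot_every and (k + 1) % snapshot_every == 0:
            snapshots.append(work.copy())
    return TrajectoryResult(
        params=params,
        anchors=anchors,
        pulses=pulses,
        final_system=work,
        snapshots=snapshots,
        error=error,
    )


def theoretical_max_force(
    v_target: float,
    mass_da: float | None = None,
    mass_pn: float | None = None,
) -> float:
    """Force cap 2·M·V_target in pN.

    Supply the pulling mass either in Da (``mass_da``, converted internally)
    or directly in pN·ps²/Å (``mass_pn``) when a pre-converted figure is the
    given quantity.
    """
    if (mass_da is None) == (mass_pn is None):
        raise InvalidArgumentError("supply exactly one of mass_da or mass_pn")
    if v_target < 0:
        raise InvalidArgumentError("v_target must be >= 0")
    m = mass_to_force_units(mass_da) if mass_da is not None else float(mass_pn)
    if m < 0:
        raise InvalidArgumentError("mass must be >= 0")
    return 2.0 * m * v_target


def per_pulse_displacement(v_target: float, pulse_fs: float = 100.0) -> float:
    """Distance scale V_target × T_pulse explored within one pulse, in Å."""
    return v_target * pulse_fs * 1e-3


@dataclass
class SmdResult:
    """Per-step log of a moving-harmonic-restraint (steered MD) run."""

    times: np.ndarray  # ps
    separations: np.ndarray  # Å
    targets: np.ndarray  # Å, restraint centre
    forces: np.ndarray  # pN, k_spring × (target − separation)
    final_system: ParticleSystem

    @property
    def peak_force(self) -> float:
        return float(np.max(np.abs(self.forces)))


def run_smd_baseline(
    system: ParticleSystem,
    anchors: AnchorSpec,
    spring_k: float,
    cantilever_velocity: float,
    duration_fs: float,
    dt_fs: float = 1.0,
) -> SmdResult:
    """Constant-velocity steered-MD baseline on the same engine.

    A harmonic restraint of stiffness ``spring_k`` (pN/Å) acts on the anchor
    separation; its centre starts at the current separation and moves at
    ``cantilever_velocity`` (Å/ps).  The restraint force k·(target − s) is
    distributed over each group in proportion to particle mass (equal and
    opposite on the two groups) and logged every step.  The input system is
    copied.
    """
    if spring_k <= 0:
        raise InvalidArgumentError("spring_k must be > 0")
    n_steps = int(round(duration_fs / dt_fs))
    if abs(n_steps * dt_fs - duration_fs) > 1e-9:
        raise InvalidArgumentError("duration_fs must be a multiple of dt_fs")

    from .engine import _check_finite, compute_forces  # internal reuse
    from .units import FORCE_PN_PER_DA_ACCEL

    work = system.copy()
    dt = dt_fs * 1e-3
    k_int = spring_k / FORCE_PN_PER_DA_ACCEL  # Da/ps² per Å
    g1, g2 = list(anchors.group1), list(anchors.group2)
    m1, m2 = anchors.group_masses(work)
    w1 = (work.masses[g1] / m1)[:, None]
    w2 = (work.masses[g2] / m2)[:, None]
    _, s0 = pulling_axis(work, anchors)

    times = np.empty(n_steps)
    seps = np.empty(n_steps)
    targets = np.empty(n_steps)
    forces = np.empty(n_steps)

    inv_m = 1.0 / work.masses[:, None]

    def total_force(t_now: float) -> tuple[np.ndarray, float, float, float]:
        f, _ = compute_forces(work)
        axis, sep = pulling_axis(work, anchors)
        target = s0 + cantilever_velocity * (t_now - system.time)
        pull = k_int * (target - sep)  # Da·Å/ps², along +axis on group2
        f[g2] += w2 * (pull * axis)
        f[g1] -= w1 * (pull * axis)
        return f, sep, target, pull

    f, _, _, _ = total_force(work.time)
    _check_finite(f)
    for step in range(n_steps):
        a = f * inv_m
        work.positions += work.velocities * dt + 0.5 * a * dt * dt
        work.time += dt
        f, sep, target, pull = total_force(work.time)
        _check_finite(f)
        work.velocities += 0.5 * (a + f * inv_m) * dt
        times[step] = work.time
        seps[step] = sep
        targets[step] = target
        forces[step] = pull * FORCE_PN_PER_DA_ACCEL
    return SmdResult(
        times=times, separations=seps, targets=targets, forces=forces, final_system=work
    )
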