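"""Synthetic bead-spring systems with known mechanical properties.

These generators are first-class citizens: they define the study conditions
under which the pulling protocol is validated.  Each fixture has a property
known in closed form — an exact rupture force (breakable bonds), an exact
force maximum (Morse bonds), or guaranteed trapping (an unbreakable stiff
bond) — so protocol outputs can be checked against ground truth.

Design of the rupture-recovery suite
------------------------------------
For a two-bead breakable bond driven by the pulse cycle, the extension obeys
the linear pulse map x' = x·cosφ + (v/ω)·sinφ with φ = ω·τ (ω the bond
angular frequency, τ the pulse length), whose fixed point has amplitude
(v/ω)/sin(φ/2).  The bond therefore ruptures above a critical velocity
v_c = ω·r_break·sin(φ/2), and the momentum estimate 2·M·v_c recovers the true
rupture force k·r_break up to the factor 2·(M/μ)·sin(φ/2)/ω (μ the reduced
mass).  The suite fixes M/μ = 10 (an uneven anchor-mass split) and ω ≈ 7–9
rad/ps, i.e. bond vibrational periods comparable to the pulse spacing — the
regime in which an impulse-per-pulse is meaningfully read as a force.  Total
anchor masses mirror typical two-residue pulling masses (≈200–260 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    Bond,
    BreakableBond,
    HarmonicBond,
    ParticleSystem,
    max_restoring_force,
)
from .errors import InvalidArgumentError
from .protocol import AnchorSpec

__all__ = [
    "make_two_bead_system",
    "make_chain_system",
    "make_breakable_pair",
    "make_trapped_pair",
    "make_trapped_chain",
    "make_free_pair",
    "make_staged_hairpin",
    "RecoveryFixture",
    "recovery_suite",
    "PAIR_ANCHORS",
    "HAIRPIN_TEMPERATURE",
    "RECOVERY_TEMPERATURE",
]

PAIR_ANCHORS = AnchorSpec(group1=(0,), group2=(1,))

# Study temperatures for the synthetic validation fixtures.  The rupture
# suite runs cold so the recovered threshold measures the bond mechanics,
# not thermal activation; the staged hairpin runs at 50 K so its two
# rupture extensions stay several thermal amplitudes wide; the trapped-state
# fixtures keep the conventional 300 K where thermal motion is part of the
# signal being measured.
RECOVERY_TEMPERATURE = 5.0  # K
HAIRPIN_TEMPERATURE = 50.0  # K

# anchor-mass split with (m1+m2)^2/(m1·m2) = 10, i.e. M/μ = 10
_SPLIT_HEAVY = 0.5 * (1.0 + np.sqrt(0.6))
_SPLIT_LIGHT = 1.0 - _SPLIT_HEAVY


def make_two_bead_system(
    mass1: float, mass2: float, bond: Bond | None, separation: float
) -> ParticleSystem:
    """Two beads on the x-axis at the given separation, at rest."""
    if separation <= 0:
        raise InvalidArgumentError("separation must be > 0")
    return ParticleSystem(
        masses=np.array([mass1, mass2]),
        positions=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        velocities=np.zeros((2, 3)),
        bonds=[] if bond is None else [bond],
    )


def make_chain_system(
    masses,
    backbone_bonds: list[Bond],
    geometry: str = "extended",
    cross_links: list[Bond] | None = None,
    strand_gap: float = 4.0,
) -> ParticleSystem:
    """Bead chain with consecutive backbone bonds, extended or folded back.

    ``backbone_bonds`` must connect (0,1), (1,2), … in order.  With
    ``geometry="extended"`` the beads lie along x at the cumulative bond rest
    lengths (end-to-end distance = Σ r0).  With ``geometry="hairpin"`` the
    second half of the chain folds back antiparallel at a perpendicular
    offset of ``strand_gap`` Å, so opposing beads sit ``strand_gap`` apart —
    the natural rest length for ``cross_links`` between them.  Sequential
    rupture of staged cross-links then produces a distance plateau between
    the two rupture events.
    """
    masses = np.asarray(masses, dtype=float)
    n = masses.shape[0]
    if n < 3:
        raise InvalidArgumentError("a chain needs at least 3 beads")
    if len(backbone_bonds) != n - 1:
        raise InvalidArgumentError(
            f"expected {n - 1} backbone bonds for {n} beads, got {len(backbone_bonds)}"
        )
    for k, b in enumerate(backbone_bonds):
        if (b.i, b.j) != (k, k + 1):
            raise InvalidArgumentError(
                f"backbone bond {k} must connect ({k}, {k + 1}), got ({b.i}, {b.j})"
            )
    positions = np.zeros((n, 3))
    if geometry == "extended":
        x = 0.0
        for k, b in enumerate(backbone_bonds):
            x += b.r0
            positions[k + 1, 0] = x
    elif geometry == "hairpin":
        n_half = (n + 1) // 2
        x = 0.0
        xs = [0.0]
        for b in backbone_bonds[: n_half - 1]:
            x += b.r0
            xs.append(x)
        for k in range(n_half):
            positions[k, 0] = xs[k]
        for k in range(n_half, n):
            positions[k, 0] = positions[n - 1 - k, 0]
            positions[k, 1] = strand_gap
    else:
        raise InvalidArgumentError(f"unknown geometry {geometry!r}")
    bonds: list[Bond] = list(backbone_bonds) + list(cross_links or [])
    return ParticleSystem(
        masses=masses,
        positions=positions,
        velocities=np.zeros((n, 3)),
        bonds=bonds,
    )


def make_breakable_pair(
    total_mass: float,
    omega: float,
    r_break: float,
    r0: float = 2.0,
    even_split: bool = False,
) -> ParticleSystem:
    """Two beads joined by a breakable-harmonic bond of angular frequency ω.

    The bond constant is k = μ·ω² so the pair oscillates at ``omega`` rad/ps;
    its rupture force is exactly k·r_break.  By default the total mass is
    split unevenly so M/μ = 10 (see module docstring); ``even_split`` gives
    the symmetric M/μ = 4 pair instead.
    """
    if even_split:
        m1 = m2 = 0.5 * total_mass
    else:
        m1, m2 = _SPLIT_LIGHT * total_mass, _SPLIT_HEAVY * total_mass
    mu = m1 * m2 / (m1 + m2)
    bond = BreakableBond(i=0, j=1, k=mu * omega * omega, r0=r0, r_break=r_break)
    return make_two_bead_system(m1, m2, bond, separation=r0)


def make_trapped_pair(
    total_mass: float = 224.0, omega: float = 15.0, r0: float = 3.0
) -> ParticleSystem:
    """Equal-mass pair with a stiff *unbreakable* harmonic bond.

    Pulled at any finite target velocity this system can only reflect, so it
    realises the fully trapped regime: persistently negative pre-pulse
    velocities and applied forces riding the 2·M·V_target cap.
    """
    mu = total_mass / 4.0
    bond = HarmonicBond(i=0, j=1, k=mu * omega * omega, r0=r0)
    return make_two_bead_system(total_mass / 2, total_mass / 2, bond, separation=r0)


def make_free_pair(total_mass: float = 224.0, separation: float = 10.0) -> ParticleSystem:
    """Two unbonded beads: the exactly solvable unimpeded-motion control."""
    return make_two_bead_system(total_mass / 2, total_mass / 2, None, separation)


def make_trapped_chain(
    n_beads: int = 5,
    bond_k: float = 3000.0,
    anchor_mass: float = 112.0,
    internal_mass: float = 50.0,
    r0: float = 3.0,
) -> tuple[ParticleSystem, AnchorSpec]:
    """Stiff unbreakable chain pulled by its end beads: the trapped-regime probe.

    An isolated two-bead bond reflects a pulse perfectly elastically — at its
    pulse-map fixed point the extension is cycle-periodic, so energy
    conservation returns exactly −V_target at every boundary.  Real molecules
    reflect only partially because recoil energy drains into internal modes
    between pulses.  This fixture supplies the minimal such bath: the stiff
    chain's internal vibrations absorb part of each kick, so the mean
    pre-pulse velocity settles at a fraction of −V_target (≈ −0.85·V_target
    at the defaults) while the applied forces still ride the 2·M·V_target
    cap.  The default end-bead masses give the pulling mass M = 224 Da.
    """
    masses = [anchor_mass] + [internal_mass] * (n_beads - 2) + [anchor_mass]
    backbone = [HarmonicBond(i=k, j=k + 1, k=bond_k, r0=r0) for k in range(n_beads - 1)]
    system = make_chain_system(masses, backbone, geometry="extended")
    return system, AnchorSpec(group1=(0,), group2=(n_beads - 1,))


@dataclass(frozen=True)
class RecoveryFixture:
    """One rupture-force recovery case: a pair plus its sweep settings."""

    name: str
    total_mass: float  # Da
    omega: float  # rad/ps
    r_break: float  # Å
    v_max: float  # top of the 0.2 Å/ps sweep grid

    def build(self) -> ParticleSystem:
        return make_breakable_pair(self.total_mass, self.omega, self.r_break)

    @property
    def bond(self) -> BreakableBond:
        return self.build().bonds[0]

    @property
    def rupture_force(self) -> float:
        """Ground truth k·r_break in pN."""
        return max_restoring_force(self.bond)


def recovery_suite() -> list[RecoveryFixture]:
    """Five breakable bonds spanning a >10× range of rupture force.

    Total masses mirror typical two-residue anchor masses; sweep tops give
    each grid head-room above the predicted critical velocity
    ω·r_break·sin(ω·0.05).
    """
    return [
        RecoveryFixture("pair-060pN", total_mass=224.0, omega=8.0, r_break=0.25, v_max=1.6),
        RecoveryFixture("pair-139pN", total_mass=262.0, omega=8.0, r_break=0.50, v_max=2.6),
        RecoveryFixture("pair-175pN", total_mass=206.0, omega=8.0, r_break=0.80, v_max=3.8),
        RecoveryFixture("pair-326pN", total_mass=202.0, omega=9.0, r_break=1.20, v_max=6.2),
        RecoveryFixture("pair-625pN", total_mass=240.0, omega=7.0, r_break=3.20, v_max=9.6),
    ]


@dataclass(frozen=True)
class StagedHairpin:
    """A hairpin fixture plus everything needed to probe its two-stage rupture."""

    system: ParticleSystem
    anchors: AnchorSpec
    f_rupture_1: float  # pN, outer (weak) cross-link
    f_rupture_2: float  # pN, inner (strong) cross-link
    contour_length: float  # Å
    temperature: float  # K


def make_staged_hairpin() -> StagedHairpin:
    """Six-bead hairpin whose two cross-links rupture at staged forces.

    Strand beads of 100 Da (turn beads 60 Da) fold back at a 4 Å gap.  The
    outer cross-link joins the two pulled end beads directly and fails at
    ≈106 pN; the inner cross-link joins the next bead pair and fails at
    ≈850 pN.  Pulling the ends apart at a force cap between the two
    thresholds unzips the outer link only, leaving the chain dangling from
    the inner link at roughly triple the initial separation — a metastable
    partially-extended state, the bead-spring analogue of an unfolding
    intermediate.  Rupture extensions are several thermal amplitudes at the
    fixture temperature (50 K), so the thresholds are mechanically sharp.
    """
    masses = [100.0] * 6
    k_bb, r0 = 4000.0, 4.0
    backbone = [HarmonicBond(i=k, j=k + 1, k=k_bb, r0=r0) for k in range(5)]
    outer = BreakableBond(i=0, j=5, k=615.0, r0=4.0, r_break=1.04)
    inner = BreakableBond(i=1, j=4, k=2561.0, r0=4.0, r_break=2.00)
    system = make_chain_system(
        masses, backbone, geometry="hairpin", cross_links=[outer, inner], strand_gap=4.0
    )
    return StagedHairpin(
        system=system,
        anchors=AnchorSpec(group1=(0,), group2=(5,)),
        f_rupture_1=max_restoring_force(outer),
        f_rupture_2=max_restoring_force(inner),
        contour_length=5 * r0,
        temperature=HAIRPIN_TEMPERATURE,
    )
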