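"""Everything downstream of the pulse logs.

Response curves, FFT smoothing, regime classification, critical-velocity and
unfolding-force estimation, and distance-plateau (intermediate) detection.
All functions accept either a :class:`~puffmd.protocol.TrajectoryResult` or
plain arrays read back from a pulse-log CSV, so stored logs can be re-analysed
without re-simulation.

Regime vocabulary
-----------------
A velocity sweep of constant-momentum runs shows four responses as the target
velocity grows: *trapped* (no net extension), *intermittent* (partial
extension), *constant_momentum* (extension tracks the target rate) and
*saturated* (the chain is already fully extended well before the run ends).
The boundary between intermittent and constant-momentum defines the critical
velocity v_c, and 2·M·v_c estimates the rupture/unfolding force.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    BoundaryNotBracketedError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidCutoffError,
)
from .protocol import TrajectoryResult, theoretical_max_force
from .units import mass_to_force_units

__all__ = [
    "RegimeLabel",
    "SweepResult",
    "Plateau",
    "PlateauReport",
    "ForceResponse",
    "fit_separation_slope",
    "smooth_force_curve",
    "mean_pre_pulse_velocity",
    "classify_regime",
    "estimate_critical_velocity",
    "unfolding_force",
    "force_response_curve",
    "detect_plateaus",
]


class RegimeLabel(str, enum.Enum):
    TRAPPED = "trapped"
    INTERMITTENT = "intermittent"
    CONSTANT_MOMENTUM = "constant_momentum"
    SATURATED = "saturated"


# distance-ratio boundaries between the regimes; exposed so sweeps can
# override them, chosen to reproduce the four-band structure on fixtures
R_TRAPPED_MAX = 0.1
R_CONSTANT_MIN = 0.8
SATURATION_FRACTION = 0.95


def _times_seps(trajectory) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trajectory, TrajectoryResult):
        return trajectory.times, trajectory.separations
    times, seps = trajectory
    return np.asarray(times, dtype=float), np.asarray(seps, dtype=float)


def fit_separation_slope(
    trajectory, window: tuple[float, float] | None = None
) -> float:
    """Least-squares slope of separation vs time, Å/ps.

    ``window`` restricts the fit to times in [t0, t1] (default: everything).
    """
    t, s = _times_seps(trajectory)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, s = t[keep], s[keep]
    if t.size < 3:
        raise InsufficientDataError(
            f"slope fit needs at least 3 points, got {t.size}"
        )
    return float(np.polyfit(t, s, 1)[0])


def smooth_force_curve(
    forces: np.ndarray, cutoff_pulses: float = 20.0
) -> tuple[np.ndarray, float]:
    """Low-pass the per-pulse force series with a hard FFT cutoff.

    Fourier components with period shorter than ``cutoff_pulses`` samples are
    zeroed; the DC component always survives, so a constant series is
    returned unchanged.  Returns the smoothed series and its maximum.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 4:
        raise InsufficientDataError("need at least 4 samples to smooth")
    if cutoff_pulses < 2:
        raise InvalidCutoffError(
            f"cutoff must be at least 2 samples, got {cutoff_pulses}"
        )
    spectrum = np.fft.rfft(forces)
    freqs = np.fft.rfftfreq(forces.size, d=1.0)
    spectrum[freqs > 1.0 / cutoff_pulses] = 0.0
    smoothed = np.fft.irfft(spectrum, n=forces.size)
    return smoothed, float(smoothed.max())


def mean_pre_pulse_velocity(trajectory, burn_in_pulses: int | None = None) -> float:
    """Average pre-pulse axis velocity after a burn-in, Å/ps.

    Default burn-in discards the first 10% of pulses (the early transient
    where the system has not yet felt the pull).
    """
    if isinstance(trajectory, TrajectoryResult):
        v = trajectory.pre_pulse_velocities
    else:
        v = np.asarray(trajectory, dtype=float)
    if burn_in_pulses is None:
        burn_in_pulses = v.size // 10
    if burn_in_pulses >= v.size:
        raise InsufficientDataError("burn-in discards every pulse")
    return float(v[burn_in_pulses:].mean())


def classify_regime(
    trajectory,
    v_target: float,
    contour_length: float | None = None,
) -> tuple[RegimeLabel, float]:
    """Label a trajectory and return its distance ratio r.

    r = (final − initial separation) / (v_target × elapsed time): the
    fraction of the commanded extension actually achieved.  Saturated means
    the separation reached ``SATURATION_FRACTION`` of the contour length
    before the last 10% of the run; pass ``contour_length=None`` for systems
    with no finite contour.  ``v_target = 0`` is trapped by convention.
    """
    t, s = _times_seps(trajectory)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 pulses to classify")
    if contour_length is not None and contour_length <= s[0]:
        raise InvalidArgumentError("contour_length must exceed the initial separation")
    elapsed = t[-1] - t[0]
    if v_target == 0.0 or elapsed <= 0:
        return RegimeLabel.TRAPPED, 0.0
    r = max(0.0, float((s[-1] - s[0]) / (v_target * elapsed)))
    if contour_length is not None:
        reached = np.nonzero(s >= SATURATION_FRACTION * contour_length)[0]
        if reached.size and t[reached[0]] <= t[0] + 0.9 * elapsed:
            return RegimeLabel.SATURATED, r
    if r >= R_CONSTANT_MIN:
        return RegimeLabel.CONSTANT_MOMENTUM, r
    if r >= R_TRAPPED_MAX:
        return RegimeLabel.INTERMITTENT, r
    return RegimeLabel.TRAPPED, r


def estimate_critical_velocity(
    v_targets: np.ndarray, labels: list[RegimeLabel]
) -> float:
    """Smallest grid velocity from which the response stays constant-momentum.

    Saturated entries (already fully extended) are ignored.  If every
    pre-saturation entry is constant-momentum the boundary is unresolved:
    the smallest grid value is returned with a warning.  If none is
    constant-momentum the boundary is not bracketed and an error is raised.
    Reported at grid resolution — no interpolation.
    """
    v = np.asarray(v_targets, dtype=float)
    if v.size != len(labels):
        raise InvalidArgumentError("v_targets and labels must have equal length")
    if v.size and np.any(np.diff(v) <= 0):
        raise InvalidArgumentError("v_targets must be strictly increasing")
    pre_sat = [
        (vi, lab) for vi, lab in zip(v, labels) if lab is not RegimeLabel.SATURATED
    ]
    if not pre_sat:
        raise BoundaryNotBracketedError("every trajectory is saturated")
    const = [lab is RegimeLabel.CONSTANT_MOMENTUM for _, lab in pre_sat]
    if not any(const):
        raise BoundaryNotBracketedError(
            "no constant-momentum trajectory below saturation; extend the grid upward"
        )
    # smallest v from which all later pre-saturation labels are constant
    idx = len(const)
    for i in range(len(const) - 1, -1, -1):
        if const[i]:
            idx = i
        else:
            break
    if idx == len(const):
        raise BoundaryNotBracketedError(
            "the largest pre-saturation velocity is not constant-momentum; "
            "the boundary lies above the grid"
        )
    if idx == 0 and all(const):
        warnings.warn(
            "every velocity is constant-momentum; boundary unresolved, "
            "reporting the smallest grid value",
            stacklevel=2,
        )
    return float(pre_sat[idx][0])


def unfolding_force(
    v_critical: float,
    mass_da: float | None = None,
    mass_pn: float | None = None,
    rounded: bool = True,
) -> float:
    """Unfolding-force estimate 2·M·v_critical in pN.

    The mass is given either in Da or directly in pN·ps²/Å.  By default the
    result is rounded to the nearest pN (the conventional reporting
    precision); pass ``rounded=False`` for full precision.
    """
    if v_critical <= 0:
        raise InvalidArgumentError("v_critical must be > 0")
    f = theoretical_max_force(v_critical, mass_da=mass_da, mass_pn=mass_pn)
    return float(round(f)) if rounded else f


@dataclass
class ForceResponse:
    """Simulated vs theoretical maximum force across a velocity sweep."""

    v_targets: np.ndarray
    max_forces: np.ndarray  # pN, max of the smoothed per-pulse force
    theoretical: np.ndarray  # pN, 2·M·v per grid point
    deviation_velocity: float | None  # smallest v where simulated < 0.8 × theory
    critical_force: float | None  # 2·M·v at the deviation point, pN


def force_response_curve(
    v_targets: np.ndarray,
    max_forces: np.ndarray,
    mass_da: float,
    deviation_fraction: float = 0.8,
) -> ForceResponse:
    """Compare measured force maxima with the 2·M·V_target cap.

    The deviation point — the smallest velocity whose simulated maximum falls
    below ``deviation_fraction`` of the cap — provides an alternative
    critical-force estimate: trapped systems ride the cap, unimpeded ones
    fall away from it.
    """
    v = np.asarray(v_targets, dtype=float)
    f = np.asarray(max_forces, dtype=float)
    if v.size == 0 or v.size != f.size:
        raise InvalidArgumentError("need matching, non-empty v_targets and max_forces")
    theory = np.array([theoretical_max_force(vi, mass_da=mass_da) for vi in v])
    below = f < deviation_fraction * theory
    if below.any():
        i = int(np.argmax(below))
        dev_v = float(v[i])
        crit = float(theory[i])
    else:
        dev_v = None
        crit = None
    return ForceResponse(
        v_targets=v,
        max_forces=f,
        theoretical=theory,
        deviation_velocity=dev_v,
        critical_force=crit,
    )


@dataclass
class Plateau:
    start_ps: float
    end_ps: float
    mean_separation: float
    label: str  # folded | intermediate | unfolded


@dataclass
class PlateauReport:
    plateaus: list[Plateau]

    @property
    def intermediates(self) -> list[Plateau]:
        return [p for p in self.plateaus if p.label == "intermediate"]


def detect_plateaus(
    trajectory,
    min_duration_ps: float | None = None,
    tolerance_A: float = 2.0,
    contour_length: float | None = None,
    initial_separation: float | None = None,
) -> PlateauReport:
    """Find maximal flat stretches of the separation trace.

    A plateau is a maximal interval whose separation spread (max − min) is at
    most 2·``tolerance_A`` — i.e. every point lies within ``tolerance_A`` of
    the interval midrange — lasting at least ``min_duration_ps`` (default:
    20% of the trace).  Plateaus are classified by their mean extension:
    *folded* if within tolerance of ``initial_separation`` (default: the
    first recorded separation; pass the rest-state separation explicitly
    when the run starts from a thermally displaced snapshot), *unfolded* if
    at ≥ 95% of the contour length (when given), otherwise *intermediate*.
    Intervals never overlap.
    """
    t, s = _times_seps(trajectory)
    if t.size < 2:
        return PlateauReport(plateaus=[])
    if min_duration_ps is None:
        min_duration_ps = 0.2 * float(t[-1] - t[0])
    if initial_separation is None:
        initial_separation = float(s[0])

    # partition the trace into consecutive maximal flat windows, then merge
    # neighbours at the same level (a single physical plateau can otherwise
    # be split when the scan enters it from a ramp)
    n = t.size
    windows: list[tuple[int, int]] = []
    i = 0
    while i < n:
        lo = hi = s[i]
        j = i
        while j + 1 < n:
            nxt = s[j + 1]
            if max(hi, nxt) - min(lo, nxt) > 2.0 * tolerance_A:
                break
            lo, hi = min(lo, nxt), max(hi, nxt)
            j += 1
        windows.append((i, j))
        i = j + 1
    merged: list[tuple[int, int]] = [windows[0]]
    for i, j in windows[1:]:
        pi, pj = merged[-1]
        if abs(s[i : j + 1].mean() - s[pi : pj + 1].mean()) <= tolerance_A:
            merged[-1] = (pi, j)
        else:
            merged.append((i, j))

    plateaus: list[Plateau] = []
    for i, j in merged:
        if j == i or (t[j] - t[i]) < min_duration_ps:
            continue
        mean = float(s[i : j + 1].mean())
        if mean - initial_separation < tolerance_A:
            label = "folded"
        elif contour_length is not None and mean >= SATURATION_FRACTION * contour_length:
            label = "unfolded"
        else:
            label = "intermediate"
        plateaus.append(
            Plateau(
                start_ps=float(t[i]),
                end_ps=float(t[j]),
                mean_separation=mean,
                label=label,
            )
        )
    return PlateauReport(plateaus=plateaus)


@dataclass
class SweepResult:
    """Aggregated response of one system over a grid of target velocities.

    ``table`` has one row per velocity: v_target, mean_pre_pulse_velocity,
    max_smoothed_force, r, regime.  ``v_critical``/``f_unfold`` are None when
    the sweep did not bracket the boundary.
    """

    table: pd.DataFrame
    pulling_mass_da: float
    v_critical: float | None
    f_unfold: float | None  # pN, 2·M·v_critical rounded
    force_response: ForceResponse

    @property
    def regimes(self) -> list[RegimeLabel]:
        return [RegimeLabel(x) for x in self.table["regime"]]
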