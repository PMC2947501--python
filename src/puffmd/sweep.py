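"""Velocity sweeps: run the protocol over a grid of target velocities and
aggregate the per-velocity responses into a critical-velocity estimate.

The sweep is the measurement the protocol exists for: below the critical
velocity the system is trapped or only intermittently extends; above it the
extension tracks the target rate, and 2·M·v_critical estimates the force
needed to break the system out of its well.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .analysis import (
    RegimeLabel,
    SweepResult,
    classify_regime,
    estimate_critical_velocity,
    force_response_curve,
    mean_pre_pulse_velocity,
    smooth_force_curve,
    unfolding_force,
)
from .engine import ParticleSystem
from .errors import BoundaryNotBracketedError, InvalidArgumentError
from .protocol import AnchorSpec, PuffParams, run_puff

__all__ = ["velocity_grid", "run_velocity_sweep"]


def velocity_grid(v_min: float = 0.2, v_max: float = 8.0, step: float = 0.2) -> np.ndarray:
    """Inclusive arange that avoids float fencepost surprises."""
    n = int(round((v_max - v_min) / step))
    return np.round(v_min + step * np.arange(n + 1), 10)


def run_velocity_sweep(
    starts: ParticleSystem | list[ParticleSystem],
    anchors: AnchorSpec,
    velocities: np.ndarray,
    n_pulses: int,
    pulse_fs: float = 100.0,
    dt_fs: float = 1.0,
    rescale_temp: float | None = 300.0,
    contour_length: float | None = None,
    smoothing_cutoff: float = 20.0,
    seed: int = 0,
) -> SweepResult:
    """One constant-momentum run per target velocity, plus the aggregation.

    ``starts`` is either one starting state or a list of equilibration
    snapshots cycled across the grid (repeat starts).  Each run begins from a
    copy, so starts can be reused.  If the sweep does not bracket the
    trapped-to-unimpeded boundary, ``v_critical``/``f_unfold`` are None and a
    warning is issued rather than raising.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.size < 3:
        raise InvalidArgumentError("a sweep needs at least 3 target velocities")
    pool = starts if isinstance(starts, list) else [starts]
    if not pool:
        raise InvalidArgumentError("starts must contain at least one system")

    mass_da = anchors.pulling_mass(pool[0])
    rows = []
    labels: list[RegimeLabel] = []
    for i, v in enumerate(velocities):
        params = PuffParams(
            v_target=float(v),
            n_pulses=n_pulses,
            pulse_fs=pulse_fs,
            dt_fs=dt_fs,
            rescale_temp=rescale_temp,
            seed=seed,
        )
        traj = run_puff(pool[i % len(pool)], anchors, params)
        label, r = classify_regime(traj, float(v), contour_length)
        _, fmax = smooth_force_curve(traj.applied_forces, smoothing_cutoff)
        rows.append(
            {
                "v_target": float(v),
                "mean_pre_pulse_velocity": mean_pre_pulse_velocity(traj),
                "max_smoothed_force": fmax,
                "r": r,
                "regime": label.value,
            }
        )
        labels.append(label)

    table = pd.DataFrame(rows)
    try:
        v_crit = estimate_critical_velocity(velocities, labels)
        f_unf = unfolding_force(v_crit, mass_da=mass_da)
    except BoundaryNotBracketedError as exc:
        warnings.warn(f"critical velocity not bracketed: {exc}", stacklevel=2)
        v_crit, f_unf = None, None
    response = force_response_curve(
        velocities, table["max_smoothed_force"].to_numpy(), mass_da
    )
    return SweepResult(
        table=table,
        pulling_mass_da=mass_da,
        v_critical=v_crit,
        f_unfold=f_unf,
        force_response=response,
    )
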