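# Methods

## The constant-momentum pulse cycle

One cycle of `run_puff` does, in order:

1. **Record** the pre-pulse state: anchor separation and the relative axis
   velocity V₁₂,axis (mass-weighted group COM velocities projected on the
   axis N₁₂ from group1's COM to group2's COM).  This is sampled *before*
   the thermostat so the logged resistance is the raw dynamical response.
2. **Rescale** all velocities so the COM-free kinetic temperature equals the
   bath temperature (default 300 K).  The mass-weighted COM velocity is
   removed first and stays removed, so momentum injected by earlier pulses
   is not counted as heat.  Anchor atoms are included in the rescale; the
   reset in step 3 happens afterwards and is therefore never distorted by
   the thermostat.
3. **Reset**: ΔV = V_target − V₁₂,axis (post-rescale); every group2 atom
   gains +½ΔV·N₁₂ and every group1 atom −½ΔV·N₁₂.  Immediately afterwards
   V₁₂,axis = V_target to machine precision, whatever the masses.
4. **Relax**: one pulse (default 100 fs, 1 fs velocity-Verlet steps) of
   unmodified constant-energy dynamics.

The booked force is F = M·ΔV with M = M₁+M₂ converted to pN·ps²/Å
(0.1660539 pN per Da·Å/ps²).  Dimensionally M·ΔV is an impulse (pN·ps) read
as a force in pN — the instantaneous-event convention; all force numbers
the package reports inherit it, and the identities F_max = 2·M·V_target and
F_unfold = 2·M·v_critical are stated in exactly these units.

Two deliberate asymmetries are worth knowing.  The ±½ΔV scheme applies equal
and opposite *velocity increments*, so with unequal group masses each pulse
injects net momentum ½ΔV·(M₂−M₁); the thermostat's COM removal absorbs it a
cycle later, and `PuffParams(remove_com_drift=True)` subtracts it at the
pulse itself for users who want strict momentum neutrality.  Second,
`rescale_temp=None` disables the thermostat entirely.  That mode exists
because for a minimal system — two free beads — the rescale would
renormalise the pulling velocity itself (the pulling mode *is* the system's
entire kinetic energy), breaking the exact zero-force property of unimpeded
motion that the bookkeeping tests rely on.  In many-particle systems the
pulling mode is a negligible energy fraction and the thermostat is benign.

## Units, engine, integrators

Internal units are Å, ps, Da, K throughout; pN appears only at the analysis
boundary.  k_B = 0.8314463 Da·Å²/(ps²·K).  Kinetic temperature uses
3N−3 degrees of freedom with COM removal (the default), because pulses
inject drift that must not read as heat.

The engine integrates bonded bead-spring systems only: harmonic, Morse and
breakable-harmonic bonds, no nonbonded terms, no constraints.  NVE segments
use velocity-Verlet; equilibration uses the BAOAB Langevin splitting with
friction γ in ps⁻¹ (γ = 5 ps⁻¹ default — the conventional engine input
unit; a per-second friction would be physically inert on these timescales).
Fixed seeds make Langevin runs bit-reproducible on a platform.

A breakable bond is harmonic until its extension first exceeds `r_break`
during a force evaluation, then irreversibly dead.  Its rupture force is
exactly k·r_break, which is what makes parameter-recovery studies possible;
`max_restoring_force` returns it (a·D/2 for Morse at the inflection,
∞ for an unbreakable harmonic bond).

With a 1 fs step, velocity-Verlet's relative energy fluctuation per mode is
≈ (ω·dt)²/8, so bond angular frequencies in the validation fixtures are
kept at or below ~9 rad/ps; all fixtures then hold NVE drift under 1×10⁻⁵
relative over a 100 fs pulse interior, the tolerance the test suite
enforces.

## Fixture design

The synthetic fixtures are the study conditions; their parameters were set
by the analysis below, once, and the tests then measure against them.

**Rupture-force recovery.**  For a two-bead breakable bond under the cycle
(rescale ≈ drains the boundary velocity at the cold study temperature, reset
restores +v), the extension follows the linear pulse map
x′ = x·cosφ + (v/ω)·sinφ, φ = ω·τ with τ = 0.1 ps.  Its fixed point has
amplitude (v/ω)/sin(φ/2), giving a sharp critical velocity

    v_c = ω · r_break · sin(φ/2)

and hence 2·M·v_c / (k·r_break) = 2·(M/μ)·sin(φ/2)/ω.  The estimator is
therefore only meaningful when the bond's vibrational half-period is
comparable to the pulse spacing — the same regime the protocol operates in
on real molecules.  The suite (`recovery_suite`) uses ω = 7–9 rad/ps and an
uneven anchor-mass split with M/μ = 10, for which the prefactor is ≈ 0.97;
total masses (202–262 Da) mirror typical two-residue anchor masses, and
`r_break` spans a 10.5× range of rupture force (60–625 pN).  Sweeps run at
5 K so the recovered threshold measures bond mechanics rather than thermal
(Kramers) escape; measured recovery errors are below 2%, dominated by the
0.2 Å/ps grid resolution.

**Trapped-regime probe.**  An isolated pair cannot show partial reflection:
at the pulse-map fixed point the extension is cycle-periodic, so energy
conservation returns the boundary speed to exactly V_target and the mean
pre-pulse velocity pins at −V_target for *any* two-body potential (we
verified this numerically for harmonic and strongly anharmonic bonds).
Real molecules reflect partially because recoil energy drains into internal
modes between pulses.  `make_trapped_chain` therefore supplies the minimal
bath: a stiff 5-bead chain (k = 3000 Da/ps², end beads 112 Da so M =
224 Da) pulled by its end beads at 300 K.  Its mean pre-pulse velocity
settles around −0.9·V_target — negative but sub-unit magnitude, the
signature of a trapped-but-dissipating system — while the smoothed force
maximum stays within ~10% of the 2·M·V cap.  (The cap can be modestly
exceeded: when the boundary happens at a high-potential phase the rescale
factor exceeds 1 and ΔV > 2V_target; this is physics of the thermostat, not
an error.)

**Staged intermediate.**  `make_staged_hairpin` folds a six-bead chain
(100 Da beads, backbone k = 4000 Da/ps², r₀ = 4 Å) back on itself at a 4 Å
gap with two breakable cross-links: the outer joins the pulled end beads
and fails at 106 pN; the inner joins the next pair and fails at 851 pN.
Pulling with a force cap between the thresholds breaks only the outer link;
the chain unzips until the inner link carries the load and the separation
plateaus ~10 Å above the folded value.  Rupture extensions are ≥ 8 thermal
energies at the fixture temperature (50 K), keeping the thresholds
mechanically sharp over the run lengths used.  At very large caps the
backbone itself stretches elastically well beyond the nominal 20 Å contour
— harmonic bonds have no finite extensibility — which the saturation
classification tolerates by thresholding at 95% of the contour.

## Response analysis

* **Slope**: ordinary least squares of separation vs time over an optional
  window.
* **Force smoothing**: hard low-pass on the per-pulse force series (real
  FFT, components with period < cutoff zeroed, default cutoff 20 pulses).
  The default keeps the envelope of a trapped run while removing the
  per-pulse ripple; it is configurable and the DC component always
  survives.
* **Regimes**: r = (final − initial separation)/(V_target·elapsed).
  Boundaries r < 0.1 trapped, 0.1–0.8 intermittent, ≥ 0.8
  constant-momentum; saturated when separation reaches 95% of the contour
  length before the last 10% of the run.  The 0.1/0.8/0.95 values are
  package choices that reproduce the four-band structure on the fixtures
  and are exposed as module constants.  V_target = 0 is trapped by
  convention.
* **Critical velocity**: smallest grid velocity from which every larger
  pre-saturation velocity is also constant-momentum; reported at grid
  resolution, no interpolation.  Degenerate grids warn (all constant) or
  raise (boundary above the grid).  The force-response deviation point
  (first velocity whose smoothed maximum falls below 0.8× the 2·M·V line)
  provides an independent estimate; on fixtures the two agree within one
  grid step.
* **Mean pre-pulse velocity**: arithmetic mean after discarding a default
  burn-in of 10% of pulses (the early transient).
* **Plateaus**: the separation trace is partitioned into maximal windows of
  spread ≤ 2× tolerance (default 2 Å), adjacent windows at the same level
  are merged (a single plateau entered from a ramp would otherwise split),
  and surviving intervals of at least the minimum duration (default 20% of
  the run) are classified folded / intermediate / unfolded by their mean
  extension relative to a reference separation (pass the rest-state
  separation explicitly when starting from thermal snapshots) and the
  contour length.

## Restart-file boundary

The ASCII restart dialect (title; atom count + optional time; %12.7f
coordinates six per line; optional velocity block; optional box line) is
read and written exactly; truncated or malformed files fail with the line
number.  Restart velocities are in Å per 1/20.455 ps and are converted at
this boundary only — internal velocities are always Å/ps.  A two-atom file
with one trailing 6-value line is ambiguous between velocities and box and
is read as velocities (the case the pulling workflow round-trips).
"No velocities" and "all-zero velocities" are distinct states.

## Problem sizes in the validation studies

The test suite and the acceptance script use: 400 pulses (40 ps) for the
trapped and intermediate studies, 120 pulses per sweep point with 0.2 Å/ps
grids (8–48 points per bond) for recovery, 2–5 ps Langevin equilibration,
and a 20 ps spring-baseline run.  These sizes give regime classifications
and plateau detections that are stable across seeds for the fixtures
shipped; larger systems would need proportionally longer relaxation and
sweep horizons.

## Limitations

The engine is a validation vehicle, not a force field: no nonbonded terms,
no solvent, no constraints, harmonic backbones with unlimited extensibility.
The protocol estimates the force needed to unfold *without impedance*; it
does not model unfolding kinetics at fixed velocity, so no loading-rate
dependence should be read into its outputs.  Regime thresholds and the
smoothing cutoff are sensible defaults, not universal constants; sweeps on
new systems should check that the trapped band and the constant-momentum
band are both actually visited.
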