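# puffmd

Constant-momentum pulling for mechanical-unfolding studies, with a built-in
bead-spring MD engine for validation at desk scale.

## The problem

Single-molecule force spectroscopy (AFM) measures the forces at which
proteins such as titin's I27 domain mechanically unfold — typically
100–300 pN.  Conventional steered-MD simulations pull with a moving harmonic
spring; because the spring keeps loading whenever the molecule resists, the
simulated forces overshoot the measured ones by up to an order of magnitude.

`puffmd` implements the alternative: a **pulsed constant-momentum protocol**.
Time is broken into short pulses (default 100 fs at a 1 fs step).  At each
pulse boundary the relative velocity of two anchor groups along their
centre-of-mass axis N₁₂ is *instantaneously reset* to a target value:

    ΔV = V_target − V₁₂,axis
    every atom of group2 gains +½·ΔV·N₁₂, of group1 −½·ΔV·N₁₂

and the system then relaxes under plain constant-energy dynamics (velocities
are rescaled to the bath temperature just before each reset).  Because the
reset is instantaneous, the booked force is the momentum change
**F = M·ΔV** with M = M₁+M₂ the combined anchor mass in pN·ps²/Å.  A system
reflecting off a barrier arrives at each boundary near −V_target, so the
applied force is *capped* at

    F_max = 2·M·V_target

Sweeping V_target and finding the **critical velocity** v_c at which
extension first proceeds unimpeded gives an unfolding-force estimate
**F_unfold = 2·M·v_c**.  Systems pulled below v_c are actively stabilised
(every excess velocity fluctuation is damped at the next reset), which makes
partially unfolded intermediates easy to trap and identify as plateaus in
the distance trace.

The package provides the controller (`puffmd.protocol`), a minimal NVE /
Langevin bead-spring engine and synthetic fixtures with exactly known
rupture forces (`puffmd.engine`, `puffmd.fixtures`), response analysis —
FFT-smoothed force curves, regime classification, critical-velocity and
plateau detection (`puffmd.analysis`, `puffmd.sweep`) — and AMBER-style
ASCII restart I/O so the same controller can drive an external engine
(`puffmd.mdio`).

## A worked example

A breakable bond with rupture force k·r_break = 175 pN, swept at 0.2 Å/ps
resolution (`python examples/critical_velocity_sweep.py`):

```
 v_target  mean_pre_pulse_velocity  max_smoothed_force        r            regime
    ...
    2.400                   -2.398             112.088    0.025           trapped
    2.600                    2.600             100.087    0.944 constant_momentum
    ...
critical velocity      : 2.6 A/ps
2*M*v_critical         : 178 pN
true rupture force     : 175 pN (k * r_break)
relative error         : +1.6%
```

Below 2.6 Å/ps the pair is trapped: the pre-pulse velocity mirrors the
target (full reflection) and the applied force tracks the 2·M·V cap.  At
2.6 Å/ps the bond snaps and extension runs at the target rate (r ≈ 1); the
momentum estimate recovers the true rupture force to 1.6%.

Other examples: `worked_forces.py` (the published-mass force arithmetic:
82, 213, 158, 177, 109 pN), `trapped_vs_unimpeded.py`,
`unfolding_intermediate.py` (a two-stage fixture trapped at a partially
unzipped plateau), `smd_contrast.py` (spring pulling's peak force is ~30×
the capped protocol's on the same trapped system).

## Command line

```bash
puffmd run   -c config.yaml -o out/    # one trajectory -> pulses.csv + summary
puffmd sweep -c config.yaml -o out/    # velocity grid  -> v_critical, 2·M·v_c
puffmd analyze out/pulses.csv --plateaus
```

See `puffmd.cli` for the config schema; flags override file values.

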