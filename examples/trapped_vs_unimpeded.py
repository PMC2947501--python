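"""Two limiting responses to constant-momentum pulling.

A free pair of beads moves at exactly the target velocity with zero applied
force after the first pulse; a stiff bonded chain is trapped — its pre-pulse
velocities turn negative (the system rebounds against the pull between
pulses) and the applied force rides the 2·M·V_target cap.
"""

import puffmd as pm
from puffmd.fixtures import PAIR_ANCHORS, make_free_pair, make_trapped_chain

v = 1.0  # Å/ps

free = pm.run_puff(
    make_free_pair(),
    PAIR_ANCHORS,
    pm.PuffParams(v_target=v, n_pulses=100, rescale_temp=None),
)
print("free pair (no bond, thermostat off):")
print(f"  fitted separation slope : {pm.fit_separation_slope(free):6.3f} A/ps (target {v})")
print(f"  max |force| after pulse1: {abs(free.applied_forces[1:]).max():6.2e} pN")

chain, anchors = make_trapped_chain()
pm.langevin_equilibrate(
    chain, pm.EquilibrationParams(temperature=300.0, duration=3.0, gamma=5.0, seed=17)
)
trapped = pm.run_puff(chain, anchors, pm.PuffParams(v_target=v, n_pulses=400))
mean_v = pm.mean_pre_pulse_velocity(trapped)
_, fmax = pm.smooth_force_curve(trapped.applied_forces)
cap = pm.theoretical_max_force(v, mass_da=anchors.pulling_mass(chain))
print("stiff chain, pulled at the ends (300 K):")
print(f"  mean pre-pulse velocity : {mean_v:6.3f} A/ps  (negative = resisting)")
print(f"  max smoothed force      : {fmax:6.1f} pN vs cap 2*M*V = {cap:.1f} pN")
print(f"  fitted separation slope : {pm.fit_separation_slope(trapped):6.3f} A/ps (no extension)")
# The trapped chain converts nearly the whole velocity reset into reaction
# force every pulse while gaining no extension at all.
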