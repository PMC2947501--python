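"""Trapping a staged fixture in its unfolding intermediate.

The hairpin fixture has two cross-links that rupture at ~106 pN and ~850 pN.
Because the protocol caps its force at 2·M·V_target, a target velocity whose
cap lies between the two thresholds breaks only the weak link: the chain
partially unzips and then sits on a distance plateau — an unfolding
intermediate — for the rest of the run.  Velocities below the first
threshold leave it folded; far above the second it unfolds completely.
"""

import puffmd as pm
from puffmd.fixtures import make_staged_hairpin

hp = make_staged_hairpin()
two_m = 2.0 * pm.mass_to_force_units(hp.anchors.pulling_mass(hp.system))
start = hp.system.copy()
pm.langevin_equilibrate(
    start,
    pm.EquilibrationParams(temperature=hp.temperature, duration=5.0, gamma=5.0, seed=3),
)

print(f"rupture thresholds: F1 = {hp.f_rupture_1:.0f} pN, F2 = {hp.f_rupture_2:.0f} pN")
for v in (0.5, 2.0, 13.0):
    traj = pm.run_puff(
        start.copy(),
        hp.anchors,
        pm.PuffParams(v_target=v, n_pulses=400, rescale_temp=hp.temperature),
    )
    report = pm.detect_plateaus(
        traj, contour_length=hp.contour_length, initial_separation=4.0
    )
    tags = ", ".join(
        f"{p.label} at {p.mean_separation:.1f} A for {p.end_ps - p.start_ps:.0f} ps"
        for p in report.plateaus
    )
    print(f"V_target = {v:5.1f} A/ps (cap {two_m * v:6.0f} pN): {tags}")
# The middle run shows exactly one intermediate plateau ~10 A beyond the
# folded separation, held up by the still-intact strong cross-link.
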