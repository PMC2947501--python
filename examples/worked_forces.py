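"""Force arithmetic of the constant-momentum protocol.

The protocol caps the applied force at 2·M·V_target (M the combined anchor
mass in pN·ps²/Å), and the smallest target velocity at which pulling proceeds
unimpeded — the critical velocity — turns into an unfolding-force estimate
2·M·v_critical.  These identities need no simulation; this script evaluates
them for three classic pulling geometries with published anchor masses.
"""

import puffmd as pm

# anchor masses, quoted in pN·ps²/Å as is conventional for these systems
cases = [
    ("titin I27, N-C pulling", 41.0, 2.6),
    ("e2lip3, N-41 pulling", 44.0, 1.8),
    ("ubiquitin, N-C pulling", 34.0, 2.6),
    ("ubiquitin, 48-C pulling", 34.0, 1.6),
]

print("mass conversions: 262 Da ->", round(pm.mass_to_force_units(262.0)),
      "pN*ps^2/A;  206 Da ->", round(pm.mass_to_force_units(206.0)), "pN*ps^2/A")
print()
for name, mass_pn, v_c in cases:
    f = pm.unfolding_force(v_c, mass_pn=mass_pn)
    print(f"{name:28s} M = {mass_pn:.0f} pN*ps^2/A, v_c = {v_c} A/ps -> F_unfold = {f:.0f} pN")

print()
cap = pm.theoretical_max_force(1.0, mass_pn=41.0)
print(f"force cap at V_target = 1.0 A/ps with M = 41: 2*M*V = {cap:.0f} pN")
print(f"distance explored per 100 fs pulse at 1.0 A/ps: "
      f"{pm.per_pulse_displacement(1.0, 100.0):.1f} A")
# The F_unfold values are the unfolding forces implied by each geometry's
# critical velocity; the cap is the largest force a single pulse can apply.
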