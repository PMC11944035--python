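"""Unloading-induced swelling of one cervical disc.

Solves the Donnan load-height equilibrium for the C2-C3 disc at its 1 g
axial load and at its microgravity-float load, and prints the resulting
height ratio, swelling pressure and compartment water fractions. The jump
in height and water content between the two loads is the osmotic swelling
that spinal unloading permits.
"""

from cervdisc import load_reference_table, partition_water_content, solve_equilibrium

ref = load_reference_table()[0]  # C2-C3
print(f"disc {ref.level.value}: A0={ref.A0} mm^2, h0={ref.h0} mm, c0F={ref.c0F_NP} mol/m^3")

for label, force in [("1 g neutral stance", 91.83), ("0 g neutral float", 21.5)]:
    sol = solve_equilibrium(force, ref)
    phi_np, phi_af, phi = partition_water_content(sol.r, ref)
    print(
        f"{label:20s} F={force:7.2f} N -> r={sol.r:.4f}  h={sol.r * ref.h0:.3f} mm  "
        f"Fs={sol.Fs:.1f} kPa  phi_NP={phi_np:.3f}  phi_AF={phi_af:.3f}"
    )

print(
    "\nLower axial load -> higher equilibrium height ratio, lower swelling\n"
    "pressure, and wetter NP/AF: the disc swells until the diluted fixed\n"
    "charges balance the remaining load."
)
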