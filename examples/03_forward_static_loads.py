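"""Forward quasi-static load estimates for the packaged postures.

Uses the transparent posture load model (supported weight resolved by disc
tilt, an equivalent-extensor term, and a constant co-contraction offset)
instead of the packaged reference loads. Absolute agreement with a full
inverse-dynamics engine is not claimed; orderings and signs are.
"""

from cervdisc import disc_loads, packaged_scenario

for name in ("nbp1g", "sm0g", "nbp0g"):
    loads = disc_loads(packaged_scenario(name))
    print(f"{name}:")
    for load in loads:
        print(f"  {load.level.value}  compression={load.compression:7.2f} N  shear={load.shear:7.2f} N")

print(
    "\nAt 1 g compression grows cranio-caudally with anterior (negative)\n"
    "shear; in microgravity only the co-contraction offset remains and\n"
    "shear vanishes."
)
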