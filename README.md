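# cervdisc

Cervical intervertebral-disc mechanics under gravitational unloading.

Astronauts lose the axial load on their spine in microgravity; cervical
discs imbibe water, swell, and the altered load path is a suspected driver
of the elevated cervical disc-herniation risk after spaceflight. `cervdisc`
is a small, fully testable pipeline for studying that mechanism at the
lumped-parameter level:

* an **osmotic swelling model** of the disc: ideal Donnan equilibrium of the
  fixed negative matrix charges (glycosaminoglycans) against a physiological
  salt bath, with nucleus pulposus (NP) and annulus fibrosus (AF)
  compartments, and a solver for the load–height equilibrium;
* a **piecewise-linear ligament model** (ALL, PLL, LF; two cervical regions)
  with cadaveric stiffness values and a failure-threshold annotation;
* a **quasi-static posture load model** — a transparent stand-in for a
  commercial inverse-dynamics engine — mapping joint angles and a gravity
  factor to per-level disc compression and sagittal shear;
* **synthetic-data generators** (perturbed disc populations, random
  postures, noisy water-content observations) and recovery of the
  unmeasured NP fixed charge density from load/water-content pairs;
* a **reporting stage** that contrasts three reference posture scenarios —
  relaxed standing at 1 g (`nbp1g`), the same stance in microgravity
  (`sm0g`), and the neutral microgravity float with 24° neck flexion
  (`nbp0g`) — reproducing the published per-level contrast tables cell for
  cell, with known internal inconsistencies flagged rather than corrected.

## The model

With height ratio `r = h/h0`, the tissue volume scales as `r³`, so the
fixed charge density dilutes and the water fraction rises:

    cF(r)  = c0F · φ0 / (φ0 + r³ − 1)
    φ(r)   = (φ0 + r³ − 1) / r³
    Fs(r)  = R·T·( √(cF² + 4c*²) − 2c* )          (ideal Donnan pressure)

Each compartment (NP: area fraction 0.4, reference water 0.80; AF: 0.6,
0.75, fixed charge 0.8× NP) applies these with its own parameters; the
disc pressure is the area-weighted mixture, and `φ = 0.4·φ_NP + 0.6·φ_AF`
holds exactly. Equilibrium under an axial force F solves `Fs(r)·A0 = F` by
bracketed bisection on the strictly monotone residual. Ligament force is
`k(ε) · (ε − ε_slack)/100 · L0` with strain-dependent stiffness from the
cadaveric table. Defaults: `R = 8.3144 J K⁻¹ mol⁻¹`, `T = 310.15 K`,
`c* = 150 mol m⁻³`, `c0F = 250 mol m⁻³` (configurable; see
`docs/methods.md`).

## Worked example

```bash
python examples/01_swelling_equilibrium.py
```

```
disc C2C3: A0=380.0 mm^2, h0=3.1 mm, c0F=250.0 mol/m^3
1 g neutral stance   F=  91.83 N -> r=0.9642  h=2.989 mm  Fs=241.7 kPa  phi_NP=0.777  phi_AF=0.721
0 g neutral float    F=  21.50 N -> r=1.1917  h=3.694 mm  Fs=56.6 kPa  phi_NP=0.882  phi_AF=0.852
```

Dropping the C2-C3 axial load from its 1 g value (91.83 N) to its
microgravity-float value (21.5 N) lets the disc swell from 96% to 119% of
its reference height: the swelling pressure falls from 242 kPa to the
57 kPa needed to carry the remaining load, and both compartments get
wetter. The other scripts in `examples/` cover the reference contrast
tables, the forward posture load model, fixed-charge-density recovery, and
ligament failure margins, e.g.:

```bash
python examples/02_reference_contrasts.py
```

```
neutral float (0 g) vs relaxed standing (1 g):
  compression  C2C3: -76.6%  C3C4: -74.7%  C4C5: -74.7%  C5C6: -74.8%  C6C7: -75.7%  C7T1: -77.1%
  height       C2C3: +1.6%  C3C4: +2.6%  C4C5: +2.2%  C5C6: +4.8%  C6C7: +1.9%  C7T1: +2.7%
  ...
  shear direction changes at: C6C7, C7T1
```

A thin CLI wraps the same pipeline:

```bash
cervdisc run --scenario nbp1g --out out/
cervdisc compare nbp1g nbp0g --out contrast.csv
cervdisc simulate --seed 1 --subjects 10 --out synthetic/
```

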