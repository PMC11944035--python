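# Methods

## Scope and structure

`cervdisc` models the quasi-static mechanics of the six cervical
intervertebral discs (C2-C3 … C7-T1) as lumped elements: each disc is a
cylinder-like element of cross-sectional area `A` and height `h` (volume
`h·A`), with a nucleus pulposus (NP) core occupying a fixed fraction of the
area and an annulus fibrosus (AF) ring around it. There is no spatial
resolution inside a disc and no time dependence: every computed state is an
equilibrium.

The pipeline has two distinct operating modes, kept strictly separate in
the outputs' metadata:

* **paper mode** — all per-level loads, geometry and water contents come
  from the packaged reference tables (the published study conditions), and
  the reporting stage only derives contrasts from them. This is the exact,
  reproducible path.
* **forward mode** — loads come from the package's own quasi-static posture
  model and disc states from the swelling solver. This path is labeled
  experimental: it preserves orderings, signs and scalings, but no claim is
  made that it reproduces the absolute output of a full inverse-dynamics
  engine with muscle-recruitment optimization, which is what produced the
  reference load tables.

## Osmotic swelling model

Assumptions: ideal Donnan equilibrium (unit activity and osmotic
coefficients), a monovalent salt bath, isotropic volume scaling with the
height ratio (`V/V0 = r³`, `r = h/h0`), incompressible solid phase, and a
single height ratio shared by NP and AF (rigid endplates). Under these, the
fixed charge density dilutes as water is imbibed,

    cF(r) = c0F · φ0 / (φ0 + r³ − 1),        valid for r³ > 1 − φ0,

the water fraction follows the same bookkeeping, `φ(r) = (φ0 + r³ − 1)/r³`,
and the swelling pressure is

    Fs(r) = R·T·(√(cF(r)² + 4c*²) − 2c*).

The pressure expression is the standard ideal Donnan form: it is the only
reading of the model consistent with units and with `Fs → 0` as `cF → 0`.
Compartments: NP area fraction 0.40, AF 0.60; AF reference fixed charge
0.80× the NP value; reference water fractions 0.80 (NP) and 0.75 (AF).
Because the water-content update is linear in `φ0`, the area-weighted
combined fraction equals the update applied to the combined reference
fraction (0.77) exactly; this identity is asserted to 1e-12 in the tests.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| R | 8.3144 | J K⁻¹ mol⁻¹ | gas constant |
| T | 310.15 | K | body temperature |
| c* | 150 | mol m⁻³ | physiological saline around the disc |
| c0F (NP) | 250 | mol m⁻³ | no measured value accompanies the reference geometry; 250 is a typical healthy-disc magnitude, and the recovery routine (below) fits it from data |
| NP area fraction | 0.40 | – | cadaveric cross-section data |
| AF/NP FCD ratio | 0.80 | – | experimental compositional data |

All are exposed through `OsmoticConstants`, `DiscReference` and the YAML
config (`osmotic.*`, `disc.*`).

### Equilibrium solver

`solve_equilibrium` finds `r` with `Fs(r)·A0 = F` by bisection on the
bracket `((1 − φ0_AF)^{1/3}(1+1e-6), 3.0)`. The residual is strictly
monotone, so the root is unique and bisection cannot fail inside the
bracket; the solver reports the iteration count and the force residual
(tolerance 1e-10 relative to max(F, 1 N)). Choices worth stating:

* **Reference area in the balance.** The published deformed areas do not
  follow any single function of height, so the deformed area is treated as
  an independent observable and the load balance uses `A0`. A config switch
  (`solver.area_mode`) reserves the alternative; only `reference` is
  implemented as the default behavior.
* **Zero load has no finite root.** `Fs > 0` for all finite `r`, so free
  swelling only equilibrates in the `r → ∞` asymptote; the solver raises a
  bracketing error that reports the attainable force interval instead of
  returning a spurious root. The upper bracket edge 3.0 (water fraction
  ≈ 0.99) is far beyond physiological swelling.
* **Vectorized path.** `solve_equilibrium_many` runs 80 fixed bisection
  halvings on arrays of forces (bracket width < 1e-23), used by the
  calibration and Monte-Carlo loops.

## Ligament model

ALL, PLL and LF are piecewise-linear springs with region-specific stiffness
(C2-C5 and C5-T1), one tabulated segment per region; force is
`k(ε)·(ε − ε_slack)/100·L0` with stiffness selected by segment, clamped
outside the table and linearly interpolated across gaps, which keeps the
force continuous and non-decreasing. Two quantities the stiffness table
does not provide are explicit modeling choices: the reference length
(default 20 mm per region) and the slack strain (default 0). Published
per-ligament totals are therefore treated as *calibration targets* — the
model exposes the uniform regional strain that reproduces each total — and
never as forward predictions. The failure annotation compares totals
against cadaveric failure loads (ALL 494 N, PLL 462.9 N, LF 315.8 N). The
LF C5-T1 strain range is stored in ascending order (75.3–101.5%); the
source table prints it reversed.

## Quasi-static posture loads

Per level: supported weight `W = g0·(head + cervical segments above)` times
the gravity factor, resolved by the level's sagittal tilt into compression
`W·cosθ` and shear `−W·sinθ` (positive shear = posterior); plus an
equivalent-extensor compression `W·d/a` balancing the gravitational flexion
moment (CoM lever `d` = 20 mm anterior offset + CoM height × sin(neck
flexion); moment arm `a` = 40 mm); plus a constant co-contraction offset
(default 30 N) standing in for baseline muscle tone — this is what makes
microgravity disc compression nonzero, and its value was chosen so 0 g
compressions sit in the 20–45 N band of the reference tables (a documented
tuning constant, not a prediction). Baseline tilts decline linearly from
10° (C2-C3) to 5° (C7-T1); neck flexion shifts all levels uniformly.
Anthropometry defaults to a 72 kg subject with a 6.94% head-mass fraction
and 0.15%-of-body-mass cervical increments per level. The model is linear
in the gravity factor (co-contraction aside) and frame-consistent
(`compression² + shear² = W²` with muscle terms off) — both are tested
properties, and both would be destroyed by any attempt to also match the
reference engine's absolute values, which is why that is out of scope.

## Synthetic data and recovery

* **Disc populations**: `A0` and `h0` are multiplied by independent
  mean-preserving lognormal factors with configurable CV (default 5%, a
  plausible inter-subject spread); lognormal keeps the geometry positive so
  every draw satisfies the reference-table invariants.
* **Water-content observations**: Gaussian noise (default sd 0.005, i.e.
  half a percentage point — the precision of the reference tables) added to
  the model fractions; out-of-(0,1) draws are resampled, not clipped, to
  avoid boundary point masses.
* **Recovery of c0F**: for a candidate value, each observed load is solved
  to a height ratio and predicted NP/AF fractions; the sum of squared
  errors is minimized over a bounded scalar search (scipy
  `minimize_scalar`, xatol 1e-4). The map from c0F to predicted water
  content at fixed load is strictly monotone, so the fit is unique.
  Noiseless data recovers the generating value to well under 0.1%; at
  noise sd 0.005 with 50 observations, the relative RMSE over 100
  replicates is ~0.3%. All-zero loads are rejected as non-identifiable
  (the free-swelling state carries no FCD information through this model).

What the generators do *not* emulate: real measurement error structure
(MRI-derived water contents are biased, not i.i.d. Gaussian), inter-level
parameter correlation within a subject, and any longitudinal adaptation.
Passing recovery tests therefore demonstrate the pipeline's internal
consistency, not field accuracy on imaging data.

## Reporting stage

Contrast rows carry the raw values, the difference, the relative change in
percent, and the ratio in percent (published tables use both conventions:
compression contrasts between the two microgravity postures are printed as
ratios, nearly everything else as relative changes). Two numerical
conventions matter for cell-exact reproduction:

* **Decimal percent arithmetic.** Relative changes are computed in decimal
  arithmetic on the shortest representation of the inputs, so table values
  produce exact ties (0.80 → 0.87 is exactly 8.75%) rather than
  binary-float near-ties.
* **Half-even rounding.** Printed percentages are reproduced with 1-decimal
  round-half-even (banker's) rounding; it is the only mode consistent with
  both tie cells that occur (6.25 → 6.2 and 8.75 → 8.8).
  Half-away-from-zero is available as an option.

Volumes are always recomputed as `h·A`; the shipped volume value is kept
alongside and a flag raised where the two disagree (one cell: the standing
0 g C5-C6 volume, 2814.4 vs 2818.4 mm³). A packaged discrepancy table
lists every cell of the reference report that cannot be recomputed from
its own state tables — the entire upright-0g-vs-neutral-0g geometry
contrast block (18 cells), one LF ligament percentage (3.9 printed vs 4.0
recomputed), the summary's "average 76.6%" compression reduction (the
per-level mean is 75.6%; 76.6% is the C2-C3 value), and the
residual-scale muscle-force table. Flagged rows emit both the printed and
the recomputed value; nothing is silently corrected. The shear contrasts
printed as huge percentages at the two caudal levels (2011.1% and 1175.9%)
are exact relative changes off small references (0.09 N and 0.29 N) and
reproduce without flags.

## Problem sizes and determinism

The acceptance script checks the solver against a 10⁶-point grid scan on
100 randomized parameter/force instances and runs the recovery study with
100 replicates × 50 observations; both are vectorized and complete in
seconds. Report generation is pure (same inputs, byte-identical CSV); all
stochastic components draw from explicitly seeded `numpy` generators and
no global random state is touched.

## Known limitations

* Equilibrium-only: no poroelastic creep, no permeability, no time course
  of in-flight adaptation.
* Ideal Donnan: no activity/osmotic coefficients; pressures at high FCD are
  upper-bound-ish.
* The forward load model deliberately omits individual muscles,
  out-of-sagittal loads and recruitment optimization.
* The per-scenario reference water contents vary by level in ways the
  two-parameter reference table cannot generate; they are stored verbatim
  per scenario, and the calibration helper quantifies (but does not
  assert) the per-level parameters that would be needed.
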