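# Methods

`phostim` simulates, at desk scale, the chain of reasoning that links
volume-conductor models of transcranial alternating-current stimulation
(tACS) to phosphene thresholds: if simulated current densities reflect real
current flow, montages that deliver more current to the retina should
elicit phosphenes at lower stimulation amplitudes. The package builds
synthetic head phantoms, solves the quasi-static current-injection problem,
summarizes retinal / visual-pathway current densities, simulates the
psychophysical threshold protocol over synthetic observer cohorts, and runs
the corresponding statistical battery.

## Volume-conductor model

The forward problem is the quasi-static approximation ∇·(σ∇φ) = 0 with
insulating (homogeneous Neumann) boundary except at the electrodes.
Capacitive and frequency-dependent effects are neglected; the 16 Hz
stimulation waveform enters only through its amplitude. Conductivities are
isotropic per tissue.

Two electrode boundary conditions are implemented, mirroring the two
modelling traditions:

* **Point-injection Neumann mode** ("compartmental-eye model" default):
  the stimulation current I is split equally across the exposed outer
  nodes of each electrode's electrolyte layer (4 mm thick, 1.4 S/m).
* **Complete electrode model** ("coarse-eye model" default): a 5 mm,
  1.5 S/m electrolyte layer topped by an ideal conductor at one unknown
  potential per electrode, coupled to the exposed electrolyte faces
  through a contact impedance, with the total current per electrode
  constrained to ±I. The literature gives the electrode impedance as a
  lumped 10 kΩ; we convert it to a surface impedance z = R·A over the
  patch contact area A so the lumped resistance of the whole electrode is
  exactly R. The z → 0 limit reproduces an equal-potential-patch (shunt)
  model; z → ∞ approaches pure current injection with a growing contact
  voltage drop — both limits are tested.

### Discretization

Every conducting voxel of the phantom is a trilinear 8-node hexahedral
element with 2×2×2 Gauss quadrature (exact for this integrand); element
stiffness is σ·h·K₀ with K₀ the unit-cube matrix, verified in the tests
against symbolic integration. The assembled system is symmetric positive
semi-definite with the constant vector as nullspace; the load vector sums
to zero. It is solved with Jacobi-preconditioned conjugate gradients to a
relative residual of 1e-8 (max 10⁴ iterations), and the gauge is fixed
afterwards (zero-mean by default, pinned node optional) — the gauge cannot
affect the current density. Per-element current density is J = −σ∇φ from
the trilinear shape-function gradients at the element center, stored in
A/m² and reported in mA/m².

Conservation is checked algebraically: for a node set S, Σ_{i∈S}(Kφ)_i
equals the branch current crossing the cut around S, so any region
containing exactly one electrode must emit ±I and any electrode-free
region zero, up to the solver residual.

### Validation against closed-form series

The solver's ground truth is the Legendre-series solution for two point
electrodes on a homogeneous or N-layer concentric sphere (insulating
elsewhere). The homogeneous series is classical:

φ(r, γ) = I/(4πσR) Σ_{l≥1} (2l+1)/l (r/R)^l [P_l(cos γ_A) − P_l(cos γ_B)].

The layered solution expands each layer as A_l r^l + B_l r^{−l−1} per
degree, propagating coefficients inner→outer through a transfer-matrix
recursion that enforces continuity of φ and σ∂φ/∂r, regularity at the
center, and the surface Neumann source. Default truncation is degree 120
with a tail-ratio stopping criterion of 1e-8; radii are normalized by the
outer radius for conditioning.

The acceptance-level comparison uses a three-layer scalp/skull/brain
sphere (0.43/0.01/0.33 S/m). Shell radii are 92/84/76 mm so every shell
is resolved by at least four elements at the 2 mm production spacing —
with the default head's 6 mm skull (three elements) the thin resistive
shell is under-resolved and the global error rises above the 5% target.
Point electrodes sit at the poles; a 10 mm exclusion zone around each
removes the point-vs-node modelling mismatch from the error norm.
Measured relative L2 error: 4.1% at 2 mm, 2.9% at 1.5 mm.

## Phantoms

The default phantom is a four-shell sphere (scalp 92, skull 86, CSF 80,
brain 78 mm — adult averages) with mirror-symmetric compartmental eyes and
an optional torso cylinder (radius 100 mm, length 120 mm, joined through a
35 mm neck of scalp-conductivity tissue) carrying the right-shoulder
electrode point. Grids are RAS-oriented, voxel ownership by center point,
built symmetric about x = 0 so mirror-symmetric configurations are
voxelwise mirror-symmetric. Default spacing is 2 mm; 1 mm is supported.

Each eye (radius 12 mm, center ±31, 70, −12 mm, corneal pole ~2.5 mm
beneath the scalp surface — eyes sit directly under the thin lids) is a
sphere whose outer element layer splits into cornea (45° cap about the
optic axis), retina (posterior semi-shell — the computational proxy for
the retina) and sclera; the interior holds lens, aqueous and vitreous
humor; an optic nerve cylinder (2.5 mm radius) runs from the posterior
pole toward the head center, overwriting the retina at the optic disc and
carving the optic canal. The optic axis defaults to radially outward
through the eye center: on a spherical head that is where the overlying
scalp opening sits, so the cornea faces the surface and the nerve leaves
toward the interior, self-consistently.

Because a 24 mm eyeball cannot fit inside a 6 mm spherical scalp shell,
an orbital cavity (eye radius + 4 mm) is carved through the shells before
embedding, and the bony socket is then rebuilt (`seal_orbit_posterior`):
every non-eye voxel within eye radius + 12 mm of the eye center at or
below the outer skull radius becomes skull, except a 4 mm soft sleeve
over the superficial eye hemisphere (the lids/conjunctiva). Each eye is
thus bone-encased except its scalp-side opening and the optic-nerve
canal. This matters quantitatively: a plain soft-tissue cavity leaves a
wide low-resistance opening through the skull, and because the eyeball
itself is large and highly conductive, *every* montage then funnels its
trans-skull current through the retina, inverting the expected montage
ordering of retinal current density (distant montages beat the near
Fp2-So pair). The bone floor — in a real head, orbital bone and
air-filled sinuses — removes that shortcut; with it, the suborbital
electrode placed infraorbitally (directly below the orbit, at the eye
center's azimuth), the Fp2-So montage delivers the highest mean eye and
retinal current densities and Cz-F8 the lowest, matching the qualitative
ordering the threshold experiments imply.

The conductivity presets follow the two modelling traditions: the
coarse-eye preset (scalp 0.43, CSF 1.79, brain 0.33, skull 0.01,
electrode 1.5, homogeneous eye incl. optic nerve 0.4 S/m) and the
compartmental preset (white matter 0.14, gray matter 0.33, CSF 1.79,
skull 0.014, scalp 0.33, vitreous humor 1.55, lens 0.32, aqueous humor
1.8, retina 0.7, sclera 0.56, cornea 0.5, optic nerve 0.03, muscle 0.35,
fat 0.04, electrode 1.4 S/m). An extra "orbit" tissue (0.43 / 0.35 S/m
respectively) parameterizes the carved cavity. Aliases map merged tissues
(e.g. every eye compartment → the homogeneous eye under the coarse
preset) so one phantom serves both presets.

### Electrode placement

10/20-style positions are fixed spherical angles (documented in
`TEN_TWENTY_ANGLES`): the circumferential ring (Fp2, F7/F8, O2, …) on the
z = 0 equator, Cz at the vertex, the suborbital position directly below
the right orbit (the eye center's azimuth, 25° below the ring), and the
right shoulder on the lateral torso surface.
A patch is the set of outer-surface voxels within straight-line (chord)
distance √(900/π) ≈ 16.93 mm of the patch center — for patches much
smaller than the local curvature radius the chord metric is within ~1% of
the geodesic one, and one rule serves both the spherical scalp and the
cylindrical shoulder (we use equal-area geodesic discs rather than
geodesic squares; the electrode's 900 mm² footprint, not its shape, is
what the physics sees at this resolution). Patch area is measured as the
magnitude of the vector sum of exposed face areas (the staircase
artifacts cancel in the vector sum) and lands within 10% of 900 mm².
Electrolyte voxels are extruded outward through exposed faces to the
mode's default thickness.

## Threshold staircase

The three-step protocol operates on a 25 µA grid:

1. ascending 50 µA steps from 50 to 500 µA; the first detected intensity
   is the reference (none ⇒ the record is invalid);
2. reference −25/+25/+50 µA, twice each; the lowest intensity detected
   both times carries forward (nothing detected twice ⇒ fall back to the
   reference, flagged — a branch the protocol description leaves open);
3. refined −25/0/+25 µA, three 16 Hz bursts each in randomized order plus
   one 5 Hz catch burst per intensity (logged, never counted); the
   threshold is the lowest intensity detected in ≥2 of 3, else
   refined + 25 flagged invalid.

Observers are psychometric models: detection probability
p = gate(f) · [(1−lapse)·Ψ((I−θ)/s) + fp·(1−Ψ)] with Ψ the normal CDF,
θ the true threshold (µA), s the spread (s = 0 ⇒ step function), and a
frequency gate of 0 at the 5 Hz control frequency by default. For
deterministic observers the protocol provably returns 25·⌈θ/25⌉ µA
(floored at 50) for every θ ∈ [26, 500] — the exhaustively tested
quantization law. Burst timing and inter-stimulus intervals do not enter
the computation.

## Synthetic cohorts

Cohorts default to n = 15 subjects across the seven montages. Two modes:

* **direct**: per-montage thresholds drawn from Normal(mean, SD) truncated
  to [30, 450] µA (defaults: the packaged per-montage threshold table,
  e.g. 95 ± 33 µA for F7-F8). The truncation keeps every true threshold
  inside the protocol's ~[50, 525] µA dynamic range; note it also shifts
  the population mean slightly upward (to ≈97 µA for the F7-F8 numbers),
  which the tests account for via the truncated-normal oracle.
* **coupled**: one retinal current-density threshold per subject, with
  per-montage thresholds θ_m = d/c_m where c_m is the montage's simulated
  mean retinal density per mA. The density distribution is scaled so the
  reference montage (F7-F8) reproduces its stated 95 ± 33 µA law; montages
  with stronger retinal coupling then get lower thresholds by
  construction, which is the idealized form of the negative
  density-threshold relationship the pipeline is meant to recover.

Montage order is permuted per subject and logged; each subject × montage
staircase runs on its own RNG substream of the master seed, so order
cannot leak into responses. Eye dominance is generated as a label with no
threshold effect by default (an effect-size knob exists for power
exploration).

What the generator does *not* emulate: between-day adaptation, subject
dropout, inter-montage threshold correlations beyond the shared retinal
density, reporting biases, or any cortical contribution to phosphene
generation. Passing pipeline tests therefore show that the machinery
recovers the relationships *built into* the generator through the full
staircase quantization and statistics — not that those relationships hold
in any particular human cohort.

## Regions of interest and retinal maps

ROIs are geometric stand-ins defined once: eye surface (outer element
layer of each eyeball, optic nerve excluded), retina (posterior semi-shell
elements), occipital cortex (brain voxels in a posterior cap, 30°
half-angle, outer 45% shell — the inner-radius floor keeps it disjoint
from the LGN stand-in), and LGN (5 mm ball at ±12, −18, 0 mm). ROI means
are volume-weighted (arithmetic for uniform voxels), reported in mA/m²
and per mA injected.

Retinal topography bins retina elements into 4 quadrants × 2 eccentricity
rings (central within 30° polar angle of the posterior pole — the
published figure's degree ranges are internally inconsistent, so the
boundary is our own, configurable). The visual-field version flips both
quadrant axes relative to the retinal version, because the eye's optics
invert the image; the flip is tested with a single hot element.
Splitting current into normal vs tangential retinal components is out of
scope.

## Statistics

Friedman's two-factorial rank ANOVA (chi-square form with tie correction,
optional exact within-row permutation null for small matrices), Wilcoxon
signed-rank post hocs (zero differences dropped, average ranks over tied
magnitudes, exact tie-aware null by dynamic programming for n ≤ 20,
Bonferroni factor defaulting to the number of comparisons performed),
Mann-Whitney U for the eye-dominance contrast, one-tailed Spearman rank
correlations (exact full-permutation p for n ≤ 8, t approximation above)
with the density correlations tested toward the negative tail for
eye/retina and the positive tail for the occipital cortex, and Pearson
regression for the density and electrode-distance relationships (the
suborbital–shoulder montage is excluded from the distance analysis, as in
the reference analysis, because its eye and occipital densities are
outliers by construction). Ties always get average ranks. Every exact
p-value is cross-checked in the tests against brute-force enumeration.

The published rank correlation of 0.929 between visual-pathway densities
and thresholds cannot be reproduced from the printed table with
average-rank ties under any hemisphere choice we tried; the package
displays its own recomputed values and does not assert that number.

## Problem sizes and runtime choices

Production resolution is 2 mm (≈0.9 M nodes with torso; one montage solve
≈500 CG iterations). The seven-montage coupling table, the FEM-vs-series
validation at 2 mm and 1.5 mm, and 200 replicate simulated studies
(n = 15, psychometric spread 10 µA) together define the test-suite
workload; all are deterministic given the seed. The acceptance script
runs only the staircase-recovery computation (501 observers) and is
seconds-fast.

## Known limitations

* Spherical-shell anatomy: no gyri, no realistic orbit shape, no foramen
  magnum (head and torso connect through scalp tissue only).
* The coarse-eye ("brain-model") physics runs on the same hexahedral
  grid as the compartmental model; tetrahedral meshing is out of scope,
  so the two models differ only in boundary condition and conductivity
  preset. Absolute density magnitudes are therefore not comparable to
  MRI-derived models — only per-montage orderings and ratios are
  meaningful, which is why the published table values are shipped as
  checksummed fixtures rather than regeneration targets.
* Pure Neumann loads on single nodes make the potential singular at the
  electrode in the continuum limit; validation excludes 10 mm around
  electrodes.
* Anisotropic conductivity and capacitive effects are not modelled.
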