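# Methods

## Constitutive model

The tissue is modelled as an incompressible, hyperelastic solid: a Yeoh
isotropic matrix reinforced by two fiber families lying in the
circumferential–longitudinal plane. With the unimodular right
Cauchy–Green tensor C̄ (J = det F ≡ 1), the strain-energy density is

    Ψ = Σᵢ₌₁³ aᵢ (Ī₁ − 3)ⁱ + Σⱼ₌₂⁴ cⱼ (Ī₄ − 1)ʲ + Σₖ₌₂⁴ eₖ (Ī₆ − 1)ᵏ   [Pa]

where Ī₁ = tr C̄ and Ī₄ = a·C̄a, Ī₆ = g·C̄g are the squared fiber
stretches along a = (cos β₁, sin β₁, 0) and g = (cos β₂, sin β₂, 0). The
polynomial orders are fixed (isotropic 1..3, fiber 2..4, eleven
coefficients in total); starting the fiber sums at power two makes the
fiber stress vanish smoothly at Ī = 1 and keeps the reference state
stress-free without a tension-only switch.

### Uniaxial solution

Uniaxial tension along in-plane axis d gives C̄ = diag with λ² on the
loading axis and λ⁻¹ transversely. Writing S̃ = 2∂Ψ/∂C̄, the total stress
is S = S̃ + p C̄⁻¹; the multiplier p is fixed by the traction-free
out-of-plane condition S₃₃ = 0, which yields the closed form

    S_axial = S̃_axial − S̃₃₃ λ⁻³

with S̃_axial weighting the fiber terms by cos²β (circumferential pull) or
sin²β (longitudinal pull), and S̃₃₃ purely isotropic because both families
are in-plane. Cauchy and engineering stress follow as σ = λ²S and
P = λS. An alternative denominator convention (3λ³ instead of λ³) is
retained behind the `legacy_denominator` flag purely for sensitivity
analysis: it does not satisfy the S₃₃ = 0 elimination and does not reduce
to the classical incompressible Yeoh closed form, so it is off by
default.

Because only the out-of-plane traction is set to zero while the
transverse stretches are constrained equal, an in-plane transverse
residual S₂₂ generally remains; this is an assumption of the model class,
not of this implementation.

### Numerical choices

- The invariant excesses are computed from λ²−1 and λ⁻¹−1 directly, so
  all stresses are exactly zero at λ = 1 (no round-off residue from
  cos²β + sin²β).
- The 0⁰ convention (Ī₁−3)⁰ ≡ 1 applies to the first isotropic term, so
  a₁ acts neo-Hookean-like at the reference state and the model reduces
  to known closed forms.
- Fiber terms are evaluated as written for Ī₄, Ī₆ < 1 (contracted
  fibers); since the sums start at power two the contribution near the
  reference state is second-order small.
- Angles are stored in degrees and converted internally; the fiber
  direction enters only through its dyadic square, so β and β+180° are
  identical and canonicalization maps angles into [0°, 180°) and orders
  the families by angle (`canonicalize`), removing the label-switching
  degeneracy without changing any stress.

The test suite verifies the closed form against an independent oracle
that finite-differences the energy and solves S₃₃(p) = 0 numerically
with an explicit Lagrange multiplier (1e-6 relative over random
parameter sets, λ ∈ [0.9, 1.3]).

## Parameter identification

Calibration is a two-objective minimization of the normalized errors

    Ec = Σ(σ_ce − σ_cm)² / Σσ_ce²,   Et = Σ(σ_te − σ_tm)² / Σσ_te²

over the eleven coefficients, solved with an in-package real-coded
NSGA-II (fast non-dominated sorting, crowding distance, binary
tournament, SBX crossover η = 15, polynomial mutation η = 20, mutation
probability 1/11). All randomness flows through one integer-seeded
generator; identical seeds give bit-identical fronts.

Defaults and rationale:

- **Population 200, generations 300** (defaults; the validation suite
  uses 80–100 × 100–150, which converges on the synthetic recovery task
  in well under a minute per run on one CPU).
- **Bounds**: ±10⁷ Pa for coefficients, [0°, 180°) for angles — about two
  orders of magnitude around the published coefficient scale; override
  per coefficient in `FitConfig`. Recovery studies use sign-preserving
  multiplicative bounds (truth × [0.1, 10], `bounds_around`).
- **Aggregation**: with several specimens per direction the default pools
  every sampled point ("pooled-points"); a "mean-curve" mode interpolates
  the specimens onto a common grid and fits their average instead. Which
  of the two an experimentalist wants depends on whether specimen-level
  scatter should weight the fit; both are exposed because neither is
  canonical.
- **Objective stress measure**: engineering stress by default; true
  stress selectable, since published comparisons use both conventions.
- **Balanced solution**: the front member minimizing max(Ec, Et), ties
  broken by smaller Ec+Et, then input order. "Balanced" is otherwise
  underspecified; minimax is reproducible and symmetric in the two
  directions.

The `HyperelasticCurveFitter` estimator exposes the same fit through a
scikit-learn interface (X = [strain, axis] rows, y = stress in Pa) so it
composes with sklearn tooling; `run_moo`/`select_balanced` are the
functional equivalents.

No gradient refinement follows the GA, and no uncertainty quantification
of the coefficients is attempted.

## Synthetic data

The generator emulates the study conditions of the uniaxial experiment:

- **Geometry** (`sample_geometry`): truncated-normal draws (±3 SD,
  positive) of width, thickness and post-conditioning dimensions with the
  per-orientation means/SDs of the experimental specimen tables
  (circumferential width 10.1 ± 1.7 mm, post-conditioning length
  29.0 ± 2.6 mm, etc.); the die-cut 20 mm gauge length has no variance.
- **Curves** (`generate_curves`): model predictions on a uniform strain
  grid (default 0–20% strain, where tissue damage is not yet expected)
  times multiplicative Gaussian noise `1 + ε`, `ε ~ N(0, CV)` i.i.d. per
  point, clipped at zero stress. Multiplicative noise was chosen because
  experimental stress SDs grow roughly with the stress level; an additive
  model would overweight the toe region.
- **Load histories** (`generate_load_history`): four triangular
  preconditioning cycles to 7% of gauge length then a monotone ramp, at
  0.05 mm/s sampled at 30 Hz; force is the model engineering stress times
  the post-conditioning cross-section, with the ramp stretch referred to
  the post-conditioning length. The true onset index ships as metadata so
  detectors can be scored.

What it does **not** emulate — and hence what passing tests do not show
about real data: preconditioning hysteresis and other viscoelastic
effects (cycle force reuses the equilibrium model), stepper-motor
ripple, load-cell noise, specimen slippage, tissue tearing beyond 20%
strain, and inter-specimen correlation (synthetic specimens are
independent; real specimens from one animal are not).

## Load-record processing

1. **Smoothing**: sliding local least-squares quartic (Savitzky–Golay)
   on the force, window 31 samples (~1 s at 30 S/s) by default — wide
   enough to suppress stepping ripple, short against a ~28 s
   preconditioning half-cycle. A global quartic cannot represent cycles
   plus ramp, hence the local fit.
2. **Slope filtering**: numerical derivative followed by a zero-phase
   5th-order Butterworth low-pass. At 30 S/s the Nyquist frequency is
   15 Hz, so the cutoff is specified as a fraction of Nyquist (default
   0.5). Zero-phase (forward–backward) filtering is used so the onset
   index is not phase-shifted.
3. **Onset detection**: loading phases appear as sustained
   positive-slope runs; the onset is the start of the first run (slope
   above threshold for ≥ `hold` = 5 samples) after the final
   preconditioning unloading, i.e. run number `cycles`. The threshold
   defaults to 10% of the peak filtered slope. Time and load are zeroed
   there. On synthetic histories the detected onset is within a couple
   of samples of ground truth.
4. **Normalization**: strain = displacement past onset over the
   post-conditioning length; stress = force past onset over (minimum
   width at onset × thickness). N and mm in, Pa out. Curves pass through
   the origin exactly and are truncated at 20% strain by default.

The noise-free round trip (generator → pipeline → curve) reproduces the
generating model curve to ≲ 0.1% RMS; the validation threshold is 2%.

## Width tracking from frames

Frames are Otsu-binarized (polarity configurable for inverted-contrast
footage), specks below a configurable area removed, interior holes
filled, and the largest connected component taken as the specimen. Its
boundary pixels are split into four edge groups by the quadrant of their
centroid-relative offset normalized by the bounding-box half-extents
(ties go to the lateral groups, so the four groups always partition the
boundary). The per-row span between the left and right groups gives a
width profile; the minimum over rows, times the pixel scale, is the
reported width — on a waisted specimen this is the neck. Extension is
the change in top-to-bottom extent relative to the first frame; both
image-based extension and motor displacement are available, and the
choice between them is left to the user.

The synthetic renderer draws the incompressibly deformed silhouette
(length × λ, width × λ^(−1/2)) with Gaussian pixel noise and stores the
ground-truth width in metadata; tracked widths stay within 1–2 px of
truth across randomized geometry/stretch/noise/waist combinations. The
loading axis is assumed vertical in the frame; there is no lens
correction or full digital image correlation, and the pixel scale is a
single scalar.

## Validation problem sizes

The shipped validation suite uses: 100 random parameter sets for the
oracle equivalence; one noiseless 50-point curve per direction
(GA 100 × 150, one seed) and twenty 5%-noise curves per direction
(GA 80 × 100, three seeds, ≥ 2 must recover to 0.01) for parameter
recovery; one synthetic load history per orientation for the round trip;
and 50 randomized rendered frames for width tracking. These sizes were
chosen to exercise every failure mode while keeping a full run in a few
minutes on one CPU.

## Known limitations

- Uniaxial, incompressible, in-plane-fiber response only: no biaxial or
  shear modes, no volumetric penalty, no viscoelasticity, damage or
  residual-stress modelling, and no 3-D boundary-value solver.
- The identified coefficients are generally non-unique (the model is
  over-parameterized for two uniaxial curves); the Pareto front and the
  canonicalization remove only the discrete label degeneracy.
- Published coefficient sets are treated as a fixture for verifying the
  forward model, not as a fitting target: reproducing them exactly would
  require the original experimental curves.
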