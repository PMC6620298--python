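# Methods

## The physical problem

A slender cylindrical beam of collagen-1 seeded with contractile cells is
embedded-printed into a packed-microgel support medium. The cells pull on
the collagen network; depending on the beam's elastic modulus *E* and the
medium's small-strain shear modulus *G′* and yield stress *σ*<sub>y</sub>,
the beam either **buckles** into a sinusoidal undulation, **breaks up**
into short contracting segments, **contracts axially** while staying
straight, or **remains stable**. Each instability threshold doubles as a
gauge for the contractile stress a single cell generates inside the matrix.

## Mechanical models

**Buckling (beam on an elastic foundation).** Treating the medium as an
elastic continuum, the equilibrium of a laterally deflected beam under
axial load selects the wavelength

  λ = 2π (E I / G′)<sup>1/4</sup>,  I = πR⁴/4,

and the axial force sustaining an undulation of wavelength λ is
F(λ) = (4π²/λ²) E I + (λ²/4π²) G′, strictly convex in λ² with its minimum
at λ above. Substituting back gives the critical force
F<sub>b</sub> = R²√(πEG′) and critical stress σ<sub>b</sub> = √(EG′/π).
The "≈" often written with these two expressions is implemented as exact
equality, because substituting the optimal wavelength makes both terms of
F(λ) equal — an identity the brute-force minimiser
(`minimize_force_curve`: log-spaced grid bracketing, then bounded Brent
refinement with 1e-9 tolerance in log λ) verifies to 1e-6 relative in the
tests. Finite-length end effects are out of scope: the infinite-beam
sinusoidal mode is taken as ground truth, which is how the wavelength is
used downstream. The quarter-power makes λ weakly sensitive to the
moduli (doubling E or G′ moves λ by 2<sup>1/4</sup>−1 ≈ 19%) but linearly
sensitive to R; inverting λ to estimate E amplifies wavelength errors
fourfold.

**Break-up (energy balance in a yield-stress medium).** The stored strain
energy U<sub>s</sub> = (σ²<sub>int</sub>/E)πR²L₀ is balanced against the
cost of yielding microgel around N separating segments,
U<sub>y</sub> = σ<sub>y</sub>NπR²L₁, assuming the yielded hydrodynamic
volume equals the segment volume (factor 1, hard-coded; N·L₁ = L₀ is
enforced with a 5% relative tolerance when both are supplied). This gives
the failure stress σ<sub>f</sub> = √(Eσ<sub>y</sub>). A Griffith-style
variant with effective surface energy γ ≈ Rσ<sub>y</sub>/2 gives
√(Eσ<sub>y</sub>/π), uniformly 1/√π smaller; the energy-balance form is
the default everywhere downstream, the Griffith form is exposed for
comparison only.

**Axial contraction.** Intact stiff beams shorten by ε = ΔL/L₀ (observed
window 1–5%), with equilibrium σ<sub>cell</sub>φ = εE + σ<sub>y</sub>.
At the moduli and strains of the contraction window the elastic term εE
(0.01–0.5 Pa) is dominated by σ<sub>y</sub> (0.44–1.95 Pa). The forward
prediction of strain clamps negative values to zero — cells that cannot
overcome the medium's yield stress simply do not contract.

**Cross-model predictions.** Equating σ<sub>b</sub> and σ<sub>f</sub> at
equal E gives G′<sup>b</sup> = πσ<sub>y</sub><sup>f</sup> exactly; at the
triple point where break-up, contraction and stability meet, E = σ<sub>y</sub>
is predicted. Both are judged at a factor of two in the report's
consistency block, computed from whatever thresholds were estimated —
the observed default thresholds give σ<sub>y</sub><sup>f</sup>/E\* = 1.95
and G′<sup>b</sup>/σ<sub>y</sub><sup>f</sup> ≈ 1.74, inside the factor-of-two
band but below π; the package reports the computed ratio rather than any
remembered value.

## Stability classification

Fates compete, and the observed diagram is *not* reproduced by "lowest
critical stress wins": at the parameter values of interest
σ<sub>f</sub> < σ<sub>b</sub> nearly everywhere, yet soft media produce
buckling. Classification therefore applies ordered empirical rules:

1. φ < φ<sub>min</sub> → `undetermined` in buckling-permissive media
   (G′ < G′<sup>b</sup>, where buckling is hard to rule out), else `stable`;
2. L/D < aspect<sub>min</sub> → `stable`;
3. G′ < G′<sup>b</sup> → `buckled`;
4. σ<sub>y</sub> ≥ σ<sub>y</sub><sup>f</sup> → `stable`;
5. E < E\* → `breakup`;
6. otherwise `contracted`, unless L₀ ≥ L<sub>max</sub> (friction pins long
   beams) → `stable`.

Boundary inclusivity (G′ = G′<sup>b</sup> does not buckle; σ<sub>y</sub> =
σ<sub>y</sub><sup>f</sup> is stable; E = E\* contracts) is a convention,
chosen so the E = 1 Pa contraction case classifies correctly with
E\* = 1 Pa. Defaults: G′<sup>b</sup> = 3.4 Pa, σ<sub>y</sub><sup>f</sup> =
1.95 Pa, E\* = 1 Pa, φ<sub>min</sub> = 0.03, aspect<sub>min</sub> = 10,
L<sub>max</sub> = 30 mm (the friction limit is only bracketed between 1
and 30 mm by observation; the upper bracket is used).

**Calibration maps.** Both material calibrations are log–log
piecewise-linear through printed anchor pairs: E(c) through (0.5 mg/mL,
0.04 Pa), (1.0, 1.0), (1.5, 10.0); σ<sub>y</sub>(G′) through (0.46 Pa,
0.06 Pa) and (1.92, 0.25) — a near-proportional power law
σ<sub>y</sub> ≈ 0.130·G′<sup>0.999</sup>. Extrapolation beyond the anchors
uses the nearest segment's slope and warns: above 1.5 mg/mL no printed
modulus exists, and cohort media routinely exceed G′ = 1.92 Pa, so those
warnings are routine for synthetic cohorts and are filtered in the test
configuration. Users with measured σ<sub>y</sub> bypass the map entirely.

**Threshold estimation.** Each boundary is estimated as the log-midpoint
(geometric mean) between the extreme observations on its two sides — max
G′ among buckled vs. min G′ among non-buckled for G′<sup>b</sup>, and
analogously for σ<sub>y</sub><sup>f</sup> (failing vs. stable), E\*
(break-up vs. contracted below the yield boundary) and φ<sub>min</sub>
(non-buckled vs. buckled in soft media). Because per-beam threshold
jitter makes fates ambiguous near boundaries, a beam within a factor 1.5
of a *different* boundary (about 4 lognormal standard deviations at the
default jitter) is excluded when estimating a given one; without this, a
beam sitting at the φ<sub>min</sub> boundary that happens to be labelled
stable in a stiff medium at low σ<sub>y</sub> would corrupt the
σ<sub>y</sub><sup>f</sup> midpoint. Boundaries lacking data on either
side keep their defaults and are flagged in the output. The aspect and
length limits are never estimated (cohorts rarely vary them) and are
always flagged.

## Cell-stress estimators and the scaling fit

At the buckling threshold, φσ<sub>cell</sub> = √(EG′<sup>b</sup>/π); at the
break-up threshold, φσ<sub>cell</sub> = √(Eσ<sub>y</sub><sup>f</sup>); for
contracting beams, σ<sub>cell</sub> = (εE + σ<sub>y</sub>)/φ. Both
threshold estimators are homogeneous of degree ½ in E, so cohorts with
E-independent thresholds fit to an exponent of exactly 0.5. Pooled
estimates (all three methods, equal weight — the pooling choice is open
and this is the simplest) are fit by unweighted OLS of ln σ<sub>cell</sub>
on ln E; R² is reported in that same log–log space, the fit's native one.
Estimates at φ > 0.2 are flagged, not excluded: the modulus calibration is
unreliable for dense beams but the estimate is still defined. φ ≥ 0.64
(random close packing) is rejected outright.

## The synthetic cohort generator

No raw imaging data is deposited, so the pipeline is exercised on virtual
cohorts that encode the study conditions as defaults: 500 beams, radius
uniform over 25–100 μm, length 5 mm, collagen uniform over 0.5–2.5 mg/mL
(mapped to E through the calibration), φ log-uniform over 0.005–0.2, G′
log-uniform over 0.4–55 Pa with σ<sub>y</sub> from the G′ calibration,
per-cell stress law σ<sub>cell</sub> = 15·E<sup>0.46</sup>. Each beam's
fate comes from the classifier with its own copy of the four material
thresholds jittered by a multiplicative lognormal (sd 0.1 in log) — the
experiments report only n = 3 per condition, far too few to infer a noise
model, so the jitter magnitude is a stated choice, not a measurement.
Geometric limits (aspect, length) are not jittered. Buckled beams carry
the theoretical wavelength as ground truth; centerlines are sinusoids of
amplitude 0.2λ (amplitude is not predicted by the linear theory at
threshold and does not affect any downstream quantity; 0.2λ is a visible,
configurable default) with random phase and additive Gaussian noise of sd
`noise_sd_frac`·amplitude (default 0.1). Non-buckled beams get flat lines
with noise scaled to `noise_sd_frac`·R — a centerline-localisation error
of a fraction of the beam radius. Contracted beams draw ε uniformly from
the observed 1–5% window by default; a config flag switches to the
force-balance forward prediction instead (the default avoids relying on
the unprinted modulus at 2 mg/mL).

Randomness is keyed as `SeedSequence(seed, spawn_key=(beam, stream))`, so
cohorts are byte-identical across runs and extending a cohort leaves
earlier beams untouched.

**What the generator does not emulate:** pixel-level imaging, 3D helical
modes (centerlines are 2D projections), time evolution over the 24–48 h
observation window, cell proliferation or migration, covariation of
G′ and σ<sub>y</sub> beyond the two-anchor map, and any correlation
between φ and E. Passing recovery tests therefore demonstrates that the
estimators invert the generative model they assume — not that real beams
obey it.

## Wavelength measurement

The original measurement procedure is not specified beyond "multiple
approaches", so two standard, mutually independent estimators are
implemented and required to agree within 5% on noisy sinusoids:

* **Spectral** — OLS linear detrend (printed beams are nominally straight,
  so only tilt/offset removal is justified; no high-pass filtering), Hann
  window, periodogram, dominant nonzero-frequency bin refined by
  three-point parabolic interpolation in log power. Error ≤ 0.5% with ≥ 8
  periods at 512 samples; noiseless end-to-end cohorts reach R² > 0.999
  against theory.
* **Real-space** — zero crossings of the detrended signal after a
  5-sample moving average, located by linear interpolation; twice the
  mean crossing spacing. Noise blips near the baseline create crossing
  pairs much closer than a half-period; the tightest pair is stripped
  until no spacing is below a quarter of the median, which removes the
  downward bias such blips otherwise cause.

Flat or monotone signals raise a dedicated no-undulation signal rather
than returning a number. Centerlines must be uniformly sampled with ≥ 16
points; the spectral route needs at least one full period in the record,
and its accuracy degrades below ~3 periods (beams stiffer than ~10 Pa in
a 5 mm record approach this limit, which is why clean-regression cohorts
cap E at 10 Pa).

## Problem sizes and determinism

Default analysis sizes — 500-beam cohorts for threshold recovery, 300 for
the φ sweep, 100 noiseless beams for the wavelength regression, 50
observations for the scaling fit — mirror the scale of the reported
experiments while keeping every pipeline stage in the seconds range. All
stages are single-process and deterministic given (config, seed); re-runs
produce byte-identical CSV and JSON outputs.

## Known limitations

* G′ is treated as a given scalar; whether the small-strain plateau
  modulus at a particular frequency is the right foundation stiffness for
  a yield-stress fluid is an open physical question.
* The classifier treats G′ and σ<sub>y</sub> as independent inputs even
  though real microgel media co-vary them; printed data cannot
  disentangle whether G′<sup>b</sup> is a property of G′ alone.
* The ~25 μm intermixed collagen–microgel interfacial zone is not
  modelled (no effective-radius correction in the yield-energy term).
* Post-buckling amplitude, crack dynamics, and the segment-size
  distribution beyond N·L₁ = L₀ are out of scope.
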