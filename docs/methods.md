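# Methods

## What the synthetic data emulate — and what they do not

The generator produces the two seasonal phenotypes of the type I male
midshipman swim bladder as implicit surfaces: a superellipsoid body
(exponent 2.5, slightly boxier than an ellipsoid) blended by a polynomial
smooth-minimum with two capsule horns placed at ±half the horn separation
off the sagittal plane. Meshes come from marching cubes at a user-chosen
voxel pitch (the "mesh resolution", default 1.5 mm for morphometrics,
2.0 mm for FEM); field values within 0.05·pitch of the iso-level are
snapped away from it, which keeps the triangulation free of sliver
elements (these otherwise spread the stiffness-matrix diagonal over ~13
orders of magnitude and destroy eigen-solver accuracy). Axes are fixed:
+x rostral, +y left, +z dorsal.

Cohort presets encode the dimorphism: non-reproductive fish get
30×20×15 mm bodies with 10 mm horns and a 3.31 mm bladder-otolith gap
(SD 0.75 mm); reproductive fish get wider 32×26×17 mm hornless bodies, an
11.62 mm gap (SD 1.57 mm), and a roughly threefold sonic-muscle somatic
index (preset means 0.42 g vs 1.35 g muscle on ~42-46 g fish). Somatic
scalars are drawn from normal distributions truncated at physical bounds.
Otolith centroids are placed rostral of the surface and then nudged along
+x until the measured closest-point distance equals the drawn gap, so the
distance operation has an exact generator-controlled oracle.

Evoked recordings follow the saccular protocol grids (95–950 Hz in 95 Hz
steps; 100–154 dB re 1 µPa in 3 dB steps; 8 repetitions per cell; 8
background-only measurements per session). The response model is
threshold-linear with a hard saturation: mean magnitude
min(bg + slope·max(0, L − L₀), saturation) plus i.i.d. Gaussian noise
floored at zero. The repetition noise SD is a free parameter (defaulting
to the background SD) because no empirical value for it is available. The
two state threshold profiles used by the pipeline (reproductive ~8 dB more
sensitive at low frequencies; non-reproductive unresponsive above 665 Hz)
are package choices that reproduce the qualitative seasonal pattern —
recovered thresholds, detection-rate roll-off, and a ~2-fold (≥6 dB)
sensitivity difference — not measured values.

What passing tests therefore show: the measurement chain (geometry →
morphometrics → shape space; simulation → thresholding → group
statistics; mesh → modes → damped response) is internally correct against
independent oracles. What they do not show: that real microCT bladders
or real evoked recordings have these parameter values; the synthetic
surfaces are smooth and bilaterally symmetric, real bladders are not, and
the simulated noise is Gaussian and independent across repetitions,
which real lock-in magnitudes need not be.

## Morphometrics

Horn length is defined as bladder length minus width (floored at zero);
length and width are extents along the first two principal axes of the
vertex covariance, making the measurement invariant to file orientation.
Bladder-otolith distance is the minimal surface distance per side,
averaged bilaterally. All linear measures are divided by standard length
(after mm → cm conversion). Somatic indices use the
100·organ/(body − organ) convention; the sonic-muscle index follows the
same convention as the gonadosomatic index since no separate formula is
established.

Pseudo-landmarks are produced by farthest-point sampling over the
vertices of the y > 0 half, seeded at the rostral-most vertex, each sample
paired with its mirror image projected back to the surface; this makes
the set symmetric, deterministic, and nested (a denser sampling extends a
sparser one). Landmark transfer is similarity registration — principal-axis
initialisation followed by scale-aware ICP (Umeyama fits to
closest-surface-point correspondences) — then nearest-point projection
onto the target. This is a deliberately rigid correspondence scheme:
adequate for the smoothly varying synthetic shapes, and not a deformable
registration; strongly dissimilar anatomies would need one.

Shape space: generalized Procrustes alignment (centring, unit centroid
size, iterative Kabsch rotation to the evolving mean) followed by SVD-based
PCA of the aligned flattened coordinates. Singular values below an
absolute floor (1e-9 on unit-size configurations) are treated as null so
that identical shapes yield a degenerate (all-zero) morphospace rather
than noise components.

Mesh geometry primitives (closest point on surface, ray-parity
containment with an irrational ray direction, similarity ICP) are
implemented in `bladderkit._geometry` as brute-force vectorised kernels;
at the 10³–10⁴-face meshes this package targets they are fast and carry
no spatial-index dependency.

## Shell finite elements

The bladder wall is a thin linear-elastic shell: flat-facet triangles
carrying a constant-strain membrane field and discrete-Kirchhoff (DKT)
bending, with a small penalty (1e-2·E·t·A on relative rotations) on the
drilling degree of freedom. Defaults are wall properties measured in the
oyster toadfish, a close relative: E = 1 MPa, thickness 824.5 µm, density
1000 kg/m³ (≈ water), uniform modal damping ratio ζ = 0.325. Poisson's
ratio is not available for bladder wall; the default is 0.4 (soft
tissue), configurable. The element passes exact rigid-body and
constant-curvature patch tests, and a 16×16 simply-supported plate
reproduces the closed-form thin-plate frequencies to within ~1.5%.

Mass is consistent for translations (linear interpolation) with lumped
rotary inertia ρt³/12 per unit area, which keeps M positive definite.
Boundary conditions clamp all six DOFs of nodes on the dorsal midline
(|y| within 1.5 median edge lengths) over the caudal 25% of the length —
the package's reading of the bladder's dorsal-caudal attachment; the
fraction is configurable and the first natural frequency rises
monotonically as the band grows.

Modal analysis solves K·λ = ω²·M·λ by shift-invert Lanczos about zero
after symmetric Jacobi scaling of both matrices (rotational and
translational stiffnesses differ by many orders; scaling keeps eigenpair
residuals near 1e-10). A fixed unit start vector makes results
bit-reproducible. The mode count is doubled until the band
f_max × margin (default margin 1.2 for analysis; harmonic response
requires its own coverage margin) is covered, and one mode beyond the
band is retained so coverage checks are inclusive.

Sectioning inserts dorso-ventral planes every 22.5° about the vertical
axis, splitting the bladder into 16 azimuthal wedges in the horizontal
plane (azimuth 0 = rostral, half-open sectors). Representative points are
the per-wedge nodes nearest the dorsal apex, the horizontal midline, and
the ventral apex (48 points), plus the two horn tips when the rostral
band of the surface separates into two connected components (50 points).

Pressure loading models a horizontal incident wave from azimuth θ:
elements whose outward normal faces the wave receive
force = pressure × projected area along the propagation direction, shared
equally by their nodes, so total force / loaded projected area equals the
nominal pressure exactly (1 Pa default). Harmonic response is modal
superposition with uniform ζ per mode, evaluated on the 0–750 Hz grid in
25 Hz steps plus every natural frequency in band. "Power" is reported as
the kinetic proxy P = ½ω²|U|² (the magnitude |U| is the Euclidean norm of
the complex displacement vector); the quantity has no unique definition
in this context and alternatives (e.g. input power) would change scale
but not peak locations, which sit at the velocity resonance ω = ωₙ.

On the synthetic geometries the horned-minus-hornless power difference
integrated over all angles and frequencies is small and its sign is not
stable under mesh refinement; the per-angle pattern is stable (horned
bladders capture more broadside power at 90°/270°, less rostro-caudally).
The pipeline reports the per-angle table; the acceptance script reports
the broadside sign. Whether this direction matches the real anatomies is
documented as a demonstration, not asserted.

## Evoked-potential analysis

Thresholds use the background-referenced rule: with the session's 8
background magnitudes giving mean m and sample SD s (n−1 denominator),
the threshold at a frequency is the lowest grid level whose
mean-over-repetitions magnitude is ≥ m + 2s (inclusive), else "no
response" (stored as NaN). Group tuning curves average defined
thresholds only, report per-frequency n, and carry t-distribution 95%
confidence intervals; no imputation is performed. Threshold differences
are converted to pressure-amplitude fold changes via 10^(Δ/20) (a 2-fold
change is 6.02 dB) because the levels are amplitude decibels.
The lock-in demodulator mixes the waveform with a complex exponential at
twice the stimulus frequency over an integer number of cycles and reports
the RMS amplitude of that component, mirroring the hardware lock-in's DC
output on the second harmonic (the saccule's opposed hair-cell
populations double the response frequency).

## Statistics

Morphometric state comparisons are pooled-variance two-sample t-tests
(df = n₁+n₂−2, two-tailed). Threshold/magnitude comparisons use a
mixed-design ANOVA with reproductive state (or bladder condition) between
subjects and stimulus frequency within subjects, Greenhouse-Geisser
corrected by default; a trial-pooled two-way fixed-effects mode is also
provided because the subject-level and trial-level conventions give very
different denominator degrees of freedom, and neither is asserted as
canonical. Per-frequency contrasts are planned comparisons and carry no
multiplicity correction — a documented caveat: with 10 frequencies at
α = 0.05 the familywise false-positive rate under the null is ~0.4.

## Numerical choices and degenerate inputs

* Marching-cubes meshes are used unprocessed (`process=False`); vertex
  merging can break watertightness of the already vertex-shared output.
* Triangles with area < 1e-14 m² abort assembly with the element named.
* Zero pooled variance in the t-test returns p = 1 for equal means and a
  flagged degenerate result otherwise.
* "On surface" tolerance for landmarks: 1e-6 × bounding-box diagonal.
* Landmark counts must be even (mirror pairing); identical input shapes
  yield a single null principal component.
* All randomness flows from explicit integer seeds; no global state. The
  pipeline manifest records the full configuration, and a re-run from the
  same configuration is byte-identical on every CSV.

## Problem sizes

Default pipeline: 8 specimens per state at 1.5 mm pitch for
morphometrics; the two FEM models at 2.0 mm pitch (≈650–750 nodes,
≈4000 constrained DOFs, ≈80–110 modes below 900 Hz); 200 landmarks.
The test suite and acceptance script use coarser variants of the same
conditions (2.5–2.8 mm pitch, 40–60 landmarks, 2 specimens per state for
the end-to-end demo); these sizes were chosen as the smallest at which
every oracle and property above is comfortably resolved.

## Known limitations

* No fluid-structure coupling, internal gas compliance, or radiated
  sound; the FEM is a dry shell in vacuo with pressure applied as a
  static-pattern harmonic load.
* Rigid similarity correspondence cannot capture localised shape
  differences a deformable method would; PC interpretations on real data
  should not be extrapolated from the synthetic morphospace.
* The evoked simulator's noise is homoscedastic and uncorrelated across
  repetitions and frequencies.
* The sign of the aggregate power difference between phenotypes is
  resolution-sensitive on synthetic geometries (see above).
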