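# bladderkit

Seasonal plasticity of the swim bladder in type I male plainfin midshipman
(*Porichthys notatus*) links reproductive state to hearing: out of the
breeding season the bladder carries paired rostral horns that reach to
within a few millimetres of the saccule (the main auditory end organ),
while in the breeding season hypertrophied sonic muscles reshape the
bladder, the horns regress, and the bladder-ear gap roughly triples.
`bladderkit` implements the full quantitative analysis of that phenomenon
as a tested, self-contained pipeline on synthetic data, for auditory
neuroethologists and biomechanics researchers who want to reproduce,
probe, or extend each stage:

* **synthetic** — parametric bladder geometries (superellipsoid body +
  capsule horns, closed triangulated surfaces), specimen cohorts with
  realistic somatic scalars, and simulated saccular evoked-potential
  recordings with a saturating threshold-linear response embedded in
  Gaussian background noise; plus a quadrature lock-in demodulator for the
  second-harmonic channel.
* **morphometrics** — somatic indices
  (GSI = 100·gonad/(body−gonad), SMSI analogously), bladder length/width,
  horn length (= length − width), bilateral bladder-otolith distance,
  standard-length normalisation, dense pseudo-landmarks (symmetric
  farthest-point sampling), landmark transfer by similarity registration,
  and generalized Procrustes analysis + PCA morphospace.
* **fem** — thin-shell finite elements (CST membrane + discrete-Kirchhoff
  bending on flat facets): modal analysis
  (K·λ = ωₙ²·M·λ, shift-invert Lanczos), 16 azimuthal sections from 22.5°
  dorso-ventral planes, 1 Pa pressure loads at horizontal incidence angles
  0°–315° in 45° steps, damped harmonic response by modal superposition
  with qₙ(ω) = λₙᵀF / (ωₙ² − ω² + 2iζωₙω), ζ = 0.325, and vibrational
  power ½ω²|U|² at representative surface points.
* **ephys** — background statistics, the 2-SD threshold rule (lowest level
  whose mean evoked magnitude ≥ background mean + 2 SD), tuning curves,
  iso-level profiles, detection rates, and between-group threshold
  differences in dB and pressure-amplitude fold change (6.02 dB = 2-fold).
* **stats** — pooled-variance two-sample t-tests, mixed-design
  repeated-measures ANOVA (condition × stimulus frequency), and a priori
  per-frequency contrasts.

## Worked example

```python
from bladderkit import synthetic, morphometrics as morph

cohort = synthetic.generate_cohort(4, seed=1)
tbl = morph.morphometrics_table(cohort)
print(tbl.groupby("state")[["horn_length_mm", "otolith_distance_mm", "smsi"]]
         .mean().round(2))
```

prints

```
                  horn_length_mm  otolith_distance_mm  smsi
state
non-reproductive           19.26                 3.18  0.95
reproductive                5.27                11.89  2.92
```

Non-reproductive specimens carry ~19 mm of measured horn length and sit ~3 mm from
the otoliths; reproductive specimens are hornless (their residual
length-minus-width is ~5 mm), lie ~12 mm away — a ~3.7-fold gap increase in
this draw (3.5-fold at the preset means) — and show a roughly threefold
sonic-muscle somatic index.

The full pipeline (cohort → morphospace → FEM vibroacoustics → evoked
thresholds → statistics, with figures and a reproducibility manifest):

```bash
bladderkit all --out artifacts --seed 1
```

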