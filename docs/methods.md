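# Methods

This note records the models, conventions and parameter choices behind
`ldhtraj`, what the synthetic generator does and does not emulate, and the
numerical decisions a user should know before trusting the outputs.

## Units and conventions

Coordinates are Å, times fs, frequencies cm⁻¹ (conversion
c = 2.99792458×10⁻⁵ cm/fs, so ν[cm⁻¹] = f/(c·dt) with f in cycles per
frame). Boxes are orthorhombic; pair distances use the minimum-image
convention on all three axes, while the z axis is additionally treated as
a periodic stack of sheets and galleries for the density analysis. Atom
order is stable everywhere: index i always refers to the same atom.

## Infrared spectra

The line shape is the Fourier transform of the dipole time-correlation
function ⟨μ(0)·μ(t)⟩. The quantum prefactor that converts a classical TCF
into an absorption cross-section is deliberately **not** applied; a hook
(`mem_spectrum(..., prefactor=...)`) lets a user multiply one in.

* **Dipole reference.** The anions carry net charge −2, so μ is
  origin-dependent; we reference each molecule's dipole to its per-frame
  center of mass, which restores translation invariance. A fragment
  option restricts the charge sum (e.g. to one carboxylate) while keeping
  the whole-molecule reference. Whole-anion dipoles are the default.
* **Maximum-entropy estimation.** The transform is computed by Burg's
  recursion per Cartesian component; the three all-pole spectra are
  summed. Default order min(500, n_frames/10). The mean is removed before
  fitting; intensities are one-sided spectral densities, so integrating
  the unshifted spectrum to the Nyquist frequency recovers the series
  variance (the sum-rule test checks this to 5%). The recursion stops
  early once the residual power is numerically exhausted (noise-free line
  spectra saturate the model order); a NaN in the recursion raises.
  Because the per-component fit is nonlinear, the summed estimate is only
  asymptotically invariant under coordinate rotations — band *positions*
  are stable (tested), pointwise intensities are not exactly so.
* **Band gap.** ν_S and ν_AS are grid argmaxes in the windows
  [1300, 1500] and [1500, 1750] cm⁻¹ (translated along with any applied
  shift); the gap is their difference. No sub-grid interpolation: results
  are reproducible and resolution-bounded, and the default grid step is
  1 cm⁻¹. A maximum on a window edge raises a "no interior peak" error
  rather than reporting a fake band. The windows are a documented choice;
  the well-separated synthetic bands are insensitive to them.
* **Shift.** Comparing with experiment conventionally applies a rigid
  −200 cm⁻¹ correction for force-field and missing-prefactor bias. The
  shift is recorded in the spectrum and cancels exactly in the gap.
* **Per-anion averaging.** Spectra are computed per anion and averaged,
  excluding cross-anion dipole correlations by design.
* **Velocity power spectra** (band assignment) use the same MEM machinery
  on atomic velocities, derived by central finite differences when the
  trajectory stores only coordinates.

## Synthetic generator

The generator emulates the *statistical* structure the analyses assume,
not the physics of an MD engine — there is no force field, thermostat, or
hydrogen-bond network dynamics.

* **Composition.** Per formula unit: 4 Mg + 2 Al + 12 OH in one rigid
  sheet (formal charges Mg +2, Al +3, OH −1 split as O −1.42 / H +0.42,
  i.e. +2 per unit), one anion with fixed per-role partial charges
  summing to −2 exactly, and round(n_fu·X) three-site neutral waters
  (largest-remainder distribution over formula units). Anions are
  rigid ideal-geometry templates (C–C 1.53 Å, C–O 1.26 Å, tetrahedral /
  sp² angles) with two free degrees of freedom: the orientation of the
  carboxylate-carbon axis and the classifying torsion χ. The charge
  table is a documented constant set, not force-field-faithful; only
  dipole *changes* matter for the spectra.
* **States.** Each anion holds an orientation state (parallel: θ drawn
  uniform in (81°, 90°]; otherwise uniform in [0°, 70°], tilted upward in
  0.5° steps when a narrow gallery cannot accommodate the draw) and a
  conformer state (χ drawn uniformly within ±25° of 180°/+60°/−60°, far
  from the ±120° classification boundaries). States switch by a Markov
  chain with mean dwell `state_dwell_frames` (default 100 frames);
  initial states are allocated across anions by largest remainder and
  shuffled, so the ensemble cross-section matches the prescribed
  populations up to integer rounding. Population recovery is therefore an
  *ensemble* property: the recommended estimator geometry is many anions
  over few frames (the tests use 2000 anions × 2 frames = 4000 samples),
  because time averages of a dwell-correlated chain carry a much larger
  variance than the binomial count suggests.
* **Timescale caveat.** 100 frames at the spectra-grade dt of 0.5 fs is
  50 fs — far faster than real reorientation (ps–ns) and faster than the
  vibrational dephasing time, so at that dwell the instantaneous
  direction jumps broaden the carboxylate bands by ~100 cm⁻¹ and, for the
  near-centrosymmetric succinate, bury them. Spectra-grade runs must use
  a physical dwell; the pipeline and the analysis drivers use 2 ps
  (`state_dwell_frames=4000`). Smoothing the jumps instead was rejected:
  interpolating orientations can transiently collapse the θ-defining
  vector and break the exact per-frame θ guarantees.
* **Vibrations.** Each carboxylate group carries two mode coordinates —
  in-phase (S, default 1400 cm⁻¹) and out-of-phase (AS, default
  1600 cm⁻¹) — realized as noise-driven underdamped oscillators
  (exact 2×2 propagator plus a per-step velocity kick) with stationary
  RMS displacement `mode_amplitude` (default 0.10 Å) and damping time
  500 fs (Lorentzian-like bands of ≈11 cm⁻¹ FWHM). Displacements are
  applied along the instantaneous C→O unit vectors; the S displacement is
  scaled by the geometric factor |u₁−u₂|/|u₁+u₂| (≈1.9) so both bands
  carry comparable dipole strength, as carboxylate spectra show.
* **Placement.** Parallel anions sit in the surface-contact layer of a
  randomly chosen sheet; intermediate/perpendicular anions are centered
  at the gallery midplane (the bridging picture). Waters are anchored in
  the hydration shell of a random carboxylate O (2.4–3.0 Å, displaced
  toward the nearer sheet — the surface hydration layer), except for a
  `midplane_water_fraction` placed at the gallery midplane, the feature
  that appears in the real systems only at high hydration. Thermal
  Gaussian jitter (σ = 0.05 Å) is added to all non-sheet atoms each
  frame; the two θ-defining carbons of each anion share one jitter draw
  so the orientation class is exact per frame, and the ±25° torsion draws
  leave ≥35° of margin to the conformer boundaries, far beyond the ~3°
  jitter-induced torsion noise.
* **Presets** cover all eleven defined systems (anion, X, spacing d,
  parallel population, and a band splitting ν_AS − ν_S matching each
  system's computed gap, with ν_S pinned at 1400 cm⁻¹). Conformer
  fractions follow the qualitative record: ASP mixes anti with gauche−
  only (steric exclusion of gauche+), GLU is all-anti when anhydrous and
  mixes both gauche wells when hydrated, SUC is all-anti at low hydration
  with a small gauche admixture in the wettest state. The succinate
  "8_WAT" state appears in derived tables but has no defined spacing; it
  is flagged undefined rather than guessed. Defaults: 8 formula units,
  3 layers, 4096 frames at dt 0.5 fs.
* **What passing tests do not show.** The generator has no anharmonic
  couplings, no band-shape physics beyond a Lorentzian-like envelope, no
  water dynamics (waters ride their anchors), and jump reorientation
  instead of diffusive reorientation. Recovery of prescribed parameters
  validates the *estimators*, not any force field.

## Structural descriptors

* **Orientation.** θ = arccos(|v_z|/|v|) ∈ [0°, 90°] with v the
  carboxylate-carbon vector, so the carbon order is irrelevant.
  "Parallel" means θ strictly greater than the 80.0° threshold; exactly
  80.0° is intermediate/perpendicular. Populations are fractions over all
  frame × anion samples.
* **Torsions.** Signed IUPAC convention in (−180°, 180°], validated
  against MDAnalysis and RDKit. Conformer windows are centered on the
  known wells with boundaries at ±120°; χ = +120° is gauche+ by the
  stated convention and χ = −120° gauche− by symmetry (the boundary set
  has measure zero). Collinear quadruples raise a degenerate-geometry
  error.
* **z densities.** Atoms are wrapped into the periodic sheet stack,
  assigned to their enclosing gallery, and histogrammed relative to that
  gallery's midplane, pooled over galleries and frames; units are counts
  Å⁻¹ frame⁻¹, so the integral times n_frames equals the number of
  assigned observations. Profiles are mirror-symmetrized across the
  midplane by default (slab symmetry; toggleable; integral preserved).
* **RDFs.** Minimum-image distances, ideal-gas normalization with the
  full 3-D box volume, self-pairs excluded for identical roles. In a slab
  geometry this normalization is only qualitative beyond one gallery
  height, which is why the default range stops at 5 Å.
* **Slab geometry** is detected from the Mg z coordinates by 1-D k-means
  (gap-split initialization, Lloyd refinement — deterministic), with the
  layer count from topology metadata or from >3 Å gaps; the spacing is
  the mean adjacent-center difference, and galleries span between
  adjacent centers plus the periodic wrap gallery.

## Pipeline

A `RunConfig` names one input source (preset, explicit generator config,
or trajectory + topology files), toggles analyses, and fixes all
parameters. Analyses are isolated: one failure is recorded in the report,
the rest still run. All randomness flows from a single seed through named
substreams; reports serialize as delimited text with a provenance header
(seed, config hash, package version) and are byte-identical under a fixed
seed. Problem sizes used by the shipped drivers — 8 anions × 8192 frames
for spectra, 500–2000 anions × 2–4 frames for populations, 24 anions ×
80 frames for densities, 400 frames for RDFs — were chosen as the
smallest ensembles whose sampling error is comfortably below the effects
being measured.

## Known limitations

* Band shapes are Lorentzian-like by construction; only band positions
  and gaps are meaningful observables of the synthetic spectra.
* The RDF normalization is spherical in an anisotropic pore; read g(r)
  qualitatively, and only below ~5 Å.
* Density profiles drop atoms that fall outside every detected gallery
  (possible only for non-uniform layer spacings in real data).
* Rigid anion templates cannot compress; very narrow galleries tilt the
  intermediate-state draws upward, truncating the nominal [0°, 70°]
  range.
* The trend table's monotonicity flag uses a 5 cm⁻¹ slack to absorb
  estimator noise in neighboring hydration states.
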