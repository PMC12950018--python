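# Methods

## Geometry and coordinate conventions

Phantom coordinates are right-handed with x lateral, y anterior and z
increasing caudally; the vertex (cranial top) is z = 0 mm and the isocenter
sits on the midline. The phantom is scanned in a fixed chin-up posture in
which the orbitomeatal (OM) plane is inclined 35° to the axial plane
(`om_inclination_deg`); this value is chosen so that a beam tilt of −35°
relative to the OM line corresponds to perpendicular (axial) incidence,
matching how perpendicular-incidence calculators relate to the tilted
clinical geometry. A gantry tilt t therefore produces a beam plane at
t + 35° to the axial plane, realized as a rigid rotation of the source
trajectory about the lateral axis through the isocenter; positive tilt
moves the anterior beam portion cranially. Slice positions k are always
measured along the phantom z axis on the isocenter line, and the tilted
beam plane through slice k satisfies z = k − (y − y_iso)·tan φ.

Two consequences drive everything the package studies. First, the beam
plane that actually crosses the lens (which sits ~75 mm anterior of the
isocenter axis) belongs to slice k_peak = z_lens + Δy·tan φ, so the lens
dose peak moves caudally by ≈2 mm per degree of upward tilt. Second, the
caudal limit of a "brain only" scan — the most caudal plane still touching
brain — moves more slowly (≈1.3 mm/deg), so upward tilt pushes the lens
peak out of a brain-only scan while a brain+eyes scan always contains it.

## Synthetic head phantom

The phantom is a parametric stand-in built from nested ellipsoids and
capsules: skin shell (3 mm), cranium (8 mm cortical-bone shell around the
brain ellipsoid with orbital openings carved around the globes), brain
(semi-axes 60 × 72 × 62 mm, ≈1.17 kg), two eyeballs (r = 12 mm) with
lenses (r = 3.5 mm, ≈0.18 g) at their anterior poles, parotid-like
salivary glands, an oral-mucosa ellipsoid, a thyroid in the neck capsule,
and generic soft tissue elsewhere. Tissue compositions and densities are
ICRU-style reference values. Default spacing is 2 mm (1 mm supported);
the volume extends 300 mm caudally so every studied scan line lies inside.

The default anatomy was dimensioned once so that the lens peak sits inside
the brain-only scan range for tilts of about −10° and below and outside it
for −5° and above — the qualitative configuration of an adult head in the
chin-up scan position — and was not revisited afterwards. What the phantom
deliberately does not emulate: anatomical realism beyond organ topology
and rough masses, posture-dependent deformation, bone marrow distribution,
or inter-patient variability. Passing tests therefore demonstrate the
geometry-driven tilt and scan-range mechanisms, not patient-specific
absolute doses.

`downsample_labels` uses nearest-neighbor subsampling rather than a
plurality vote: subsampling preserves organ volumes in expectation even
for structures a few voxels across (the lens), which a mode filter erodes.

## Beam model

The spectrum is a Kramers bremsstrahlung continuum N(E) ∝ (E_max − E)/E
with tungsten K characteristic lines carrying 8% of the unfiltered
continuum, filtered through inherent aluminum (default 2.5 mm) using an
embedded NIST-style Al attenuation table. The bowtie is a symmetric
parametric filter (0 mm Al on the center ray rising quadratically to
10 mm at the 25° fan edge). Both can be overridden by user TSV tables, so
the pipeline structure is scanner-agnostic even though the default beam
quality is generic rather than vendor-specific. Source-to-isocenter
distance defaults to 595 mm; z-collimation of the source model is 2 mm
(5 mm supported) and rotation is sampled continuously over 360° per
history (a fixed-view mode exists for the tracking cross-check).

## Photon transport

Analog transport of photons between 1 and 150 keV with photoelectric
absorption, incoherent (Compton) and coherent (Rayleigh) scattering.
Electrons are not transported: their energy is deposited at the
interaction voxel (kerma approximation), a deliberate simplification
justified by sub-voxel secondary-electron ranges at CT energies. The
photon cutoff is 1 keV; energy below it is booked explicitly so the
bookkeeping identity emitted = deposited + escaped + below-cutoff holds to
1e-6 relative on every run.

Cross sections come from an embedded parametric model: exact
Klein–Nishina per-electron cross sections times electrons per gram for the
incoherent channel (binding neglected), a Z^4.5/E^3.21 photoelectric fit
and a Z^2.5/E² coherent fit calibrated against standard water reference
values (total 0.8096 cm²/g at 20 keV; coherent 0.030 cm²/g at 30 keV).
The resulting water totals agree with standard tables to within ~1% over
40–100 keV. Mass energy-transfer coefficients combine the photoelectric
term with the Klein–Nishina mean electron-energy fraction. Compton
sampling uses Kahn's rejection method; Rayleigh angles use the Thomson
(1 + cos²θ) shape (form-factor-free approximation, small at CT energies
and switchable off).

Tracking is Woodcock delta-tracking with the grid-wide maximum attenuation
at the photon's energy as majorant; an independent Amanatides–Woo voxel
ray-marching ("Siddon") mode is retained purely as a cross-check and the
two are required to agree within statistics in the test suite. Randomness
is a counter-based splitmix64 stream keyed on (master seed, slice index,
batch), so results are bit-reproducible and independent of execution
order. Uncertainties are standard errors of 10 history-batch means.

The free-in-air kerma per photon qK_air uses a track-length estimator over
a 10 mm-diameter air cell at the isocenter (the cell size is a documented
default; air attenuation over the source-cell distance is neglected).

## Dose pipeline

A scan is a set of independent axial acquisitions stepped by
beam-width × pitch; by linearity of transport this is equivalent to a
contiguous pitch-1 acquisition. Profiles are tallied over the full
0–260 mm extent regardless of scan range so out-of-range tails stay
visible; the scan dose includes a slice iff its center lies inside
[start, end]. Scan-range presets: (i) brain+eyes and (ii) brain-only are
tilt-aware caudal projections of the target organs' voxels; (iii)
infraorbital and (iv) supraorbital margins are fixed landmarks defined for
perpendicular incidence. FWHM crossings are located by linear
interpolation between bracketing samples (published crossing positions are
grid-rounded; interpolation may legitimately return non-integer values);
ties in the peak search break toward the smallest position, and the "tail"
is operationalized as in-range dose outside the [x₁, x₂] peak interval.

Effective dose uses the ICRP-103 tissue weighting factors with the
arithmetic-mean remainder rule restricted to supplied remainder organs.
The synthetic phantom supplies only brain, salivary glands, skin, thyroid
and oral mucosa (a remainder tissue); the result is therefore labeled a
*partial* effective dose with the covered weight reported, and the lens —
which has no tissue weighting factor — never enters it.

## Photon budgets and precision

The default exploratory budget is 4 000 photons per slice (a full
131-slice scan in a few seconds on one CPU). The documented
high-precision budget is 6×10⁶ photons (10 batches) per slice, at which
the relative standard error of brain and lens energy deposition at the
lens-peak slice stays below 5% with margin (typically 2–4%); this budget
exists because the study design fixes the precision target and the photon
number is whatever achieves it. Acceptance and mechanism tests use 60 000
photons per slice, enough for ≥3σ separation of the brain-only lens doses
at ±10° tilt.

## Known limitations

Electron transport, bremsstrahlung regeneration, polarization, helical
trajectories and over-ranging, dynamic collimation, tube-current
modulation and image-quality assessment are out of scope. Incoherent
scattering neglects electron binding (a few percent at the softest end of
the spectrum); the coherent fit is a rough magnitude model. Absolute organ
doses depend on the generic beam and synthetic anatomy and should be read
as protocol contrasts, not scanner dosimetry.
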