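# Methods

This note records the models behind `pyxfet`, the defaults and why they were
chosen, the numerical choices, and what the synthetic studies do and do not
demonstrate about the bench system they emulate.

## Atomic-physics tables

The package ships its own XCOM-style tables (`src/pyxfet/data/`, generated by
`make_tables.py` there) rather than depending on an external physics library.

* **K lines and edges.** Intensity-weighted Kα = (2Kα1 + Kα2)/3 and Kβ1
  energies, K-edge energies and K fluorescence yields for Mo, Cd, Te, La, Gd,
  W, Pt, Au and Pb are standard data-booklet values (the test suite checks
  them against an independent reference fixture to 1%).
* **Photoelectric.** A piecewise power law anchored at each element's own
  K edge: σ ∝ Z^4.3 · E_K⁻³ · (E_K/E)^2.85 above the edge, divided by the
  K-jump 3.5 + 125/Z between L3 and K, and by a further factor 2.5 below L3.
  The overall scale is set by gadolinium's above-edge value (12.5 cm²/g) for
  heavy elements and by the water photoelectric coefficient at 30 keV for
  Z ≤ 13. These exponents are the field's standard scaling; they give a
  La/Gd above-edge ratio of 1.48.
* **Incoherent.** Klein–Nishina times Z with a binding-suppression factor
  E²/(E² + (1.165 Z)²) anchored to water at 30 keV. **Coherent.** Z^2.5/E²
  anchored to water at 30 keV.

Accuracy: water/acrylic/PTFE total attenuation is within a few percent of
the standard tables between 20 and 90 keV (the band all imaging quantities
live in); light-element photoelectric below ~15 keV is 10–25% low and heavy
elements far from their edges carry tens-of-percent uncertainty. Every
quantity the pipeline reports is a ratio or a shape, which is why this
fidelity level is sufficient; absolute heavy-element attenuation never
enters a result. Interpolation is log-log with edge-straddling grid nodes,
so power-law segments are interpolated exactly and no interpolation bridges
an edge discontinuity.

## Source spectrum

Thick-target Kramers continuum (fluence per bin ∝ Z(kVp − E)/E, 0.1 keV bins
from 1 keV to kVp), filtered by the Be exit window, plus the anode K lines
when kVp exceeds the anode K edge. The characteristic share of the exit
fluence is a configurable parameter, default 0.25, chosen so that the
fluence-energy fraction below 21 keV exceeds one half — the qualitative
property of the measured 90 kVp Mo spectrum this model stands in for. The
measured spectrum's exact characteristic/continuum balance is not published.

Known deviation: a real thick-target spectrum is harder above 40 keV than
Kramers (target self-absorption and the true bremsstrahlung cross section
deplete the soft end less steeply). This matters for exactly one output —
the Gd:La response-deficit factor — and is discussed below. Anode
self-filtration was evaluated and deliberately omitted: at plausible
effective target depths it changes the La/Gd excitation ratio by <5% while
collapsing the sub-21 keV energy dominance the measured spectrum shows.

## Geometry

Six panels at 60° steps about the axial (z) axis; the beam (y) passes
through the hexagon's vertex gaps; x is the scan direction. Detector planes
sit 41 mm from the axis (82 mm opposite-face spacing). The pinhole plane is
derived, not quoted: with 1:2 minification and the detector at 41 mm, the
apertures sit at 41·⅔ = 27.33 mm, just inside the 14 mm collimator. The 16
pinholes per panel form a 4 × 4 grid aligned so that each projects the
field-of-view center onto the center of its own 40 × 40-pixel subdetector
region (forced by the no-multiplexing design); aperture disks lie in the
panel plane by default (`aimed_pinholes` tilts them toward the FOV center —
it changes the obliquity factor by ~5% and nothing else). The two lower
modules of each panel are mounted physically inverted; all orientation
handling falls out of the projection geometry rather than stored flip
tables.

Ray acceptance is exact: a photon is transmitted if its first outward
collimator-plane crossing passes through an aperture disk and its
continuation lands inside that aperture's assigned region, and if its origin
lies inside the (convex) aperture ring — so points behind the collimator see
nothing, and tungsten is otherwise perfectly opaque (no penetration or
collimator scatter).

**Geometric sensitivity.** The analytic value at the FOV center is
Σᵢ Aᵢcosθᵢ/(4πdᵢ²) = 0.659%, and the Monte-Carlo tracer agrees within
statistics. Note an upper bound: even if all 96 apertures sat exactly
on-axis at 27.33 mm the sensitivity could not exceed 96·A/(4πd²) = 0.80%.
The ~0.9% sometimes quoted for this aperture class therefore must include
knife-edge penetration (an effective diameter above 1 mm) or refer to a
variant geometry; with ideal 1 mm disks this package reports ~0.65% and
regards that as the correct value for the modeled system.

## Phantom and ray tracing

Analytic finite cylinders: a 19 × 10 mm acrylic body (PMMA at the stated
1.18 g/cm³) and four PTFE tubes (4.7/3.0 mm diameters, 8 mm tall, walls at a
declared default of 2.2 g/cm³) at 5.5 mm offsets, 90° apart (exact angles
are not published; the fixture assignment is 0°/90°/180°/270° with fills in
study order). Solutions are water plus solute at mg/mL in the dilute limit
(density = water; at ≤6 mg/mL the error is <1%). Ray–phantom intersection is
closed-form (quadratics plus z-slabs); a vectorized per-material path-length
routine backs the photon transport and is cross-checked against the scalar
segment tracer in the tests.

The published "≈2.35 µg of Gd in the irradiated volume of interest" is not
reproduced: the irradiated volume it refers to is undefined (a beam-chord
volume gives ≈0.24 µg at 0.1 mg/mL), so no mass claim is made.

## Forward simulation

Per scan position:

1. **Beam attenuation** along the chord, analytically per 0.25 mm depth bin
   and spectrum bin.
2. **XRF production**: expected K emissions per depth bin = surviving
   fluence above the K edge × the element's photoelectric mass-interaction
   probability × the K-shell share (1 − 1/jump) × fluorescence yield × line
   branching. Kα and Kβ are both emitted.
3. **Emission and transport**: emission counts are Poisson; directions are
   isotropic. Because photons are detectable only through the 96 apertures,
   the isotropic Poisson stream is split by superposition into 96
   enclosing-cone streams (cones padded for the emission jitter inside a
   depth bin and the 1 mm beam cross-section) plus an untraced remainder;
   every traced photon gets an exact position, an exact aperture-disk test,
   exit attenuation along its own path (Bernoulli survival), and the CdTe
   photoelectric absorption probability (1 mm slab). This is distributionally
   identical to brute-force isotropic emission — the remainder could never
   produce an event — and ~50× faster.
4. **Compton background**: single scatter only. Expected scatters per
   (depth, energy) bin are thinned by a configurable `compton_scale`
   (variance reduction; background level is never an absolute claim);
   scattering angles are rejection-sampled from Klein–Nishina, and scattered
   photons are transported like XRF at their scattered energy. Multiple
   scatter, collimator scatter and Rayleigh-scattered beam photons are
   omitted: the downstream background subtraction is empirical, so only the
   smoothness of the continuum matters.
5. **Detector response**: Gaussian energy blur with FWHM linearly
   interpolated between the measured anchors (0.5 keV at 35, 0.88 at 60,
   1.02 at 122 keV, flat outside); charge sharing with a neighbor pixel with
   probability 0.3 (uniform split, same frame; the bench value is not
   published — 0.3 is typical for 250 µm CdTe pixels and its exact value
   cancels in every ratio because CSD rejects shared events of all
   energies alike); a 4 keV discriminator threshold.
6. **Cd/Te K-escape** (on by default): a photopeak event may record
   E − E(Cd/Te K line) instead of E, with the standard semi-infinite-slab
   escape fraction 0.5·[1 − r·ln(1 + 1/r)], r = µ(E_fl)/µ(E), weighted by
   atom share, K-shell fraction, yield and branching. This is visible in
   measured CdTe spectra and matters quantitatively here: La Kα (33.3 keV,
   just above the Te K edge) loses ~14% of its photopeak to escape versus
   ~9% for Gd Kα.
7. **Framing**: each photon draws an arrival time from the Poisson process
   over the dwell; frames tick at 2000 s⁻¹; charge-sharing partners share
   their parent's frame.

The absolute beam flux is a configuration parameter (the bench value is
unpublished), so all claims downstream are ratios, shapes or statistical
properties — never absolute count rates.

## Event processing and image formation

* **Calibration**: per-pixel two-point linear fit through the 59.54 and
  122 keV photopeak centroids (highest bin ± 3 centroid; a pixel missing a
  peak is flagged dead and dropped).
* **CSD**: within each (frame, module), any event with another event at
  Chebyshev distance ≤ 1 is rejected, whole clusters at a time. Modules are
  physically separate, so no cross-module adjacency exists. The fast
  implementation is group-wise and is proven equal to the O(n²) all-pairs
  rule on a thousand seeded random frames.
* **Merging**: each event's pixel center is back-projected through its
  pinhole; the point of closest approach to the beam line gives its
  object-space beam depth (1 mm rows over the 20 mm FOV — 2 detector pixels
  per row through the 1:2 minification) and axial column. All module
  inversions and opposite-panel flips fall out of this single geometric
  rule. Nearest-bin assignment with edge clipping keeps integer count
  conservation exact.
* **Net XRF**: 3 keV window centered on the tabulated Kα energy; straight
  line fitted by least squares to 2 keV sidebands on each side ("close
  vicinity" is unquantified; 2 keV keeps the Kβ lines of both elements out
  of every sideband); σ combines Poisson window counts with the propagated
  fit covariance. No attenuation correction is applied anywhere.
* **Assembly**: column j of the 20 × 37 image is the net-XRF row vector of
  scan position j (0.5 mm columns, 1 mm rows).

## Quantification and dosimetry

CNR, SNR and the Rose rule are as defined above; threshold comparisons are
inclusive. The linearity fit normalizes ROI means by the series maximum
(R² is invariant under any monotone normalization). Tube localization uses
a 3 × 3 bore-matched box filter before the peak search: the 3 mm bore spans
a plateau of ~5 scan columns, so a raw per-voxel argmax is noise-unstable on
the plateau at desk-scale counts even though the signal sits exactly on the
tube.

Dose: exact arithmetic (rate × dwell × positions) reproduces the benchtop
numbers (0.88 cGy/min × 10 min = 8.8 cGy/position, ×37 ≈ 326 cGy). The MC
dose-rate estimator delta-tracks photons through the heterogeneous phantom
with local (kerma) energy deposition — photoelectric absorbs fully, Compton
deposits the Klein–Nishina electron share and follows the photon, coherent
scattering continues the photon undeflected (it is predominantly forward
below 90 keV). Spectrum filtering removes photons from the same source, so
the filtered photon rate is the unfiltered flux times the retained fluence
fraction. The estimator is validated against its closed-form single-pass
expectation (a µ_en-weighted integral built from the same tables) on a thin
water slab; for the full 90 kVp spectrum the sub-21-keV photons carry
~80–85% of the dose, less than the bench's ~95% because the Kramers
continuum is the softer-spectrum bottleneck in the other direction here:
its *relative* hardness above 21 keV exceeds the measured spectrum's.

## The Gd:La response-deficit factor

The end-to-end simulation of the two-element study reports the mean factor
by which observed Gd:La concentration ratios fall below truth. The package's
decomposition: above-edge cross-section ratio 1.48 (La/Gd, per unit mass) ×
Kramers spectrum-intensity factor ≈ 1.57 between the two excitation bands ×
fluorescence-yield and branching corrections (≈0.99) × exit-attenuation and
escape corrections (≈0.85–0.9), giving ≈1.95–2.0; seeded runs report
1.9–2.0. The bench reports ≈1.67 with the difference constant across tubes —
consistent with a measured continuum that is harder above 40 keV than the
Kramers form this model deliberately retains (see Source spectrum). The
constancy across tubes and the element separability (each element's image
peaking at its own highest-concentration tube) are reproduced; the absolute
factor carries the spectrum model's bias and should be read with that
caveat.

## What passing tests do and do not show

The synthetic studies demonstrate geometric correctness (projection,
merging, localization to a voxel), statistical correctness (Poisson
emission, count conservation, estimator calibration against closed-form
oracles) and the directions and approximate magnitudes of the physical
effects (edge ratios, spectrum fractions, attenuation ordering, escape
asymmetry, dose-filter reduction). They do not validate absolute count
rates or absolute dose (unpublished source flux, analytic spectrum),
detector-specific artifacts beyond Gaussian blur + sharing + escape
(polarization, pile-up, depth-of-interaction), collimator penetration, or
multiple scatter. Detection-limit claims (e.g. visibility of 0.1 mg/mL Gd)
are therefore condition-relative: they hold at the simulated statistics,
which are far below the bench's.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest that
make each statistical check stable: 10⁶ rays for the sensitivity MC,
≥2 × 10⁵ emitted XRF photons per tube (t7 runs at ≈2× that), 20 seeded
scans for localization at the one-hour protocol, 2–6 × 10⁴ histories for
dose MC. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical configuration and seed reproduce
byte-identical event streams.
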