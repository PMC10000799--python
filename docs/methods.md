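# Methods

## Forward model

The hologram is computed in normal mode — the fluorescent photon is the
scattered wave, so the relevant wavenumber is that of the Mn Kα line
(5.899 keV, k = 2πE/hc ≈ 2.99 Å⁻¹; configurable).  For each
emitter-centered cluster the oscillation along emission direction k̂ is the
single-scattering sum

    chi(k_hat) = -r_e * sum_j occ_j * f_j(theta_rj)/r_j
                 * exp(-sigma^2 k^2 (1 - cos theta_rj))
                 * cos(k r_j (1 - cos theta_rj)),
    sigma^2 = <u2>_Rel / 3.

Assumptions and conventions:

* **Single scattering, real form factors.** No multiple scattering, no
  polarization factor, no anomalous (complex) phase.  The overall sign and
  r_e prefactor are convention constants (`constants.CHI_SIGN`, the
  `physical_scale` switch): the sign is fixed so forward-scattering
  features are intensity *dips*, and the amplitude scale cancels in every
  downstream statistic (the R-factor carries a free least-squares scale,
  FS directions and the valence decomposition are scale-invariant).
* **Disorder.** `<u2>_Rel` is the isotropic mean-square displacement of a
  scatterer *relative to its emitter* (thermal plus static positional
  disorder), entering as a Gaussian damping with sigma^2 = `<u2>_Rel`/3
  from the per-component relation <u2>/6 = sigma^2/2.  The damping is
  identically 1 at theta_rj = 0, which is why FS dips survive the extreme
  disorder of protein crystals while interference rings wash out — the
  behavior the dimer tests pin down.  Only an isotropic, cluster-wide value
  is modelled (no per-atom or anisotropic disorder).
* **Form factors** are the International-Tables 4-Gaussian sums evaluated
  at q = 2k sin(theta_rj/2); coefficients come from gemmi's table and the
  vectorised evaluation is cross-checked against gemmi's own scalar
  evaluator in the tests.  f(0) ≈ Z within 0.1%.
* **Occupancy** scales each scatterer's contribution linearly — the
  simplest physically sensible treatment of partial sites.
* **Grids.** chi lives on a regular (theta, phi) grid in degrees, theta
  from the +z pole, phi from +x toward +y; default 1° steps, theta up to
  90° for calculated patterns and up to 180° in the reduction (an
  arbitrarily oriented crystal's detector cap can fall in either
  hemisphere).  All grid-wide statistics use sin(theta) solid-angle
  weights; the theta = 0 row therefore carries zero statistical weight.

## Structure handling

PDB/mmCIF files are read with gemmi.  Alternate conformations keep the
highest-occupancy altloc (ties alphabetical).  Unit-cell expansion applies
the space-group operators in fractional coordinates with the standard
a-along-x orthogonalization, wrapping each *residue group* by its centroid
so cluster geometry is never split across cell boundaries; the expansion of
the bundled two-cluster dimer under P2₁2₁2₁ yields 8 cluster copies and 32
Mn emitters with identical intra-cluster distance multisets.  S₁-state
valence tags map the Mn sites as Mn1, Mn4 → III and Mn2, Mn3 → IV.

### The bundled stand-in structure

`data/oec_synthetic.pdb` is a *synthetic* Mn₄CaO₅ model: the deposited
PSII coordinates are not redistributable, so the metal skeleton was solved
from the published distance set (Mn1–Mn2 2.81, Mn2–Mn3 2.91, Mn1–Mn3 3.29,
Mn3–Mn4 2.89, Mn1–Mn4 4.90, Mn2–Mn4 5.44, Ca–Mn 3.35–3.41 Å) with
µ-oxo bridges placed at chemically sensible 1.8–2.1 Å bonds, in the
printed unit cell (122.2 × 228.5 × 286.4 Å, P2₁2₁2₁), two copies per
asymmetric unit related by a non-crystallographic two-fold.  It reproduces
the worked-example numbers (cell read-back, 32 emitters, 16+16 valence
split, the 2.89 Å dangler pair) through the real code path; it is not a
substitute for deposited coordinates when analysing real data.

## Detector model and synthetic data

A flat detector at distance D records the gnomonic projection: pixel
offsets (x, y) map to the direction (x, y, D)/|·|, composed with the
detector basis (axis default along the hologram pole; the physical
detector arm is reduced to one configurable rotation, and the in-plane
mount rotation is explicit).  Energy windowing and filter transmission are
folded into a single exposure scale; charge sharing, flat-field and
pile-up are out of scope.

The synthetic-scan generator defines the study conditions the tests run
under: expected counts `exposure * P * (1 + chi)` with Poisson noise,
24-bit saturation, a configurable number (default 20) of seeded hot/dead
pixels, per-crystal orientations, multi-position scans at two incident
energies mixing the valence holograms as chi_H = (chi_III + chi_IV)/2 and
chi_L = (alpha chi_III + beta chi_IV)/2 with (alpha, beta) = (0.75, 0.55).
Fixture holograms are rescaled to a peak modulation of 0.2 — large enough
to measure cheaply, still well inside |chi| < 1 — and the default fixture
exposure is 1000 counts/pixel.  What the generator does *not* emulate:
Kossel/diffraction lines, detector sensitivity structure, cryo-loop
scatter, orientation-indexing errors, dose-dependent drift.  Passing tests
therefore demonstrate the correctness of the reduction and fitting chain
under the stated noise model, not robustness to every artifact of real
beamtime data.

## Reduction chain

Per crystal: integrate the scan frames; repair outliers selectively (a
pixel is replaced by its 3×3 median only when its residual against the
median image exceeds `clip` × scale of the residual histogram, scale being
the MAD floored at the Poisson level sqrt(median count) — a global median
filter would blur the hologram); normalize by the rotation-series mean P
(pixels masked in any series frame are masked in P); resample the gnomonic
image onto the sphere by bilinear back-projection; flatten by dividing
with a wide spherical-Gaussian smooth (sigma unstated upstream — a free
parameter, default 20°); rotate into the common crystal frame (the inverse
of the crystal→lab orientation from diffraction indexing).  Across
crystals: photon-weighted per-node mean over valid contributors (the scans
have unequal totals), subtract 1, low-pass with sigma = 10°, remove the
residual weighted mean so chi is exactly mean-zero, and optionally average
over the crystal point group (default operators for the PSII case: the
three two-fold rotations of 222; inversion partners optional and off by
default, since the operators are not stated upstream).

Numerical choices:

* **Spherical smoothing** (used by flatten and the low-pass) is an exact
  great-circle Gaussian kernel with sin(theta) weights, evaluated row-wise
  by azimuthal FFTs (the kernel depends only on the two polar angles and
  delta-phi), with masked nodes excluded and weights renormalized — masked
  nodes never leak, and the kernel is exact up to the 4-sigma row window.
* **Interpolation** is bilinear everywhere, with periodic phi and a strict
  mask rule: a sample touching any masked corner is invalid.  Tolerances in
  tests are stated relative to grid step.
* **Mask monotonicity:** every per-fragment step can only shrink validity;
  only composition and symmetry averaging (union semantics) grow coverage.
* Flattening happens on the spherical grid, after projection; the
  gnomonic-space alternative is noted but not implemented.

The end-to-end tests compare the reduced hologram against the *same
spherical-domain operations applied to the exact truth* (flatten, orient,
compose, finalize on analytically evaluated lab-frame holograms).  This
isolates the detector mapping and resampling errors (measured well under
1%) from the intentional filter response: with flatten at 20° and low-pass
at 10° no band passes both filters unchanged, so comparing against raw
truth would mostly measure the designed filters, not the pipeline.

## Fitting

R = Σ w (chi_e − s·chi_c)² / Σ w chi_e², w = sin(theta) on the joint valid
nodes, s the least-squares scale; R = 0 iff proportional, R = 1 for
orthogonal patterns.  The exact normalization of the photoelectron-
diffraction R-factor this mirrors is not printed in the source literature
we follow, so the implemented form is documented here and a symmetric
alternative Σw(e−c)²/Σw(e²+c²) sits behind `form="symmetric"` for
sensitivity checks.  The disorder scan re-evaluates the superposed cluster
hologram on an ascending `<u2>_Rel` grid (default 0.05–2.00 Å², step
0.05), applying the same low-pass and de-meaning as the experimental
hologram before scoring; per-scatterer amplitudes and damping exponents
are precomputed once, so each grid point costs one exponential per
scatterer field.  Ties break toward smaller `<u2>_Rel`.  The mapping from
`<u2>_Rel` to the average per-atom <u2> is *not* implemented as a formula
(the source relation is not fully legible); the module exposes only
B = 8π²<u2>, and the documented reference pair is `<u2>` = 0.2945 Å² →
B = 23.25 Å².

## Valence decomposition

chi_H = f_III chi_III + f_IV chi_IV and chi_L = f_III alpha chi_III +
f_IV beta chi_IV are inverted exactly nodewise; fractions are general (the
S₂ state with a single remaining Mn(III) is expressible) with S₁ defaults
(½, ½).  alpha and beta are *inputs* read off measured absorption spectra
— their normalization involves spectrum-processing choices outside this
package's scope, so they are never computed here.  The inversion amplifies
chi_L noise by 1/(alpha−beta) (a factor 2/(alpha−beta) = 10 on chi_III for
the default parameters), verified against 50 seeded realizations.

Edge inflection: Savitzky–Golay smoothing (default 5-point quadratic,
spectra resampled to a uniform energy step when needed) followed by the
first +→− zero crossing of the second derivative nearest the steepest
rise, linearly interpolated between samples.  A spectrum whose first
derivative never rises 3× above its median magnitude is reported as
"no edge found" (a linear ramp has no inflection).  The damage flag
threshold is 0.5 eV by default.

## Problem sizes used in tests and the acceptance script

Calculated holograms use the full 1° grid where the result is the point
(the disorder-scan recovery); statistical and pipeline tests use 2–3°
grids and 64–128 px detectors, sizes at which every tested quantity is
already stable to well inside its asserted tolerance.  The noisy-recovery
checks use 20 seeded Poisson realizations at the fixture exposure, and the
noise-amplification checks 50.

## Known limitations

* Single-scattering model only; no Barton or L1-regularized atomic
  reconstruction.
* Isotropic, cluster-wide disorder; no per-atom or anisotropic fitting.
* Orientations are inputs — no diffraction indexing.
* No physical XANES modelling beyond inflection detection.
* The bundled structure is a geometric stand-in, not deposited
  coordinates.
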