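# Methods

## Focal-field model

The focal fields are computed with the Richards–Wolf angular-spectrum method
for an aplanatic objective: each plane-wave component of the converging cone
is weighted by the √cos θ apodization and the pupil amplitude, and the
cylindrically symmetric input modes reduce to 1D Bessel integrals over the
focusing angle θ ∈ [0, arcsin(NA/n)]:

* azimuthal input: E_φ ∝ ∫ P(θ) √cosθ sinθ J₁(kρ sinθ) dθ, E_z ≡ 0;
* radial input: E_ρ ∝ ∫ P(θ) √cosθ sinθ cosθ J₁(kρ sinθ) dθ and
  E_z ∝ i ∫ P(θ) √cosθ sin²θ J₀(kρ sinθ) dθ;
* linear (x) input: the standard I₀/I₁/I₂ integrals with their cos φ /
  cos 2φ azimuthal structure.

Assumptions and deliberate simplifications:

* **Homogeneous medium (n = 1.33).** The membrane sits in buffer at the
  focal plane; mica/water and coverslip interface corrections and
  supercritical-angle effects are not modeled. The analysis consumes
  *ratios* of integrated excitation, which are first-order insensitive to a
  common interface transmission factor.
* **Focal plane only (z = 0).** The bilayer (~5 nm) is far thinner than the
  axial extent of the focus, so a single plane suffices.
* **Pupil profile.** The converter's output mode profile is not specified by
  typical hardware; the default is a uniform annular amplitude for the
  doughnut modes (`filling_factor=None`). A Laguerre–Gauss-like filled
  profile (r·exp(−r²) with configurable filling factor) is available; the
  ratio curve shifts only mildly because both modes share the apodization.
* **Quadrature.** Gauss–Legendre over the aperture angle, 128 nodes by
  default; the integrands are smooth, so doubling the node count changes
  field values by far less than 10⁻⁶ relative (asserted in the tests).
* **Normalization.** Every field is rescaled so its grid-window-averaged
  intensity equals a common reference (1, arbitrary units), encoding the
  experimental condition that beam power at the sample is matched across
  polarizations. All downstream ratios are invariant to the constant.

Default sampling is 257 px over ±1000 nm (odd count so the optical axis is a
grid sample); the test suite and acceptance script use 65 px over ±800 nm
with 96 nodes, which resolves the doughnut rings with ~25 px across the
central structure and leaves every field-dependent quantity converged at the
precision the assertions demand.

## Photoselection and the ratio curve

Excitation of a fixed dipole μ(θ, φ) is |E·μ|². Because a fluid membrane is
isotropic in plane, φ is averaged uniformly; the cross terms vanish and the
grid-summed rate collapses to a·sin²θ + b·cos²θ with the two beam moments
a = ½Σ(|Eₓ|²+|E_y|²), b = Σ|E_z|². This closed form is the production path;
the explicit average over discrete φ grids is kept as an independent oracle
in the tests (agreement < 10⁻⁹ relative).

The theoretical ratio R(θ) = a_A sin²θ / (a_R sin²θ + b_R cos²θ) is strictly
increasing on [0°, 90°]: the azimuthal beam cannot excite an axial dipole,
so low ratios mean upright probes and high ratios mean in-plane probes. The
inverse is analytic, θ = arctan √(b_R R/(a_A − a_R R)); a monotone PCHIP
interpolant covers curves re-read from CSV without coefficients. A measured
ratio above a_A/a_R is refused with a diagnostic, since it indicates broken
normalization rather than any orientation.

For an orientation *distribution* the recovered angle is an **effective
tilt**: the unique θ solving R(θ) = ⟨I_A⟩/⟨I_R⟩. Because R is nonlinear,
this is not the distribution mean (for a truncated normal centered at 41°
with 15° spread the effective angle is ≈ 41.6°); the estimate records this
convention in its `method_tag`/metadata rather than pretending to a mean.

Tilt angles are measured from the membrane normal (the optical axis)
throughout. Molecular-dynamics tilt series that span 0–180° are folded into
the first quadrant (θ ↦ 180° − θ above 90°, so 100° → 80°), which preserves
the physics since μ and −μ are the same absorber, and conformer
distributions are combined by probability-weighted means with configurable
conformer population weights (default equal; 0.51/0.49 is the
single-component-membrane literature value).

Emission-side collection is treated as orientation-independent by default:
in the ratio of two excitation modes at a single θ the collection factor
cancels exactly, and for distributions it is a second-order reweighting. A
`high_na_weighting` model (classical sin²Ψ dipole radiation integrated over
the collection cone, normalized to its maximum) is provided for sensitivity
analysis.

## Image analysis

Paired scans from one piezo raster are assumed pixel-registered; an
integer-shift cross-correlation aligner exists behind a flag for drifted
pairs. Segmentation defaults to Otsu thresholding of the radial-excitation
image — both phases are bright there, so the threshold is stable — with the
ordered phase taken as the darker class, followed by a binary opening
(disk, radius 2 px) to remove speckle. Thresholding the mean-normalized
difference image is available as `otsu_difference`, and a manual label TIFF
can bypass segmentation entirely (`manual_roi`), mirroring hand-drawn ROI
workflows. Constant images and segmentations that empty a class are refused
rather than silently quantified. Phase statistics are plain arithmetic means
per phase per image; line profiles use bilinear sampling with configurable
transverse averaging width.

## Spectra and generalized polarization

GP = (I_blue − I_red)/(I_blue + I_red) with each band averaged over a
rectangular window (default 440/490 ± 5 nm, the common Laurdan band
convention; both centers and the half-width are configurable so alternative
band definitions, including integrated-band variants via wider windows, can
be matched). The statistic is bounded in [−1, 1], scale-invariant, and
antisymmetric under band swap — all asserted as properties.

The orientation-conditioned spectral model is a unit-peak single band per
phase (Gaussian in wavelength by default, log-normal behind a flag; defaults
425 nm / 50 nm FWHM ordered, 475 nm / 60 nm FWHM disordered) whose center
red-shifts by c·sin²θ with a configurable coefficient c (nm per sin²θ,
default 0; 20 nm is used where the coupling itself is under test). The
population spectrum under a beam is the mixture of θ-spectra weighted by
p(θ)·(a sin²θ + b cos²θ); with c > 0 the azimuthal weighting necessarily
yields a lower GP than the radial weighting for any broad distribution,
which is the experimentally observed direction of the polarization bias in
GP. The coefficient is a phenomenological stand-in for dipolar-relaxation
physics — the model is for direction and magnitude exploration, not for
fitting absolute GP values.

## Synthetic data generator

The generator emulates a phase-separated supported bilayer as the analysis
sees it:

* **Domain map**: Gaussian noise smoothed at a feature scale (default 12 px)
  and thresholded at the target quantile, giving blob-like ordered domains
  with an exact area fraction (default 30%).
* **Tilt distributions**: delta (default) or truncated normal on [0°, 90°];
  defaults 32° (ordered) and 41° (fluid) with spreads 8°/15° when the spread
  family is selected — the ordered phase narrower, as tighter packing
  implies.
* **Pixel intensities**: expected counts = background + (molecules per
  pixel)·brightness·⟨a sin²θ + b cos²θ⟩, Poisson-sampled. The beam moments
  here are window means (grid-resolution independent). Defaults: 100 nm
  pixels, dye surface density 3×10⁵ µm⁻² (10 mol% of ~3×10⁶ lipids/µm² over
  two leaflets, consistent with ~10⁴ probes in a diffraction-limited spot),
  brightness 0.04 (Lo) / 0.065 (Ld) photons per molecule per unit excitation
  — the fluid phase brighter under either beam, as in real Laurdan scans —
  and 1 background count.
* **Spectra**: the population spectrum per phase scaled to a peak count
  (default 10⁴) and Poisson-sampled.

Per-pixel expectation uses the φ-averaged closed form rather than
per-molecule Monte Carlo: it is exact in expectation and fast; the
excitation-pattern path remains available for single-molecule fidelity
work. All randomness flows from explicit integer seeds (sub-seeds derived
via `SeedSequence`), so identical configurations are bit-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: domain-edge pixels of mixed phase, probe
partitioning differences beyond a scalar brightness, photobleaching, stage
drift, detector afterpulsing, flat-field error, interface-modified focal
fields, and any coupling between orientation and quantum yield. Recovery
accuracy on synthetic scenes is therefore an internal-consistency statement
about the estimator chain, not an error bar for instrument data.

## End-to-end recovery and problem sizes

`end_to_end_recovery` simulates a scan pair, segments it, forms phase-wise
ratios (after subtracting the known background, as one would subtract
measured dark counts), and inverts them. Truth is defined as the inversion
of the noise-free expected ratios through the same curve, so delta scenes
have exact integer truths. The validation suite runs 20 replicates of a
128×128 px scene with ≥10⁶ expected photons per phase: recovered tilts land
within a few hundredths of a degree of 32°/41° and the Lo < Ld ordering is
preserved in every replicate. Convergence with photon budget is checked on
ground-truth masks to isolate photon statistics from segmentation.

## Numerical and design notes

* Equality of normalized mean intensities is enforced to 10⁻⁹ relative
  before a ratio curve is built; measured ratios are clipped to the curve
  maximum only in the recovery harness (where Poisson noise can push a
  ratio marginally past it), never in `invert_ratio` itself.
* Angle-distribution normalization is enforced to 10⁻⁹; probability weights
  are renormalized after excitation weighting in population spectra.
* The rotational-symmetry checks compare cubic-spline rotated intensity maps
  inside 60% of the window radius at 2% of the peak — the tolerance of the
  interpolation, not of the fields, which are radially exact by
  construction.
* One sign convention deserves a flag: lower I_A/I_R always corresponds to a
  *smaller* tilt from the membrane normal (more upright probe). Statements
  to the contrary occasionally appear in the applied literature; the
  monotone-increasing curve follows directly from the azimuthal mode's
  sin²θ-only coupling and is what the inversion here implements.
* Known limitations: no 3D PSF or defocus, no aberrations, no
  interface/supercritical emission corrections, effective angles only (no
  distribution-shape inference), excitation-side photoselection only
  (ground-state geometry; excited-state TDM rotation ignored).
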