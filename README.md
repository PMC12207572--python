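# polorient

Polarization-resolved orientation analysis of fluorescent membrane probes.

Environment-sensitive probes such as Laurdan do not sit in a lipid bilayer at
a random angle: the tilt of their transition dipole moment (TDM) relative to
the membrane normal depends on the lipid phase, and that tilt biases every
fluorescence readout made with polarized excitation. `polorient` implements
the full quantitative workflow for measuring this tilt in supported lipid
bilayers with cylindrical vector beams, for microscopists and membrane
biophysicists who have paired azimuthal/radial scan images and emission
spectra and want numbers out of them:

1. **Vectorial focal fields.** Richards–Wolf angular-spectrum focusing of
   azimuthally, radially, and linearly polarized beams through a high-NA
   aplanatic objective (default: λ = 375 nm, NA 1.30, water-like medium,
   n = 1.33). The azimuthal focus is purely transverse; the radial focus has
   a strong longitudinal on-axis component — the contrast that encodes
   orientation.
2. **Dipole photoselection.** The excitation of a dipole tilted at θ from
   the membrane normal, averaged over the in-plane azimuth, is the quadratic
   form a·sin²θ + b·cos²θ, with beam moments a = ½ Σ(|Eₓ|²+|E_y|²) and
   b = Σ|E_z|² of the focal field.
3. **Tilt inversion.** With both beams normalized to equal mean focal-plane
   intensity, the theoretical ratio

   R(θ) = I_A/I_R = a_A sin²θ / (a_R sin²θ + b_R cos²θ)

   rises strictly from 0 (θ = 0) to a_A/a_R (θ = 90°), so a measured
   phase-wise ratio inverts uniquely:
   θ = arctan √(b_R·R / (a_A − a_R·R)).
4. **Image quantification.** Otsu segmentation of the liquid-ordered (Lo)
   domains — the darker patches — from the radial-excitation image,
   phase-wise mean intensities, difference images and line profiles.
5. **Spectra.** Generalized polarization GP = (I_blue − I_red)/(I_blue +
   I_red) with configurable bands (default 440/490 ± 5 nm), plus an
   orientation-conditioned spectral model in which in-plane probes red-shift
   ∝ sin²θ, reproducing the excitation-polarization dependence of GP.
6. **Synthetic ground truth.** A forward simulator (two-phase domain maps,
   per-phase tilt distributions, Poisson photon noise, noisy spectra) so the
   whole chain is testable end to end without instrument data.

## Worked example

```python
import polorient as po

cfg = po.ObjectiveConfig(grid_points=65, grid_extent_nm=800.0,
                         aperture_quadrature_points=96)
az  = po.focal_field("azimuthal", cfg)
rad = po.focal_field("radial", cfg)
curve = po.ratio_curve(az, rad)
print("max ratio:", round(curve.max_ratio, 3))

# synthetic bilayer: ordered phase tilted 32 deg, fluid phase 41 deg
model = po.default_membrane(seed=1, shape=(128, 128),
                            lo_theta_deg=32.0, ld_theta_deg=41.0,
                            brightness={"Lo": 0.16, "Ld": 0.26})
report = po.end_to_end_recovery(model, az, rad, seed=1)
print(f"Lo: I_A/I_R = {report.measured_ratio_lo:.3f} "
      f"-> theta = {report.recovered_theta_lo_deg:.2f} deg")
print(f"Ld: I_A/I_R = {report.measured_ratio_ld:.3f} "
      f"-> theta = {report.recovered_theta_ld_deg:.2f} deg")
```

prints

```
max ratio: 2.231
Lo: I_A/I_R = 0.305 -> theta = 31.99 deg
Ld: I_A/I_R = 0.523 -> theta = 40.98 deg
```

The simulated scan pair is segmented by Otsu thresholding, the phase-wise
mean-intensity ratios are formed, and each ratio is inverted through the
theoretical curve: both ground-truth tilts come back to within a few
hundredths of a degree at this photon budget (~10⁶ expected photons per
phase). A lower I_A/I_R means the probe stands more upright (closer to the
membrane normal); a higher ratio means it lies more in the membrane plane.

With the tilt→red-shift coupling enabled, the same machinery shows the
spectral consequence of orientation: for a broad fluid-phase tilt
distribution the azimuthal (in-plane-selective) beam probes a redder
population than the radial beam, e.g. GP = −0.654 (azimuthal) versus −0.580
(radial) for the disordered phase of the default synthetic scene — polarized
excitation biases GP, which matters whenever GP is read as membrane fluidity.

## Command line

```bash
polorient simulate --config run.yaml --out data/      # synthetic TIFF pair + spectra
polorient curve    --config run.yaml --out out/       # theoretical ratio curve (CSV + PNG)
polorient analyze  --azimuthal data/azimuthal.tif --radial data/radial.tif \
                   --config run.yaml --out stats.json # segmentation -> ratios -> tilt angles
polorient invert   --curve out/ratio_curve.csv --ratio 0.31 --phase Lo
polorient gp       --spectra data/ --blue 440 --red 490 --halfwidth 5
```

All JSON outputs embed the package version, a config hash, and the seed.

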