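# pctpath

Quantitative micro-morphology from propagation-based X-ray phase-contrast
tomography (PCT).

Synchrotron PCT images weakly absorbing soft tissue by letting the beam
propagate a distance *D* past the sample, turning phase distortion into
measurable edge-enhanced intensity. `pctpath` implements the full analysis
chain that turns such projections into tumor micro-morphology statistics —
and, because real specimen data of this kind are not public, it ships a
synthetic-phantom module with exact ground truth so every stage is testable
end to end:

1. **Forward simulation** — Fresnel free-space propagation of homogeneous
   (single-material) objects; 3D cylinder-network vessel phantoms; labeled
   texture-class image sets; parallel-beam sinograms.
2. **Phase retrieval** — single-distance inversion under the
   phase-attenuation duality. With `χ(u,v) = πλD(u² + v²)` on the discrete
   frequency grid and duality ratio `ε = δ/β`,

       φ(x,y) = (ε/2) · ln F⁻¹[ F(I_D/I_in) / (cos χ + ε·sin χ) ]

   which reduces to the Paganin-type low-pass filter `1 + εχ` as `χ → 0`
   and exactly inverts the linearized homogeneous-object contrast transfer
   model (verified by round trip). Includes flat/dark background
   correction, `λ = hc/E`, and the surface-dose estimate
   `dose = F·E·(μ_en/ρ)`.
3. **Reconstruction** — parallel-beam filtered back-projection
   (ramp / Shepp–Logan / Hann filters, optional rotation-center offset).
4. **Vessel morphometry** — Otsu binarization (exhaustive between-class
   variance, ties to the lowest level), medial-axis + distance-transform
   local diameters, sectional areas per diameter interval `Σ π(d/2)²`,
   volumetric microvessel density (3D-MVD) split into surface and inner
   regions, and pooled-variance t-tests at α = 0.05.
5. **Texture panel** — the fixed 49-feature descriptor: GLCM
   energy/homogeneity/contrast/correlation at (0°,1), (45°,1), (90°,1),
   (135°,1) [A1–D4]; 15 gray–gradient co-occurrence features [E1–E15];
   gray-histogram moments [H1–H5]; gray-level difference statistics
   [I1–I4]; 3-level Haar wavelet subband energies [M1–M9].
6. **Feature screening** — per-feature ROC AUC (rank-sum with tie
   correction, folded to `max(AUC, 1−AUC)`, threshold 0.75), PCA on the
   correlation matrix with Kaiser retention (eigenvalue > 1) and the
   cumulative contribution rate reported against 90%, and per-stage
   mean ± SD of summed component scores.
7. **Classifier data prep** — the deterministic tiling arithmetic feeding
   a CNN: 3 orthogonal orientations × every slice × 4 quadrant subgraphs
   (1024² → 4 × 512² → 227²) × fourfold rotation augmentation, with
   specimen-level 70/15/15 splits. A 1024³ volume yields 12,288 original
   and 49,152 augmented tiles; 100 specimens give 1,228,800 images.
   Counts come from manifests — no giant arrays are materialized.

## Worked example

```python
import numpy as np
from pctpath import (ImagingGeometry, PhantomSpec, Cylinder, make_vessel_phantom,
                     simulate_projection, retrieve_phase, segment_vessels,
                     local_diameters, mvd, wavelength_from_energy)

print(f"wavelength at 15 keV: {wavelength_from_energy(15.0):.3e} m")

# simulate a 7 cm propagation image of a smooth soft-tissue blob and invert it
geom = ImagingGeometry(energy_keV=15.0, distance_m=0.07, pixel_m=6.5e-6,
                       delta=1e-6, beta=1e-9)
yy, xx = np.mgrid[:256, :256]
thickness = 5e-4 * np.exp(-((yy - 128)**2 + (xx - 128)**2) / (2 * 40.0**2))
intensity = simulate_projection(thickness, geom)
phi = retrieve_phase(intensity, geom).phi
true_phi = -2 * np.pi * geom.delta * thickness / geom.wavelength_m
rmse = np.sqrt(np.mean((phi - true_phi)**2)) / np.ptp(true_phi)
print(f"phase retrieval RMSE: {100 * rmse:.3f}% of the true phase range")

# vessel morphometry on a tube phantom with known geometry
spec = PhantomSpec(shape=(64, 64, 64), voxel_size=6.5e-6,
                   cylinders=(Cylinder((0, 32, 32), (1, 0, 0), 8.0, 200.0),),
                   background_value=10.0)
volume, truth = make_vessel_phantom(spec)
mask = segment_vessels(volume)
skel = local_diameters(mask)
total, surface, inner = mvd(mask)
print(f"median vessel diameter: {1e6 * np.median(skel.diameter_m):.1f} um "
      f"(true 104.0 um)")
print(f"3D-MVD total/surface/inner: {total:.4f} / {surface:.4f} / {inner:.4f} "
      f"(voxelized truth {truth['volume_fraction']:.4f})")
```

prints

```
wavelength at 15 keV: 8.266e-11 m
phase retrieval RMSE: 0.003% of the true phase range
median vessel diameter: 104.8 um (true 104.0 um)
3D-MVD total/surface/inner: 0.0481 / 0.0195 / 0.0729 (voxelized truth 0.0481)
```

The retrieved phase matches the simulated object's true phase map to a
fraction of a percent; the radius-8-voxel tube (true diameter 2r = 16 voxels
= 104 µm at 6.5 µm/voxel) is recovered within one voxel; the measured
vessel volume fraction equals the phantom's voxelized truth.

A command-line interface mirrors the library
(`pctpath phantom|retrieve|recon|vessels|features|screen|tiles --help`).

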