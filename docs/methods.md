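# Methods

## Imaging model and forward simulation

The sample is modelled as a single homogeneous material with complex
refractive index n = 1 − δ + iβ. A parallel monochromatic beam of energy
E (wavelength λ = hc/E; 8.27 × 10⁻¹¹ m at the default 15 keV) crosses a
projected thickness t(x, y), producing the exit wave

    ψ₀ = exp(−2πβt/λ) · exp(−2πiδt/λ),

which propagates a distance D to the detector via the angular-spectrum
transfer function H(u, v) = exp(−iπλD(u² + v²)) evaluated on the discrete
frequency grid implied by the pixel pitch. The recorded quantity is
|ψ_D|², normalized to unit incident intensity. The grid is edge-padded by
a factor 2 before the FFT to suppress wrap-around; Poisson noise at a
stated photon fluence is available but off by default, with an explicit
seed. At D = 0 the model reduces exactly to Beer–Lambert transmission
exp(−4πβt/λ), and for β = 0 propagation is unitary (mean intensity
conserved to better than 10⁻³ on interior-supported objects) — both are
tested.

Defaults mirror a synchrotron soft-tissue acquisition: 15 keV, D = 7 cm,
6.5 µm pixels. No public δ/β value exists for these specimens, so the
duality ratio defaults to ε = 1000, the right order of magnitude for soft
tissue at 15 keV; it is a constructor argument everywhere.

## Single-distance phase retrieval

For a homogeneous object the phase and attenuation projections are
proportional (φ = −ε·B with B = 2πβt/λ), which lets one intensity image
at one distance determine the phase map:

    φ(x, y) = (ε/2) · ln F⁻¹[ F(I_D/I_in) / (cos χ + ε·sin χ) ],
    χ(u, v) = πλD(u² + v²).

Linearizing the forward model gives Ĩ(f) = δ(f) − 2B̃(f)(cos χ + ε sin χ),
so the filter above inverts it exactly; the implementation recovers a
simulated smooth phantom's phase with RMSE ~10⁻⁴ of the phase range
(the acceptance suite requires < 5%). As χ → 0 the denominator tends to
the transport-of-intensity (Paganin) form 1 + εχ, and at D = 0 it is
identically 1, collapsing to the pure-absorption inversion (ε/2)·ln I.
An alternative parsing of the filter, cos χ + (ε + χ)·sin χ, is available
via `denominator="alternative"`; it does not invert the linearized model
and is provided for comparison only.

Numerical choices: the denominator crosses zero at finite frequencies, so
its magnitude is clamped at a Tikhonov floor (default 10⁻³, sign
preserved); the filtered field is clipped at 10⁻⁶ of its maximum before
the logarithm and the number of clipped pixels is reported on the result;
flat/dark frames are reduced by a per-pixel median (robust to hot
pixels), and pixels where flat ≤ dark are floored with a warning. The
filter acts per projection, before reconstruction.

The surface-dose estimate multiplies fluence rate, exposure per
projection, projection count, photon energy and the mass
energy-absorption coefficient; with fluence in photons·mm⁻²·s⁻¹ and
μ_en/ρ in mm²·kg⁻¹ the product resolves to Gy.

## Reconstruction

Parallel-beam filtered back-projection (no optics between sample and
detector justifies the parallel geometry). Filtering and back-projection
are delegated to scikit-image's `iradon` (frequency-domain ramp filter,
optionally Shepp–Logan or Hann windowed; linear-interpolation
back-projection scaled to recover attenuation units); the module
contributes the sinogram layout (angle × detector), validation, an
optional rotation-center offset (real axes never center exactly), and
slice-wise stacking into (z, y, x) volumes. The forward `radon` restricts
each slice to the inscribed circle about the discrete rotation center —
the only region parallel-beam FBP determines. Round trips on disk and
cylinder phantoms hold interior RMSE under 5% with 180 views at 1°.

## Vessel morphometry

Binarization uses Otsu's criterion over a 256-bin histogram, written out
explicitly (rather than wrapped) because the tie-break matters for
reproducibility: the lowest level attaining the maximal between-class
variance is chosen, and tests verify exact agreement with an exhaustive
search over all splits. Components smaller than 27 voxels (6-connected)
are removed as speckle; both the bin count and the minimum size are
parameters.

Local diameters come from 3D topological thinning plus the Euclidean
distance transform: diameter = 2 × EDT × voxel size at each skeleton
voxel. Two numerical corrections matter at this scale. First, the
discrete skeleton of an oblique tube sits up to about half a voxel off
the true axis, biasing EDT low; sampling the EDT as the maximum over each
skeleton voxel's 26-neighborhood removes the bias (validated on 20 random
tube orientations: worst median-diameter error 0.46 voxel, tolerance one
voxel). Second, the installed thinning routine can erase perfectly
straight, translation-symmetric tubes entirely at some sub-voxel
alignments; when thinning empties a non-empty mask the implementation
falls back to the distance-transform ridge (voxels whose EDT equals its
26-neighborhood maximum) as the medial locus.

Sectional area per diameter interval is Σ π(d/2)² over skeleton points in
the bin — an explicit, monotone-in-d definition. 3D-MVD is the vessel
voxel fraction, reported in total and separately for the surface region
(voxels within a shell of the sample boundary; default shell 10% of the
smallest dimension) and the inner remainder, each on its own voxel
count, so the total is exactly the count-weighted mean of the two.
Group comparison is the two-sided pooled-variance t-test with
significance at p < 0.05.

Known limitation: the cylinder phantoms rasterize by voxel-center
membership, so a tube of radius r voxels carries an O(1/r) discrepancy
between voxel count and πr² — up to ~3% below r ≈ 5 at unfavourable
sub-voxel centers. Morphometry recovers the voxelized mask essentially
exactly; comparisons against the *analytic* cross-section are therefore
made on tubes of radius ≥ 8 voxels, where rasterization is below the 2%
tolerance.

## Texture panel

All 49 features are computed on 2D grayscale images. Co-occurrence
families quantize gray values (and Sobel gradient magnitudes) to 16
levels by linear min–max rescaling — a constant image maps to level 0 —
making them invariant to affine gray rescaling of non-constant images.
GLCM matrices are symmetric and normalized; directions follow 0° = +column,
90° = +row (hence 45° = (+1,+1), 135° = (+1,−1)), distance 1. GGCM uses
the classical 15-feature definition on the joint gray/gradient histogram
(the small-gradient dominance uses 1/(j+1)² with 0-based gradient level).
Histogram moments use the integer gray value floor(pixel) clipped to
0–255, so an image of constant value c reports mean c. GDS averages the
four unit displacements (0,1), (1,0), (1,1), (1,−1) on the quantized
image. Wavelet features are detail-subband energies of a 3-level Haar
decomposition with periodized boundaries (keeps the transform orthogonal:
the nine detail energies plus the approximation energy sum to the image
energy), normalized by total image energy. All entropies use the natural
logarithm with 0·log 0 = 0; all correlations define 0 on zero marginal
variance. Quantization depth, GDS displacements and the wavelet family
are configurable; the recorded defaults above are used throughout the
tests. Every co-occurrence family is verified against brute-force
double-loop oracles to 10⁻¹².

## Feature screening

AUC uses the rank-sum (Mann–Whitney) formulation with midranks, folded to
max(AUC, 1 − AUC) so anti-correlated features survive; with multiclass
stage labels each feature keeps its maximum folded one-vs-rest AUC. The
selection threshold defaults to 0.75. PCA standardizes features (z-score)
and eigendecomposes the correlation matrix — the appropriate choice for
heterogeneous feature scales — retaining components with eigenvalue > 1
(Kaiser) and reporting the retained set's cumulative contribution rate
against the 90% mark. Component signs are fixed so the largest-magnitude
loading is positive; eigenvalue sums are conserved to 10⁻⁹ (trace of the
correlation matrix). Stage summaries report mean ± SD of each sample's
summed retained-component scores, grouped by stage. On synthetic 4-stage
data with planted monotone-trend features (n = 240, which makes a noise
feature crossing 0.75 a > 5σ event), selection recovers exactly the
planted set across 50 seeds.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* of the study conditions —
single-material weak absorbers at 15 keV / 7 cm / 6.5 µm, tube networks
of known radii and volume fraction in a uniform background, and
texture-class image sets with class-distinct correlation lengths, means
and contrasts standing in for lesion types. They do not emulate detector
blur, polychromaticity, ring artifacts, real vessel branching topology,
or the actual gray-level statistics of tumor tissue; passing tests
demonstrate correctness of the algorithms against known ground truth, not
clinical performance on real specimens. Reported screening percentages
(e.g. per-component contribution rates) on synthetic data will differ
from any real-data values by construction.

## Problem sizes

Tests and the acceptance script use 256² projections, 128² slices with
180 views, 64³ morphometry volumes, ≤ 16² oracle images and n = 240
screening samples; full-scale (1024³) tiling quantities are computed from
manifests without materializing volumes. The whole suite runs in well
under a minute.
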