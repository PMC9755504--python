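# Methods

## Model and scope

The package reconstructs maps of shear wave speed (SWS, m/s) and
penetration rate (PR, m/s) from multifrequency MRE displacement series by
k-MDEV inversion: phase-gradient wavenumber estimation on directionally
decomposed scalar wave fields, compounded with amplitude weights over
directions and components and harmonically over frequencies.  The model
assumes time-harmonic plane shear waves in a linear viscoelastic medium,
u(r,t) = u₀·exp(i(k*·r − ωt)) with k* = k′ + i·k″.  First-order gradients
make the estimate robust to noise relative to Laplacian-based direct
inversion; the price is edge artifacts wherever filter or stencil support
crosses a boundary, which is why edge slices are trimmed.

Wavenumbers are averaged across the vibration frequencies without a
dispersion model (the harmonic means above are equivalent to averaging
k′/ω and k″·2π/ω); no rheological model is fitted.

Conventions: axis order (x, y, z) = NIfTI (i, j, k), slice axis z; voxel
spacing stored in mm and converted to metres for all wavenumber math;
displacements in µm; k′ in rad/m and k″ in 1/m, kept distinct to avoid 2π
mistakes; a complex harmonic field ũ represents Re[ũ·exp(−iωt)], so a wave
travelling along +n̂ has phasor exp(+ik′ n̂·r).  Inputs are displacement
fields in µm — converting scanner phase images via the encoding efficiency
is the caller's responsibility.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| 2D bandpass | order 3, 15–250 cycles/m | compression suppression + smoothing per slice |
| 2D directions | 8 over the full circle | cos² windows, half-width 2π/8, exact partition of unity |
| 3D lowpass | order 1, 200 cycles/m | pre-curl smoothing |
| 3D directions | 20 dodecahedron vertices | max(0, k̂·n̂)⁸ windows, normalized to an exact partition |
| trim_slices | 4 per side | edge-slice exclusion (40 acquired → 32 analysed) |
| min_cycles_per_fov | 1.0 | flag wavelengths the FOV cannot resolve |
| density ρ | 1000 kg/m³ | modulus conversions |
| boundary | "anchored" | field extension before FFT filtering (below) |

Threshold units: the filter thresholds are spatial frequencies in cycles
per metre.  At 20 Hz and ~1.2–1.3 m/s the shear spatial frequency
(~16 cycles/m) sits just above the 15 cycles/m highpass, which thereby
removes slowly varying compression content while passing the shear band.

The angular exponent 8 of the spherical windows keeps adjacent-direction
amplitude crosstalk below 15% at the 41.8° vertex separation; the
per-sample normalization keeps the decomposition lossless regardless.

## Numerical choices

**Gradient stencils.**  Phase gradients are computed unwrapping-free from
conjugate products, ∂arg(u)/∂x ≈ arg(u[i+1]·conj(u[i−1]))/2h, and
amplitude decay from log-ratios ∂log|u|/∂x ≈ log(|u[i+1]|/|u[i−1]|)/2h
(one-sided at boundaries).  These agree with Im(conj(u)∇u)/|u|² to second
order but are exact for plane waves and exponential envelopes; a plain
central difference of the complex field would bias k′ by sin(k′h)/(k′h)
≈ −1% at brain wavenumbers and 1.6 mm spacing, more than the quantity of
interest in validation.

**Boundary extension.**  Wave fields are not periodic over the FOV, and
brain fields decay strongly across it; filtering the raw DFT lets the
wrap discontinuity leak broadband energy that biases k′ by several
percent deep into the interior.  Each pipeline run therefore extends the
complex field once into a smoothly periodic volume using a phase-anchored
conjugate reflection: the conjugated mirror image continues the phase
ramp of any travelling wave, and re-anchoring by the squared boundary
phase per face pixel makes the continuation exact for any locally plane
wave, independent of its global phase; the two single-sided continuations
are cross-faded where the reflected amplitude is smallest.  All FFT
filtering then runs periodically on the extended volume and the maps are
cropped back.  Plain `mirror` and `conj` extensions are available for
comparison and are measurably worse on attenuated waves.

**Stage order in 3D.**  The curl (3-pixel symmetric kernels on the
physical anisotropic spacing, second-order one-sided at faces) runs on
the acquired volume *before* the extension and lowpass: curl and lowpass
commute as linear shift-invariant operators, and applying the curl first
eliminates curl-free compression content exactly before any extension
artifact can mix with it.  The three curl components replace the
displacement components in the amplitude weights; the curl's overall
scaling cancels in the phase gradient and only reweights w.

**Validity.**  A directional estimate is zero-weighted where its
amplitude is below 10⁻¹² of the field maximum or its k′ corresponds to
less than `min_cycles_per_fov` cycles across the largest FOV extent — a
phase gradient cannot resolve a wave it does not see one cycle of, and
such voxels carry low-frequency filter residue rather than signal.
Compounded voxels with zero total weight, and trimmed edge slices, are
NaN in the written maps (0 m/s would be a physically meaningful wrong
value).  Directions holding under 10⁻⁶ of a component's spectral energy
are skipped outright — they cannot influence the weighted sums — and the
per-direction stencils run in single precision (phase error ~10⁻⁷ rad);
both choices are pure performance measures.

**Slice-phase correction.**  The inter-slice offset estimator takes the
argument of the amplitude-weighted mean of u_z·conj(u_{z−1}) per slice
pair, applied cumulatively and independently per (frequency, component).
It is exact for constant per-slice offsets and idempotent.  Limitation:
for a field whose through-plane content is all one-signed (a single
oblique wave) it cannot distinguish a genuine mean phase advance from an
offset and removes it; in reverberant fields with balanced ±k_z content
the estimator is neutral.

## The synthetic generator

`synthesize` evaluates plane shear sources through voxelwise material
fields (slowness, attenuation, shear-amplitude support), accumulating
phase and log-amplitude by exact trapezoidal ray integration along
axis-aligned propagation directions — so the local complex wavenumber
equals 2πf/SWS(r) + i·f/PR(r) even across smoothed interfaces.  Oblique
directions use the homogeneous projection k*·(n̂·r), exact only in
uniform media.  The attenuation scaling is k″ = f/PR, matching the
inversion's PR_f = (ω/2π)/k″.  Compression contamination is a
longitudinal (curl-free) plane wave of wavelength ≥ 10× the largest shear
wavelength; Gaussian noise is added to time-domain displacement samples;
per-slice phase factors exp(iφ_z) emulate interleaved-acquisition timing
offsets.  Everything is deterministic given the seed.

Two study phantoms are provided:

* `brain_like_phantom` — nested ellipsoids with WM 1.28, CGM 1.21,
  DGM 1.42 m/s (PR 0.85/0.80/0.90 m/s) and a central fluid cavity with 2%
  shear support, material fields smoothed over 1.5 voxels, insonified
  from the four in-plane faces with ~10.8 ± 2.5 µm amplitudes.  The head
  is embedded in a tissue-mimicking gel (1.25 m/s) rather than air so
  that the wave field carries no amplitude edge at the object boundary —
  the configuration of a validation phantom scanned in a coupling
  medium.  With a head-in-air configuration, support-edge ringing biases
  even deep white matter by −6…−8%, which mirrors the fluid-boundary
  artifacts seen in vivo (and the practice of excluding fluid-adjacent
  voxels from analysis masks) but would make the phantom useless as a
  quantitative oracle.
* `reverberant_slab_phantom` — homogeneous slab filled by eight plane
  waves in balanced ±30° tilted pairs from four azimuths, providing
  genuine through-plane wave structure while keeping the slice-phase
  estimator neutral; used for the slab-thickness experiment.

What the generator does **not** emulate: diffraction, refraction and mode
conversion at interfaces (wavefronts are straight rays), scanner noise
correlations, ghosting/distortion, physiological motion.  Passing the
synthetic suites therefore demonstrates correctness of the inversion
chain on fields satisfying the method's own model, not performance on
artifact-laden in-vivo data.

## Validation scenarios and their design

* **Plane-wave oracle** (64×64×24, 1.6×1.6×2 mm³, 20/25/30/35 Hz, SWS
  1.28 m/s, k″ = f/0.8 1/m): propagation along the in-plane diagonal, the
  generic orientation — exactly axis-aligned propagation is degenerate in
  that the entire spectrum and all residual boundary leakage collapse
  onto a single FFT axis line where the angular windows cannot separate
  them.  Errors are means over the central quarter of the in-plane FOV
  (within untrimmed slices), clear of the first sidelobes of the
  band-limited filter kernels whose support is of order 1/(15 cycles/m)
  ≈ 7 cm.  Measured recovery: SWS within ~0.6% (2D) / ~0.5% (3D), PR
  within ~2.4% / ~1.7%.
* **Compression suppression**: the brain phantom with a curl-free
  contaminant at 5× the strongest shear amplitude changes the 3D WM mean
  by under 0.3%; the 2D route (bandpass only) shifts by a few percent.
* **Slab thickness**: starting from 39 slices the centre-slice WM SWS is
  exact by construction and becomes increasingly underestimated as slice
  pairs are removed (−5…−8% at 9 slices with the default phantom),
  reproducing the known instability of 3D inversion in thin slabs.  The
  crossover depends on the phantom's wavelength support and is checked as
  a trend, not a fixed threshold.

Problem sizes (64 or 48 voxels in-plane) were chosen so the full
validation battery runs in minutes on a single CPU while keeping ≥1.5
wavelengths of support at the lowest frequency.

## Known limitations

* PR estimates inherit the bandpass tilt over the attenuation-broadened
  spectrum; at 20 Hz the shear line sits on the highpass edge and
  single-frequency PR_f can be biased by tens of percent — the
  multifrequency harmonic mean largely cancels this, which is part of why
  compounding stabilizes the inversion.
* The 3D route is systematically slightly lower and noisier than 2D on
  heterogeneous phantoms (curl and volumetric gradients amplify boundary
  effects), the same ordering reported for in-vivo data.
* Small structures (≲ a wavelength, e.g. the deep-gray nucleus of the
  brain phantom) are flattened toward their surroundings by the filter
  support; region means there are resolution-limited, not unbiased.
* The slice-phase estimator removes genuine net through-plane phase
  advance in single-direction fields (see above).
* Memory: the 3D pipeline on a full 126×126×40 acquisition peaks at
  roughly 2–3 GB per frequency with the doubled (extended) volume.
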