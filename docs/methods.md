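# Methods

`oamrecon` implements model-based image reconstruction for scanning
optoacoustic mesoscopy (OAM): a spherically focused, broadband ultrasound
detector with a central illumination hole is raster-scanned over the sample,
recording one time-resolved pressure trace (A-scan) per position, and the
initial-pressure distribution is recovered by inverting a linear forward
model of the acquisition. The package provides two routes to that model —
a geometric simulation of the detector (sTIR) and an emulated experimental
calibration (cTIR) — plus a delay-and-sum baseline (SAFT) and the metrology
used to compare them.

## The acquisition model

For a homogeneous medium with speed of sound `c`, the signal a point
absorber at position `r` produces at scan position `s` depends only on the
relative offset `r - s` (translational symmetry of the raster). Tabulating
the detected waveform over relative lateral offsets (Δx, Δy), depth z and
time yields the 4D **total impulse response (TIR)**. The forward model is
then, per depth and time sample, a lateral cross-correlation of the
absorption volume with the TIR:

    scan(s, t) = Σ_z Σ_Δ  K[t, z](Δ) · vol(s + Δ, z),

with zero absorption assumed outside the reconstructed volume. The
operator and its exact algebraic transpose are applied matrix-free with
per-(t, z) kernels (FFT correlations per depth plane); their consistency is
enforced by a dot-product identity test at < 1e-10 relative defect.

### Simulated TIR

The detector surface — the spherical cap of radius F = 7 mm whose aperture
projection is the annulus between the 0.6 mm hole rim and the 3.2 mm
aperture rim — is divided uniformly into 25 polar × 40 azimuthal patches
(1000 virtual elements). Element centers sit at the exact area centroid of
each patch projected to the sphere, and each element carries its exact
spherical-patch area (areas vary with polar angle and are carried per
element). The **spatial impulse response (SIR)** at a field point is the
histogram of element arrival times d/c, weighted by element area divided by
distance (the 1/d of the Rayleigh integral; a flag reproduces the plain
area-only histogram). Weights are deposited with linear interpolation
between the two adjacent 4 ns time bins, which suppresses bin-quantization
ringing. The TIR is the SIR convolved with the source transient of a
uniformly heated sphere — the classical antisymmetric N-wave of duration
2R/c (default R = 7.5 µm, the nominal calibration-sphere radius) — with the
electrical response of detector and amplifier taken as flat and acoustic
attenuation/dispersion deliberately absent. Default support: 1 mm lateral
radius, 3 mm axial extent, sampled at 20 µm and 250 MHz; per-depth time
windows are stored with their own start offsets so near and far planes do
not share one long buffer.

A known limitation of the 1000-element histogram: for on-axis field points
every element of a polar ring is equidistant, so the SIR degenerates to a
comb of 25 arrivals, and doubling the discretization moves the teeth
(tens of percent pointwise change away from the focus, ~4% in global
energy). At the focus the SIR is exactly discretization-invariant (all
distances equal F). This coarseness is intrinsic to the simulated model and
is one of the reasons a calibrated TIR outperforms it.

### Calibrated TIR

The calibration experiment scans a sub-resolution microsphere (10–20 µm)
through the sensitivity field on a 20 µm isotropic grid, 3 repeats per
node. The package emulates it: a synthetic "real" detector is built by
perturbing the virtual-element positions — lateral tilt about the focus,
astigmatic radial warp `1 + a·cos 2φ` (a stretched-foil analogue) — and its
traces are shaped by a Gaussian band-pass electrical response and white
noise. `assemble_ctir` averages the repeats, and applies a single global
normalization (focal on-axis peak = 1). Per-depth normalization is never
applied: it would erase the depth-dependent sensitivity falloff that the
model-based inversion corrects. The focal plane itself is estimated from
the assembled TIR (on-axis peak amplitude, ties to the shallower plane)
because the absolute transducer–sphere distance is unknown in practice.

### Inversion

Reconstruction solves `argmin_x ||Ax - b||² + λ²||x||²` with damped LSQR
(Golub–Kahan bidiagonalization, damping eliminated by an extra plane
rotation per step), 20 iterations from x = 0 — the point where the
augmented residual norm has effectively converged for this model class.
LSQR is implemented in the package because the per-iteration augmented
residual history is part of the results contract; it is cross-checked in
the tests against an independent library implementation and against a dense
normal-equations solve on a materialized operator. λ is not a physical
constant; the default is 0.01 × the operator norm (20-step power
iteration), a scale-invariant choice that behaves consistently across grid
sizes. No positivity constraint is applied (reconstructions are signed);
an explicit clamp is available as post-processing.

### SAFT baseline

The delay-and-sum baseline collapses the detector to a virtual point
receiver at its focus. A voxel at depth z (relative to the focal plane) and
distance d from a scan position's focus contributes at delay F/c ± d/c
(+ deeper, − shallower); voxels are averaged over all scan positions whose
acceptance cone (half-angle arcsin(a/F) ≈ 27°, configurable) contains them,
with linear interpolation in time and normalization by the contributor
count so the depth-dependent aperture does not inflate amplitudes. No
apodization or coherence weighting. Because the cone closes at the focal
plane, few neighbours contribute there — the origin of SAFT's non-uniform
noise background near the focus, which the tests assert via the
contributor-count profile.

## Preprocessing

A-scans are corrected per pulse: division by the relative pulse energy and
removal of the emission-time jitter by a band-limited frequency-domain
phase ramp (sub-sample accurate). Band-limiting uses a 4th-order
Butterworth between 1 and 90 MHz applied forward–backward (zero phase), so
arrival times used by SAFT and the forward model are untouched. Filter
family and order are repository choices; only the band edges are fixed by
the acquisition design.

## Synthetic data and what it does (not) show

The synthetic module generates every input at test time. Spheres are
rasterized with analytic partial-volume weights (3-point Gauss–Legendre
quadrature per axis), so sub-resolution spheres neither vanish nor alias on
a 20 µm grid. Scan data are produced through a forward model on a grid 2×
finer than the reconstruction grid with a larger sphere (25 µm vs the 15 µm
calibration sphere) and tent-kernel binned ([1/4, 1/2, 1/4], centred on the
coarse positions so binning introduces no half-step shift) back to the scan
grid — reconstructions never see the discrete operator that generated
their data (inverse-crime guard). All noise is seeded; identical
configurations are bitwise reproducible.

The emulation captures geometric asymmetry, band-limited electrical
response, measurement noise and repeat averaging. It does not capture
frequency-dependent acoustic attenuation, shear-wave conversion in the
detector foil, optical fluence inhomogeneity (available only as an optional
exponential per-depth taper, off by default) or motion. Passing benchmarks
therefore demonstrate the *mechanism* — that a calibrated response model
recovers resolution and depth uniformity a mismatched ideal model cannot —
not instrument-grade performance figures.

## The benchmark experiment

`oamrecon.experiments.run_depth_uniformity_benchmark` reproduces the
phantom study design at reduced desk scale (the package's own choice of
problem size): reconstruction grid 20 µm lateral / 40 µm axial, TIR support
0.42 mm lateral and ±0.8 mm axial, 51×51 scan positions, five 25 µm
spheres on-axis at 0.4 mm spacing. The reduction preserves a constraint the
full-scale design satisfies: the TIR lateral support covers the
acceptance-cone radius at maximum defocus (tan 27.2° × 0.8 mm = 0.41 mm).
Truncating the cone would starve the off-focus operator columns and leave
the inversion under-converged at the fixed 20 iterations — a distortion of
the method, not a smaller instance of it. The truth detector is tilted 3° with a
5% astigmatic warp and a Gaussian electrical response (30 MHz centre, 150%
fractional bandwidth); calibration repeats (3×) and the phantom scan carry
white noise at 1% of the respective peak amplitudes. Both MBR variants use
the same regularization weight (0.01 × the ideal model's operator norm):
the two TIRs share the focal-peak normalization, and an equal penalty keeps
the comparison about the response model rather than the damping. Metrics:
main-lobe lateral FWHM through each sphere's local maximum (side lobes of
artifact-ridden reconstructions do not abort the measurement; the
standalone `fwhm` is strict by default), intensity drop
100·(max − min)/max over depths, and a mirror-asymmetry index
‖V − flip(V)‖/‖V‖ quantifying the side-lobe artifacts a mismatched model
produces. The SNR metric elsewhere in the package is peak |signal| over
noise standard deviation in dB — a repository definition, since published
comparisons of this kind report SNR qualitatively.

## Numerical choices

- Coordinate convention: acoustic axis = z, origin at the geometric focus,
  z increasing away from the detector; lateral offset sign
  Δx = (voxel x) − (scan x), fixed once in the TIR container.
- Speed of sound defaults to 1490 m/s (deionized water near room
  temperature) — a configuration value, not a measured constant.
- Histogram deposition, edge policy (zero padding), tie-breaks
  (focal-plane estimate → shallower plane), and the averaged-repeat
  equality tolerance (1 ulp from floating-point mean) are documented at
  their definitions.
- `estimate_focus` warns and returns the middle plane on a flat amplitude
  profile; `saft_reconstruct` zeroes voxels with an empty aperture and
  counts them in the diagnostics.
- Operators keep per-depth kernel time supports trimmed to their nonzero
  range; this is an exact optimization (dropped entries are zero).

## Known limitations

- The virtual-element SIR is coarse off-focus (see above); increasing
  n_polar/n_azimuth helps at quadratic cost.
- The cTIR emulation shares the virtual-element machinery with the sTIR;
  real calibrations differ from simulations in ways no emulation spans.
- SAFT's amplitude at depth is noise-limited; its FWHM readings far from
  the focus measure a noise lobe once the sphere signal drops below the
  noise floor (visible as missing values in the metric table).
- No attenuation, dispersion, or fluence model; single wavelength; CPU
  implementation (the operator contract is execution-strategy agnostic).
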