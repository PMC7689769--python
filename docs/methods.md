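# Methods

This note documents the models behind `halbachmri`, the defaults they use,
and what the synthetic test conditions do and do not demonstrate.

## Coordinate convention

`x` is the bore axis of the cylindrical magnet; `z` is the main-field (B0)
direction, which in a dipolar (k = 1) Halbach array lies *transverse* to the
bore; `y` completes the right-handed frame. "Gradient" always means a spatial
derivative of Bz. Positions are in metres and fields in tesla internally;
protocol-level quantities use mm/ms to match scanner convention.

## Magnet model

Each permanent-magnet cube is a point dipole with moment m = Br·V/μ0 placed
at the cube centre. Against an exact analytic cuboid (surface-charge) field,
the dipole approximation is accurate to better than 0.5% at the ≥13 cm
distances that occur between ring magnets and the imaging volume, and a stack
of dipole rings reproduces the continuous Halbach cylinder value
Br·ln(Ro/Ri) to 0.05% in the dense limit; the exact cuboid formula is kept
only as a test oracle because the optimizers need ~10^3–10^4 cheap field
evaluations. Demagnetization, inter-magnet interaction and temperature
dependence during optimization are out of scope.

Remanence defaults are vendor-typical: N48 → 1.42 T, N45 → 1.35 T. The NdFeB
temperature coefficient is configurable with default 0.12 %/°C (data sheets
quote 0.10–0.12 %/°C); at 50 mT this gives a thermal sensitivity of
≈ 2.5 kHz/°C.

### Reference geometry

The full-scale magnet is 23 rings over 0.50 m, two concentric layers of
12-mm N48 cubes per ring, 27-cm clear bore. Per-ring magnet counts and layer
radii of such systems are rarely published, so the defaults here are fixed
by requiring mutual consistency of four hard constraints: (i) the 32.5-cm
diameter shim grid must fit inside the ring layers, so layer radii exceed
~0.17 m; (ii) operation near 50 mT; (iii) total magnet mass of a few tens of
kilograms; (iv) cubes mounted in printed trays need finite azimuthal
clearance. A 7-mm azimuthal clearance (count = ⌊2πr/(12 mm + 7 mm)⌋ per
layer) with first-layer radii searched in [0.185, 0.215] m satisfies all
four: the nominal mid-window design carries ≈ 2 900 cubes (≈ 38 kg of
magnet material) and produces 48–57 mT across the window. A dense packing
(2-mm clearance) would be physically fine but puts the operating field at
62–100 mT for any radius that clears the bore, incompatible with a 50 mT
system; the clearance is therefore a deliberate geometry choice, not a free
tuning knob, and is configurable.

The second layer sits at r₁ + 13 mm (cube size + 1 mm tray wall). Ring
radii are mirror-symmetric about the magnet midplane.

### Homogeneity metric and DSV sampling

Homogeneity is peak-to-peak over mean, ×10⁶ (ppm). An RMS variant exists but
is non-default; peak-to-peak is the convention consistent with
shimming narratives quoted in the ~10³–10⁴ ppm range. The 20-cm DSV is
sampled with a centre point plus 11 concentric shells × 100 golden-angle
points (1 101 points) by default; optimizer-facing code uses a lighter
5 × 40 + 1 sample, which changes measured ppm by only a few percent and the
mean field negligibly.

### Genetic algorithms

Both optimizers share one engine: tournament selection (size 3), uniform
crossover (rate 0.8), per-gene mutation (rate 0.02), elitism 1, seeded
`numpy` Generator. Elitism makes the best-so-far fitness monotone
non-increasing, which is asserted on every run. Identical config + seed give
bit-identical trajectories.

*Ring diameters*: real-coded genes (one radius per half-ring, mirrored) with
Gaussian mutation (σ = 10% of the window) clipped to bounds, or a discrete
candidate mode used for exhaustive cross-checks. Fitness evaluations
memoize per-(ring, radius) field contributions; because uniform crossover
re-uses parent gene values, a full GA run costs only a few hundred distinct
ring-field evaluations.

*Shim grid*: ternary genes over 15 × 60 = 900 slots (empty / k = 1 aligned /
flipped). The per-slot ALIGNED field is precomputed once on the DSV sample
(a 900 × n matrix); population fitness is then a single matrix product. The
all-empty individual is seeded into the initial population, so the result is
never worse than not shimming. The synthetic "as-built" field used in tests
perturbs every cube's remanence by 1% (vendor tolerance class), which
produces ~10⁴ ppm over the 20-cm DSV — the same order as an unshimmed real
magnet; the tests assert strict improvement, not a specific final ppm, since
the achievable improvement depends on the specific imperfection realization.

## Gradient coil design (target-field / stream function)

The surface current on a cylindrical former (default radius 0.125 m, length
0.35 m — the largest former clearing the 0.135 m bore radius) is represented
by a stream function ψ(φ, x) = Σ c_mn · {1, cos mφ, sin mφ} ·
sin(nπ(x + L/2)/L), m ≤ 4, n ≤ 12. Sine axial modes force ψ = 0 at the
former ends, so no current crosses them and every ψ-contour closes. The
current density K = ∇ψ × n̂ is divergence-free by construction.

Bz at target points (a spherical sample, default 18-cm diameter, which must
fit inside the former with ≥ 1 cm radial margin) is linear in the
coefficients; the design solves

  min ‖A c − G·u‖² + λ ∫|K|² dA,

with λ chosen at the corner of an L-curve over nine decades unless given
explicitly. Discretization contours ψ at levels ±(k−½)·ψmax/n_contours
(default 12): each closed contour becomes a wire loop carrying the level
spacing Δψ as its series current, resampled to ≤ 4 mm segments. Contours are
extracted on a doubly-unrolled azimuthal domain so loops crossing the φ = 0
seam and full hoops are both stitched correctly. The overall polarity of a
coil is normalized to the sign of the requested gradient.

Efficiency is the central ∂Bz/∂u per ampere (finite difference, 2-mm step);
nonlinearity is max |Bz − G₀u| / (G₀·FOV/2) over a cubic lattice restricted
to the inscribed sphere of the FOV (the full cube is available via
`region='cube'`). At the defaults, the y and z coils come out
quadrupole-like with sub-1% nonlinearity over a 15-cm FOV; the x coil
(gradient along the bore) is intrinsically harder in a transverse-B0
geometry — its efficiency is several times lower and its field exhibits a
gradient null and reversal just beyond the former ends. On a former with a
~1:1 length-to-diameter ratio (length 0.25 m), x-nonlinearity over 15 cm
rises to tens of percent; that short-former coil is what the
distortion-correction demonstrations use, since it reproduces the strong
bore-axis distortion characteristic of compact systems. Printed efficiency
figures of any particular built system depend on its unpublished former
dimensions and turn counts, so efficiencies here are order-of-magnitude
comparisons only. A wire-resistance estimate (ρ_Cu · length / area, 1.5-mm
wire) is attached for the same soft purpose.

## Sequence model

Scan time is ceil(n_encodes/ETL) × TR, with n_encodes the number of
phase-encode points kept by the elliptical mask
(i/(n1/2))² + (j/(n2/2))² ≤ 1 on centred integer indices (fraction → π/4).
Startup shots, partial Fourier and TI are excluded from the count; the
discretization rule is the package's own choice since index conventions are
never printed. Centre-out ordering sorts lines by elliptical radius and
acquires the centre at echo 1 (effective TE = echo spacing);
linear low-to-high ordering partitions lines into ETL contiguous bands
(effective TE = (ETL+1)/2 × spacing — the unique simple rule consistent with
a 410 ms effective TE at ETL 40 and 20 ms spacing). Refocusing phases are
recorded as alternating ±90° CPMG labels. Full Bloch/EPG evolution through
the train is out of scope.

The resolution report converts: drift (Hz) / (bandwidth/FOV) → mm of
readout-direction blur; B0 linewidth (Hz) / (bandwidth/matrix) → PSF in
pixels (× voxel for mm); combined readout resolution is the quadrature sum of
voxel and linewidth PSF. The T2-train PSF is the FWHM of the Fourier
transform of the echo-train decay weighting applied to the first
phase-encode axis (a flat train gives the plain sampling PSF, FWHM ≈ 1.21
px).

## Forward simulation and reconstruction

The simulator evaluates s(k) = Σ_r ρ(r)·w(r)·exp(−i2π[kx·G̃x(r) + ky·G̃y(r)
+ kz·G̃z(r)])·exp(−i2π·ΔB0(r)·t(kx)), with G̃ the effective-coordinate maps
(Bz/G₀ from Biot–Savart on the actual wire paths), t the readout time from
the echo centre (dwell = 1/bandwidth), w the saturation-recovery or
inversion-recovery steady-state weighting, plus optional per-shot drift
phase, optional per-echo T2 decay (off by default: subpixel for the
protocols of interest), and seeded circular complex Gaussian noise. With
identity maps the sum is exactly the centred DFT of the weighted phantom
(verified against a brute-force triple sum to 10⁻¹⁰). The sum is factorized
per axis and contracted in voxel chunks, which is what keeps 128² and 32³
problems in seconds. ΔB0 phase accrues only across the readout window
(echo-centred), mirroring a spin echo that refocuses static offsets at the
echo centre; the reconstruction uses the identical convention. Signs are
chosen so the forward model is the DFT and the reconstruction its inverse.

The conjugate-phase reconstruction evaluates the same sum with conjugated
phases and the measured maps, normalized by the sample count; with identity
maps and zero ΔB0 it equals the centred inverse FFT to 10⁻¹⁰ on every tested
matrix size. It is the adjoint, not the inverse, of the distorted encoding,
so it restores geometry where the encoding field is monotone but cannot
recover fold-over regions (beyond gradient reversal points); a warning is
emitted when map values exceed half the FOV. Model-based iterative
reconstruction is deliberately out of scope. Drift correction multiplies
each k-space line by exp(−i2π·Δf(t_echo)·t_sample) using the schedule's
recorded echo times (a per-shot variant is available), which undoes the
simulator's drift term exactly.

Distortion is quantified by thresholding the magnitude image at half
maximum, labelling connected components, computing intensity-weighted
centroids and matching them to reference tube positions by minimum-cost
assignment; RMS and per-tube errors are reported, on the matched subset if
the counts differ.

## Phantoms

The resolution phantom is 45 water tubes (8 mm diameter, 35 mm long) on a
7 × 7 grid, 17-mm pitch, corners empty, rasterized with 5³ staggered
subsamples per voxel so total volume is exact to ≪ 1%. Tissue phantoms use
low-field relaxation estimates: brain tissue T1/T2 = 500/250 ms with CSF
ventricles at T1 = 1750 ms and T2 = 0.9·T1 (T1 ≈ T2 for mobile liquids at
these fields); knee compartments (muscle, fat, cartilage) at
(200, 47), (140, 84), (70, 20) ms. These phantoms exercise contrast and
encoding logic only — they contain no susceptibility, motion, flow, partial
volume beyond rasterization, or coil-sensitivity structure, so passing tests
demonstrate correctness of the encoding/reconstruction chain, not in vivo
image quality.

## Problem sizes used by the shipped checks

The acceptance script runs the 23-ring GA at population 24 × 25 generations
on the light DSV sample and reports the mean DSV field of the optimized
design (~49–51 mT across seeds). The test suite designs the three coils once
per session, evaluates gradient linearity on a 31³ lattice over 15 cm,
simulates the tube grid at 2-mm voxels on a 110² matrix, and checks the
recon equivalences up to 32³. These sizes were chosen as the smallest at
which each check is meaningful; all scale up by changing the respective
parameters.

## Known limitations

* Point-dipole magnets: sub-0.5% error at design radii, but not valid for
  magnets close to the evaluation point (guarded by a singularity error).
* The conjugate-phase method degrades near encoding-field folds; this is a
  property of the method, not the implementation.
* The GA is a stochastic heuristic: it guarantees monotone improvement and
  reproducibility, not global optimality (exhaustive cross-checks are done
  on toy problems only).
* Scan-time arithmetic excludes dummy shots and sequence dead time, so it
  reproduces protocols defined by shots × TR only.
* No RF transmit/receive physics: B1 is uniform, noise is white complex
  Gaussian referred to k-space.
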