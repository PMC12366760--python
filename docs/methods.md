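# Methods

This note records the model assumptions, parameter defaults, numerical
choices and known limitations of `scotkit`. Units are mm, 1/mm, s and
mm²/s throughout; vacuum wavelengths in nm are converted once at medium
construction (k₀ = 2π/λ with λ in mm, so 852 nm → 7375 rad/mm).

## Correlation diffusion model

The field autocorrelation G₁(r, τ) is modeled by the correlation
diffusion equation (CDE), a Helmholtz equation with decay constant
C²(τ) = 3 μs′ μa + 6 μs′² k₀² D_b τ. Scatterer motion is purely Brownian
(⟨Δr²⟩ = 6 D_b τ); convective red-blood-cell motion is ignored, which is
the accepted regime for human cortical measurements where shear-induced
diffusion dominates the decorrelation.

**Semi-infinite boundary.** The homogeneous solution uses the
extrapolated-boundary image-source form with source depth z₀ = 1/μs′ and
extrapolation distance z_b = (5/3)/μs′. The value 5/3 corresponds to an
internal-reflection boundary (tissue n = 1.33 against air), not to an
index-matched interface (which would give 2/3). The Monte Carlo
therefore applies unpolarized Fresnel reflection at the surface by
default; with that pairing the analytic first-order flow-sensitivity
kernel reproduces the Monte Carlo kernel to ~1–2% over the lag range
that dominates the contrast integral. (We verified that pairing an
index-matched random walk with z_b = 5/3 instead leaves a ~10%
mismatch in kernel magnitude, while z_b = 2/3 pairs with the matched
walk to the same 1–2%.)

**Perturbation kernel.** The Born integrand couples the source field
G₁₀(r_s, r′, τ) to the detector Green's function H(r′, r_d, τ). The
physical source optode is represented by an isotropic point source at
depth z₀ beneath it; the detector-side factor is the δ-source Green's
function evaluated at the *surface* detector position (its image taken
about z = −z_b only). This distinction is load-bearing: shifting the
detector to depth z₀ as well inflates the kernel by ~60% against the
exact derivative of the homogeneous solution under a uniform D_b
change, whereas the implemented form matches that derivative to ~1%
(midpoint quadrature at 1 mm³ voxels). The slight source/detector
asymmetry this introduces in `phi_s` is the standard price of modeling
a collimated physical source; the public `g1_point_interior` helper
remains exactly reciprocal.

**Quadrature and clamping.** The voxelized perturbation sum uses the
midpoint rule at voxel centers weighted by the voxel volume, 1 mm³ for
the phantom experiments. Green's-function distances are clamped below
at half the smallest voxel spacing; this affects only voxels touching
an optode and is logged when it happens.

## Speckle contrast and signals

K² is computed by composite Simpson quadrature of
(2β/T_exp)∫g₁²(1−τ/T_exp)dτ on a lag grid of {0} followed by 128
log-spaced points from 10⁻⁷ s to T_exp. Simpson keeps the quadrature
error near 10⁻⁵ relative across decorrelation times τ_c/T_exp ∈
[10⁻³, 10³] (the trapezoidal rule plateaus near 10⁻³, which is visible
in the signals). Defaults: T_exp = 2 ms and β = 1 for the phantom
experiments; β cancels identically in both relative signals. The
package treats r(1/K²) − 1 as the primary flow signal; rK² − 1 is
available for comparison and is measurably less linear in rD_b − 1.

## Monte Carlo oracle

Photons are launched as a collimated beam normally incident at the
origin and random-walked with isotropic scattering at μs = μs′
(similarity relation; per-event momentum transfer q²/2k₀² = 1 − cos θ
with mean 1). Absorption is never sampled in flight: it enters as
exp(−μa L) weights at analysis time, so one seeded run is reusable
across μa values. Detection is an annulus of ±0.5 mm at radius ρ on
the surface, all exit angles accepted after the Fresnel transmission
test.

**Azimuthal rotation of tallies.** The annulus boosts statistics by
2πρ/Δ relative to a small disk, but a perturbation region fixed in
space is not azimuthally symmetric; naively tallying per-region
momentum transfer over all exit azimuths dilutes it severely (we
measured a 25–30% distortion of the deep-region kernel). Each detected
photon's scattering-event list is therefore rotated about z so its exit
lands at azimuth 0 (the nominal detector direction) before region
tallying — exact for the azimuthally symmetric baseline medium, and
restoring the point-detector geometry at annulus statistics.

**Termination.** Walks are killed below a depth of max(100 mm, 4ρ) or
after 2×10⁵ steps. Photons that deep carry momentum transfer so large
that their contribution at any lag ≥ 10⁻⁷ s is e⁻¹⁵ or smaller;
doubling the depth cap moves the measured kernels by less than the
sampling noise.

**Effective-absorption fluence mode.** For voxelized heterogeneous
media (e.g. the six-layer head slab: skin, skull, dura, CSF, gray and
white matter with their tabulated μa, μs′ and α·D_b values — α·D_b is
treated as a single product parameter), a static fluence solver is run
once per lag with μa,eff = μa + 2 α μs′ k₀² D_b τ, yielding volumes
proportional to G₁(r_s, r′, τ). Tracking is Woodcock (delta-collision)
with a global majorant and a collision-density fluence estimator;
survival weighting with Russian roulette below w = 10⁻⁴. At τ = 0 this
is the ordinary fluence; lags large enough to extinguish the fluence
yield zero voxels, not NaN. This mode exists because history-based
sensitivity matrices are computationally out of reach for full-volume
models; it is exercised here on small synthetic slabs only.

## Probe and reconstruction

The high-density array has 7 sources on a triangular lattice of pitch
38 mm and 16 detectors at lattice-edge midpoints (12 interior to the
7-source flower, 4 on outward-slanted edges). Source–detector
separations then fall exactly into 19 mm, 19√3 ≈ 33 mm and ≥ 19√7 ≈ 50 mm
classes; the 19 and 33 mm classes form exactly 50 channels (28 + 22),
and longer channels are excluded as they would fall below camera read
noise in practice. The detector subset is asserted at construction; an
impossible configuration raises with a listing of the separation
classes present.

Sensitivity matrix: each column is the Rytov forward signal of a
single-voxel probe perturbation ΔD_b = 10⁻⁷ mm²/s divided by its
rD_b − 1; halving the probe amplitude moves entries by < 0.1%, i.e. the
construction sits in the linear regime. The inversion solves
(AᵀA + λI)x = Aᵀy with λ = α·max diag(AᵀA), α = 0.001 for noiseless
simulated data; when voxels outnumber channels the algebraically
identical dual form Aᵀ(AAᵀ + λI)⁻¹y is used, which keeps the linear
algebra at channel dimension. A voxel-mask hook restricts columns to a
subregion (the stand-in for anatomical surface projection, which needs
external mesh data and is out of scope).

Problem sizes for the reconstruction experiment: sensitivity grid at
4 mm voxels over the probe footprint plus margins (~24 000 voxels),
forward inclusion voxelized at 2 mm. The experiment's linearity metrics
changed by < 0.5% when either resolution was doubled.

## Linearity experiments and their reference fits

The percent error of a sweep is taken against a through-origin OLS fit
of the *small-signal regime* (rD_b − 1 ≤ 0.1) of the same method — a
deterministic, noise-free reference anchored where Born, Rytov and
Monte Carlo coincide. Crossings of the 5% band are located by linear
interpolation of |error| between grid points. The spatial-linearity
error (sum of single-region signals vs the jointly perturbed signal)
involves no fit at all.

## What the synthetic phantoms do and do not show

The generator covers homogeneous semi-infinite media with box
inclusions — the geometry in which the breakdown thresholds are
defined. It does not emulate heterogeneous anatomy, curved boundaries,
measurement noise (shot/read/quantization), or probe-tissue coupling
variation; passing tests therefore validate the model chain, not
robustness to experimental artifacts. Reconstruction with noisy
signals would use a larger α (0.005 is a reasonable starting point)
and correspondingly coarser effective resolution.

## Measured model fidelity, and two honest discrepancies

With the consistent boundary pairing, the three methods agree on the
small-signal sensitivity of the large-inclusion experiment to ~1.3%
(slopes 0.427 / 0.422 / 0.417 for Born / Rytov / MC). Beyond small
signals the ground-truth MC signal is mildly *sub*linear (−7% at
rD_b − 1 = 1), while Rytov is *super*linear (+12%) and Born strongly so
(+30%): the Rytov exponent is linear in ΔD_b whereas the true decay
saturates, so Rytov overestimates large flow increases. Two
consequences:

1. The Rytov signal's maximum deviation from its small-signal fit over
   (0, 1] is ~11.7%, not below 5%: by that criterion Rytov, too, has a
   breakdown point (≈ 0.47, versus ≈ 0.26 for Born). Claims that Rytov
   "stays linear" over this range depend on fitting the reference line
   through the full sweep of a (noisy, itself sublinear) MC curve,
   which redistributes the shared trend; no fit convention we tried
   makes Rytov's deviation < 5% while simultaneously placing Born's
   crossing near 0.32.
2. In the reconstruction experiment the region-averaged estimate is
   linear in the true rD_b − 1 over [0, 1] (R² = 0.9993) but departs
   from the fitted line by 5% already near rD_b ≈ 2.7 — again driven by
   the Rytov forward's superlinearity, not by the (exactly linear)
   inversion.

A further measured limit: the correlation-diffusion g₁ shape at
ρ = 30 mm differs from the transport (MC) g₁ by up to ~0.9% of
amplitude — invisible at small photon budgets but a genuine model bias,
so agreement tests must budget for it once sampling error drops below
~0.3%.

## Determinism

All Monte Carlo entry points take an explicit seed and produce
bit-identical outputs for identical arguments; the analytic pipeline is
deterministic. CLI runs archive their resolved configuration and a log
(package and numpy versions, seed, detected-photon counts) beside their
outputs.
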