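# Methods

This note records the models, conventions and numerical choices behind
tomomatch, and what the synthetic validation does and does not demonstrate.

## Scoring model

The score is the masked, locally normalized cross-correlation ("local
correlation coefficient", LCC) between a rotated template and the tomogram.
For a mask *M* with mass P = ΣM, a rotated, wedge-filtered template T
with masked mean T̄ = Σ(M·T)/P and masked standard deviation
σ_T = sqrt(Σ M·(T−T̄)²/P), the numerator at position x is the correlation
of the tomogram with the mean-free, mask-weighted kernel M·(T−T̄); the
denominator is P·σ_T·σ_MV(x), where σ_MV(x) = sqrt(mean_M(V²) − mean_M(V)²)
is the tomogram's local standard deviation under the mask. All three
position-dependent quantities are computed for every voxel at once with
FFTs (three real-to-complex transforms per orientation, one when the mask
is spherical). With this normalization an exact copy of the wedge-filtered
template on empty background scores exactly 1 (Cauchy–Schwarz equality),
and the score is invariant to affine intensity transforms of the tomogram.

Conventions that matter for reproducibility:

- The missing-wedge weighting is applied to the rotated template in the
  tomogram frame (the wedge belongs to the tomogram's Fourier sampling, not
  to the particle), as a binary mask on the FFT grid; unpaired Nyquist rows
  are symmetrized so the mask is exactly Hermitian.
- Rotation center is floor(n/2) on each axis; template rotation uses
  prefiltered cubic b-spline interpolation (order 3), mask rotation — when
  the mask is not spherical — trilinear with re-clamping to [0, 1].
- Ties between orientations at a voxel keep the lowest orientation index,
  which makes angular-split execution bit-identical to the serial loop.
- Positions whose local standard deviation falls below 1e-8 × the global
  tomogram standard deviation score 0 instead of dividing by noise.
- FFT wrap-around contaminates a margin of half a template box at the
  volume faces; those scores are set to −1 and flagged invalid, and
  extraction never returns candidates there.

Subvolume splitting extends every piece by one full template box on shared
faces and crops the result back to the piece interior, so the merged
volumes equal the unsplit run to floating-point accuracy inside the valid
region. `score_at_positions` evaluates the identical score by direct
summation at selected voxels only; it is the economical route for scoring
known annotations under very large orientation sets (it is exactly the
value the full search would store at those voxels).

## Orientation sampling

The searched set covers SO(3) with a deterministic construction: the
directions of the rotated z-axis come from a Fibonacci spiral lattice with
round(4π/Δα²) points, and the in-plane angle from a uniform ring with
round(360°/Δα) samples. Counts are within ~5% of the reference list sizes
in common use (7112 at 13°, 45 123 at 7°, 553 680 at 3°) and Monte-Carlo
coverage tests show every random rotation within 1.5·Δα of a set member.
The increment itself comes from the Crowther criterion Δα = 1/(r·d): at
Nyquist voxel size 1/(2r), a voxel at the particle radius d/2 moves about
one voxel per increment step.

Euler conventions: triplets are natively anticlockwise intrinsic ZXZ
(R = Rz(φ)·Rx(θ)·Rz(ψ), active). Conversion to the clockwise ZYZ convention
of RELION/XMIPP/SPIDER/FREALIGN goes through the rotation matrix and back,
with the middle angle kept in [0°, 180°]; at gimbal lock (θ within 1e-8° of
0 or 180) the whole in-plane rotation is placed on ψ with φ = 0.

## Template, mask and wedge construction

Templates are processed at the reference voxel size: the Fourier transform
is multiplied radially by the weak-phase CTF
−(√(1−A²)·sin χ + A·cos χ), χ(k) = πλΔz·k² − (π/2)·Cs·λ³k⁴ (defocus Δz > 0
for underfocus, no envelope, no phase plate), optionally truncated to 0
beyond its first zero crossing of the full amplitude-contrast-shifted
curve; then by a low-pass with a raised-cosine edge two Fourier voxels wide
centered on the cutoff; finally the map is downsampled by Fourier cropping
(alias-free) and centered in the requested box. Defaults mirror a common
200 kV setup: 3 µm defocus, Cs 2.7 mm, 8% amplitude contrast.

The spherical mask is 1 inside the given diameter, falls off as a Gaussian
with σ = 1.5 voxels (default) and is clamped to 0 beyond radius + 3σ. The
wedge mask passes Fourier voxels whose (kx, kz) direction lies within
90° − wedge angle of the kx axis (tilt axis y, beam axis z), with the
kx = kz = 0 line always passed; a symmetric ±t° tilt range gives wedge
angles 90° − t on both sides.

## Candidate extraction

Ranked non-maximum suppression: repeatedly take the global maximum of the
valid score region, record position, best orientation and score, and zero a
spherical region of the masking radius (spherical rather than cubic, since
the radius is isotropic). Ties in score break lexicographically by
(z, y, x). No sub-voxel interpolation is applied — positional refinement
belongs to subtomogram averaging downstream.

## Score classification

The LCCmax histogram of the candidates (bin width 0.015 by default) is fit
by least squares with a sum of two Gaussians. The background component is
initialized at the score-volume mean and standard deviation and bounded to
mean ± 2σ and [0.5σ, 2σ]; its initial height is N/(w·σ·√(2π)) for N scores,
bin width w, score-volume standard deviation σ. Two identifiability guards
keep the components from swapping roles on unimodal histograms: the
particle mean is bounded below by mean + 2σ of the score volume, and the
particle width by two bins. Components are re-ordered after the fit so the
particle mean exceeds the background mean. Sensitivity and FDR at a cutoff
are upper-tail masses of the fitted Gaussians scaled to counts; the ROC
curve is sampled at 500 evenly spaced cutoffs and the RUC point maximizes
sensitivity × (1 − FDR), with ties resolved toward the higher cutoff. This
definition reproduces both calibration anchors: 1 for a fully separable
model, 0.25 for the diagonal (sensitivity = FDR) reference curve.

Known limitation: the background scores of *extracted candidates* are
maxima over orientations and over suppression neighborhoods, i.e. extreme
values, not Gaussian draws. On synthetic data with few true particles
among many candidates the fitted particle component absorbs part of that
upper tail and overestimates the true-positive count; the fit behaves best
when true particles form a substantial fraction of the candidate list,
which is the intended operating regime.

## Spatial analyses

Neighbor-density maps: for each particle, the vectors to its n = 4 nearest
neighbors beyond a 100 Å exclusion radius (guarding against clashes and
duplicate picks) are rotated by the inverse particle orientation and
accumulated on a (20 Å)³ histogram spanning ±1000 Å, then normalized by
the number of accumulated neighbors so voxels hold probabilities.
Neighbors are counted directionally (each pair contributes once per
member). With plane alignment enabled the pooled vectors are first rotated
so their least-variation principal axis lies along z. Neighbor search is
exact all-pairs — particle counts per tomogram are at most thousands.

Depth profiles: particle coordinates are rotated onto their principal axes
(smallest variance along z, rotation forced proper), the median z is
subtracted so the ice-layer center sits at 0, and each particle's score is
reported against its depth. A score drop-off toward |z| extremes is the
signature of surface damage in FIB-milled lamellae.

## Synthetic data

Phantoms are built by pasting cubic-b-spline-rotated copies of a template
at rejection-sampled positions (pairwise separation ≥ 350 Å by default,
half a template box clear of borders), wedge-filtering the complete volume,
and adding white Gaussian noise with variance set by the requested SNR
(signal variance of the wedge-filtered volume divided by noise variance;
SNR 0.5 is the default test condition, with a 39°/39° wedge matching a ±51°
tilt range). Orientations are uniform on SO(3) via seeded random unit
quaternions — deliberately independent of the orientation-set generator
under test. The same seed reproduces a phantom bit for bit.

What the phantom does not emulate: CTF modulation of the tomogram itself,
correlated (non-white) noise, molecular crowding, membranes and other
cellular context, per-tilt dose and defocus effects. Passing the phantom
tests therefore demonstrates the correctness of the scoring, search and
extraction machinery under controlled degradation, not detection
performance on real cellular tomograms.

## Problem sizes used in validation

The test suite validates the full search on 64³–128³ phantoms with 16³
templates. The recovery test uses the 128³ / 25-particle / SNR 0.5 / 39°
wedge condition with a full 15° search (~4400 orientations); the
finer-sampling comparison at 7° (~43 000 orientations) evaluates the
median planted-particle LCCmax with `score_at_positions`, which returns
exactly the values a full 7° search would store at those voxels. The
monotone gain of LCCmax with finer sampling is additionally checked across
35° → 25° → 15° on a 96³ phantom. Oracle-equivalence checks (FFT vs
direct-space sums) run on 16³–24³ volumes where brute force is exact and
fast.
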