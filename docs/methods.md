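# Methods

This note documents the models, conventions, parameter choices and known
limitations of `npctomo`. It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate and transform conventions

Volumes are `(x, y, z)` arrays; the electron beam runs along z and the tilt
axis along y (an azimuth parameter rotates it in-plane). Rigid transforms
are intrinsic Z–X–Z Euler angles (ϕ about z, θ about the new x, ψ about the
final z; right-handed axes, degrees) plus a translation in voxels. The
rotation acts on the volume about the center voxel `floor(N/2)`;
out-of-field voxels are filled with the volume mean, which keeps
cross-correlation normalization stable near box edges. Interpolation is
trilinear everywhere. All alignment stages *compose* transforms; raw data
is resampled exactly once when an average is formed. Composition satisfies
the group laws to 1e−9 on parameters (property-tested).

The Euler convention and handedness are our declaration — pinned by the
impulse test (`ϕ=90°` moves mass from +x to +y) — since no convention is
universal in the field.

## The synthetic specimen

The phantom emulates an eightfold pore: eight solid spheres (diameter
40 nm) on a 90 nm circle with raised-cosine edges (edge width a third of
the sphere radius, so a 45° trilinear resampling retains ≥0.999
self-correlation), plus C8-replicated protomer substructure — a
cytoplasmic-side blob above the midplane, a smaller nucleoplasmic blob
below it, and an off-azimuth blob that makes the protomer chiral. The
membrane is a double Gaussian shell with 35 nm luminal spacing on a gently
curved oblate spheroid (semi-axes 900/450 nm) whose upper surface crosses
the tomogram; it exists for spheroid-fit and orientation tests, not as a
quantitative membrane model.

Two optional features make specific contracts testable. A *variable
domain* — the central channel, radius 13 benchmark voxels about the pore
axis — is re-filled per particle with a smooth zero-mean Gaussian random
field scaled to 2.5× the local RMS of the density it replaces. The field
must be zero-mean (a one-signed field would imprint the mask shape itself
as a feature common to all particles) and strong (the domain rim remains
common, and a weak field would leave that rim dominating the local
correlation). A *planted Y-complex-like body* — a beaded stem with two
unequal, out-of-plane-kinked arms, ~45 nm extended — provides an
asymmetric docking target with no self-similar wrong orientation above
cc ≈ 0.9.

### Scales

The reference acquisition works at 3.3 Å pixels with 512³ particle boxes;
those constants are kept (`PAPER_PRESET`) and the physical geometry (90 nm ring,
80-voxel ≙ 26.4 nm subprotomer boxes, 17 nm channel mask) is expressed in
nanometres so any sampling reproduces it. Working scales are:

| preset | voxel | particle box | field |
|---|---|---|---|
| paper | 3.3 Å | 512³ | 169 nm |
| desk  | 13.2 Å | 128³ | 169 nm |
| bench | 26.4 Å | 64³ | 169 nm |

Benchmarks run at `bench` (full pipelines in minutes); docking and the C8
hierarchy contracts run at `desk`. Protomer boxes default to 76 nm — just
containing the ±22 nm subprotomer centers plus their half-boxes — and
subprotomer boxes to 26.4 nm at every scale.

### SNR and noise

SNR is signal variance over noise variance inside a spherical envelope of
0.45× the box; noise is white Gaussian added *before* the wedge filter, so
reconstructed particles contain no out-of-wedge content (a reconstruction
cannot create any, and that emptiness is precisely what biases
wedge-ignorant correlation). The simulator has no structural-noise or
dose-damage model; passing tests therefore demonstrate correctness of the
algorithms under idealized imaging, not performance on micrographs.

## Imaging model

Projections are line integrals along the beam of the volume rotated about
the tilt axis (−60°…+60°, 3° steps → 41 images). The CTF is the standard
phase-contrast transfer function, CTF(k) = −(√(1−A²)·sin χ + A·cos χ) with
χ = πλΔz·k² − (π/2)Cs λ³k⁴, amplitude contrast A = 0.07, Cs = 2.7 mm,
300 keV; defocus is negative for underfocus (−6 μm nominal). It is applied
per strip with Δf(x) = Δf₀ + x·sin α (x the signed distance from the tilt
axis). The detector MTF is sinc²(k/2k_Nyq) — the simplest strictly
positive, invertible falloff. Weighted backprojection applies a |k⊥| ramp
per projection, backprojects, and restricts the result to the sampled
wedge, so the missing-wedge region is empty by construction.

`invert_corruption` divides by the known CTF·MTF (floored at 0.05) — the
exact inverse of the forward model, used for round-trip validation. Note
that *phase flipping alone* restores signs but not amplitudes: the
remaining |CTF| modulation caps the real-space correlation of a flipped
image with the clean image well below unity, which is why the round-trip
contract uses the known-model inverse while phase flipping is tested for
its own guarantees (exact involution, amplitude preservation, strict
improvement over the corrupted image).

## Defocus estimation

Sixteen Hann-windowed strips with 50% overlap, zero-padded to the full
frame, pooled over all images; radial averaging is restricted to the
|ky| ≥ |kx| sector (the strip window smears rings along kx) and uses the
exact per-bin mean frequency (an assumed bin center biases the estimate by
a fraction of a ring spacing). The log spectrum and log|CTF|² are both
detrended with a cubic polynomial over the 0.05–0.45 Nyquist band and
correlated; the search grid spans −12…−2.5 μm (shallower defoci have no
resolvable rings in-band and are degenerate with the background
polynomial). Estimation requires a quasi-amorphous specimen contribution
(true of vitrified samples; the simulator's `amorphous_tilt_series`
provides it — projections of a smooth particle alone carry no usable
Thon rings) and detector noise at or below `dose_noise_sigma ≈ 1`, the
documented working bound. A correlation floor of 0.65 separates signal
from the pure-noise null; on failure callers fall back to the nominal
defocus (the pipeline logs which source was used). Phase flipping uses an
exact non-overlapping strip tiling — an overlap-blended flip would not be
an involution.

## Constrained alignment

`constrained_cc` rotates the reference and its Fourier support by the
candidate transform and computes the normalized correlation over
Ω = support(ref, rotated) ∩ support(particle), excluding DC (which removes
the mean), with norms inside Ω. `align_particles` searches an exhaustive
grid of incremental Euler offsets composed onto the current pose in the
reference frame: candidate rotations of the reference are precomputed once
and shared across particles; rotations are scored at the current
translation (applied as an exact Fourier phase ramp), the translation is
re-read from the correlation map of the best rotation with per-axis
parabolic sub-voxel refinement, and this inner loop runs three times. The
Euler grid contains duplicate rotations (ϕ/ψ degenerate at θ = 0); ties
are broken by smallest rotation magnitude, then smallest label — otherwise
a perfectly aligned particle would be reported at the window limit via the
(−w, 0, +w) label of the identity.

Wedge-compensated averaging masks each aligned particle's Fourier data to
its rotated support, accumulates, and divides by pooled coverage floored
at 1e−3 of its maximum. FSC uses one-voxel shells; `resolution_at`
interpolates the first downward threshold crossing and returns the Nyquist
resolution with a `no_crossing` flag otherwise.

Angular steps: 10° at the template (global) stage, 2° for the ±4° window
and 1° for the ±2° window at refinement (the ±4° window uses half- rather
than quarter-window steps to keep the graded problem sizes within minutes;
both are configuration). Translation bounds: ¼ box globally, ±4 voxels at
refinement.

### The missing-wedge benchmark

The benefit of constrained correlation is measured by aligning 50
particles (SNR 0.25, orientations uniform in-plane with tilts to 30°)
against a wedge-bearing reference of matched SNR — registering raw
subtomograms to an initial reconstruction, the situation the constraint
exists for. Both routes get the identical two-stage search; recovery is
counted within 10° modulo C8. Against a *clean, fully sampled* reference
the two scorings differ much less: ignoring the particle wedge then only
adds empty-region terms whose normalization is nearly
rotation-independent.

## C8 hierarchy

Protomer k's transform composes the global transform with a −45°·k
rotation about the pore axis plus the offset to the protomer center
(ring radius, i.e. 45 nm); crops stay raw and the fractional part of the
crop origin is carried in the transform, so the single-interpolation
accounting survives both hierarchy levels. The missing wedge follows the
composed transform and therefore differs between protomers by exactly
45°·k. Subprotomer centers sit at 33 nm radius and z = +22/−22/0 nm
(cytoplasmic ring, nucleoplasmic ring, spoke + central-channel rings).
Pairwise protomer comparisons are made inside the inscribed soft sphere —
corners of a rotated crop are out-of-field fill and undefined by contract.

Orientation verification compares the aligned pore axis (unsigned) with
the fitted membrane normal; mismatches > 20° are excluded. The spheroid
fit solves the general quadric and symmetrizes the two closest
eigenvalues; when a membrane *cap* (a nearly flat patch) drives the
general fit hyperbolic, an axis-aligned spheroid fit takes over, with the
scale fixed on the quadratic coefficients (p₁+p₂ = 1) because the usual
"= 1" normalization degenerates whenever the surface passes near the
origin. Cap fits recover surface normals to fractions of a degree but not
absolute semi-axes; only the normals are consumed downstream.

Model assembly blends the three subprotomer averages with normalized soft
spherical weights and imposes C8 by averaging the eight rotations — a
deterministic replacement for manual segmentation of overlap regions. The three 26.4 nm boxes sample the ring moieties, not
the whole protomer, so round-trip comparisons are restricted to the
returned coverage region. The final low-pass filter's raised-cosine edge
ends *at* the cutoff frequency: per-shell correlation measures are
insensitive to amplitude scaling, so the band limit a filtered map reports
is where the filter support ends.

Ring radii are measured as density-weighted centroid radii per azimuthal
sector (a radial histogram peak is biased by annulus arc-coverage/area
factors). The central-channel cylinder volume is π(d/2)²h from the
measured pore diameter and channel-ring height.

## Local resolution

Subparts (20³ voxels, 4-voxel grid) are masked with a soft sphere (radius
8/20 of the box, 2-voxel edge); node values are the FSC threshold
crossings (0.5 for half-sets, 0.14 for independently processed maps),
trilinearly interpolated between nodes, with skipped edge nodes
hole-filled by nearest neighbour. Two estimator properties matter for
interpreting values: (1) mask convolution spreads in-band correlation
outward, so a uniform band limit reads finer by up to one mask-kernel
bandwidth (0.7/(mask_radius·voxel) ≈ 1.75 subpart shells) — tests account
for exactly that bandwidth; (2) the leakage check pools |FSC| over trials
and shells with ≥100 Fourier samples (a per-shell 95th percentile fails
even an unmasked 20³ box on shell-population statistics alone) and passes
soft or all-ones masks while failing hard-edged or undersized ones.

## Docking

Each random start draws a uniform rotation; its position is set to the
best in-region translation of that rotated body by FFT-normalized
correlation (the desk-scale substitute for a 100,000-placement random
search — position sampling alone cannot cover the region with 500
starts, since the correlation gradient vanishes in empty map regions), and
then rotation and position are refined jointly by coordinate ascent:
angle steps 20°→12°→4° on 2×-binned, smoothed maps, then 1°→0.25° at full
resolution, shifts 3→2→1→0.25 voxels, rotations taken about Cartesian plus
face-diagonal axes (Euler-offset moves collapse ϕ and ψ onto the same z
rotation; pure coordinate axes stall on oblique ridges) and pivoted about
the body's center of mass so rotation and translation decouple. The
body's soft support rotates with it as a continuous correlation weight — a
hard support mask makes the score discontinuous in rotation and strews the
landscape with discretization maxima. Coarse endpoints are ranked and the
top fifth refined at full resolution. Convergence: less than 1e−4
correlation gain per sweep or 200 sweeps.

Redundancy removal is greedy by descending correlation at 5°/2-voxel
tolerances. Restraint scoring transforms each anchor, projects out the
axial component, and reports |radial − target| per label with mean,
sample s.d. (n−1) and maximum; the statistics are invariant under
rotations of the whole scene about the pore axis.

## Pipeline

Stages write once into their own subdirectories; a JSON-lines log carries
particle accounting (with the exhaustive, mutually exclusive exclusion
reasons `angle_at_limit`, `normal_mismatch`, `view_balance`, `boundary`),
FSC resolutions and metrics. Configuration is YAML with strict key
validation (unknown keys are rejected by name). A fixed config and seed
reproduce every artifact bit for bit. MTF correction is applied to the
corrected projections before reconstruction rather than re-applied inside
each alignment iteration — a simplification that keeps each stage's
inputs immutable. The
final assembled map is low-pass filtered to the finest measured local
resolution (floored at three voxels) — final maps should not claim detail
beyond what the resolution measurement supports.

## Problem sizes and what the tests show

Benchmarks are sized for one CPU: 32–50 particles in 32³–64³ boxes,
500-start docking on 64³ maps, 10-run local-resolution ensembles. The
two-route interpolation comparison (composed single resample versus
sequential double resample) ties at these conditions to within the FSC
crossing's half-shell quantization; the single-interpolation rule's
benefit on real data — amplitude preservation near the resolution limit —
is not resolvable by a per-shell-normalized measure at benchmark scale.
Passing tests demonstrate internal consistency and correctness of the
algorithms on idealized synthetic data; they do not establish performance
on experimental micrographs (no structural noise, no alignment errors in
the tilt geometry, no dose damage).
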