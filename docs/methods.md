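# Methods

This note records the model the package implements, the conventions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limitations. It is the companion to the
API documentation in the module docstrings.

## Image model

A tomogram reconstructed from a tilt series samples the specimen's 3D
Fourier transform on a set of central planes, one per tilt image. The
package models a tomogram's transfer function as a *missing-wedge filter*:
the union of 1-Fourier-voxel-thick central slices, each normal to the beam
direction at its tilt angle (tilt axis = volume y axis, beam = z axis at
zero tilt). Each slice can carry two radial amplitude modulations:

* **CTF magnitude** `|CTF(q)| = |sqrt(1-A^2) sin chi + A cos chi|` with
  `chi(q) = pi*lambda*dz*q^2 - (pi/2)*Cs*lambda^3*q^4`, where `lambda` is
  the relativistic electron wavelength (0.0197 Å at 300 kV), `dz` the
  defocus (positive = underfocus), `Cs` the spherical aberration and `A`
  the amplitude-contrast fraction. The magnitude is used because input
  tomograms are assumed CTF-corrected (phase-flipped) before or during
  reconstruction; astigmatism and phase plates are not modelled. To reduce
  aliasing of the rapidly oscillating CTF on the coarse Fourier grid, the
  1D curve is evaluated at four radial sub-samples per Fourier voxel and
  averaged (`antialias=True`, the default).
* **Exposure filter** `exp(-N / (2 Nc(q)))` with the empirical critical
  exposure `Nc(q) = 0.245 q^-1.665 + 2.81` (q in 1/Å, N in e-/Å²
  accumulated before the tilt image was recorded).

Per-particle filters use the *local defocus*: the nominal defocus is
referenced to the specimen's center of mass, and a particle's offset along
the beam at tilt `alpha` contributes
`((z - z_cm) cos(alpha) - (x - x_c) sin(alpha)) * pixel_size * 1e-4` µm.
The sign convention — particles farther from the beam source are more
underfocused — is documented here because the field does not agree on one;
flip it consistently when interoperating with other packages. Template
matching uses a single global filter (defocus at the center of mass) per
tomogram; alignment and averaging use per-particle filters.

Overlapping slices take the per-voxel maximum. Filters are explicitly
symmetrized on the Nyquist planes (where +n/2 and −n/2 alias onto one
index and conjugate pairs can receive different per-tilt modulations);
without this step filtered volumes acquire a small imaginary component.

## Orientations

Orientations are intrinsic ZXZ Euler triplets `(phi, theta, psi)` in
degrees; the matrix carrying the template frame into the tomogram frame is
`R = Rz(psi) Rx(theta) Rz(phi)`. `phi` spins the template about its own
axis (in-plane); `(theta, psi)` set the viewing axis. Global search lists
sample axes on rings `theta = 0, step, ..., 180` with
`ceil(360 sin(theta)/step)` azimuths per ring (poles once), each combined
with `360/step` in-plane spins; at 15° this gives 188 × 24 = 4512
orientations. The ring scheme was chosen because it reproduces that count;
its nearest-neighbour distance to an arbitrary rotation stays below 1.2×
the step (property-tested). Local lists tilt the prior axis by up to
`cone_step × cone_iter` in `cone_step` rings with matching azimuthal
density, crossed with in-plane offsets `± inplane_step × inplane_iter`;
under Cn symmetry the in-plane range is clamped to ±180/n. Entry 0 is
always the prior, and lists are equivariant under composition with a fixed
rotation (tested by brute force).

Volume rotation is trilinear about the voxel `floor(N/2)` (the FFT
origin), with out-of-bounds voxels filled by the volume mean (correlation
contexts) or zero (symmetrization and compact densities). Rotation-matrix
entries within 1e-12 of {0, ±1} are snapped so that axis-aligned rotations
are exact grid permutations. Trilinear interpolation bounds several
accuracies quoted below: rotating a smooth feature of width sigma voxels
incurs an error of order `1/(8 sigma^2)` of its peak, so C6 symmetrization
is idempotent only to ~2% and pose-then-inverse-pose resampling
attenuates shells beyond roughly a quarter of Nyquist. These are accepted
costs of the real-space interpolation design.

## Constrained cross-correlation

Scores are Pearson correlations computed with the fast local correlation
function: the reference is masked and normalized (zero mean, unit power
under the mask), and the search volume's local mean and variance under the
translated mask come from FFT convolutions; offsets with non-positive
local variance score 0. The mask may be soft; its sum acts as the
effective voxel count. Before correlation the reference is filtered with
the amplitude-modulated wedge (× bandpass) and the search data with the
*binary* slice wedge (× bandpass) — matching the data's support without
double-counting its amplitude losses. Correlations are circular; template
matching avoids wrap-around by tiling with half-box padding, alignment by
masks well inside the box. Peaks are voxel-resolution by default (an
optional 3-point parabolic refinement exists but is off; the
shift-then-re-extract workflow operates at voxel precision), with ties
broken by smallest offset norm, then lexicographically.

For rotationally symmetric (spherical) masks the local-variance term is
orientation-independent and computed once per search volume; sphericity is
auto-detected by comparing the mask to two rotated copies inside the
inscribed sphere (tolerance 0.05, covering soft-edge interpolation error).
This makes the 4512-orientation search roughly five times faster and is
exact for truly spherical masks.

## Template matching

Each tomogram is bandpass- and binary-wedge-filtered **once**, then split
into disjoint core tiles padded by half a template box. Filtering globally
(rather than per tile) makes the stitched score map exactly equal to
untiled matching away from the tomogram borders, which is also the
package's regression test for the tiling machinery. Per orientation the
template is rotated, filtered, normalized and correlated; a per-voxel
running maximum yields the score map and the argmax orientation map
(float32/int32). The optional noise pass repeats the whole search with a
phase-randomized template — amplitudes preserved exactly, phases drawn
from the FFT of white noise so Hermitian symmetry is automatic, one seed
per tomogram recorded in the output metadata — and the flattened score is
`max(0, score - noise_score)`. Peak extraction is greedy in descending
score with Euclidean suppression at the user's minimum distance, skipping
a half-template border.

Low-frequency Fourier modes carry almost all nonspecific correlation (a
template's power concentrates there, so chance overlap fluctuates as
`1/sqrt(n_modes)`); a gentle high-pass (2–3 Fourier pixels) removes them
while barely touching orientation-specific contrast, and the
noise-flattening demonstration uses lp 10 / hp 3 accordingly.

## Alignment and averaging

Alignment searches the local angle list around each particle's prior; the
CCC peak value becomes the score, the vector from map center to peak the
shift, optionally restricted by a spherical cross-correlation mask. The
reference mask is applied after wedge filtering of the rotated reference;
this order is pinned by regression tests. Everything runs as two
independent halfsets ("gold standard"); unassigned particles are split
randomly per iteration (seeded by iteration number), and instrumented
tests assert that no particle is ever scored against the other halfset's
reference.

Averaging shifts each subtomogram by minus its sub-voxel shift (an exact
Fourier phase ramp, up to the self-conjugate Nyquist bins), rotates it by
the inverse of its angles, and sums; the particle's amplitude wedge is
rotated identically (in the centered Fourier frame) and summed into a
per-voxel sampling tally. The sum's Fourier coefficients are divided by
the tally where it exceeds `tally_floor` (default 0.01) of its maximum;
below-floor voxels are zeroed — unsampled regions would only amplify
noise — and zeroed voxels inside the stated low-pass radius are reported.
Cn symmetry is applied as the mean over the group's rotations. Particles
are always accumulated in `subtomo_num` order, so averages are bit-identical
under any row permutation or worker count.

FSC uses shells of one Fourier pixel (rounded radius). The display map is
the halfmap mean filtered per shell by `Cref = sqrt(2 FSC/(1+FSC))` with
FSC clamped to [0, 1]. The toolkit reports the FSC table; low-pass
filtering and sharpening decisions stay with the user, and the
"increment the low-pass until FSC reaches 0.5" schedule is a
recommendation, not an automatism.

## Classification (MRA)

Multi-reference alignment extends the search space by a class dimension.
De novo references are seeded from independent uniform samples of
`round(seed_fraction * N)` particles per class (non-exclusive: a particle
may seed several classes or none), and particles start in uniformly random
classes. Each iteration runs, per particle, either

* **SHC** — score the prior (orientation, class) first; visit the
  remaining candidates in random order; accept the first strictly better
  one immediately; keep the re-scored prior if none wins; or
* **SA** — with probability `p`, accept the first randomly drawn candidate
  regardless of score (recording its own score); otherwise fall through to
  SHC. `p` starts at `sa_prob_start` and anneals linearly to zero over the
  SA iterations. The acceptance probability is taken directly (not a
  Metropolis rule on score differences); the conventional "temperature
  10 to 0" range maps to `p = T/100`.

Classes are re-averaged after every iteration (an emptied class keeps its
frozen reference with a warning); iteration stops when fewer than
`convergence_frac` of particles change class, or at the caps. Per-particle
RNG streams derive from `(seed, iteration, particle id)`, so results are
independent of execution order and worker count. Replicate runs are
combined by class consensus: class labels are first merged onto common
states — by user-supplied maps, or by a Hungarian matching on
co-occupancy that *proposes* what the original workflow does by visual
curation — and a particle is kept only if at least `m` of `R` replicates
agree; per-state occupancies per replicate quantify reproducibility.

## Synthetic data

The simulator generates the study conditions end to end: an asymmetric
blob-cluster phantom (seven Gaussian blobs, widths ≥ ~1.2 voxels so the
density is band-limited; a variant pair differing by one appendage for
classification tests; a featureless hollow sphere as a control), particles
planted at uniform random positions (rejection-sampled to a minimum
separation, default one box) and uniform random orientations, the whole
volume filtered in 3D Fourier space with the same slice-wedge/CTF/exposure
filters the toolkit builds, and white Gaussian noise with variance
`var(filtered signal)/SNR` — SNR is a variance ratio measured after
filtering, since the filtered signal is what competes with the noise. An
optional double-sheet slab mimics a membrane for noise-flattening tests.
All outputs are bit-reproducible given the seed.

Filtering the 3D volume directly reproduces exactly the transfer model
the toolkit assumes; it does **not** emulate 2D projection and
reconstruction, detector physics, beam-induced motion, alignment errors
between tilts, or structured cellular background. Passing tests therefore
demonstrate the internal consistency and correctness of the algorithms
under their own image model, not performance on real tomograms, where
model mismatch (reconstruction artifacts, non-white noise, crowding)
reduces every margin.

Demonstration problem sizes were chosen to exercise each mechanism at
workstation scale: 96³ tomograms with 12 particles at SNR 0.05 against the
full 4512-orientation list for template matching; 20 noise-free particles
for pose recovery (2° increments, 3 iterations, whole-voxel 3-voxel
shifts); 50 copies for the Fourier-normalization check (low-pass 6 at box
32, matching the worked 32-pixel-box parameter sets); and 100+100
particles at SNR 0.5 with four seeded classes, SA(5)+SHC(≤20), three
replicates and 2-of-3 consensus for classification.

## Files and conventions

Volumes are MRC2014, modes 0/8-bit, 1/16-bit int, 2/32-bit float, voxel
size in the header, written by a compact numpy-based writer that gemmi
reads back identically (cross-checked in tests). Particle metadata
("motive lists": position, shift, ZXZ angles, score, class, halfset) and
per-tilt acquisition metadata ("wedge lists") are STAR tables via
gemmi.cif; file positions are 1-based voxel centers for TOM/AV3-lineage
compatibility and converted at the I/O boundary, and `pos + shift` is the
conserved absolute coordinate (extraction re-centers `pos` and keeps the
sub-voxel remainder in `shift`). Parameter files are `key=value` text; the
`parse` command validates them (all errors at once, suggestions for
unknown keys) and prints every default. Tasks process independent work
units (tiles, particles) merged by unit index, so any worker count and any
resume from checkpoints give bit-identical outputs.

## Known limitations

* Real-space trilinear resampling bounds high-frequency fidelity (see
  above); there is no Fourier-space rotation path.
* Only Cn point groups; the symmetry axis must already be on z.
* No GPU path, no MPI — parallelism is the deterministic in-process worker
  pool plus file-level checkpointing.
* No tilt-series processing, tomogram reconstruction, defocus estimation
  or per-tilt refinement; the wedge list is trusted as given.
* Voxel-precision shifts during alignment (sub-voxel only via the
  bookkeeping of accumulated shifts between extractions).
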