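# subtomo

Subtomogram averaging for cryo-electron tomography (cryo-ET), built around
an amplitude-modulated missing-wedge model.

Tomograms sample Fourier space on the central slices of their tilt images;
the unsampled "missing wedge", the contrast transfer function (CTF) and
cumulative electron-exposure damage all distort what a particle looks like
in a tomogram. This package models a tomogram's transfer function
explicitly — binary Fourier slices with per-tilt |CTF| (at each particle's
local defocus) and exposure-filter amplitude modulations — and uses it
consistently through the whole single-particle-tomography workflow:

* **Template matching**: exhaustive orientation search of a wedge-filtered
  template against tiled tomograms via the 3D fast local correlation
  function (FLCF), with score and orientation maps, optional
  noise-correlation flattening (matching a phase-randomized template and
  subtracting its score map), and greedy peak extraction into a particle
  table ("motive list").
* **Subtomogram alignment and averaging**: local orientation search around
  each particle's prior, shifts from the correlation peak, gold-standard
  halfsets throughout, and averaging with per-voxel Fourier sampling
  normalization (the sum of identically rotated missing-wedge filters),
  Fourier shell correlation (FSC) between halfmaps, and a
  figure-of-merit-weighted display map (`sqrt(2 FSC/(1+FSC))` per shell).
* **Classification**: multi-reference alignment (MRA) as a 4D search over
  orientations × classes, with non-exclusive de novo class seeding,
  stochastic hill climbing (SHC), simulated annealing (SA), and
  replicate class-consensus filtering.
* **Simulator**: ground-truth phantoms planted at known poses, filtered
  with the same wedge/CTF/exposure model and Gaussian noise at a stated
  SNR — every algorithm above is tested against it end to end.

Volumes are MRC2014 (modes 0/1/2); particle and tilt metadata are STAR
tables; orientations are intrinsic ZXZ Euler triplets
(`R = Rz(psi) Rx(theta) Rz(phi)`). See `docs/methods.md` for the model,
conventions and numerical choices.

## Worked example

Simulate a tomogram with 4 planted particles, match the generating
phantom against it, and extract the found particles:

```sh
subtomo simulate --set out_tomo=tomo.mrc --set out_motl=truth.star \
    --set out_wedge=wedge.star --set tomo_size=64 --set boxsize=24 \
    --set n_particles=4 --set min_dist=22 --set snr=1.0 --set seed=3

subtomo tm --set tomogram=tomo.mrc --set template=template.mrc \
    --set wedge=wedge.star --set cone_step=40 --set inplane_step=40 \
    --set lp_radius=10 --set threshold=0.15 --set min_dist=10 \
    --set out_score=score.mrc --set out_orient=orient.mrc \
    --set out_motl=found.star
```

The `tm` task prints a JSON log ending in

```
  "elapsed_s": 13.687,
  "n_peaks": 5
```

— five peaks above the 0.15 threshold: the four planted particles (the
score map peaks at their positions, with the winning entry of the 40°
angle list recorded in the orientation map) plus one spurious
low-scoring peak that a stricter threshold or the `use_noise` flattening
pass removes. `found.star` holds one row per peak with position, Euler
angles and CCC score, ready for `subtomo extract` and
`subtomo ali_singleclass`.

The same operations are available as a library (`subtomo.simulator`,
`subtomo.template_matching`, `subtomo.align_avg`, `subtomo.mra`, ...);
the test suite shows each of them driven directly from Python, including
full classification runs with replicate consensus.

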