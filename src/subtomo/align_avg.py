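"""Subtomogram alignment and wedge-normalized halfset averaging.

Alignment does a local orientation search around each particle's prior
pose: the reference is rotated, filtered with the particle's
amplitude-modulated missing-wedge filter and a bandpass, masked, and
correlated (FLCF) against the slice-wedge/bandpass-filtered subtomogram.
The best peak gives the new orientation; the vector from the CCC-map
center to the peak gives the shift.

Averaging rotates each subtomogram back to the reference frame, sums, and
divides the sum's Fourier coefficients by a per-voxel tally of the
identically-rotated missing-wedge filters — the sampling-compensation
step that prevents anisotropic weighting of Fourier space.  All alignment
and averaging runs as two independent halfsets ("gold standard"), with
resolution assessed by Fourier shell correlation between the halfmaps and
a figure-of-merit weighted sum as the display map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import ndimage

from . import correlation as corr
from . import particles, wedge
from .geometry import (
    SymmetryGroup,
    apply_symmetry,
    generate_local_angle_list,
    invert_euler,
    rotate_volume,
)

__all__ = [
    "AlignmentParams",
    "AverageBundle",
    "align_subtomo",
    "average_halfset",
    "compute_fsc",
    "fom_weighted_sum",
    "rotate_fourier_filter",
    "run_alignment_iteration",
]


@dataclass
class AlignmentParams:
    """Search-space and filter settings for one alignment round."""

    cone_step: float = 2.0
    cone_iter: int = 3
    inplane_step: float = 2.0
    inplane_iter: int = 3
    lp_radius: float = 0.0  # Fourier pixels; 0 disables
    lp_sigma: float = 3.0
    hp_radius: float = 0.0
    hp_sigma: float = 2.0
    cc_mask_radius: float | None = None  # voxels; None allows any shift
    symmetry: SymmetryGroup = field(default_factory=lambda: SymmetryGroup("C1"))
    iterations: int = 1

    def __post_init__(self):
        if isinstance(self.symmetry, str):
            self.symmetry = SymmetryGroup(self.symmetry)
        if self.iterations > 0 and (self.cone_iter > 0 and self.cone_step <= 0):
            raise ValueError("cone_step must be > 0 when cone_iter > 0")
        if self.iterations > 0 and (self.inplane_iter > 0 and self.inplane_step <= 0):
            raise ValueError("inplane_step must be > 0 when inplane_iter > 0")

    def local_list(self, center):
        """Local angle list around ``center``; the in-plane range is clamped
        to ±180/n under Cn symmetry."""
        inplane_iter = self.inplane_iter
        if self.symmetry.n > 1 and self.inplane_iter > 0:
            half_range = 180.0 / self.symmetry.n
            inplane_iter = min(
                self.inplane_iter, int(np.floor(half_range / self.inplane_step))
            )
        return generate_local_angle_list(
            center, self.cone_step, self.cone_iter, self.inplane_step, inplane_iter
        )

    def bandpass(self, boxsize: int):
        if not self.lp_radius:
            return None
        return wedge.bandpass_filter(
            boxsize, self.lp_radius, self.lp_sigma, self.hp_radius, self.hp_sigma
        )


@dataclass
class AverageBundle:
    """Outputs of one halfset averaging round."""

    halfmap_a: np.ndarray
    halfmap_b: np.ndarray
    fom_map: np.ndarray
    wedge_tally_a: np.ndarray
    wedge_tally_b: np.ndarray
    fsc: np.ndarray


def rotate_fourier_filter(values: np.ndarray, angles) -> np.ndarray:
    """Rotate a Fourier-domain amplitude filter (unshifted layout)."""
    centered = sfft.fftshift(values)
    rot = rotate_volume(centered, angles, cval=0.0)
    return np.clip(sfft.ifftshift(rot), 0.0, 1.0)


def align_subtomo(
    subtomo: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray,
    wedge_filter: wedge.WedgeFilter,
    params: AlignmentParams,
    prior: pd.Series | dict,
) -> dict:
    """Local orientation/shift refinement of one particle.

    Returns the updated row fields: Euler angles of the best-scoring
    orientation, the CCC-peak offset as the shift, and the peak value as
    the score.
    """
    nbox = subtomo.shape[0]
    if ref.shape != subtomo.shape or mask.shape != subtomo.shape:
        raise ValueError("subtomo, reference and mask must share one box size")
    prior_angles = (prior["phi"], prior["theta"], prior["psi"])
    angle_list = params.local_list(prior_angles)

    bp = params.bandpass(nbox)
    ref_filt = wedge_filter.values if bp is None else wedge_filter.values * bp.values
    data_filt = (wedge_filter.values > 0).astype(float)
    if bp is not None:
        data_filt = data_filt * bp.values

    sub_f = sfft.ifftn(sfft.fftn(np.asarray(subtomo, dtype=float)) * data_filt).real
    spectra = corr.precompute_search(sub_f)
    cc_mask = (
        corr.spherical_mask(nbox, params.cc_mask_radius)
        if params.cc_mask_radius is not None
        else None
    )
    from .template_matching import _is_rotationally_symmetric

    spherical = _is_rotationally_symmetric(mask)
    denom = corr.local_denominator(spectra, mask) if spherical else None

    best = (-np.inf, np.zeros(3), prior_angles)
    for ang in angle_list.angles:
        rot_ref = rotate_volume(ref, ang)
        rot_ref = sfft.ifftn(sfft.fftn(rot_ref) * ref_filt).real
        rot_mask = mask if spherical else np.clip(rotate_volume(mask, ang, cval=0.0), 0, 1)
        ccc = corr.flcf(
            sub_f,
            rot_ref,
            rot_mask,
            spectra=spectra,
            denom=denom if spherical else None,
        )
        score, offset = corr.peak_find(ccc, cc_mask)
        if score > best[0]:
            best = (score, offset, tuple(ang))
    score, offset, ang = best
    return {
        "phi": ang[0],
        "theta": ang[1],
        "psi": ang[2],
        "shift_x": float(offset[0]),
        "shift_y": float(offset[1]),
        "shift_z": float(offset[2]),
        "score": float(score),
    }


def average_halfset(
    subtomos,
    rows: pd.DataFrame,
    wedges,
    sym: SymmetryGroup | str = "C1",
    tally_floor: float = 0.01,
    lp_radius: float | None = None,
):
    """Wedge-normalized average of one halfset (or class).

    Each subtomogram is shifted by minus its sub-voxel shift (Fourier phase
    ramp), rotated by the inverse of its Euler angles and summed; every
    particle's amplitude wedge is rotated identically and summed into the
    sampling tally.  The raw average's Fourier coefficients are divided by
    the tally; voxels whose tally is below ``tally_floor`` of the maximum
    are zeroed (unsampled regions would only amplify noise).
    """
    if len(rows) == 0:
        raise ValueError("cannot average an empty particle set")
    if isinstance(wedges, wedge.WedgeFilter) or (
        isinstance(wedges, np.ndarray) and wedges.ndim == 3
    ):
        wedges = [wedges] * len(rows)
    box_shape = np.asarray(subtomos[0]).shape
    vol_sum = np.zeros(box_shape)
    tally = np.zeros(box_shape)
    for v, (_, row), w in zip(subtomos, rows.iterrows(), wedges):
        shift = np.array([row["shift_x"], row["shift_y"], row["shift_z"]])
        angles = (row["phi"], row["theta"], row["psi"])
        f = sfft.fftn(np.asarray(v, dtype=float))
        if np.any(shift != 0):
            f = ndimage.fourier_shift(f, -shift)
        aligned = rotate_volume(sfft.ifftn(f).real, invert_euler(angles), cval=0.0)
        vol_sum += aligned
        wv = w.values if isinstance(w, wedge.WedgeFilter) else w
        tally += rotate_fourier_filter(wv, invert_euler(angles))

    favg = sfft.fftn(vol_sum)
    floor = tally_floor * tally.max()
    sampled = tally >= max(floor, 1e-12)
    favg = np.where(sampled, favg / np.where(sampled, tally, 1.0), 0.0)
    if lp_radius:
        kx, ky, kz = wedge._freq_grids(box_shape)
        inside = (kx**2 + ky**2 + kz**2) < lp_radius**2
        n_bad = int((~sampled & inside).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} Fourier voxels inside the low-pass radius have no "
                "sampling; zero-filled"
            )
    avg = sfft.ifftn(favg).real
    return apply_symmetry(avg, sym), tally


def compute_fsc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Fourier shell correlation in shells of one Fourier pixel.

    An optional real-space mask is applied to both maps first.  Shell 0 is
    1 for any two maps with equal (nonzero) means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    if mask is not None:
        a = a * mask
        b = b * mask
    fa = sfft.fftn(a)
    fb = sfft.fftn(b)
    kx, ky, kz = wedge._freq_grids(a.shape)
    r = np.sqrt(np.broadcast_to(kx**2 + ky**2 + kz**2, a.shape))
    shells = np.round(r).astype(int).ravel()
    n_shells = a.shape[0] // 2 + 1
    sel = shells < n_shells
    cross = np.bincount(shells[sel], (fa * np.conj(fb)).real.ravel()[sel], minlength=n_shells)
    pa = np.bincount(shells[sel], np.abs(fa.ravel()[sel]) ** 2, minlength=n_shells)
    pb = np.bincount(shells[sel], np.abs(fb.ravel()[sel]) ** 2, minlength=n_shells)
    with np.errstate(divide="ignore", invalid="ignore"):
        fsc = cross / np.sqrt(pa * pb)
    return np.nan_to_num(fsc[:n_shells], nan=0.0)


def fom_weighted_sum(halfmap_a: np.ndarray, halfmap_b: np.ndarray, fsc: np.ndarray) -> np.ndarray:
    """Figure-of-merit weighted display map.

    The halfmap mean is filtered per shell by Cref = sqrt(2*FSC/(1+FSC))
    with FSC clamped to [0, 1] (so FSC 1 -> 1, 1/3 -> 0.7071, <=0 -> 0).
    """
    f = np.clip(np.asarray(fsc, dtype=float), 0.0, 1.0)
    weights = np.sqrt(2.0 * f / (1.0 + f))
    mean_map = 0.5 * (np.asarray(halfmap_a) + np.asarray(halfmap_b))
    kx, ky, kz = wedge._freq_grids(mean_map.shape)
    r = np.sqrt(np.broadcast_to(kx**2 + ky**2 + kz**2, mean_map.shape))
    shell = np.minimum(np.round(r).astype(int), len(weights) - 1)
    return sfft.ifftn(sfft.fftn(mean_map) * weights[shell]).real


def run_alignment_iteration(
    subtomos,
    mlist: particles.MotiveList,
    wedges,
    refs: dict,
    mask: np.ndarray,
    params: AlignmentParams,
    tally_floor: float = 0.01,
    iteration: int = 0,
    seed: int = 0,
):
    """One gold-standard alignment + averaging round.

    Every particle is aligned against the reference of its own halfset
    (particles with no halfset get a per-iteration random split), the two
    halves are averaged independently, and the FSC between the new
    halfmaps plus the FoM map are returned.  Particles are processed in
    ``subtomo_num`` order so results are independent of row order.
    """
    if isinstance(wedges, wedge.WedgeFilter):
        wedges = [wedges] * len(mlist)
    if (mlist.rows["halfset"] == "").any():
        mlist = particles.assign_halfsets(
            mlist, mode="per_iteration", seed=seed + 1_000_003 * iteration
        )
    order = np.argsort(mlist.rows["subtomo_num"].to_numpy(), kind="stable")
    new_rows = mlist.rows.copy()
    for i in order:
        row = mlist.rows.iloc[i]
        updates = align_subtomo(
            subtomos[i], refs[row["halfset"]], mask, wedges[i], params, row
        )
        for key, val in updates.items():
            new_rows.loc[new_rows.index[i], key] = val
    new_list = particles.MotiveList(new_rows, mlist.binning)

    halves = {}
    tallies = {}
    for hs in ("A", "B"):
        idx = new_list.halfset_indices(hs)
        if len(idx) == 0:
            raise ValueError(f"halfset {hs} is empty")
        idx = idx[np.argsort(new_list.rows["subtomo_num"].to_numpy()[idx], kind="stable")]
        halves[hs], tallies[hs] = average_halfset(
            [subtomos[i] for i in idx],
            new_list.rows.iloc[idx],
            [wedges[i] for i in idx],
            sym=params.symmetry,
            tally_floor=tally_floor,
            lp_radius=params.lp_radius or None,
        )
    fsc = compute_fsc(halves["A"], halves["B"], mask)
    fom = fom_weighted_sum(halves["A"], halves["B"], fsc)
    bundle = AverageBundle(
        halfmap_a=halves["A"],
        halfmap_b=halves["B"],
        fom_map=fom,
        wedge_tally_a=tallies["A"],
        wedge_tally_b=tallies["B"],
        fsc=fsc,
    )
    return new_list, bundle
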