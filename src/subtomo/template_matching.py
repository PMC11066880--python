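"""Exhaustive-orientation template matching against tomograms.

The template is rotated through every entry of an angle list, filtered with
the tomogram's amplitude-modulated missing-wedge filter, and correlated
against the (binary-slice-wedge and bandpass filtered) tomogram with the
FLCF.  Per voxel, the best score over all orientations is accumulated into
a score map and the index of the winning orientation into an orientation
map.  An optional noise pass repeats the search with a phase-randomized
template; subtracting its map flattens nonspecific background
(membranes, ice) while leaving true peaks largely untouched.

Tomograms are processed in "tiles" — disjoint core regions padded by half
a template box — so work parallelizes; the tomogram is filtered once
globally before tiling, which makes stitched score maps exactly equal to
untiled matching away from the tomogram borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from . import correlation as corr
from . import particles, wedge
from .geometry import AngleList, rotate_volume

__all__ = [
    "ScoreMaps",
    "Tile",
    "make_tiles",
    "match_tile",
    "noise_flatten",
    "extract_peaks",
    "run_template_matching",
]


@dataclass
class ScoreMaps:
    """Paired score / winning-orientation volumes (plus optional noise map)."""

    score: np.ndarray
    orientation_index: np.ndarray
    noise_score: np.ndarray | None = None
    angle_list: AngleList | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class Tile:
    """Core (disjoint) and padded (overlapping) voxel ranges of one tile."""

    core: tuple  # tuple of slices into the tomogram
    padded: tuple

    @property
    def core_in_padded(self) -> tuple:
        return tuple(
            slice(c.start - p.start, c.stop - p.start)
            for c, p in zip(self.core, self.padded)
        )


def make_tiles(tomo_shape, n_tiles, template_box: int) -> list[Tile]:
    """Split a tomogram into disjoint cores padded by template_box/2.

    Core ranges exactly tile the tomogram; padding is clamped at borders.
    """
    tomo_shape = tuple(int(s) for s in tomo_shape)
    n_tiles = (n_tiles,) * 3 if np.isscalar(n_tiles) else tuple(int(n) for n in n_tiles)
    pad = template_box // 2
    bounds = []
    for size, n in zip(tomo_shape, n_tiles):
        if n < 1:
            raise ValueError("n_tiles must be >= 1 per axis")
        edges = [round(i * size / n) for i in range(n + 1)]
        if min(b - a for a, b in zip(edges[:-1], edges[1:])) < template_box:
            raise ValueError(
                f"tile cores of {tomo_shape} / {n_tiles} are smaller than the "
                f"template box {template_box}"
            )
        bounds.append(edges)
    tiles = []
    for i in range(n_tiles[0]):
        for j in range(n_tiles[1]):
            for k in range(n_tiles[2]):
                core = tuple(
                    slice(bounds[ax][idx], bounds[ax][idx + 1])
                    for ax, idx in zip(range(3), (i, j, k))
                )
                padded = tuple(
                    slice(max(c.start - pad, 0), min(c.stop + pad, s))
                    for c, s in zip(core, tomo_shape)
                )
                tiles.append(Tile(core, padded))
    return tiles


def _embed_kernel(small: np.ndarray, shape) -> np.ndarray:
    """Place a template-box kernel into a tile-shaped array such that
    correlation offsets index the template-center voxel directly."""
    n = small.shape[0]
    out = np.zeros(shape, dtype=small.dtype)
    out[:n, :n, :n] = small
    return np.roll(out, (-(n // 2),) * 3, axis=(0, 1, 2))


def _is_rotationally_symmetric(mask: np.ndarray) -> bool:
    """Detect (soft-edged) spherical masks, for which the local-variance
    denominator is orientation independent and can be computed once.  The
    tolerance allows for trilinear interpolation error on the soft edge;
    using the unrotated mask for a truly spherical mask is exact."""
    n = mask.shape[0]
    c = n // 2
    ax = np.arange(n) - c
    r2 = sum(g**2 for g in np.meshgrid(ax, ax, ax, indexing="ij", sparse=True))
    inside = np.broadcast_to(r2, mask.shape) <= (c - 1) ** 2  # rotation has data here
    for test in ((90.0, 90.0, 0.0), (37.0, 53.0, 21.0)):
        if np.abs((mask - rotate_volume(mask, test, cval=0.0))[inside]).max() > 0.05:
            return False
    return True


def match_tile(
    tile_vol: np.ndarray,
    template: np.ndarray,
    mask: np.ndarray,
    angles: AngleList,
    wedge_filter: wedge.WedgeFilter | np.ndarray,
    bandpass: wedge.WedgeFilter | np.ndarray | None = None,
) -> ScoreMaps:
    """Orientation search of a template over one (pre-filtered) tile.

    ``wedge_filter`` and ``bandpass`` are Fourier filters on the template
    box, applied to every rotated template; the tile must already carry its
    binary slice-wedge/bandpass filtering.  Returns tile-shaped maps whose
    voxel index is the template-center position.
    """
    tile_vol = np.asarray(tile_vol)
    template = np.asarray(template, dtype=tile_vol.dtype)
    nbox = template.shape[0]
    if any(nbox > s for s in tile_vol.shape):
        raise ValueError("template box exceeds tile box")
    wvals = wedge_filter.values if isinstance(wedge_filter, wedge.WedgeFilter) else wedge_filter
    if bandpass is not None:
        bvals = bandpass.values if isinstance(bandpass, wedge.WedgeFilter) else bandpass
        wvals = wvals * bvals

    spectra = corr.precompute_search(tile_vol)
    spherical = _is_rotationally_symmetric(mask)

    def _inv_denominator(m):
        den = corr.local_denominator(spectra, _embed_kernel(m, tile_vol.shape))
        with np.errstate(divide="ignore"):
            inv = np.where(den > 0, 1.0 / den, 0.0)  # zero variance scores 0
        return inv.astype(np.float32)

    inv_den = _inv_denominator(mask) if spherical else None

    score = np.full(tile_vol.shape, -np.inf, dtype=np.float32)
    orient = np.zeros(tile_vol.shape, dtype=np.int32)
    better = np.empty(tile_vol.shape, dtype=bool)
    for i, ang in enumerate(angles.angles):
        rot_t = rotate_volume(template, ang)
        rot_t = sfft.ifftn(sfft.fftn(rot_t) * wvals).real
        rot_m = mask if spherical else np.clip(rotate_volume(mask, ang, cval=0.0), 0.0, 1.0)
        w, ref_norm = corr.normalize_reference(rot_t, rot_m)
        num = sfft.irfftn(
            np.conj(sfft.rfftn(_embed_kernel(w.astype(tile_vol.dtype), tile_vol.shape)))
            * spectra.fs,
            s=spectra.shape,
        )
        vals = num * ((1.0 / ref_norm) * (inv_den if spherical else _inv_denominator(rot_m)))
        np.greater(vals, score, out=better)
        np.copyto(score, vals, where=better)
        np.copyto(orient, np.int32(i), where=better)
    return ScoreMaps(score=score, orientation_index=orient, angle_list=angles)


def noise_flatten(maps: ScoreMaps) -> ScoreMaps:
    """Subtract the noise-correlation map and clamp negatives to zero."""
    if maps.noise_score is None:
        raise ValueError("no noise_score present; run matching with use_noise")
    flattened = np.maximum(maps.score - maps.noise_score, 0.0)
    return ScoreMaps(
        score=flattened,
        orientation_index=maps.orientation_index,
        noise_score=maps.noise_score,
        angle_list=maps.angle_list,
        metadata={**maps.metadata, "noise_flattened": True},
    )


def extract_peaks(
    maps: ScoreMaps,
    threshold: float,
    min_dist: float,
    angles: AngleList | None = None,
    border: int = 0,
) -> particles.MotiveList:
    """Greedy peak extraction into a motive list.

    Peaks are accepted in descending score order; each accepted peak
    suppresses all voxels within ``min_dist`` (Euclidean).  Voxels within
    ``border`` of the map edge are excluded (incomplete template support).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if min_dist < 1:
        raise ValueError("min_dist must be >= 1")
    angles = angles if angles is not None else maps.angle_list
    score = maps.score
    valid = score >= threshold
    if border > 0:
        edge = np.zeros_like(valid)
        edge[border:-border, border:-border, border:-border] = True
        valid &= edge
    coords = np.argwhere(valid)
    if len(coords) == 0:
        return particles.empty_motivelist()
    vals = score[tuple(coords.T)]
    order = np.argsort(-vals, kind="stable")
    coords = coords[order]
    vals = vals[order]
    kept: list[int] = []
    kept_pos = np.empty((0, 3))
    for idx in range(len(coords)):
        p = coords[idx]
        if len(kept) and (np.linalg.norm(kept_pos - p, axis=1) < min_dist).any():
            continue
        kept.append(idx)
        kept_pos = np.vstack([kept_pos, p])
    pos = coords[kept]
    ml = particles.new_motivelist(
        pos.astype(float),
        angles=(
            np.array([angles.angles[maps.orientation_index[tuple(p)]] for p in pos])
            if angles is not None
            else None
        ),
        scores=vals[kept],
    )
    return ml


def run_template_matching(
    tomo: np.ndarray,
    template: np.ndarray,
    mask: np.ndarray,
    wedge_list: wedge.WedgeList,
    angles: AngleList,
    lp_radius: float = 0.0,
    lp_sigma: float = 3.0,
    hp_radius: float = 0.0,
    hp_sigma: float = 2.0,
    use_ctf: bool = True,
    use_exposure: bool = True,
    use_noise: bool = False,
    noise_seed: int = 42,
    n_tiles=1,
    dtype=np.float32,
) -> ScoreMaps:
    """Full template-matching task for one tomogram.

    The tomogram is filtered once with its binary slice wedge (and the
    bandpass, expressed in Fourier pixels of the template box), then matched
    tile by tile against the wedge- and bandpass-filtered rotated template.
    One global amplitude wedge (defocus at the tomogram's center of mass) is
    used throughout.  With ``use_noise`` a second pass with a
    phase-randomized template fills ``noise_score``.
    """
    tomo = np.asarray(tomo, dtype=dtype)
    nbox = template.shape[0]

    # template-frame filters
    amp = wedge.amplitude_wedge(
        wedge_list.tomo_center, wedge_list, nbox, use_ctf=use_ctf, use_exposure=use_exposure
    )
    bp_small = (
        wedge.bandpass_filter(nbox, lp_radius, lp_sigma, hp_radius, hp_sigma)
        if lp_radius
        else None
    )

    # tomogram-frame filtering (binary slice wedge x bandpass), applied once
    binary = wedge.binary_slice_wedge(wedge_list.tilt_angles, tomo.shape)
    filt = binary.values
    if lp_radius:
        filt = filt * wedge.radial_bandpass(
            tomo.shape, lp_radius, lp_sigma, hp_radius, hp_sigma, ref_box=nbox
        ).values
    tomo_f = sfft.ifftn(sfft.fftn(tomo) * filt).real.astype(dtype)

    tiles = make_tiles(tomo.shape, n_tiles, nbox)
    templates = {"score": np.asarray(template, dtype=dtype)}
    if use_noise:
        templates["noise"] = corr.phase_randomize(template, noise_seed).astype(dtype)

    full = {
        key: (
            np.zeros(tomo.shape, dtype=np.float32),
            np.zeros(tomo.shape, dtype=np.int32),
        )
        for key in templates
    }
    for tile in tiles:
        for key, tmpl in templates.items():
            sub = match_tile(tomo_f[tile.padded], tmpl, mask, angles, amp, bp_small)
            full[key][0][tile.core] = sub.score[tile.core_in_padded]
            full[key][1][tile.core] = sub.orientation_index[tile.core_in_padded]

    maps = ScoreMaps(
        score=full["score"][0],
        orientation_index=full["score"][1],
        noise_score=full["noise"][0] if use_noise else None,
        angle_list=angles,
        metadata={"noise_seed": noise_seed if use_noise else None, "n_tiles": n_tiles},
    )
    return maps
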