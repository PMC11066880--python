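"""Synthetic ground-truth generator for subtomogram-averaging tests.

Simulates the image model the rest of the package assumes: particles of a
known density planted at known poses, the whole volume filtered in 3D
Fourier space with a slice-wedge filter (optionally CTF/exposure
modulated), plus white Gaussian noise at a stated signal-to-noise ratio.
The SNR is defined as the variance ratio var(filtered signal)/var(noise):
the filtered signal is what competes with the noise.

Filtering in 3D Fourier space (rather than projecting and reconstructing
2D tilts) reproduces exactly the transfer model the toolkit's filters
describe, which keeps plant-and-recover tests self-consistent and fast.
Detector physics, beam-induced motion and reconstruction artifacts are not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from . import particles, wedge
from .geometry import matrix_to_euler, rotate_volume

__all__ = [
    "GroundTruth",
    "make_phantom",
    "simulate_subtomogram",
    "simulate_tomogram",
    "random_euler",
    "shift_volume",
    "score_recovery",
]


def shift_volume(vol: np.ndarray, shift) -> np.ndarray:
    """Translate a volume by a (possibly sub-voxel) vector via Fourier phase ramp."""
    f = ndimage.fourier_shift(sfft.fftn(np.asarray(vol, dtype=float)), shift)
    return sfft.ifftn(f).real


def random_euler(rng: np.random.Generator) -> tuple[float, float, float]:
    """Euler triplet of a rotation drawn uniformly from SO(3)."""
    # uniform quaternion -> matrix -> ZXZ triplet
    u1, u2, u3 = rng.random(3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    x, y, z, w = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return matrix_to_euler(R)


def _gaussian_blob(shape, center, sigma, amplitude=1.0):
    ax = [np.arange(s) for s in shape]
    grids = np.meshgrid(*ax, indexing="ij", sparse=True)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def make_phantom(kind: str = "blob_cluster", boxsize: int = 32, seed: int = 0):
    """Smooth, band-limited test density with identifiable orientation.

    ``blob_cluster``: an asymmetric cluster of Gaussian blobs.
    ``hollow_sphere``: a soft spherical shell (no angular features).
    ``two_class_pair``: a (base, base+appendage) pair for classification
    tests; the two correlate strongly but distinguishably.
    """
    if boxsize < 16:
        raise ValueError("boxsize must be >= 16")
    rng = np.random.default_rng(seed)
    n = int(boxsize)
    c = n // 2
    if kind == "hollow_sphere":
        ax = np.arange(n) - c
        r = np.sqrt(sum(g**2 for g in np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)))
        shell = np.exp(-((r - n / 4.0) ** 2) / (2.0 * (n / 16.0) ** 2))
        return shell
    if kind in ("blob_cluster", "two_class_pair"):
        vol = np.zeros((n,) * 3)
        n_blobs = 7
        # asymmetric arrangement: blobs biased along distinct directions
        for i in range(n_blobs):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(0.08, 0.26) * n
            center = c + direction * radius
            # sigma >= ~1.2 voxels at the smallest allowed box keeps the
            # density band-limited on the voxel grid
            sigma = rng.uniform(0.05, 0.075) * n
            vol += _gaussian_blob((n,) * 3, center, sigma, rng.uniform(0.6, 1.0))
        if kind == "blob_cluster":
            return vol
        appendage = _gaussian_blob((n,) * 3, (c + 0.24 * n, c, c + 0.1 * n), 0.06 * n, 1.0)
        return vol, vol + appendage
    raise ValueError(f"unknown phantom kind {kind!r}")


def simulate_subtomogram(
    phantom: np.ndarray,
    angles=(0.0, 0.0, 0.0),
    shift=(0.0, 0.0, 0.0),
    wedge_filter=None,
    snr: float = np.inf,
    seed: int = 0,
) -> np.ndarray:
    """Rotate and shift the phantom, apply the wedge filter, add noise.

    Noise is white Gaussian with variance ``var(filtered signal)/snr``;
    ``snr = inf`` returns the noise-free filtered, posed phantom.
    Deterministic given ``seed``.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    posed = rotate_volume(np.asarray(phantom, dtype=float), angles, cval=0.0)
    if np.any(np.asarray(shift) != 0):
        posed = shift_volume(posed, shift)
    if wedge_filter is not None:
        values = (
            wedge_filter.values
            if isinstance(wedge_filter, wedge.WedgeFilter)
            else wedge_filter
        )
        posed = sfft.ifftn(sfft.fftn(posed) * values).real
    if np.isinf(snr):
        return posed
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(posed.var() / snr)
    return posed + rng.normal(0.0, sigma, posed.shape)


@dataclass
class GroundTruth:
    """A simulated tomogram with its generating truth."""

    density: np.ndarray
    plants: particles.MotiveList
    wedge_list: wedge.WedgeList
    snr: float
    slab_z: tuple[float, float] | None = None


def _place_positions(rng, tomo_shape, n_particles, margin, min_dist, max_attempts=10_000):
    positions: list[np.ndarray] = []
    lo = np.full(3, margin, dtype=float)
    hi = np.array(tomo_shape, dtype=float) - margin
    attempts = 0
    while len(positions) < n_particles:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_particles} particles with min_dist {min_dist} "
                f"in {max_attempts} attempts; placed {len(positions)}"
            )
        attempts += 1
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= min_dist for q in positions):
            positions.append(p)
    return np.array(positions)


def simulate_tomogram(
    phantoms,
    n_particles: int,
    tomo_shape,
    wedge_list: wedge.WedgeList,
    snr: float = 0.05,
    seed: int = 0,
    min_dist: float | None = None,
    use_ctf: bool = False,
    use_exposure: bool = False,
    slab: bool = False,
    slab_amplitude: float = 1.0,
    integer_positions: bool = False,
) -> GroundTruth:
    """Plant particles at random poses in a noisy, wedge-filtered tomogram.

    ``phantoms`` is one volume or a list of class volumes (classes drawn
    uniformly).  Positions are uniform with rejection sampling at
    ``min_dist`` (default: the phantom box size).  ``slab`` adds a
    membrane-like double sheet spanning x-y, for noise-flattening tests.
    Returns the tomogram together with the ground-truth motive list.
    """
    if np.ndim(phantoms) == 3:
        phantoms = [np.asarray(phantoms)]
    else:
        phantoms = [np.asarray(p) for p in phantoms]
    box = phantoms[0].shape[0]
    tomo_shape = tuple(int(s) for s in tomo_shape)
    rng = np.random.default_rng(seed)
    if min_dist is None:
        min_dist = float(box)

    clean = np.zeros(tomo_shape)
    if n_particles > 0:
        coords = _place_positions(rng, tomo_shape, n_particles, box // 2, min_dist)
        if integer_positions:
            coords = np.round(coords)
        eulers = np.array([random_euler(rng) for _ in range(n_particles)])
        labels = rng.integers(0, len(phantoms), n_particles) + 1
        for pos, ang, lab in zip(coords, eulers, labels):
            base = np.floor(pos).astype(int)
            frac = pos - base
            posed = rotate_volume(phantoms[lab - 1], ang, cval=0.0)
            posed = shift_volume(posed, frac)
            lo = base - box // 2
            sl = tuple(slice(l, l + box) for l in lo)
            clean[sl] += posed
        plants = particles.new_motivelist(coords, angles=eulers, classes=labels)
    else:
        plants = particles.empty_motivelist()

    slab_z = None
    if slab:
        zc = tomo_shape[2] * 0.5
        spacing = 2.5
        z = np.arange(tomo_shape[2])
        profile = np.exp(-((z - (zc - spacing)) ** 2) / 2.0) + np.exp(
            -((z - (zc + spacing)) ** 2) / 2.0
        )
        clean += slab_amplitude * profile[None, None, :]
        slab_z = (zc - 2 * spacing, zc + 2 * spacing)

    filt = wedge.amplitude_wedge(
        wedge_list.tomo_center, wedge_list, tomo_shape, use_ctf=use_ctf, use_exposure=use_exposure
    )
    filtered = sfft.ifftn(sfft.fftn(clean) * filt.values).real
    if np.isinf(snr):
        tomo = filtered
    else:
        base_var = filtered.var()
        sigma = np.sqrt(base_var / snr) if base_var > 0 else 1.0  # empty field: unit noise
        tomo = filtered + rng.normal(0.0, sigma, tomo_shape)
    return GroundTruth(density=tomo, plants=plants, wedge_list=wedge_list, snr=snr, slab_z=slab_z)


def score_recovery(truth: particles.MotiveList, found: particles.MotiveList, max_dist: float = 4.0):
    """Match found peaks to planted particles within ``max_dist`` voxels.

    Returns a dict with the number of recovered plants, positional errors
    and angular errors (geodesic degrees) of the matched pairs.
    """
    from .geometry import rotation_distance

    t_pos = truth.coords
    f_pos = found.coords
    t_ang = truth.angles
    f_ang = found.angles
    matched_t: set[int] = set()
    dist_err = []
    ang_err = []
    for i in range(len(f_pos)):
        d = np.linalg.norm(t_pos - f_pos[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_dist and j not in matched_t:
            matched_t.add(j)
            dist_err.append(float(d[j]))
            ang_err.append(rotation_distance(t_ang[j], f_ang[i]))
    return {
        "n_recovered": len(matched_t),
        "dist_errors": np.array(dist_err),
        "angular_errors": np.array(ang_err),
    }
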