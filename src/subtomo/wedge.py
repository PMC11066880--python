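"""Fourier-space missing-wedge filters for tomographic data.

A tomogram reconstructed from a tilt series samples Fourier space on a set
of central planes, one per tilt image (the central-slice theorem); the
unsampled region is the "missing wedge".  The filters built here model a
tomogram's transfer function as the union of those Fourier slices, each of
which may carry amplitude modulations from the contrast transfer function
(CTF) at the particle's local defocus and from the electron-exposure damage
accumulated before that tilt image was recorded.

Conventions
-----------
* Volumes are indexed (x, y, z); the tilt axis is the volume y axis and the
  untilted beam direction is the z axis.  A tilt by ``alpha`` rotates the
  beam in the x-z plane, so the Fourier slice of that image is the plane
  ``kx*sin(alpha) + kz*cos(alpha) = 0``.
* Filters are real-valued arrays laid out in unshifted FFT order (apply by
  multiplying the output of ``fftn``); all values lie in [0, 1] and are
  Hermitian-symmetric by construction.
* The CTF magnitude is used (``|CTF|``): tomograms are assumed to be
  CTF-corrected (phase-flipped) before or during reconstruction, so only
  the amplitude envelope remains.  Astigmatism is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

__all__ = [
    "TiltEntry",
    "WedgeList",
    "WedgeFilter",
    "electron_wavelength",
    "ctf_1d",
    "exposure_filter_1d",
    "local_defocus",
    "binary_slice_wedge",
    "amplitude_wedge",
    "bandpass_filter",
    "apply_fourier_filter",
    "make_wedge_list",
]


@dataclass
class TiltEntry:
    """Acquisition metadata of one tilt image."""

    tilt_angle: float  # degrees, rotation about the tilt (y) axis
    defocus_global: float = 3.0  # micrometres at the specimen's center of mass
    exposure_pre: float = 0.0  # e-/A^2 accumulated before this image


@dataclass
class WedgeList:
    """Per-tomogram table of tilt metadata plus microscope constants."""

    tomo_id: int
    tilts: list[TiltEntry]
    pixel_size: float = 2.0  # Angstrom per voxel at the working binning
    voltage: float = 300.0  # kV
    cs: float = 2.7  # spherical aberration, mm
    amplitude_contrast: float = 0.07
    tomo_center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels
    z_center_of_mass: float = 0.0  # voxels

    def __post_init__(self):
        if not self.tilts:
            raise ValueError("wedge list needs at least one tilt entry")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        exp = [t.exposure_pre for t in self.tilts]
        if min(exp) < 0:
            raise ValueError("accumulated exposure must be >= 0")

    @property
    def tilt_angles(self) -> np.ndarray:
        return np.array([t.tilt_angle for t in self.tilts])


@dataclass
class WedgeFilter:
    """3D Fourier amplitude filter on the grid of a target box.

    ``values`` is in unshifted FFT layout; ``kind`` is ``"binary"`` or
    ``"amplitude_modulated"``.
    """

    values: np.ndarray
    kind: str = "binary"

    @property
    def shape(self):
        return self.values.shape

    def binary_support(self) -> "WedgeFilter":
        """Binary slice mask of the sampled region (support of this filter)."""
        return WedgeFilter((self.values > 0).astype(self.values.dtype), kind="binary")

    def __mul__(self, other):
        ov = other.values if isinstance(other, WedgeFilter) else other
        kind = "binary" if self.kind == "binary" and getattr(other, "kind", "") == "binary" else "amplitude_modulated"
        return WedgeFilter(self.values * ov, kind=kind)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom (300 kV -> ~0.0197 A)."""
    v = voltage_kv * 1e3
    return 12.2643 / np.sqrt(v * (1.0 + 0.978476e-6 * v))


def ctf_1d(defocus_um: float, q, wl: WedgeList):
    """|CTF| at spatial frequency ``q`` (1/Angstrom).

    CTF = -[sqrt(1-A^2) sin(chi) + A cos(chi)] with
    chi(q) = pi*lambda*dz*q^2 - (pi/2)*Cs*lambda^3*q^4 (dz > 0 underfocus);
    the magnitude is returned because input tomograms are assumed
    phase-corrected.
    """
    q = np.asarray(q, dtype=float)
    lam = electron_wavelength(wl.voltage)
    dz = defocus_um * 1e4  # um -> A
    cs = wl.cs * 1e7  # mm -> A
    a = wl.amplitude_contrast
    chi = np.pi * lam * dz * q**2 - 0.5 * np.pi * cs * lam**3 * q**4
    return np.abs(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def exposure_filter_1d(exposure: float, q):
    """Dose-dependent amplitude attenuation exp(-N / (2 Nc(q))).

    Nc(q) = 0.245 q^-1.665 + 2.81 is the empirical critical exposure curve
    (q in 1/Angstrom, exposure N in e-/A^2).  At q = 0 the filter is 1.
    """
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    q = np.asarray(q, dtype=float)
    out = np.ones_like(q)
    pos = q > 0
    nc = 0.245 * np.power(q[pos], -1.665) + 2.81
    out[pos] = np.exp(-exposure / (2.0 * nc))
    return out


def local_defocus(particle_pos, tilt: TiltEntry, wl: WedgeList) -> float:
    """Per-particle defocus (um) in the tilt image at angle alpha.

    The global defocus is referenced to the specimen's center of mass; a
    particle's offset along the beam direction at tilt alpha adds
    ``height * pixel_size * 1e-4`` um, with
    ``height = (z - z_cm) cos(alpha) - (x - x_c) sin(alpha)`` (tilt axis = y).
    Particles farther from the beam source are more underfocused.
    """
    x, _, z = particle_pos
    a = np.deg2rad(tilt.tilt_angle)
    height = (z - wl.z_center_of_mass) * np.cos(a) - (x - wl.tomo_center[0]) * np.sin(a)
    return tilt.defocus_global + height * wl.pixel_size * 1e-4


def _freq_grids(shape):
    """Fourier coordinates in voxel units, unshifted layout, axes (x, y, z)."""
    kx = sfft.fftfreq(shape[0]) * shape[0]
    ky = sfft.fftfreq(shape[1]) * shape[1]
    kz = sfft.fftfreq(shape[2]) * shape[2]
    return np.meshgrid(kx, ky, kz, indexing="ij", sparse=True)


def _as_shape(boxsize) -> tuple[int, int, int]:
    if np.isscalar(boxsize):
        return (int(boxsize),) * 3
    return tuple(int(b) for b in boxsize)


def hermitian_symmetrize(values: np.ndarray, binary: bool = False) -> np.ndarray:
    """Enforce F(k) = F(-k) on the discrete grid.

    Away from the Nyquist planes the slice/radial constructions are already
    symmetric; on the Nyquist planes +n/2 and -n/2 alias onto one index, so
    conjugate frequency pairs can receive different per-tilt modulations.
    Binary masks take the union, amplitude filters the mean, of each pair.
    """
    flip = [(-np.arange(n)) % n for n in values.shape]
    flipped = values[np.ix_(*flip)]
    if binary:
        return np.maximum(values, flipped)
    return 0.5 * (values + flipped)


def binary_slice_wedge(tilt_angles, boxsize) -> WedgeFilter:
    """Union of central Fourier slices, one per tilt image.

    Each slice is a 1-Fourier-voxel-thick plane through the origin normal to
    the beam direction at that tilt (nearest-voxel rasterization).
    """
    tilt_angles = np.atleast_1d(np.asarray(tilt_angles, dtype=float))
    if tilt_angles.size == 0:
        raise ValueError("empty tilt list")
    shape = _as_shape(boxsize)
    kx, ky, kz = _freq_grids(shape)
    out = np.zeros(shape, dtype=np.float32)
    for a in np.deg2rad(tilt_angles):
        t = kx * np.sin(a) + kz * np.cos(a)  # distance along the beam normal
        out[np.broadcast_to(np.abs(t) < 0.5, shape)] = 1.0
    return WedgeFilter(hermitian_symmetrize(out, binary=True), kind="binary")


def _ctf_amplitude_vox(r_vox, dq_vox, defocus_um, wl: WedgeList, antialias=True):
    """|CTF| at voxel radius ``r_vox`` (dq_vox = 1/A per Fourier voxel)."""
    r_vox = np.asarray(r_vox, dtype=float)
    if not antialias:
        return ctf_1d(defocus_um, r_vox * dq_vox, wl)
    acc = np.zeros_like(r_vox)
    for off in (-0.375, -0.125, 0.125, 0.375):
        acc += ctf_1d(defocus_um, np.maximum(r_vox + off, 0.0) * dq_vox, wl)
    return acc / 4.0


def amplitude_wedge(
    particle_pos,
    wl: WedgeList,
    boxsize,
    use_ctf: bool = True,
    use_exposure: bool = True,
    antialias: bool = True,
) -> WedgeFilter:
    """Amplitude-modulated missing-wedge filter for one particle (or, with
    ``particle_pos`` at the center of mass, the global template-matching
    filter).

    Each tilt's Fourier slice is modulated radially by |CTF| at the
    particle's local defocus and by the exposure filter at that tilt's
    accumulated exposure; overlapping voxels take the per-voxel maximum.
    With both flags off this reduces exactly to :func:`binary_slice_wedge`.
    """
    shape = _as_shape(boxsize)
    if not (use_ctf or use_exposure):
        return binary_slice_wedge(wl.tilt_angles, shape)
    kx, ky, kz = _freq_grids(shape)
    rad_vox = np.sqrt(kx**2 + ky**2 + kz**2)
    dq_vox = 1.0 / (shape[0] * wl.pixel_size)  # 1/A per Fourier voxel (cubic use)
    out = np.zeros(shape, dtype=np.float32)
    for tilt in wl.tilts:
        a = np.deg2rad(tilt.tilt_angle)
        t = kx * np.sin(a) + kz * np.cos(a)
        sel = np.broadcast_to(np.abs(t) < 0.5, shape)
        mod = np.ones(shape, dtype=np.float64)
        if use_ctf:
            dz = local_defocus(particle_pos, tilt, wl)
            mod *= _ctf_amplitude_vox(rad_vox, dq_vox, dz, wl, antialias=antialias)
        if use_exposure:
            mod *= exposure_filter_1d(tilt.exposure_pre, rad_vox * dq_vox)
        np.maximum(out, np.where(sel, mod, 0.0).astype(np.float32), out=out)
    out = hermitian_symmetrize(np.clip(out, 0.0, 1.0))
    return WedgeFilter(out.astype(np.float32), kind="amplitude_modulated")


def radial_bandpass(shape, lp_radius, lp_sigma, hp_radius, hp_sigma, ref_box=None):
    """Radially symmetric band-pass on an arbitrary (possibly non-cubic) grid.

    Radii are in Fourier pixels of a box of edge ``ref_box`` (defaults to the
    first axis), so the same physical band can be built on any grid shape.
    """
    shape = _as_shape(shape)
    ref = ref_box if ref_box is not None else shape[0]
    kx, ky, kz = _freq_grids(shape)
    # normalized frequency (cycles/voxel) scaled to Fourier pixels of ref box
    r = np.sqrt((kx / shape[0]) ** 2 + (ky / shape[1]) ** 2 + (kz / shape[2]) ** 2) * ref
    out = np.ones(shape, dtype=np.float64)
    if lp_radius and lp_radius > 0:
        above = r > lp_radius
        if lp_sigma and lp_sigma > 0:
            out[above] = np.exp(-((r[above] - lp_radius) ** 2) / (2.0 * lp_sigma**2))
        else:
            out[above] = 0.0
    if hp_radius and hp_radius > 0:
        below = r < hp_radius
        if hp_sigma and hp_sigma > 0:
            out[below] = np.exp(-((hp_radius - r[below]) ** 2) / (2.0 * hp_sigma**2))
        else:
            out[below] = 0.0
    return WedgeFilter(out.astype(np.float32), kind="amplitude_modulated")


def bandpass_filter(boxsize, lp_radius, lp_sigma=3.0, hp_radius=0.0, hp_sigma=2.0) -> WedgeFilter:
    """Band-pass filter on a cubic box: 1 inside [hp_radius, lp_radius] with
    Gaussian rolloffs of the stated widths outside; ``hp_radius = 0`` disables
    the high-pass."""
    if lp_radius <= 0:
        raise ValueError("lp_radius must be positive")
    if hp_radius and lp_radius <= hp_radius:
        raise ValueError(f"low-pass radius {lp_radius} must exceed high-pass radius {hp_radius}")
    n = int(boxsize) if np.isscalar(boxsize) else int(boxsize[0])
    if lp_radius > n / 2 * np.sqrt(3) + 1:
        raise ValueError(f"lp_radius {lp_radius} is beyond the Fourier grid of box {n}")
    return radial_bandpass(boxsize, lp_radius, lp_sigma, hp_radius, hp_sigma)


def apply_fourier_filter(vol: np.ndarray, filt) -> np.ndarray:
    """Multiply a real volume's Fourier transform by an amplitude filter."""
    values = filt.values if isinstance(filt, WedgeFilter) else filt
    out = sfft.ifftn(sfft.fftn(np.asarray(vol)) * values).real
    return out.astype(vol.dtype) if np.issubdtype(np.asarray(vol).dtype, np.floating) else out


def make_wedge_list(
    tomo_id: int = 1,
    tilt_range: tuple[float, float] = (-60.0, 60.0),
    tilt_step: float = 3.0,
    defocus: float = 3.0,
    dose_per_tilt: float = 3.0,
    pixel_size: float = 2.0,
    voltage: float = 300.0,
    cs: float = 2.7,
    amplitude_contrast: float = 0.07,
    tomo_center=(0.0, 0.0, 0.0),
    z_center_of_mass: float = 0.0,
    dose_symmetric: bool = True,
) -> WedgeList:
    """Convenience constructor for a typical acquisition.

    With ``dose_symmetric`` the exposure accumulates in a 0, +s, -s, +2s, ...
    acquisition order (low tilts receive the least damage), which is the
    common modern collection scheme.
    """
    angles = np.arange(tilt_range[0], tilt_range[1] + 0.5 * tilt_step, tilt_step)
    if dose_symmetric:
        acq_rank = np.empty(len(angles), dtype=int)
        acq_rank[np.lexsort((np.sign(angles) < 0, np.abs(angles)))] = np.arange(len(angles))
    else:
        acq_rank = np.arange(len(angles))
    tilts = [
        TiltEntry(float(a), defocus, float(acq_rank[i]) * dose_per_tilt)
        for i, a in enumerate(angles)
    ]
    return WedgeList(
        tomo_id=tomo_id,
        tilts=tilts,
        pixel_size=pixel_size,
        voltage=voltage,
        cs=cs,
        amplitude_contrast=amplitude_contrast,
        tomo_center=tuple(tomo_center),
        z_center_of_mass=z_center_of_mass,
    )
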