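"""Constrained cross-correlation via the fast local correlation function.

The FLCF computes, at every translational offset, the Pearson correlation
between a reference (under a mask) and the local content of a search volume,
using FFT convolutions for the local means and variances.  Correlations use
circular boundary conditions; callers avoid wrap-around either by tiling
with padding (template matching) or by masks well inside the box
(subtomogram alignment).

The reference is expected to be filtered with the amplitude-modulated
missing-wedge filter and the search volume with the binary slice wedge
before correlation; that filtering is the caller's job (see
:mod:`subtomo.template_matching` and :mod:`subtomo.align_avg`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

__all__ = [
    "CCCMap",
    "SearchSpectra",
    "flcf",
    "phase_randomize",
    "peak_find",
    "spherical_mask",
    "precompute_search",
    "local_denominator",
    "normalize_reference",
]

# relative threshold below which local variance is treated as zero
_VAR_EPS = 1e-12


@dataclass
class CCCMap:
    """Correlation scores with the zero-offset at the volume center voxel."""

    values: np.ndarray

    @property
    def center(self) -> np.ndarray:
        return np.array([n // 2 for n in self.values.shape])

    @property
    def peak_value(self) -> float:
        return float(self.values.max())

    @property
    def peak_offset(self) -> np.ndarray:
        score, offset = peak_find(self)
        return offset


def spherical_mask(boxsize: int, radius: float, sigma: float = 0.0) -> np.ndarray:
    """Sphere of the given radius about the center voxel; optional Gaussian
    soft edge of width ``sigma`` outside the radius."""
    n = int(boxsize)
    c = n // 2
    ax = np.arange(n) - c
    r = np.sqrt(sum(g**2 for g in np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)))
    if sigma > 0:
        out = np.where(r <= radius, 1.0, np.exp(-((r - radius) ** 2) / (2 * sigma**2)))
        out[out < 1e-3] = 0.0
        return out
    return (r <= radius).astype(np.float64)


@dataclass
class SearchSpectra:
    """Cached FFTs of a search volume (and its square) for repeated FLCF."""

    fs: np.ndarray  # rfftn(search)
    fs2: np.ndarray  # rfftn(search**2)
    shape: tuple


def precompute_search(search: np.ndarray) -> SearchSpectra:
    search = np.asarray(search)
    return SearchSpectra(sfft.rfftn(search), sfft.rfftn(search * search), search.shape)


def _corr(f_kernel, spectra_f, shape):
    """Circular cross-correlation via rFFT; result indexed by offset."""
    return sfft.irfftn(np.conj(f_kernel) * spectra_f, s=shape)


def normalize_reference(reference: np.ndarray, mask: np.ndarray):
    """Masked, zero-mean reference and its power norm under the mask.

    Returns ``(w, norm)`` with ``w = mask*(ref - mu)`` and
    ``norm = sqrt(sum(mask*(ref-mu)^2))``; raises on zero variance.
    """
    reference = np.asarray(reference, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    n_eff = mask.sum()
    if n_eff <= 1:
        raise ValueError("mask must have effective size > 1")
    mu = (mask * reference).sum() / n_eff
    w = mask * (reference - mu)
    norm = np.sqrt((w * (reference - mu)).sum())
    if norm <= 0:
        raise ValueError("reference has zero variance under the mask")
    return w, norm


def local_denominator(spectra: SearchSpectra, mask: np.ndarray) -> np.ndarray:
    """Per-offset masked standard-deviation term of the search volume,
    ``sqrt(sum_m s^2 - (sum_m s)^2 / n_eff)``, with non-positive variance
    clamped to 0.  Depends only on the mask, so it can be reused across
    orientations when the mask is rotationally symmetric."""
    mask = np.asarray(mask, dtype=np.float64)
    n_eff = mask.sum()
    fm = sfft.rfftn(mask)
    local_sum = _corr(fm, spectra.fs, spectra.shape)
    local_sum2 = _corr(fm, spectra.fs2, spectra.shape)
    var = local_sum2 - local_sum * local_sum / n_eff
    np.clip(var, 0.0, None, out=var)
    var[var < _VAR_EPS * max(var.max(), 1e-300)] = 0.0
    return np.sqrt(var)


def flcf(
    search: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    spectra: SearchSpectra | None = None,
    denom: np.ndarray | None = None,
) -> CCCMap:
    """Fast local correlation function of ``reference`` against ``search``.

    At every offset the map holds the Pearson correlation between the masked
    reference and the search content under the translated mask.  ``spectra``
    and ``denom`` allow reuse of the search-volume FFTs and of the local
    standard-deviation term across orientations.
    """
    search = np.asarray(search, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(reference)
    if reference.shape != search.shape:
        raise ValueError("search and reference must have the same shape")
    if spectra is None:
        spectra = precompute_search(search)
    if denom is None:
        denom = local_denominator(spectra, mask)
    w, ref_norm = normalize_reference(reference, mask)
    num = _corr(sfft.rfftn(w), spectra.fs, spectra.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / (ref_norm * denom)
    values[denom == 0.0] = 0.0
    return CCCMap(sfft.fftshift(values))


def peak_find(ccc: CCCMap | np.ndarray, cc_mask: np.ndarray | None = None):
    """Highest score and its offset from the map center.

    Ties are broken by the smallest offset norm, then lexicographically.
    ``cc_mask`` (same shape, centered) restricts the allowed offsets.
    """
    values = ccc.values if isinstance(ccc, CCCMap) else np.asarray(ccc)
    center = np.array([n // 2 for n in values.shape])
    if cc_mask is not None:
        allowed = np.asarray(cc_mask) > 0
        if not allowed.any():
            raise ValueError("cross-correlation mask excludes every offset")
        masked = np.where(allowed, values, -np.inf)
    else:
        masked = values
    vmax = masked.max()
    cand = np.argwhere(masked == vmax)
    offs = cand - center
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], (offs**2).sum(axis=1)))
    best = offs[order[0]]
    return float(vmax), best


def parabolic_refine(values: np.ndarray, peak_index) -> np.ndarray:
    """Optional 3-point parabolic sub-voxel refinement of a peak, per axis."""
    p = np.asarray(peak_index)
    sub = np.zeros(3)
    for ax in range(3):
        lo = p.copy(); lo[ax] -= 1
        hi = p.copy(); hi[ax] += 1
        if lo[ax] < 0 or hi[ax] >= values.shape[ax]:
            continue
        y0, y1, y2 = values[tuple(lo)], values[tuple(p)], values[tuple(hi)]
        d = y0 - 2 * y1 + y2
        if d < 0:
            sub[ax] = 0.5 * (y0 - y2) / d
    return sub


def phase_randomize(vol: np.ndarray, seed: int) -> np.ndarray:
    """Replace Fourier phases by random ones, preserving all amplitudes.

    Random phases come from the Fourier transform of white Gaussian noise,
    which guarantees exact Hermitian symmetry (hence a real output) while
    being uniformly distributed on the non-degenerate frequencies.
    """
    vol = np.asarray(vol, dtype=np.float64)
    rng = np.random.default_rng(seed)
    f = sfft.fftn(vol)
    g = sfft.fftn(rng.standard_normal(vol.shape))
    mag = np.abs(g)
    phases = np.where(mag > 0, g / np.where(mag > 0, mag, 1.0), 1.0)
    return sfft.ifftn(np.abs(f) * phases).real
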