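"""Euler-angle conventions, rotations and orientation search lists.

Orientations are parameterized by intrinsic ZXZ Euler triplets
``(phi, theta, psi)`` in degrees, the convention of the TOM/AV3 lineage of
subtomogram-averaging packages.  The rotation matrix that carries a template
from its reference frame into the tomogram frame is::

    R(phi, theta, psi) = Rz(psi) @ Rx(theta) @ Rz(phi)

i.e. ``phi`` is applied first (a spin of the template about its own z axis,
the "in-plane" rotation), ``theta`` tips the axis, and ``psi`` sets the
azimuth of the tipped axis.  The template viewing axis ``R @ ez`` therefore
depends only on ``(theta, psi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AngleList",
    "SymmetryGroup",
    "euler_to_matrix",
    "matrix_to_euler",
    "invert_euler",
    "compose_euler",
    "rotation_distance",
    "angular_axis_distance",
    "normalize_euler",
    "generate_global_angle_list",
    "generate_local_angle_list",
    "rotate_volume",
    "apply_symmetry",
]


def _rz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix for an intrinsic ZXZ triplet ``(phi, theta, psi)``."""
    phi, theta, psi = angles
    return _rz(psi) @ _rx(theta) @ _rz(phi)


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; theta in [0, 180], phi/psi in [0, 360)."""
    R = np.asarray(R, dtype=float)
    ct = np.clip(R[2, 2], -1.0, 1.0)
    theta = np.degrees(np.arccos(ct))
    if abs(ct) > 1.0 - 1e-12:
        # gimbal lock: only phi+psi (ct=+1) or psi-phi (ct=-1) is determined
        if ct > 0:
            # R = Rz(phi + psi); fold everything into phi
            phi = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
            psi = 0.0
        else:
            # R = Rz(psi) Rx(180) Rz(phi) has R[1,0] = sin(psi-phi)
            phi = -np.degrees(np.arctan2(R[1, 0], R[0, 0]))
            psi = 0.0
            theta = 180.0
    else:
        psi = np.degrees(np.arctan2(R[0, 2], -R[1, 2]))
        phi = np.degrees(np.arctan2(R[2, 0], R[2, 1]))
    return (phi % 360.0, theta, psi % 360.0)


def normalize_euler(angles) -> tuple[float, float, float]:
    """Canonical form: theta in [0, 180], phi/psi in [0, 360)."""
    return matrix_to_euler(euler_to_matrix(angles))


def invert_euler(angles) -> tuple[float, float, float]:
    """Triplet of the inverse rotation: ``(-psi, -theta, -phi)`` normalized."""
    phi, theta, psi = angles
    return normalize_euler((-psi, -theta, -phi))


def compose_euler(first, second) -> tuple[float, float, float]:
    """Triplet of applying ``first`` then ``second`` (R = R2 @ R1)."""
    return matrix_to_euler(euler_to_matrix(second) @ euler_to_matrix(first))


def rotation_distance(a, b) -> float:
    """Geodesic angle in degrees between two rotations (triplets or matrices)."""
    Ra = euler_to_matrix(a) if np.shape(a) == (3,) else np.asarray(a)
    Rb = euler_to_matrix(b) if np.shape(b) == (3,) else np.asarray(b)
    tr = np.trace(Ra @ Rb.T)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def angular_axis_distance(a, b) -> float:
    """Angle in degrees between the viewing axes (R @ ez) of two orientations."""
    za = euler_to_matrix(a)[:, 2]
    zb = euler_to_matrix(b)[:, 2]
    return float(np.degrees(np.arccos(np.clip(za @ zb, -1.0, 1.0))))


@dataclass
class AngleList:
    """Ordered set of Euler triplets defining an orientation search.

    ``angles`` is an (N, 3) float array of (phi, theta, psi) in degrees.
    """

    angles: np.ndarray
    kind: str = "global"  # "global" | "local"
    cone_step: float = 0.0
    inplane_step: float = 0.0
    cone_iter: int = 0
    inplane_iter: int = 0
    center: tuple[float, float, float] | None = None

    def __len__(self) -> int:
        return len(self.angles)

    def __getitem__(self, i):
        return tuple(self.angles[i])

    def matrices(self) -> np.ndarray:
        return np.stack([euler_to_matrix(a) for a in self.angles])

    def to_text(self, path) -> None:
        """Write as a plain-text table: index phi theta psi."""
        with open(path, "w") as fh:
            fh.write("# index phi theta psi\n")
            for i, (p, t, s) in enumerate(self.angles):
                fh.write(f"{i} {p:.6f} {t:.6f} {s:.6f}\n")


def _dedupe(triplets: list[tuple[float, float, float]], tol: float = 1e-9):
    """Drop entries whose rotation matrix repeats an earlier one."""
    seen: list[np.ndarray] = []
    kept = []
    for t in triplets:
        R = euler_to_matrix(t)
        dup = any(np.abs(R - S).max() <= tol for S in seen)
        if not dup:
            seen.append(R)
            kept.append(t)
    return kept


def generate_global_angle_list(cone_step: float, inplane_step: float) -> AngleList:
    """Uniform whole-sphere orientation list.

    Viewing axes are sampled on rings theta = 0, step, ..., 180 with
    ``ceil(360*sin(theta)/step)`` azimuthal positions per ring (poles counted
    once); every axis is combined with ``360/inplane_step`` in-plane spins.
    At 15 degrees this yields 188 directions x 24 spins = 4512 orientations.
    """
    if not (0 < cone_step <= 180) or not (0 < inplane_step <= 360):
        raise ValueError("angular steps must lie in (0, 180] / (0, 360]")
    n_inplane = 360.0 / inplane_step
    if abs(n_inplane - round(n_inplane)) > 1e-9:
        raise ValueError(
            f"in-plane step {inplane_step} does not divide 360; "
            "orientation count must be integral"
        )
    n_inplane = int(round(n_inplane))
    inplane = [k * inplane_step for k in range(n_inplane)]

    thetas = np.arange(0.0, 180.0 + 0.5 * cone_step, cone_step)
    thetas = thetas[thetas <= 180.0 + 1e-9]
    triplets: list[tuple[float, float, float]] = []
    for theta in thetas:
        n_az = max(1, int(np.ceil(360.0 * np.sin(np.deg2rad(theta)) / cone_step)))
        if theta < 1e-9 or abs(theta - 180.0) < 1e-9:
            n_az = 1  # poles counted once
        for j in range(n_az):
            az = j * 360.0 / n_az
            for phi in inplane:
                triplets.append((phi, float(theta), az))
    triplets = _dedupe(triplets)
    return AngleList(
        np.array(triplets, dtype=float),
        kind="global",
        cone_step=cone_step,
        inplane_step=inplane_step,
    )


def _axis_tilt(rho: float, az: float) -> np.ndarray:
    """Pure tilt of the z axis by rho degrees toward azimuth az (no net spin)."""
    return _rz(az) @ _rx(rho) @ _rz(-az)


def generate_local_angle_list(
    center,
    cone_step: float,
    cone_iter: int,
    inplane_step: float,
    inplane_iter: int,
) -> AngleList:
    """Local search list around ``center``.

    The cone search covers axis tilts up to ``cone_step*cone_iter`` sampled
    at ``cone_step``; in-plane offsets run over ``±inplane_step*inplane_iter``
    at ``inplane_step``.  Entry 0 is the center orientation.  Entries are
    ``R_center @ tilt(rho, az) @ Rz(dphi)`` so the list is equivariant under
    left-composition with a fixed rotation.
    """
    if cone_iter < 0 or inplane_iter < 0:
        raise ValueError("iteration counts must be >= 0")
    Rc = euler_to_matrix(center)

    dphis = [0.0]
    for k in range(1, inplane_iter + 1):
        dphis += [-k * inplane_step, k * inplane_step]

    tilts: list[np.ndarray] = []
    for i in range(cone_iter + 1):
        rho = i * cone_step
        if rho == 0.0:
            tilts.append(np.eye(3))
            continue
        n_az = max(1, int(np.ceil(360.0 * np.sin(np.deg2rad(min(rho, 90.0))) / cone_step)))
        for j in range(n_az):
            tilts.append(_axis_tilt(rho, j * 360.0 / n_az))

    triplets = []
    for T in tilts:
        for dphi in dphis:
            triplets.append(matrix_to_euler(Rc @ T @ _rz(dphi)))
    triplets = _dedupe(triplets)
    return AngleList(
        np.array(triplets, dtype=float),
        kind="local",
        cone_step=cone_step,
        inplane_step=inplane_step,
        cone_iter=cone_iter,
        inplane_iter=inplane_iter,
        center=tuple(float(x) for x in center),
    )


def volume_center(n: int) -> int:
    """Rotation/shift center voxel: index floor(n/2), matching the FFT origin."""
    return n // 2


def rotate_volume(vol: np.ndarray, angles, order: int = 1, cval=None) -> np.ndarray:
    """Rotate a cubic volume about its center voxel by a ZXZ triplet.

    Trilinear interpolation by default; out-of-bounds voxels are filled with
    the volume mean (``cval`` overrides).  Axes are indexed (x, y, z).
    """
    vol = np.asarray(vol)
    if vol.ndim != 3 or len(set(vol.shape)) != 1:
        raise ValueError(f"volume must be cubic, got shape {vol.shape}")
    if tuple(np.asarray(angles)) == (0.0, 0.0, 0.0):
        return vol.copy()
    n = vol.shape[0]
    c = np.array([volume_center(n)] * 3, dtype=float)
    R = euler_to_matrix(angles)
    # output(x) = input(R^T (x - c) + c); ndimage maps output coords -> input
    M = R.T.copy()
    # snap elements that are 0/+-1 up to rounding: keeps axis-aligned
    # rotations exact grid permutations (coordinates like 23.0000000000004
    # would otherwise fall outside the last voxel and be filled)
    M[np.abs(M) < 1e-12] = 0.0
    M[np.abs(M - 1.0) < 1e-12] = 1.0
    M[np.abs(M + 1.0) < 1e-12] = -1.0
    offset = c - M @ c
    fill = float(vol.mean()) if cval is None else float(cval)
    return ndimage.affine_transform(
        vol, M, offset=offset, order=order, mode="constant", cval=fill,
        prefilter=(order > 1),
    )


@dataclass
class SymmetryGroup:
    """Cyclic point group Cn with the symmetry axis along volume z."""

    symbol: str = "C1"
    operators: list = field(default_factory=list)

    def __post_init__(self):
        s = self.symbol.strip().upper()
        if not s.startswith("C"):
            raise ValueError(f"only Cn symmetry supported, got {self.symbol!r}")
        n = int(s[1:])
        if n < 1:
            raise ValueError("Cn requires n >= 1")
        self.symbol = f"C{n}"
        self.order = n
        if not self.operators:
            self.operators = [
                normalize_euler((k * 360.0 / n, 0.0, 0.0)) for k in range(n)
            ]

    @property
    def n(self) -> int:
        return self.order

    @property
    def inplane_range(self) -> float:
        """In-plane search range needed under this symmetry (360/n degrees)."""
        return 360.0 / self.order


def apply_symmetry(vol: np.ndarray, sym: SymmetryGroup | str) -> np.ndarray:
    """Mean of the volume over all Cn rotations about the z axis.

    Out-of-bounds voxels are filled with zero: symmetrization targets
    compact densities, where the box edge carries no signal.
    """
    if isinstance(sym, str):
        sym = SymmetryGroup(sym)
    if sym.n == 1:
        return np.asarray(vol).copy()
    acc = np.zeros_like(np.asarray(vol, dtype=float))
    for op in sym.operators:
        acc += rotate_volume(vol, op, cval=0.0)
    return acc / sym.n
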