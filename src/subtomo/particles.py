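"""Motive lists and subtomogram extraction.

The motive list is the central alignment state: one row per particle with
its position, sub-voxel shift, ZXZ Euler triplet, correlation score, class
and halfset.  On disk, positions are 1-based voxel centers (MATLAB-lineage
compatibility); in memory everything is 0-based.  The absolute particle
coordinate is always ``pos + shift``; extraction re-centers ``pos`` on the
nearest voxel and keeps the sub-voxel remainder in ``shift``.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stario

__all__ = [
    "MOTL_COLUMNS",
    "MotiveList",
    "read_motivelist",
    "write_motivelist",
    "extract_subtomograms",
    "rescale_motivelist",
    "clean_motivelist",
    "assign_halfsets",
]

MOTL_COLUMNS = [
    "motl_idx",
    "tomo_num",
    "object",
    "subtomo_num",
    "halfset",
    "orig_x",
    "orig_y",
    "orig_z",
    "shift_x",
    "shift_y",
    "shift_z",
    "phi",
    "theta",
    "psi",
    "score",
    "class",
]

_POS = ["orig_x", "orig_y", "orig_z"]
_SHIFT = ["shift_x", "shift_y", "shift_z"]
_ANGLES = ["phi", "theta", "psi"]


@dataclass
class MotiveList:
    """Ordered collection of per-particle alignment records."""

    rows: pd.DataFrame
    binning: int = 1

    def __post_init__(self):
        missing = [c for c in MOTL_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"motive list is missing mandatory columns: {missing}")
        sn = self.rows["subtomo_num"]
        if sn.duplicated().any():
            dupes = sorted(sn[sn.duplicated()].unique().tolist())
            raise ValueError(f"duplicate subtomo_num values: {dupes}")
        self.rows = self.rows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def copy(self) -> "MotiveList":
        return MotiveList(self.rows.copy(), self.binning)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) integer-voxel positions (0-based)."""
        return self.rows[_POS].to_numpy(dtype=float)

    @property
    def shifts(self) -> np.ndarray:
        return self.rows[_SHIFT].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        """Absolute particle coordinates pos + shift."""
        return self.positions + self.shifts

    @property
    def angles(self) -> np.ndarray:
        return self.rows[_ANGLES].to_numpy(dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return self.rows["score"].to_numpy(dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return self.rows["class"].to_numpy(dtype=int)

    def halfset_indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.rows["halfset"].to_numpy() == which)


def empty_motivelist(binning: int = 1) -> MotiveList:
    return MotiveList(pd.DataFrame(columns=MOTL_COLUMNS), binning)


def new_motivelist(
    coords,
    angles=None,
    scores=None,
    classes=None,
    tomo_num: int = 1,
    binning: int = 1,
) -> MotiveList:
    """Build a motive list from raw arrays; shifts start at the sub-voxel
    remainder of the coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    pos = np.round(coords)
    table = pd.DataFrame(
        {
            "motl_idx": np.arange(1, n + 1),
            "tomo_num": tomo_num,
            "object": 1,
            "subtomo_num": np.arange(1, n + 1),
            "halfset": "",
            "orig_x": pos[:, 0],
            "orig_y": pos[:, 1],
            "orig_z": pos[:, 2],
            "shift_x": coords[:, 0] - pos[:, 0],
            "shift_y": coords[:, 1] - pos[:, 1],
            "shift_z": coords[:, 2] - pos[:, 2],
            "phi": 0.0,
            "theta": 0.0,
            "psi": 0.0,
            "score": 0.0,
            "class": 1,
        }
    )
    if angles is not None:
        table[_ANGLES] = np.atleast_2d(np.asarray(angles, dtype=float))
    if scores is not None:
        table["score"] = np.asarray(scores, dtype=float)
    if classes is not None:
        table["class"] = np.asarray(classes, dtype=int)
    return MotiveList(table, binning)


def write_motivelist(path, mlist: MotiveList) -> None:
    table = mlist.rows.copy()
    table[_POS] = table[_POS] + 1.0  # file positions are 1-based voxel centers
    table["halfset"] = table["halfset"].replace("", ".")
    stario.write_star(path, "motl", table, header={"binning": mlist.binning})


def read_motivelist(path) -> MotiveList:
    table, header = stario.read_star(path, "motl")
    if len(table) == 0:
        return empty_motivelist(binning=int(header.get("binning", 1)))
    missing = [c for c in MOTL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"motive list file is missing columns: {missing}")
    table[_POS] = table[_POS].astype(float) - 1.0
    table["halfset"] = table["halfset"].astype(str).replace(".", "")
    return MotiveList(table, binning=int(header.get("binning", 1)))


def extract_subtomograms(
    tomo: np.ndarray,
    mlist: MotiveList,
    boxsize: int,
    dtype_bits: int = 32,
):
    """Crop subtomograms centered on round(pos + shift).

    Returns ``(volumes, new_list)``.  The residual sub-voxel shift is stored
    back into each row and ``pos`` is updated to the rounded center, so
    ``pos + shift`` is conserved.  Out-of-bounds voxels are filled with the
    tomogram mean; rows whose center lies outside the tomogram are skipped
    with a warning.  8/16-bit extraction linearly rescales each subtomogram
    to the integer range and back (the quantization the file format would
    apply).
    """
    if boxsize % 2:
        raise ValueError("boxsize must be even")
    if dtype_bits not in (8, 16, 32):
        raise ValueError("dtype_bits must be 8, 16 or 32")
    tomo = np.asarray(tomo)
    half = boxsize // 2
    fill = float(tomo.mean())
    vols = []
    keep = []
    new_rows = mlist.rows.copy()
    for i, row in mlist.rows.iterrows():
        coord = np.array([row[c] for c in _POS]) + np.array([row[c] for c in _SHIFT])
        center = np.round(coord).astype(int)
        if np.any(center < 0) or np.any(center >= tomo.shape):
            warnings.warn(
                f"subtomo_num {int(row['subtomo_num'])}: center {center.tolist()} "
                "outside tomogram; skipped"
            )
            continue
        lo = center - half
        hi = center + half
        if np.any(lo < 0) or np.any(hi > np.array(tomo.shape)):
            warnings.warn(
                f"subtomo_num {int(row['subtomo_num'])}: box clipped at the "
                "tomogram edge; padded with the tomogram mean"
            )
        box = np.full((boxsize,) * 3, fill, dtype=np.float64)
        src = [slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, tomo.shape)]
        dst = [slice(s.start - l, s.stop - l) for s, l in zip(src, lo)]
        box[tuple(dst)] = tomo[tuple(src)]
        if dtype_bits != 32:
            box = _requantize(box, dtype_bits)
        vols.append(box)
        keep.append(i)
        new_rows.loc[i, _POS] = center.astype(float)
        new_rows.loc[i, _SHIFT] = coord - center
    new_list = MotiveList(new_rows.loc[keep].reset_index(drop=True), mlist.binning)
    return vols, new_list


def _requantize(box: np.ndarray, bits: int) -> np.ndarray:
    """Round-trip through the integer range of the target bit depth."""
    info = np.iinfo(np.int8 if bits == 8 else np.int16)
    lo, hi = box.min(), box.max()
    if hi <= lo:
        return box
    scale = (info.max - info.min) / (hi - lo)
    q = np.round((box - lo) * scale)
    return q / scale + lo


def rescale_motivelist(mlist: MotiveList, new_binning: int) -> MotiveList:
    """Change the binning level: coordinates scale by old/new; angles, score,
    class and halfset carry over; shifts are re-split into an integer
    position and a sub-voxel remainder."""
    for b in (mlist.binning, new_binning):
        if b < 1 or (b & (b - 1)):
            raise ValueError(f"binning must be a power of 2, got {b}")
    ratio = mlist.binning / new_binning
    coords = mlist.coords * ratio
    pos = np.round(coords)
    rows = mlist.rows.copy()
    rows[_POS] = pos
    rows[_SHIFT] = coords - pos
    return MotiveList(rows, new_binning)


def clean_motivelist(
    mlist: MotiveList,
    score_cut: float | None = None,
    min_dist: float | None = None,
) -> MotiveList:
    """Score thresholding followed by greedy distance exclusion.

    Rows below ``score_cut`` are dropped; then, scanning in descending
    score order, any row closer than ``min_dist`` (center-to-center on
    pos + shift) to an already-kept row is removed.
    """
    rows = mlist.rows
    if score_cut is not None:
        rows = rows[rows["score"] >= score_cut]
    if min_dist is not None and len(rows) > 1:
        coords = (rows[_POS].to_numpy(float) + rows[_SHIFT].to_numpy(float))
        order = np.argsort(-rows["score"].to_numpy(float), kind="stable")
        kept: list[int] = []
        for i in order:
            if all(np.linalg.norm(coords[i] - coords[j]) >= min_dist for j in kept):
                kept.append(i)
        rows = rows.iloc[sorted(kept)]
    return MotiveList(rows.reset_index(drop=True), mlist.binning)


def assign_halfsets(mlist: MotiveList, mode: str = "fixed", seed: int = 0) -> MotiveList:
    """Random A/B split, balanced to within one particle.

    ``fixed`` stratifies by tomogram so each tomogram contributes evenly to
    both halves; ``per_iteration`` is the same draw but callers pass a new
    seed each iteration.
    """
    if mode not in ("fixed", "per_iteration"):
        raise ValueError(f"unknown halfset mode {mode!r}")
    rng = np.random.default_rng(seed)
    rows = mlist.rows.copy()
    labels = np.empty(len(rows), dtype=object)
    # stratified per tomogram, then globally rebalanced to |#A - #B| <= 1
    for _, idx in rows.groupby("tomo_num").groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        half = len(idx) // 2
        labels[idx[perm[:half]]] = "A"
        labels[idx[perm[half:]]] = "B"
    n_a, n_b = (labels == "A").sum(), (labels == "B").sum()
    while abs(n_a - n_b) > 1:
        source = "A" if n_a > n_b else "B"
        target = "B" if source == "A" else "A"
        pool = np.flatnonzero(labels == source)
        labels[rng.choice(pool)] = target
        n_a, n_b = (labels == "A").sum(), (labels == "B").sum()
    rows["halfset"] = labels
    return MotiveList(rows, mlist.binning)
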