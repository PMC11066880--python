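"""STAR-table I/O for motive lists and wedge lists (backed by gemmi.cif).

Tables are stored as a single loop block per file; scalar metadata (e.g.
microscope constants of a wedge list) are key-value pairs in the same
block.  Tags follow the ``_<block>_<column>`` convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from gemmi import cif

__all__ = ["write_star", "read_star", "write_wedge_list", "read_wedge_list"]


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6f}"
    if isinstance(value, str):
        return value if value else "."
    return str(value)


def write_star(path, name: str, table: pd.DataFrame, header: dict | None = None) -> None:
    """Write a DataFrame as a STAR loop in block ``name``.

    ``header`` entries become key-value pairs (``_<name>_<key>  value``)
    preceding the loop.
    """
    doc = cif.Document()
    block = doc.add_new_block(name)
    for key, value in (header or {}).items():
        block.set_pair(f"_{name}_{key}", _fmt(value))
    loop = block.init_loop(f"_{name}_", [str(c) for c in table.columns])
    for row in table.itertuples(index=False):
        loop.add_row([_fmt(v) for v in row])
    doc.write_file(str(path))


def read_star(path, name: str | None = None):
    """Read a STAR file; returns ``(table, header)``.

    All loop columns are returned as a DataFrame (numeric where possible);
    non-loop pairs in the block are returned as the header dict.
    """
    doc = cif.read_file(str(path))
    block = doc[0] if name is None else doc.find_block(name)
    if block is None:
        raise ValueError(f"no block {name!r} in {path}")
    prefix = f"_{block.name}_"
    header: dict = {}
    columns: list[str] = []
    loop = None
    for item in block:
        if item.loop is not None:
            loop = item.loop
            columns = [t[len(prefix):] if t.startswith(prefix) else t for t in loop.tags]
        elif item.pair is not None:
            key, value = item.pair
            key = key[len(prefix):] if key.startswith(prefix) else key
            header[key] = _parse_scalar(value)
    if loop is None:
        return pd.DataFrame(), header
    ncol = len(loop.tags)
    table = pd.DataFrame(
        np.array(list(loop.values), dtype=object).reshape(loop.length(), ncol),
        columns=columns,
    )
    for col in table.columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        if not converted.isna().any():
            table[col] = converted
        else:
            table[col] = table[col].replace(".", "")
    return table, header


def write_wedge_list(path, wl) -> None:
    """One row per tilt image; microscope constants in the header block."""
    table = pd.DataFrame(
        {
            "tomo_num": [wl.tomo_id] * len(wl.tilts),
            "tilt_angle": [t.tilt_angle for t in wl.tilts],
            "defocus": [t.defocus_global for t in wl.tilts],
            "exposure": [t.exposure_pre for t in wl.tilts],
        }
    )
    header = {
        "pixel_size": wl.pixel_size,
        "voltage": wl.voltage,
        "cs": wl.cs,
        "amplitude_contrast": wl.amplitude_contrast,
        "tomo_center_x": wl.tomo_center[0],
        "tomo_center_y": wl.tomo_center[1],
        "tomo_center_z": wl.tomo_center[2],
        "z_center_of_mass": wl.z_center_of_mass,
    }
    write_star(path, "wedge", table, header)


def read_wedge_list(path):
    from .wedge import TiltEntry, WedgeList

    table, header = read_star(path, "wedge")
    tilts = [
        TiltEntry(float(r.tilt_angle), float(r.defocus), float(r.exposure))
        for r in table.itertuples(index=False)
    ]
    return WedgeList(
        tomo_id=int(table["tomo_num"].iloc[0]),
        tilts=tilts,
        pixel_size=float(header["pixel_size"]),
        voltage=float(header["voltage"]),
        cs=float(header["cs"]),
        amplitude_contrast=float(header["amplitude_contrast"]),
        tomo_center=(
            float(header["tomo_center_x"]),
            float(header["tomo_center_y"]),
            float(header["tomo_center_z"]),
        ),
        z_center_of_mass=float(header["z_center_of_mass"]),
    )


def _parse_scalar(value: str):
    try:
        f = float(value)
        return int(f) if f == int(f) and "." not in value else f
    except ValueError:
        return value
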