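"""Parameter validation, task dispatch and the deterministic parallel contract.

Tasks are described by plain-text ``key=value`` parameter sets (or
equivalent CLI flags).  The "parser" step type-checks every key against the
task's schema, fills documented defaults, and reports *all* problems at
once.  ``run_task`` executes a validated spec; work units (template-matching
tiles, particles) may be processed by any number of workers in any order —
results are merged by unit index, so the output is bit-identical for any
worker count.  Completed template-matching tiles are checkpointed and a
finished job re-run is a no-op.
"""

from __future__ import annotations

import difflib
import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import align_avg, correlation, geometry, mra, mrc, particles, simulator, stario
from . import template_matching as tm
from . import wedge as wedge_mod

__all__ = ["TaskSpec", "ParameterError", "validate_params", "run_task", "read_param_file"]


class ParameterError(ValueError):
    """Raised with every validation problem collected into one message."""


@dataclass
class TaskSpec:
    task: str
    params: dict
    seed: int = 0
    n_workers: int = 1


def _typed(kind, value):
    if kind is bool:
        if isinstance(value, bool):
            return value
        if str(value).lower() in ("1", "true", "yes", "on"):
            return True
        if str(value).lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    return kind(value)


# schema: key -> (type, default_or_REQUIRED, validator or None)
_REQ = object()

def _pos(x):
    return x > 0

def _nonneg(x):
    return x >= 0


_COMMON = {
    "seed": (int, 0, None),
    "n_workers": (int, 1, _pos),
}

_SCHEMAS: dict[str, dict] = {
    "simulate": {
        "boxsize": (int, 32, lambda v: v >= 16),
        "tomo_size": (int, 96, _pos),
        "n_particles": (int, 12, _nonneg),
        "snr": (float, 0.05, _pos),
        "phantom": (str, "blob_cluster", None),
        "min_dist": (float, 0.0, _nonneg),  # 0 -> phantom box
        "tilt_step": (float, 3.0, _pos),
        "tilt_max": (float, 60.0, _pos),
        "defocus": (float, 3.0, None),
        "dose_per_tilt": (float, 3.0, _nonneg),
        "pixel_size": (float, 2.0, _pos),
        "use_ctf": (bool, False, None),
        "use_exposure": (bool, False, None),
        "slab": (bool, False, None),
        "out_tomo": (str, _REQ, None),
        "out_motl": (str, _REQ, None),
        "out_wedge": (str, _REQ, None),
    },
    "tm": {
        "tomogram": (str, _REQ, None),
        "template": (str, _REQ, None),
        "mask": (str, "", None),  # empty -> spherical default
        "wedge": (str, _REQ, None),
        "cone_step": (float, 15.0, _pos),
        "inplane_step": (float, 15.0, _pos),
        "lp_radius": (float, 13.0, _nonneg),
        "lp_sigma": (float, 3.0, _nonneg),
        "hp_radius": (float, 0.0, _nonneg),
        "hp_sigma": (float, 2.0, _nonneg),
        "use_ctf": (bool, True, None),
        "use_exposure": (bool, True, None),
        "use_noise": (bool, True, None),
        "n_tiles": (int, 1, _pos),
        "threshold": (float, 0.1, _nonneg),
        "min_dist": (float, 6.0, lambda v: v >= 1),
        "work_dir": (str, "", None),
        "out_score": (str, _REQ, None),
        "out_orient": (str, _REQ, None),
        "out_motl": (str, _REQ, None),
    },
    "extract": {
        "tomogram": (str, _REQ, None),
        "motl": (str, _REQ, None),
        "boxsize": (int, _REQ, lambda v: v % 2 == 0),
        "dtype": (int, 32, lambda v: v in (8, 16, 32)),
        "pixel_size": (float, 1.0, _pos),
        "out_dir": (str, _REQ, None),
        "out_motl": (str, _REQ, None),
    },
    "ali_singleclass": {
        "motl": (str, _REQ, None),
        "subtomo_dir": (str, _REQ, None),
        "wedge": (str, _REQ, None),
        "reference": (str, _REQ, None),
        "mask": (str, "", None),
        "cone_step": (float, 2.0, _pos),
        "cone_iter": (int, 3, _nonneg),
        "inplane_step": (float, 2.0, _pos),
        "inplane_iter": (int, 3, _nonneg),
        "lp_radius": (float, 0.0, _nonneg),
        "lp_sigma": (float, 3.0, _nonneg),
        "hp_radius": (float, 0.0, _nonneg),
        "hp_sigma": (float, 2.0, _nonneg),
        "cc_mask_radius": (float, 0.0, _nonneg),  # 0 -> unlimited
        "symmetry": (str, "C1", None),
        "iterations": (int, 1, _pos),
        "use_ctf": (bool, True, None),
        "use_exposure": (bool, True, None),
        "out_prefix": (str, _REQ, None),
    },
    "avg": {
        "motl": (str, _REQ, None),
        "subtomo_dir": (str, _REQ, None),
        "wedge": (str, _REQ, None),
        "symmetry": (str, "C1", None),
        "use_ctf": (bool, True, None),
        "use_exposure": (bool, True, None),
        "lp_radius": (float, 0.0, _nonneg),
        "out_prefix": (str, _REQ, None),
    },
    "ali_multiclass": {
        "motl": (str, _REQ, None),
        "subtomo_dir": (str, _REQ, None),
        "wedge": (str, _REQ, None),
        "mask": (str, "", None),
        "n_classes": (int, 10, lambda v: v >= 2),
        "seed_fraction": (float, 0.02, lambda v: 0 < v <= 1),
        "sa_iterations": (int, 10, _nonneg),
        "sa_prob_start": (float, 0.1, lambda v: 0 <= v <= 1),
        "shc_max_iterations": (int, 30, _nonneg),
        "convergence_frac": (float, 0.01, lambda v: 0 <= v <= 1),
        "cone_step": (float, 2.0, _pos),
        "cone_iter": (int, 0, _nonneg),
        "inplane_step": (float, 2.0, _pos),
        "inplane_iter": (int, 0, _nonneg),
        "lp_radius": (float, 0.0, _nonneg),
        "cc_mask_radius": (float, 0.0, _nonneg),
        "use_ctf": (bool, True, None),
        "use_exposure": (bool, True, None),
        "out_prefix": (str, _REQ, None),
    },
}


def read_param_file(path) -> dict:
    """Parse a plain-text ``key=value`` parameter file ('#' comments)."""
    raw = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"malformed line (expected key=value): {line!r}")
        key, value = line.split("=", 1)
        raw[key.strip()] = value.strip()
    return raw


def validate_params(task: str, raw: dict, check_files: bool = True) -> TaskSpec:
    """Type-check and range-check a raw parameter set against the task schema.

    Every problem (unknown keys with suggestions, missing required keys,
    type errors, range violations, cross-parameter conflicts) is collected
    and reported in a single error.
    """
    if task not in _SCHEMAS:
        raise ParameterError(
            f"unknown task {task!r}; available: {', '.join(sorted(_SCHEMAS))}"
        )
    schema = {**_COMMON, **_SCHEMAS[task]}
    errors: list[str] = []
    params: dict = {}
    for key, value in raw.items():
        if key not in schema:
            hint = difflib.get_close_matches(key, schema, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown parameter {key!r}{suffix}")
    for key, (kind, default, check) in schema.items():
        if key in raw:
            try:
                value = _typed(kind, raw[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: cannot convert {raw[key]!r} to {kind.__name__}")
                continue
        elif default is _REQ:
            errors.append(f"missing required parameter {key!r}")
            continue
        else:
            value = default
        if check is not None and not check(value):
            errors.append(f"{key}: value {value!r} out of range")
        params[key] = value

    # cross-parameter conflicts
    if not errors:
        lp = params.get("lp_radius", 0.0)
        hp = params.get("hp_radius", 0.0)
        if lp and hp and hp >= lp:
            errors.append(
                f"hp_radius {hp} must be smaller than lp_radius {lp}"
            )
        if task == "tm" and params["use_noise"] and not params["template"]:
            errors.append("use_noise requires a template")
        if check_files:
            for key, (kind, default, _) in schema.items():
                if kind is str and not key.startswith("out_") and key not in (
                    "phantom", "symmetry", "work_dir", "subtomo_dir", "out_prefix",
                ):
                    path = params.get(key, "")
                    if path and not Path(path).exists():
                        errors.append(f"{key}: file not found: {path}")
    if errors:
        raise ParameterError("; ".join(errors))
    return TaskSpec(
        task=task,
        params=params,
        seed=params.get("seed", 0),
        n_workers=params.get("n_workers", 1),
    )


def parallel_map(fn, units, n_workers: int):
    """Apply ``fn`` to work units, merging results in unit order regardless
    of worker count — the determinism contract every task relies on."""
    if n_workers <= 1:
        return [fn(u) for u in units]
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        return list(pool.map(fn, units))


def run_task(spec: TaskSpec) -> dict:
    """Execute a validated task spec; returns a structured log."""
    t0 = time.time()
    runner = {
        "simulate": _task_simulate,
        "tm": _task_tm,
        "extract": _task_extract,
        "ali_singleclass": _task_ali_singleclass,
        "avg": _task_avg,
        "ali_multiclass": _task_ali_multiclass,
    }[spec.task]
    result = runner(spec)
    log = {
        "task": spec.task,
        "seed": spec.seed,
        "n_workers": spec.n_workers,
        "params": {k: v for k, v in spec.params.items()},
        "elapsed_s": round(time.time() - t0, 3),
        **result,
    }
    return log


# --- task implementations -------------------------------------------------


def _load_mask(path, boxsize):
    if path:
        m, _ = mrc.read_mrc(path)
        return m.astype(float)
    return correlation.spherical_mask(boxsize, boxsize * 0.4, boxsize * 0.08)


def _task_simulate(spec: TaskSpec) -> dict:
    p = spec.params
    wl = wedge_mod.make_wedge_list(
        tilt_range=(-p["tilt_max"], p["tilt_max"]),
        tilt_step=p["tilt_step"],
        defocus=p["defocus"],
        dose_per_tilt=p["dose_per_tilt"],
        pixel_size=p["pixel_size"],
        tomo_center=(p["tomo_size"] / 2,) * 3,
        z_center_of_mass=p["tomo_size"] / 2,
    )
    phantom = simulator.make_phantom(p["phantom"], p["boxsize"], seed=spec.seed)
    gt = simulator.simulate_tomogram(
        phantom,
        p["n_particles"],
        (p["tomo_size"],) * 3,
        wl,
        snr=p["snr"],
        seed=spec.seed,
        min_dist=p["min_dist"] or None,
        use_ctf=p["use_ctf"],
        use_exposure=p["use_exposure"],
        slab=p["slab"],
    )
    mrc.write_mrc(p["out_tomo"], gt.density, voxel_size=p["pixel_size"])
    particles.write_motivelist(p["out_motl"], gt.plants)
    stario.write_wedge_list(p["out_wedge"], wl)
    return {"n_planted": len(gt.plants)}


def _task_tm(spec: TaskSpec) -> dict:
    p = spec.params
    tomo, pixel = mrc.read_mrc(p["tomogram"])
    template, _ = mrc.read_mrc(p["template"])
    template = template.astype(float)
    wl = stario.read_wedge_list(p["wedge"])
    mask = _load_mask(p["mask"], template.shape[0])
    angles = geometry.generate_global_angle_list(p["cone_step"], p["inplane_step"])
    nbox = template.shape[0]

    work_dir = Path(p["work_dir"]) if p["work_dir"] else None
    done_marker = work_dir / "done.json" if work_dir else None
    if done_marker and done_marker.exists():
        return {"status": "already complete", "n_peaks": None}

    # global filtering once, then tile-parallel matching with checkpoints
    amp = wedge_mod.amplitude_wedge(
        wl.tomo_center, wl, nbox, use_ctf=p["use_ctf"], use_exposure=p["use_exposure"]
    )
    bp_small = (
        wedge_mod.bandpass_filter(nbox, p["lp_radius"], p["lp_sigma"], p["hp_radius"], p["hp_sigma"])
        if p["lp_radius"]
        else None
    )
    filt = wedge_mod.binary_slice_wedge(wl.tilt_angles, tomo.shape).values
    if p["lp_radius"]:
        filt = filt * wedge_mod.radial_bandpass(
            tomo.shape, p["lp_radius"], p["lp_sigma"], p["hp_radius"], p["hp_sigma"], ref_box=nbox
        ).values
    from scipy import fft as sfft

    tomo_f = sfft.ifftn(sfft.fftn(tomo.astype(np.float32)) * filt).real.astype(np.float32)
    tiles = tm.make_tiles(tomo.shape, p["n_tiles"], nbox)
    templates = {"score": template.astype(np.float32)}
    if p["use_noise"]:
        templates["noise"] = correlation.phase_randomize(template, spec.seed).astype(np.float32)

    def do_tile(idx_tile):
        idx, tile = idx_tile
        if work_dir:
            cache = work_dir / f"tile_{idx:04d}.npz"
            if cache.exists():
                with np.load(cache) as z:
                    return {k: z[k] for k in z.files}
        out = {}
        for key, tmpl in templates.items():
            sub = tm.match_tile(tomo_f[tile.padded], tmpl, mask, angles, amp, bp_small)
            out[f"{key}_score"] = sub.score[tile.core_in_padded]
            out[f"{key}_orient"] = sub.orientation_index[tile.core_in_padded]
        if work_dir:
            work_dir.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(work_dir / f"tile_{idx:04d}.npz", **out)
        return out

    results = parallel_map(do_tile, list(enumerate(tiles)), spec.n_workers)
    score = np.zeros(tomo.shape, dtype=np.float32)
    orient = np.zeros(tomo.shape, dtype=np.int32)
    noise = np.zeros(tomo.shape, dtype=np.float32) if p["use_noise"] else None
    for tile, res in zip(tiles, results):
        score[tile.core] = res["score_score"]
        orient[tile.core] = res["score_orient"]
        if noise is not None:
            noise[tile.core] = res["noise_score"]
    maps = tm.ScoreMaps(
        score=score, orientation_index=orient, noise_score=noise, angle_list=angles,
        metadata={"noise_seed": spec.seed if p["use_noise"] else None},
    )
    if p["use_noise"]:
        maps = tm.noise_flatten(maps)
    ml = tm.extract_peaks(
        maps, p["threshold"], p["min_dist"], angles, border=nbox // 2
    )
    mrc.write_mrc(p["out_score"], maps.score, voxel_size=pixel)
    mrc.write_mrc(p["out_orient"], maps.orientation_index.astype(np.float32), voxel_size=pixel)
    particles.write_motivelist(p["out_motl"], ml)
    if done_marker:
        done_marker.parent.mkdir(parents=True, exist_ok=True)
        done_marker.write_text(json.dumps({"n_peaks": len(ml)}))
    return {"n_peaks": len(ml)}


def _task_extract(spec: TaskSpec) -> dict:
    p = spec.params
    tomo, _ = mrc.read_mrc(p["tomogram"])
    ml = particles.read_motivelist(p["motl"])
    vols, new_ml = particles.extract_subtomograms(tomo, ml, p["boxsize"], p["dtype"])
    out_dir = Path(p["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = {8: 0, 16: 1, 32: 2}[p["dtype"]]
    for v, num in zip(vols, new_ml.rows["subtomo_num"]):
        mrc.write_mrc(out_dir / f"subtomo_{int(num):06d}.mrc", v, p["pixel_size"], mode=2)
    particles.write_motivelist(p["out_motl"], new_ml)
    return {"n_extracted": len(vols), "mrc_mode": mode}


def _load_particles(spec_params, ml):
    sub_dir = Path(spec_params["subtomo_dir"])
    subtomos = []
    for num in ml.rows["subtomo_num"]:
        v, _ = mrc.read_mrc(sub_dir / f"subtomo_{int(num):06d}.mrc")
        subtomos.append(v.astype(float))
    return subtomos


def _per_particle_wedges(spec_params, ml, wl, boxsize):
    return [
        wedge_mod.amplitude_wedge(
            coord, wl, boxsize,
            use_ctf=spec_params["use_ctf"], use_exposure=spec_params["use_exposure"],
        )
        for coord in ml.coords
    ]


def _task_ali_singleclass(spec: TaskSpec) -> dict:
    p = spec.params
    ml = particles.read_motivelist(p["motl"])
    subtomos = _load_particles(p, ml)
    wl = stario.read_wedge_list(p["wedge"])
    ref, _ = mrc.read_mrc(p["reference"])
    nbox = ref.shape[0]
    mask = _load_mask(p["mask"], nbox)
    wedges = _per_particle_wedges(p, ml, wl, nbox)
    params = align_avg.AlignmentParams(
        cone_step=p["cone_step"], cone_iter=p["cone_iter"],
        inplane_step=p["inplane_step"], inplane_iter=p["inplane_iter"],
        lp_radius=p["lp_radius"], lp_sigma=p["lp_sigma"],
        hp_radius=p["hp_radius"], hp_sigma=p["hp_sigma"],
        cc_mask_radius=p["cc_mask_radius"] or None,
        symmetry=p["symmetry"], iterations=p["iterations"],
    )
    refs = {"A": ref.astype(float), "B": ref.astype(float)}
    bundle = None
    for it in range(p["iterations"]):
        ml, bundle = align_avg.run_alignment_iteration(
            subtomos, ml, wedges, refs, mask, params, iteration=it, seed=spec.seed
        )
        refs = {"A": bundle.halfmap_a, "B": bundle.halfmap_b}
    prefix = p["out_prefix"]
    mrc.write_mrc(f"{prefix}_halfmap_A.mrc", bundle.halfmap_a)
    mrc.write_mrc(f"{prefix}_halfmap_B.mrc", bundle.halfmap_b)
    mrc.write_mrc(f"{prefix}_fom.mrc", bundle.fom_map)
    np.savetxt(f"{prefix}_fsc.txt", np.c_[np.arange(len(bundle.fsc)), bundle.fsc],
               header="shell fsc", fmt="%d %.6f")
    particles.write_motivelist(f"{prefix}_motl.star", ml)
    fsc05 = int(np.argmax(bundle.fsc < 0.5)) if (bundle.fsc < 0.5).any() else len(bundle.fsc)
    return {"n_particles": len(ml), "fsc_0p5_shell": fsc05,
            "mean_score": float(ml.scores.mean())}


def _task_avg(spec: TaskSpec) -> dict:
    p = spec.params
    ml = particles.read_motivelist(p["motl"])
    subtomos = _load_particles(p, ml)
    wl = stario.read_wedge_list(p["wedge"])
    nbox = subtomos[0].shape[0]
    wedges = _per_particle_wedges(p, ml, wl, nbox)
    if (ml.rows["halfset"] == "").any():
        ml = particles.assign_halfsets(ml, seed=spec.seed)
    out = {}
    for hs in ("A", "B"):
        idx = ml.halfset_indices(hs)
        out[hs] = align_avg.average_halfset(
            [subtomos[i] for i in idx], ml.rows.iloc[idx],
            [wedges[i] for i in idx], sym=p["symmetry"],
            lp_radius=p["lp_radius"] or None,
        )
    fsc = align_avg.compute_fsc(out["A"][0], out["B"][0])
    fom = align_avg.fom_weighted_sum(out["A"][0], out["B"][0], fsc)
    prefix = p["out_prefix"]
    mrc.write_mrc(f"{prefix}_halfmap_A.mrc", out["A"][0])
    mrc.write_mrc(f"{prefix}_halfmap_B.mrc", out["B"][0])
    mrc.write_mrc(f"{prefix}_fom.mrc", fom)
    np.savetxt(f"{prefix}_fsc.txt", np.c_[np.arange(len(fsc)), fsc],
               header="shell fsc", fmt="%d %.6f")
    return {"n_particles": len(ml)}


def _task_ali_multiclass(spec: TaskSpec) -> dict:
    p = spec.params
    ml = particles.read_motivelist(p["motl"])
    subtomos = _load_particles(p, ml)
    wl = stario.read_wedge_list(p["wedge"])
    nbox = subtomos[0].shape[0]
    mask = _load_mask(p["mask"], nbox)
    wedges = _per_particle_wedges(p, ml, wl, nbox)
    cfg = mra.MRAConfig(
        n_classes=p["n_classes"], seed_fraction=p["seed_fraction"],
        sa_iterations=p["sa_iterations"], sa_prob_start=p["sa_prob_start"],
        shc_max_iterations=p["shc_max_iterations"],
        convergence_frac=p["convergence_frac"], seed=spec.seed,
    )
    params = align_avg.AlignmentParams(
        cone_step=p["cone_step"], cone_iter=p["cone_iter"],
        inplane_step=p["inplane_step"], inplane_iter=p["inplane_iter"],
        lp_radius=p["lp_radius"], cc_mask_radius=p["cc_mask_radius"] or None,
    )
    state, refs, history = mra.run_mra(subtomos, ml, wedges, mask, cfg, params)
    prefix = p["out_prefix"]
    particles.write_motivelist(f"{prefix}_motl.star", state)
    for cls, ref in refs.items():
        mrc.write_mrc(f"{prefix}_class_{cls:02d}.mrc", ref)
    occupancy = {
        int(cls): int((state.classes == cls).sum()) for cls in sorted(set(state.classes))
    }
    return {
        "n_particles": len(state),
        "converged": history["converged"],
        "n_iterations": len(history["changed_frac"]),
        "occupancy": occupancy,
    }
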