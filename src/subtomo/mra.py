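"""Multi-reference alignment (MRA): stochastic classification of subtomograms.

Classification is a 4D search: the usual three rotational dimensions plus a
class dimension.  To avoid the attractor problem (particles stuck in the
reference they seeded), class references are seeded de novo from random,
non-exclusive subsets of the data, and the per-particle search is
stochastic:

* stochastic hill climbing (SHC) — the prior (orientation, class) is scored
  first as the baseline; the remaining candidates are visited in random
  order and the first one scoring strictly better is accepted immediately;
* simulated annealing (SA) — with a given probability a random candidate is
  accepted regardless of score; the probability anneals linearly to zero.

Repeating MRA gives different but (for stable classes) consistent results;
particles are kept only when a configurable majority of replicates agrees
on their (merged) class — the class-consensus step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.optimize import linear_sum_assignment

from . import correlation as corr
from . import particles, wedge
from .align_avg import AlignmentParams, average_halfset
from .geometry import rotate_volume

__all__ = [
    "MRAConfig",
    "ConsensusTable",
    "seed_denovo_classes",
    "shc_align",
    "sa_align",
    "run_mra",
    "consensus_classes",
    "propose_merges",
]


@dataclass
class MRAConfig:
    """Parameters of one MRA run."""

    n_classes: int = 10
    seed_fraction: float = 0.02  # fraction of the data set seeded per class
    sa_iterations: int = 10
    sa_prob_start: float = 0.1  # "temperature" 10 on a 0-100 scale
    shc_max_iterations: int = 30
    convergence_frac: float = 0.01  # stop when fewer particles change class
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.seed_fraction <= 1):
            raise ValueError("seed_fraction must be in (0, 1]")
        if not (0 <= self.sa_prob_start <= 1):
            raise ValueError("sa_prob_start must be a probability")
        if not (0 <= self.convergence_frac <= 1):
            raise ValueError("convergence_frac must be a fraction")


def _particle_rng(global_seed: int, iteration: int, particle_id: int) -> np.random.Generator:
    """Per-particle stream so results are independent of execution order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, iteration, int(particle_id)])
    )


def seed_denovo_classes(mlist: particles.MotiveList, cfg: MRAConfig) -> list[np.ndarray]:
    """Random non-exclusive class seeds.

    Each class independently samples ``round(seed_fraction * N)`` particles
    without replacement; a particle may appear in several classes or in
    none.  Returns one index array (into the motive list) per class.
    """
    if cfg.n_classes < 2:
        raise ValueError("need at least 2 classes")
    n = len(mlist)
    per_class = int(round(cfg.seed_fraction * n))
    if per_class < 2:
        raise ValueError(
            f"seed_fraction {cfg.seed_fraction} of {n} particles gives "
            f"{per_class} per class; need at least 2"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xC1A55]))
    return [rng.choice(n, size=per_class, replace=False) for _ in range(cfg.n_classes)]


class _CandidateScorer:
    """Scores (orientation, class) candidates for one particle, caching the
    subtomogram spectra and (for a rotationally symmetric mask) the local
    denominator."""

    def __init__(self, subtomo, refs, mask, wedge_filter, params: AlignmentParams):
        nbox = subtomo.shape[0]
        bp = params.bandpass(nbox)
        self.ref_filt = wedge_filter.values if bp is None else wedge_filter.values * bp.values
        data_filt = (wedge_filter.values > 0).astype(float)
        if bp is not None:
            data_filt = data_filt * bp.values
        sub_f = sfft.ifftn(sfft.fftn(np.asarray(subtomo, dtype=float)) * data_filt).real
        self.spectra = corr.precompute_search(sub_f)
        self.sub_f = sub_f
        self.mask = mask
        from .template_matching import _is_rotationally_symmetric

        self.spherical = _is_rotationally_symmetric(mask)
        self.denom = corr.local_denominator(self.spectra, mask) if self.spherical else None
        self.refs = refs
        self.cc_mask = (
            corr.spherical_mask(nbox, params.cc_mask_radius)
            if params.cc_mask_radius is not None
            else None
        )

    def score(self, ang, cls):
        ref = self.refs[cls]
        rot = rotate_volume(ref, ang) if tuple(ang) != (0.0, 0.0, 0.0) else ref
        rot = sfft.ifftn(sfft.fftn(rot) * self.ref_filt).real
        rot_mask = (
            self.mask if self.spherical else np.clip(rotate_volume(self.mask, ang, cval=0.0), 0, 1)
        )
        ccc = corr.flcf(
            self.sub_f, rot, rot_mask, spectra=self.spectra,
            denom=self.denom if self.spherical else None,
        )
        return corr.peak_find(ccc, self.cc_mask)


def _candidates(params: AlignmentParams, prior_angles, classes):
    angle_list = params.local_list(prior_angles)
    return [(tuple(ang), cls) for ang in angle_list.angles for cls in classes]


def _result_row(ang, cls, score, offset):
    return {
        "phi": ang[0],
        "theta": ang[1],
        "psi": ang[2],
        "class": int(cls),
        "score": float(score),
        "shift_x": float(offset[0]),
        "shift_y": float(offset[1]),
        "shift_z": float(offset[2]),
    }


def shc_align(subtomo, refs: dict, mask, wedge_filter, params, prior, rng) -> dict:
    """Stochastic hill climbing over (orientation, class) candidates.

    The prior pair is scored first as the baseline; remaining candidates are
    visited in ``rng``-shuffled order and the first strictly better one is
    returned immediately.  If none beats the baseline the prior is returned
    re-scored.
    """
    scorer = _CandidateScorer(subtomo, refs, mask, wedge_filter, params)
    prior_angles = (prior["phi"], prior["theta"], prior["psi"])
    prior_cls = int(prior["class"])
    base_score, base_off = scorer.score(prior_angles, prior_cls)
    cands = [
        c for c in _candidates(params, prior_angles, list(refs)) if c != (tuple(prior_angles), prior_cls)
    ]
    order = rng.permutation(len(cands))
    for i in order:
        ang, cls = cands[i]
        score, off = scorer.score(ang, cls)
        if score > base_score:
            return _result_row(ang, cls, score, off)
    return _result_row(prior_angles, prior_cls, base_score, base_off)


def sa_align(subtomo, refs, mask, wedge_filter, params, prior, accept_prob, rng) -> dict:
    """Simulated-annealing step on top of SHC.

    With probability ``accept_prob`` the first randomly drawn candidate is
    accepted regardless of score (its own score is recorded); otherwise the
    step is exactly :func:`shc_align`.
    """
    if not (0 <= accept_prob <= 1):
        raise ValueError("accept_prob must be in [0, 1]")
    if accept_prob > 0 and rng.random() < accept_prob:
        scorer = _CandidateScorer(subtomo, refs, mask, wedge_filter, params)
        prior_angles = (prior["phi"], prior["theta"], prior["psi"])
        cands = [
            c
            for c in _candidates(params, prior_angles, list(refs))
            if c != (tuple(prior_angles), int(prior["class"]))
        ]
        ang, cls = cands[rng.integers(len(cands))]
        score, off = scorer.score(ang, cls)
        return _result_row(ang, cls, score, off)
    return shc_align(subtomo, refs, mask, wedge_filter, params, prior, rng)


def _average_classes(subtomos, mlist, wedges, params, prev_refs=None):
    refs = {}
    for cls in sorted(set(int(c) for c in mlist.classes)) if prev_refs is None else sorted(prev_refs):
        idx = np.flatnonzero(mlist.classes == cls)
        if len(idx) == 0:
            warnings.warn(f"class {cls} is empty; reference frozen")
            refs[cls] = prev_refs[cls]
            continue
        order = idx[np.argsort(mlist.rows["subtomo_num"].to_numpy()[idx], kind="stable")]
        avg, _ = average_halfset(
            [subtomos[i] for i in order],
            mlist.rows.iloc[order],
            [wedges[i] for i in order],
            sym=params.symmetry,
        )
        refs[cls] = avg
    return refs


def run_mra(
    subtomos,
    mlist: particles.MotiveList,
    wedges,
    mask: np.ndarray,
    cfg: MRAConfig,
    params: AlignmentParams,
    refs: dict | None = None,
):
    """Full MRA: optional de-novo seeding, SA phase, then SHC to convergence.

    With ``cfg.n_classes`` classes and no ``refs``, class references are
    seeded from random non-exclusive subsets.  Classes are re-averaged
    after every iteration.  Iteration stops when the fraction of particles
    changing class drops below ``cfg.convergence_frac`` (during the SHC
    phase) or at the iteration caps.  Returns
    ``(motive list, refs, history)`` where history records the changed-class
    fraction per iteration and whether convergence was reached.
    """
    if isinstance(wedges, wedge.WedgeFilter):
        wedges = [wedges] * len(mlist)
    rows = mlist.rows.copy()
    if refs is None:
        seeds = seed_denovo_classes(mlist, cfg)
        refs = {}
        for cls, idx in enumerate(seeds, start=1):
            idx = np.sort(idx)
            avg, _ = average_halfset(
                [subtomos[i] for i in idx], mlist.rows.iloc[idx],
                [wedges[i] for i in idx], sym=params.symmetry,
            )
            refs[cls] = avg
        # start every particle in a random class; SA moves them from there
        rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xA551]))
        rows["class"] = rng0.integers(1, cfg.n_classes + 1, len(rows))
    state = particles.MotiveList(rows, mlist.binning)

    history = {"changed_frac": [], "phase": [], "converged": False}
    total_iters = cfg.sa_iterations + cfg.shc_max_iterations
    it = 0
    for sa_it in range(cfg.sa_iterations):
        p = cfg.sa_prob_start * (1.0 - sa_it / max(cfg.sa_iterations, 1))
        state, changed = _mra_iteration(
            subtomos, state, wedges, mask, refs, params, cfg, it, accept_prob=p
        )
        refs = _average_classes(subtomos, state, wedges, params, prev_refs=refs)
        history["changed_frac"].append(changed)
        history["phase"].append("SA")
        it += 1
    for _ in range(cfg.shc_max_iterations):
        state, changed = _mra_iteration(
            subtomos, state, wedges, mask, refs, params, cfg, it, accept_prob=0.0
        )
        refs = _average_classes(subtomos, state, wedges, params, prev_refs=refs)
        history["changed_frac"].append(changed)
        history["phase"].append("SHC")
        it += 1
        if changed < cfg.convergence_frac:
            history["converged"] = True
            break
    return state, refs, history


def _mra_iteration(subtomos, state, wedges, mask, refs, params, cfg, iteration, accept_prob):
    old_classes = state.classes.copy()
    new_rows = state.rows.copy()
    order = np.argsort(state.rows["subtomo_num"].to_numpy(), kind="stable")
    for i in order:
        row = state.rows.iloc[i]
        rng = _particle_rng(cfg.seed, iteration, int(row["subtomo_num"]))
        if accept_prob > 0:
            updates = sa_align(
                subtomos[i], refs, mask, wedges[i], params, row, accept_prob, rng
            )
        else:
            updates = shc_align(subtomos[i], refs, mask, wedges[i], params, row, rng)
        for key, val in updates.items():
            new_rows.loc[new_rows.index[i], key] = val
    new_state = particles.MotiveList(new_rows, state.binning)
    changed = float((new_state.classes != old_classes).mean())
    return new_state, changed


@dataclass
class ConsensusTable:
    """Cross-replicate consensus of class assignments."""

    assignments: pd.DataFrame  # per-particle state per replicate + consensus
    occupancy: pd.DataFrame  # per-state occupancy fraction per replicate
    n_kept: int
    n_discarded: int


def propose_merges(replicate_lists: list, reference: int = 0) -> list[dict]:
    """Propose per-replicate class -> state mappings by maximum co-occupancy.

    Classes of each replicate are matched to the classes of the reference
    replicate with the Hungarian algorithm on the co-assignment matrix.
    (The original workflow does this step by visual curation; this helper
    only proposes a matching.)
    """
    ref_classes = sorted(set(replicate_lists[reference].classes))
    merges = []
    for r, ml in enumerate(replicate_lists):
        if r == reference:
            merges.append({c: c for c in ref_classes})
            continue
        classes = sorted(set(ml.classes))
        cost = np.zeros((len(classes), len(ref_classes)))
        for i, ci in enumerate(classes):
            for j, cj in enumerate(ref_classes):
                cost[i, j] = -np.sum((ml.classes == ci) & (replicate_lists[reference].classes == cj))
        ri, rj = linear_sum_assignment(cost)
        mapping = {classes[i]: ref_classes[j] for i, j in zip(ri, rj)}
        for c in classes:  # unmatched classes keep their own label
            mapping.setdefault(c, c)
        merges.append(mapping)
    return merges


def consensus_classes(
    replicate_lists: list,
    merges: list[dict] | None = None,
    m: int = 2,
) -> ConsensusTable:
    """Keep particles whose merged class agrees in at least ``m`` replicates.

    ``merges`` maps each replicate's class labels onto common states (one
    dict per replicate); by default an automatic maximum-co-occupancy
    matching is used.  Particles without an ``m``-fold majority are flagged
    for discard.  Occupancy fractions per state and replicate quantify the
    reproducibility of the classification.
    """
    ids = [tuple(ml.rows["subtomo_num"]) for ml in replicate_lists]
    if len(set(ids)) != 1:
        raise ValueError("replicates must contain the same particles in the same order")
    if merges is None:
        merges = propose_merges(replicate_lists)
    states = np.stack(
        [
            np.array([merges[r].get(int(c), int(c)) for c in ml.classes])
            for r, ml in enumerate(replicate_lists)
        ],
        axis=1,
    )  # (n_particles, n_replicates)
    consensus = np.full(len(states), -1)
    for i, row in enumerate(states):
        vals, counts = np.unique(row, return_counts=True)
        best = counts.argmax()
        if counts[best] >= m:
            consensus[i] = vals[best]
    table = pd.DataFrame(
        states, columns=[f"replicate_{r}" for r in range(states.shape[1])]
    )
    table.insert(0, "subtomo_num", replicate_lists[0].rows["subtomo_num"].to_numpy())
    table["consensus"] = consensus
    table["kept"] = consensus >= 0
    all_states = sorted(set(states.ravel().tolist()))
    occ = pd.DataFrame(
        {
            f"replicate_{r}": [
                float(np.mean(states[:, r] == s)) for s in all_states
            ]
            for r in range(states.shape[1])
        },
        index=pd.Index(all_states, name="state"),
    )
    return ConsensusTable(
        assignments=table,
        occupancy=occ,
        n_kept=int(table["kept"].sum()),
        n_discarded=int((~table["kept"]).sum()),
    )
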