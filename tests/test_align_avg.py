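"""Alignment fixed points, wedge-normalized averaging, FSC and FoM weighting."""

import numpy as np
import pytest

from subtomo import align_avg as A
from subtomo import correlation as C
from subtomo import geometry as G
from subtomo import particles as P
from subtomo import simulator as S
from subtomo import wedge as W


@pytest.fixture(scope="module")
def wl():
    return W.make_wedge_list()


@pytest.fixture(scope="module")
def amp24(wl):
    return W.amplitude_wedge((0, 0, 0), wl, 24)


@pytest.fixture(scope="module")
def phantom(wl):
    return S.make_phantom("blob_cluster", 24, seed=5)


@pytest.fixture(scope="module")
def mask(wl):
    return C.spherical_mask(24, 9, 2)


class TestAlignSubtomo:
    def test_fixed_point(self, phantom, amp24, mask):
        """A noise-free wedge-filtered copy at the prior pose stays put."""
        prior = {"phi": 20.0, "theta": 35.0, "psi": 100.0}
        sub = S.simulate_subtomogram(phantom, (20, 35, 100), wedge_filter=amp24, snr=np.inf)
        params = A.AlignmentParams(cone_step=2, cone_iter=1, inplane_step=2, inplane_iter=1,
                                   lp_radius=10, cc_mask_radius=4)
        out = A.align_subtomo(sub, phantom, mask, amp24, params, prior)
        assert (out["phi"], out["theta"], out["psi"]) == (20.0, 35.0, 100.0)
        assert (out["shift_x"], out["shift_y"], out["shift_z"]) == (0, 0, 0)
        assert out["score"] > 0.99

    def test_recovers_4_degree_offset(self, phantom, amp24, mask):
        prior = {"phi": 20.0, "theta": 35.0, "psi": 100.0}
        sub = S.simulate_subtomogram(phantom, (24, 35, 100), wedge_filter=amp24, snr=np.inf)
        params = A.AlignmentParams(cone_step=2, cone_iter=3, inplane_step=2, inplane_iter=3,
                                   lp_radius=10, cc_mask_radius=4)
        out = A.align_subtomo(sub, phantom, mask, amp24, params, prior)
        err = G.rotation_distance((out["phi"], out["theta"], out["psi"]), (24, 35, 100))
        assert err <= 2.0

    def test_zero_search_reduces_to_single_correlation(self, phantom, amp24, mask):
        prior = {"phi": 11.0, "theta": 72.0, "psi": 5.0}
        sub = S.simulate_subtomogram(phantom, (11, 72, 5), wedge_filter=amp24, snr=0.5, seed=2)
        params = A.AlignmentParams(cone_iter=0, inplane_iter=0, lp_radius=10, cc_mask_radius=0.5)
        out = A.align_subtomo(sub, phantom, mask, amp24, params, prior)
        assert (out["shift_x"], out["shift_y"], out["shift_z"]) == (0, 0, 0)
        assert -1 <= out["score"] <= 1

    def test_inplane_search_clamped_under_symmetry(self):
        params = A.AlignmentParams(cone_iter=0, inplane_step=10, inplane_iter=6,
                                   symmetry="C6")
        al = params.local_list((0, 0, 0))
        # +-30 degrees is the whole asymmetric unit in-plane under C6
        assert len(al) == 7


class TestAverageHalfset:
    def test_single_identity_particle_is_identity(self, phantom):
        full = W.binary_slice_wedge(np.arange(-90, 91, 1), 24)
        ml = P.new_motivelist([[12, 12, 12]])
        avg, tally = A.average_halfset([phantom], ml.rows, full)
        assert np.abs(avg - phantom).max() < 1e-6 * phantom.max()

    def test_wedge_filling_recovers_phantom(self, phantom, wl, rng):
        """Noise-free ±60-wedge copies at poses spanning orientation space
        average to the phantom up to the low-pass radius."""
        wf = W.amplitude_wedge((0, 0, 0), wl, 24, use_ctf=False, use_exposure=False)
        poses = [S.random_euler(rng) for _ in range(30)]
        subs = [S.simulate_subtomogram(phantom, p, wedge_filter=wf, snr=np.inf) for p in poses]
        ml = P.new_motivelist(np.tile([12, 12, 12], (30, 1)), angles=poses)
        avg, tally = A.average_halfset(subs, ml.rows, wf)
        fsc = A.compute_fsc(avg, phantom)
        # trilinear resampling (pose + inverse pose) bounds recovery at high
        # frequency; shells up to a quarter Nyquist are essentially exact
        assert fsc[:7].min() > 0.99

    def test_tally_is_sum_of_rotated_wedges(self, phantom, wl, rng):
        wf = W.amplitude_wedge((0, 0, 0), wl, 24)
        poses = [S.random_euler(rng) for _ in range(5)]
        subs = [S.simulate_subtomogram(phantom, p, wedge_filter=wf, snr=np.inf) for p in poses]
        ml = P.new_motivelist(np.tile([12, 12, 12], (5, 1)), angles=poses)
        _, tally = A.average_halfset(subs, ml.rows, wf)
        oracle = sum(
            A.rotate_fourier_filter(wf.values, G.invert_euler(p)) for p in poses
        )
        assert np.abs(tally - oracle).max() < 1e-6 * tally.max()

    def test_subvoxel_shift_compensated(self, phantom):
        full = W.binary_slice_wedge(np.arange(-90, 91, 1), 24)
        shifted = S.shift_volume(phantom, (0.4, -0.3, 0.2))
        ml = P.new_motivelist([[12.4, 11.7, 12.2]])
        vols, ml2 = P.extract_subtomograms(shifted, ml, 24)  # keeps residual shift
        avg, _ = A.average_halfset(vols, ml2.rows, full)
        # exact except for the self-conjugate Nyquist bins of the phase ramp
        assert np.abs(avg - phantom).max() < 1e-3 * phantom.max()

    def test_empty_set_rejected(self, phantom):
        with pytest.raises(ValueError, match="empty"):
            A.average_halfset([], P.empty_motivelist().rows, [])


class TestFSC:
    def test_identical_maps_give_unity(self, phantom):
        fsc = A.compute_fsc(phantom, phantom)
        assert np.allclose(fsc, 1.0, atol=1e-10)

    def test_independent_noise_fluctuates_about_zero(self, rng):
        fsc = A.compute_fsc(rng.standard_normal((32,) * 3), rng.standard_normal((32,) * 3))
        # outer shells hold thousands of voxels: |FSC| ~ 3/sqrt(n)
        for shell in range(8, 16):
            n_vox = 4 * np.pi * shell**2
            assert abs(fsc[shell]) < 3 / np.sqrt(n_vox) + 0.05

    def test_snr_relation(self, rng):
        """Halfmaps with shared signal and independent unit-SNR-s noise have
        E[FSC] = s/(s+1) per shell."""
        s = 2.0
        vals = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            sig = r.standard_normal((32,) * 3)
            a = sig + r.standard_normal((32,) * 3) / np.sqrt(s)
            b = sig + r.standard_normal((32,) * 3) / np.sqrt(s)
            vals.append(A.compute_fsc(a, b)[8])
        vals = np.array(vals)
        expected = s / (s + 1)
        assert abs(vals.mean() - expected) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))


class TestFomWeighting:
    @pytest.mark.parametrize(
        "fsc,weight",
        [(1.0, 1.0), (1 / 3, np.sqrt(0.5)), (0.0, 0.0), (-0.4, 0.0)],
    )
    def test_closed_form_weights(self, fsc, weight):
        n = 16
        a = np.zeros((n,) * 3)
        a[4, 4, 4] = 1.0
        fsc_arr = np.full(n // 2 + 1, fsc)
        out = A.fom_weighted_sum(a, a, fsc_arr)
        # weight applied uniformly: output = weight * mean map
        assert np.abs(out - weight * a).max() < 1e-10


class TestAlignmentIteration:
    def _setup(self, rng, n=8, snr=np.inf):
        phantom = S.make_phantom("blob_cluster", 24, seed=5)
        wl = W.make_wedge_list()
        wf = W.amplitude_wedge((0, 0, 0), wl, 24, use_ctf=False, use_exposure=False)
        poses = [S.random_euler(rng) for _ in range(n)]
        subs = [
            S.simulate_subtomogram(phantom, p, wedge_filter=wf, snr=snr, seed=100 + i)
            for i, p in enumerate(poses)
        ]
        ml = P.new_motivelist(np.tile([12, 12, 12], (n, 1)), angles=poses)
        ml = P.assign_halfsets(ml, seed=0)
        mask = C.spherical_mask(24, 9, 2)
        params = A.AlignmentParams(cone_step=4, cone_iter=1, inplane_step=4, inplane_iter=1,
                                   lp_radius=9, cc_mask_radius=3)
        return phantom, wf, subs, ml, mask, params

    def test_row_permutation_gives_bit_identical_averages(self, rng):
        phantom, wf, subs, ml, mask, params = self._setup(rng)
        refs = {"A": phantom, "B": phantom}
        _, bundle = A.run_alignment_iteration(subs, ml, wf, refs, mask, params)
        perm = rng.permutation(len(ml))
        ml_p = P.MotiveList(ml.rows.iloc[perm].reset_index(drop=True), ml.binning)
        _, bundle_p = A.run_alignment_iteration(
            [subs[i] for i in perm], ml_p, [wf] * len(ml), refs, mask, params
        )
        assert np.array_equal(bundle.halfmap_a, bundle_p.halfmap_a)
        assert np.array_equal(bundle.halfmap_b, bundle_p.halfmap_b)

    def test_scores_populated_and_bounded(self, rng):
        phantom, wf, subs, ml, mask, params = self._setup(rng, snr=0.5)
        refs = {"A": phantom, "B": phantom}
        new_ml, _ = A.run_alignment_iteration(subs, ml, wf, refs, mask, params)
        assert (new_ml.scores >= -1).all() and (new_ml.scores <= 1).all()
        assert (new_ml.scores != 0).all()

    def test_angular_error_non_increasing_over_iterations(self, rng):
        phantom, wf, subs, ml, mask, params = self._setup(rng)
        # perturb priors by ~4 degrees
        ml_p = ml.copy()
        ml_p.rows["phi"] += 4.0
        refs = {"A": phantom, "B": phantom}
        errs = []
        state = ml_p
        for _ in range(2):
            state, bundle = A.run_alignment_iteration(subs, state, wf, refs, mask, params)
            refs = {"A": bundle.halfmap_a, "B": bundle.halfmap_b}
            errs.append(
                np.median(
                    [G.rotation_distance(a, b) for a, b in zip(state.angles, ml.angles)]
                )
            )
        assert errs[-1] <= errs[0] + 1e-9

    def test_gold_standard_separation(self, rng, monkeypatch):
        """No particle is ever correlated against the other halfset's
        reference (instrumented via the alignment entry point)."""
        phantom, wf, subs, ml, mask, params = self._setup(rng)
        ref_a, ref_b = phantom + 0.0, phantom + 1e-6  # distinguishable objects
        seen = []
        original = A.align_subtomo

        def spy(subtomo, ref, *args, **kwargs):
            seen.append(ref is ref_a)
            return original(subtomo, ref, *args, **kwargs)

        monkeypatch.setattr(A, "align_subtomo", spy)
        A.run_alignment_iteration(subs, ml, wf, {"A": ref_a, "B": ref_b}, mask, params)
        order = np.argsort(ml.rows["subtomo_num"].to_numpy(), kind="stable")
        halfsets = ml.rows["halfset"].to_numpy()[order]
        assert seen == [hs == "A" for hs in halfsets]

    def test_empty_halfset_rejected(self, rng):
        phantom, wf, subs, ml, mask, params = self._setup(rng)
        ml.rows["halfset"] = "A"
        with pytest.raises(ValueError, match="halfset"):
            A.run_alignment_iteration(subs, ml, wf, {"A": phantom, "B": phantom}, mask, params)
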