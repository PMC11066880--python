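"""Parameter validation, task dispatch, worker determinism and resume."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from subtomo import cli, mrc, particles, runner


class TestValidation:
    def test_unknown_key_gets_suggestion(self):
        with pytest.raises(runner.ParameterError, match="lp_radius"):
            runner.validate_params("tm", {"lp_radis": "13"}, check_files=False)

    def test_all_errors_reported_at_once(self):
        try:
            runner.validate_params(
                "tm", {"bogus": "1", "lp_radius": "abc"}, check_files=False
            )
            raise AssertionError("expected ParameterError")
        except runner.ParameterError as exc:
            msg = str(exc)
            assert "bogus" in msg and "lp_radius" in msg and "missing required" in msg

    def test_defaults_filled_from_worked_settings(self, tmp_path):
        files = {}
        for key in ("tomogram", "template", "wedge"):
            p = tmp_path / f"{key}.dat"
            p.write_text("")
            files[key] = str(p)
        spec = runner.validate_params(
            "tm",
            {**files, "out_score": "s.mrc", "out_orient": "o.mrc", "out_motl": "m.star"},
        )
        assert spec.params["cone_step"] == 15.0
        assert spec.params["lp_radius"] == 13.0
        assert spec.params["use_noise"] is True

    def test_highpass_above_lowpass_conflict(self):
        with pytest.raises(runner.ParameterError, match="hp_radius"):
            runner.validate_params(
                "tm",
                {"tomogram": "t", "template": "t", "wedge": "w", "out_score": "s",
                 "out_orient": "o", "out_motl": "m", "lp_radius": "5", "hp_radius": "8"},
                check_files=False,
            )

    def test_missing_file_reported_by_key(self, tmp_path):
        with pytest.raises(runner.ParameterError, match="tomogram.*not found"):
            runner.validate_params(
                "tm",
                {"tomogram": str(tmp_path / "nope.mrc"), "template": "t", "wedge": "w",
                 "out_score": "s", "out_orient": "o", "out_motl": "m"},
            )

    def test_unknown_task_rejected(self):
        with pytest.raises(runner.ParameterError, match="available"):
            runner.validate_params("frobnicate", {})

    def test_param_file_parsing(self, tmp_path):
        p = tmp_path / "params.txt"
        p.write_text("# comment\nlp_radius = 9\nuse_noise=false\n")
        raw = runner.read_param_file(p)
        assert raw == {"lp_radius": "9", "use_noise": "false"}

    def test_malformed_param_line_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("lp_radius 9\n")
        with pytest.raises(runner.ParameterError, match="key=value"):
            runner.read_param_file(p)


@pytest.fixture(scope="module")
def tm_workspace(tmp_path_factory):
    """A tiny simulated tomogram plus template on disk for task tests."""
    root = tmp_path_factory.mktemp("tmjob")
    sim = runner.validate_params(
        "simulate",
        {
            "out_tomo": str(root / "tomo.mrc"),
            "out_motl": str(root / "truth.star"),
            "out_wedge": str(root / "wedge.star"),
            "n_particles": "3",
            "tomo_size": "48",
            "boxsize": "16",
            "min_dist": "17",
            "snr": "1.0",
            "seed": "3",
        },
    )
    runner.run_task(sim)
    from subtomo import simulator

    mrc.write_mrc(root / "template.mrc", simulator.make_phantom("blob_cluster", 16, seed=3))
    return root


def _tm_params(root, **over):
    base = {
        "tomogram": str(root / "tomo.mrc"),
        "template": str(root / "template.mrc"),
        "wedge": str(root / "wedge.star"),
        "cone_step": "60",
        "inplane_step": "60",
        "lp_radius": "7",
        "threshold": "0.1",
        "min_dist": "8",
        "out_score": str(root / "score.mrc"),
        "out_orient": str(root / "orient.mrc"),
        "out_motl": str(root / "found.star"),
    }
    base.update({k: str(v) for k, v in over.items()})
    return base


class TestTaskDeterminism:
    def test_worker_count_invariance(self, tm_workspace):
        root = tm_workspace
        log1 = runner.run_task(runner.validate_params(
            "tm", _tm_params(root, n_workers=1, n_tiles=2,
                             out_score=str(root / "s1.mrc"), out_motl=str(root / "m1.star"))))
        log4 = runner.run_task(runner.validate_params(
            "tm", _tm_params(root, n_workers=4, n_tiles=2,
                             out_score=str(root / "s4.mrc"), out_motl=str(root / "m4.star"))))
        s1, _ = mrc.read_mrc(root / "s1.mrc")
        s4, _ = mrc.read_mrc(root / "s4.mrc")
        assert np.array_equal(s1, s4)
        m1 = particles.read_motivelist(root / "m1.star")
        m4 = particles.read_motivelist(root / "m4.star")
        assert np.array_equal(m1.coords, m4.coords)

    def test_rerun_same_seed_bit_identical(self, tm_workspace):
        root = tm_workspace
        for tag in ("a", "b"):
            runner.run_task(runner.validate_params(
                "tm", _tm_params(root, seed=11, use_noise=True,
                                 out_score=str(root / f"rs_{tag}.mrc"),
                                 out_motl=str(root / f"rm_{tag}.star"))))
        sa, _ = mrc.read_mrc(root / "rs_a.mrc")
        sb, _ = mrc.read_mrc(root / "rs_b.mrc")
        assert np.array_equal(sa, sb)

    def test_resume_from_checkpoints_matches_fresh_run(self, tm_workspace):
        root = tm_workspace
        work = root / "work"
        fresh = runner.validate_params(
            "tm", _tm_params(root, n_tiles=2, out_score=str(root / "f.mrc"),
                             out_motl=str(root / "fm.star")))
        runner.run_task(fresh)
        # partial state: keep one tile checkpoint, delete the done marker
        resumed = runner.validate_params(
            "tm", _tm_params(root, n_tiles=2, work_dir=str(work),
                             out_score=str(root / "r.mrc"), out_motl=str(root / "rm.star")))
        runner.run_task(resumed)
        (work / "done.json").unlink()
        kept = sorted(work.glob("tile_*.npz"))
        for extra in kept[1:]:
            extra.unlink()
        runner.run_task(runner.validate_params(
            "tm", _tm_params(root, n_tiles=2, work_dir=str(work),
                             out_score=str(root / "r2.mrc"), out_motl=str(root / "rm2.star"))))
        f, _ = mrc.read_mrc(root / "f.mrc")
        r2, _ = mrc.read_mrc(root / "r2.mrc")
        assert np.array_equal(f, r2)

    def test_completed_job_is_noop(self, tm_workspace):
        root = tm_workspace
        spec = runner.validate_params(
            "tm", _tm_params(root, work_dir=str(root / "donejob"),
                             out_score=str(root / "d.mrc"), out_motl=str(root / "dm.star")))
        runner.run_task(spec)
        log = runner.run_task(spec)
        assert log["status"] == "already complete"


class TestAlignmentTasks:
    def test_extract_align_average_classify_pipeline(self, tm_workspace):
        """Full downstream pipeline on disk: extract the found particles,
        run one gold-standard alignment round, average, and classify."""
        root = tm_workspace
        runner.run_task(runner.validate_params("tm", _tm_params(root)))
        runner.run_task(runner.validate_params("extract", {
            "tomogram": str(root / "tomo.mrc"), "motl": str(root / "found.star"),
            "boxsize": "16", "out_dir": str(root / "subs"),
            "out_motl": str(root / "extracted.star"),
        }))
        common = {
            "motl": str(root / "extracted.star"), "subtomo_dir": str(root / "subs"),
            "wedge": str(root / "wedge.star"), "use_ctf": "false",
            "use_exposure": "false",
        }
        log = runner.run_task(runner.validate_params("ali_singleclass", {
            **common, "reference": str(root / "template.mrc"),
            "cone_step": "4", "cone_iter": "1", "inplane_step": "4",
            "inplane_iter": "1", "lp_radius": "6", "cc_mask_radius": "3",
            "out_prefix": str(root / "ali"),
        }))
        assert log["n_particles"] >= 2
        assert -1.0 <= log["mean_score"] <= 1.0
        aligned = particles.read_motivelist(root / "ali_motl.star")
        assert (aligned.scores != 0).all()
        for suffix in ("_halfmap_A.mrc", "_halfmap_B.mrc", "_fom.mrc", "_fsc.txt"):
            assert (root / f"ali{suffix}").exists()

        log_avg = runner.run_task(runner.validate_params("avg", {
            **common, "motl": str(root / "ali_motl.star"),
            "out_prefix": str(root / "avg"),
        }))
        assert log_avg["n_particles"] == log["n_particles"]
        half_a, _ = mrc.read_mrc(root / "avg_halfmap_A.mrc")
        assert half_a.std() > 0

        log_mra = runner.run_task(runner.validate_params("ali_multiclass", {
            **common, "motl": str(root / "ali_motl.star"),
            "n_classes": "2", "seed_fraction": "0.9", "sa_iterations": "1",
            "shc_max_iterations": "2", "lp_radius": "6", "cc_mask_radius": "2",
            "out_prefix": str(root / "mra"),
        }))
        assert log_mra["n_particles"] == log["n_particles"]
        assert sum(log_mra["occupancy"].values()) == log["n_particles"]
        classified = particles.read_motivelist(root / "mra_motl.star")
        assert set(classified.classes) <= {1, 2}


class TestCli:
    def test_parse_reports_validation_errors_with_exit_2(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("lp_radius=5\nhp_radius=9\n")
        result = CliRunner().invoke(cli.main, ["parse", "tm", "--param-file", str(p)])
        assert result.exit_code == 2
        assert "parameter error" in result.output

    def test_parse_prints_normalized_defaults(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(
            "tomogram=t\ntemplate=t\nwedge=w\nout_score=s\nout_orient=o\nout_motl=m\n"
        )
        result = CliRunner().invoke(cli.main, ["parse", "tm", "--param-file", str(p)])
        assert result.exit_code == 0
        assert "cone_step=15.0" in result.output
        assert "use_noise=True" in result.output

    def test_simulate_runs_end_to_end(self, tmp_path):
        result = CliRunner().invoke(cli.main, [
            "simulate",
            "--set", f"out_tomo={tmp_path}/t.mrc",
            "--set", f"out_motl={tmp_path}/m.star",
            "--set", f"out_wedge={tmp_path}/w.star",
            "--set", "n_particles=2", "--set", "tomo_size=48",
            "--set", "boxsize=16", "--set", "min_dist=17", "--set", "seed=1",
        ])
        assert result.exit_code == 0
        log = json.loads(result.output)
        assert log["n_planted"] == 2
        assert (tmp_path / "t.mrc").exists()
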