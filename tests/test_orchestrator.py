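"""Automation state machine: stack construction, journaling, stop-on-failure,
skip-and-continue, resume, and the simulated acquisition step."""
import json

import numpy as np
import pytest

from loopalign import VirtualBeamline, random_scene
from loopalign.errors import (
    AutomationStopped,
    CorruptJournal,
    Interrupted,
    UnknownMethod,
)
from loopalign.orchestrator import (
    Journal,
    build_stack,
    replay_journal,
    resume,
    run,
)
from loopalign.spreadsheet import SampleRow

from conftest import make_config


def fast_config():
    """Coarser beam -> smaller grids -> fast end-to-end runs."""
    return make_config(grid={"beam_size_mm": 0.1})


def rows_for(n, method="standard", **kwargs):
    return [
        SampleRow(puck="P1", position=i + 1, sample=f"s{i}", method=method,
                  exposure_time_s=0.01, oscillation_deg=0.1, total_range_deg=360.0,
                  **kwargs)
        for i in range(n)
    ]


def crystal_scene_source(row_index, row, rng):
    return random_scene(rng, with_crystal=True)


def sparse_scene_source(empty_rows):
    def source(row_index, row, rng):
        return random_scene(rng, with_crystal=row_index not in empty_rows,
                            background_spots=0 if row_index in empty_rows else 2)
    return source


def do_run(tmp_path, rows, seed=11, name="j.jsonl", **kwargs):
    bl = VirtualBeamline(fast_config())
    journal = tmp_path / name
    records = run(rows, bl, journal, seed, tmp_path / "out", **kwargs)
    return records, journal


class TestBuildStack:
    @pytest.mark.parametrize("method,expected", [
        ("standard", ["safety_check", "mount", "optical_center", "diff_center", "daq"]),
        ("multi_orientation", ["safety_check", "mount", "optical_center", "diff_center", "daq"]),
        ("serial", ["safety_check", "mount", "optical_center", "daq"]),
        ("robot_test", ["safety_check", "mount"]),
        ("alc_test", ["safety_check", "mount", "optical_center"]),
    ])
    def test_stacks(self, method, expected):
        assert build_stack(method) == expected

    def test_unknown_method(self):
        with pytest.raises(UnknownMethod):
            build_stack("teleport")


class TestRun:
    def test_three_crystal_samples_complete(self, tmp_path):
        records, journal = do_run(tmp_path, rows_for(3), scene_source=crystal_scene_source)
        assert len(records) == 3
        for rec in records:
            assert rec.complete()
            assert all(st.status == "success" for st in rec.steps.values())
            assert len(rec.manifests) == 1
        manifests = list((tmp_path / "out" / "datasets").glob("*.json"))
        assert len(manifests) == 3

    def test_crystal_free_sample_skipped_run_continues(self, tmp_path):
        records, _ = do_run(tmp_path, rows_for(3),
                            scene_source=sparse_scene_source({1}))
        assert records[1].steps["daq"].status == "skipped"
        assert records[1].manifests == []
        for i in (0, 2):
            assert records[i].steps["daq"].status == "success"

    def test_mount_failure_stops_run(self, tmp_path):
        bl = VirtualBeamline(fast_config())
        journal = tmp_path / "j.jsonl"
        with pytest.raises(AutomationStopped) as exc:
            run(rows_for(3), bl, journal, 5, tmp_path / "out",
                scene_source=crystal_scene_source, force_mount_failure_rows={1})
        assert exc.value.row == 1 and exc.value.step == "mount"
        recs, _ = replay_journal(journal)
        # rows beyond the failure were never touched
        assert max(r.row for r in recs) == 1
        assert recs[1].steps["mount"].status == "failed"
        events = Journal.read_events(journal)
        assert any(e.get("type") == "notification" for e in events)

    def test_status_passes_through_in_progress(self, tmp_path):
        _, journal = do_run(tmp_path, rows_for(1, method="robot_test"))
        events = [e for e in Journal.read_events(journal) if e.get("type") == "step"]
        seen = {}
        for e in events:
            key = (e["row"], e["step"])
            if e["status"] in ("success", "skipped", "failed"):
                assert seen.get(key) == "in_progress"
            seen[key] = e["status"]

    def test_journal_replay_reconstructs_records(self, tmp_path):
        records, journal = do_run(tmp_path, rows_for(2), scene_source=crystal_scene_source)
        replayed, meta = replay_journal(journal)
        assert meta["seed"] == 11
        assert [r.to_dict() for r in replayed] == [r.to_dict() for r in records]

    def test_no_centering_row_collects_without_grid(self, tmp_path):
        records, _ = do_run(tmp_path, rows_for(1, no_centering=True),
                            scene_source=crystal_scene_source)
        rec = records[0]
        assert rec.steps["daq"].status == "success"
        assert rec.decision is None


class TestDaq:
    def test_multi_orientation_manifests(self, tmp_path):
        rows = rows_for(1, method="multi_orientation",
                        orientation_pairs=[(0.0, 0.0), (20.0, 0.0)])
        records, _ = do_run(tmp_path, rows, scene_source=crystal_scene_source)
        ms = records[0].manifests
        assert [m["chi"] for m in ms] == [0.0, 20.0]
        assert all(m["folder"].startswith("datasets/") for m in ms)
        on_disk = json.loads(
            (tmp_path / "out" / "datasets" / "s0_set1.json").read_text())
        assert on_disk["chi"] == 20.0
        assert on_disk["provenance"]["outcome"] == "collect"

    def test_chi_over_limit_rejected_upstream(self):
        with pytest.raises(Exception):
            SampleRow(puck="P", position=1, sample="s", method="multi_orientation",
                      orientation_pairs=[(50.0, 0.0)])

    def test_standard_method_single_manifest(self, tmp_path):
        records, _ = do_run(tmp_path, rows_for(1), scene_source=crystal_scene_source)
        assert len(records[0].manifests) == 1
        assert records[0].manifests[0]["chi"] == 0.0


class TestResume:
    def test_resume_after_mount_failure_matches_uninterrupted(self, tmp_path):
        rows = rows_for(3)
        ref, _ = do_run(tmp_path, rows, name="ref.jsonl", scene_source=crystal_scene_source)

        bl = VirtualBeamline(fast_config())
        journal = tmp_path / "j.jsonl"
        with pytest.raises(AutomationStopped):
            run(rows, bl, journal, 11, tmp_path / "out2",
                scene_source=crystal_scene_source, force_mount_failure_rows={1})
        # failure cause cleared: resume from the journal on a fresh beamline
        bl2 = VirtualBeamline(fast_config())
        merged = resume(journal, rows, bl2, tmp_path / "out2",
                        scene_source=crystal_scene_source)
        assert [r.signature() for r in merged] == [r.signature() for r in ref]

    def test_resume_completed_run_is_noop(self, tmp_path):
        rows = rows_for(2)
        records, journal = do_run(tmp_path, rows, scene_source=crystal_scene_source)
        n_events = len(Journal.read_events(journal))
        bl = VirtualBeamline(fast_config())
        again = resume(journal, rows, bl, tmp_path / "out", scene_source=crystal_scene_source)
        assert [r.signature() for r in again] == [r.signature() for r in records]
        assert len(Journal.read_events(journal)) == n_events

    def test_interrupted_mid_row_resume(self, tmp_path):
        rows = rows_for(2)
        ref, _ = do_run(tmp_path, rows, name="ref.jsonl", scene_source=crystal_scene_source)

        bl = VirtualBeamline(fast_config())
        journal = tmp_path / "j.jsonl"
        with pytest.raises(Interrupted):
            run(rows, bl, journal, 11, tmp_path / "out2",
                scene_source=crystal_scene_source,
                interrupter=lambda r, s: (r, s) == (1, "diff_center"))
        bl2 = VirtualBeamline(fast_config())
        merged = resume(journal, rows, bl2, tmp_path / "out2",
                        scene_source=crystal_scene_source)
        assert [r.signature() for r in merged] == [r.signature() for r in ref]

    def test_truncated_journal_raises(self, tmp_path):
        _, journal = do_run(tmp_path, rows_for(1, method="robot_test"))
        raw = journal.read_text()
        journal.write_text(raw[:-10])  # chop mid-record
        with pytest.raises(CorruptJournal):
            replay_journal(journal)

    def test_malformed_line_raises(self, tmp_path):
        _, journal = do_run(tmp_path, rows_for(1, method="robot_test"))
        with open(journal, "a") as fh:
            fh.write("{not json}\n")
        with pytest.raises(CorruptJournal):
            replay_journal(journal)

    def test_missing_journal_raises(self, tmp_path):
        with pytest.raises(CorruptJournal):
            replay_journal(tmp_path / "absent.jsonl")


class TestPause:
    def test_pause_honored_at_step_boundary(self, tmp_path):
        calls = {"n": 0}

        def pause_after_first_row():
            calls["n"] += 1
            return calls["n"] > 3  # pause once the run is under way

        bl = VirtualBeamline(fast_config())
        journal = tmp_path / "j.jsonl"
        records = run(rows_for(3, method="robot_test"), bl, journal, 2, tmp_path / "out",
                      pause_check=pause_after_first_row)
        events = Journal.read_events(journal)
        assert events[-1] == {"type": "run_end", "status": "paused"}
        assert len(records) < 3
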