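"""Per-sample automation state machine with a resumable journal.

The executor iterates over validated spreadsheet rows, builds the execution
stack for each sample's collection method, and runs the steps in order:

    safety_check -> mount -> optical_center -> diff_center -> daq

Every status transition is appended to a JSON-lines journal; replaying the
journal reconstructs the execution records exactly, and a resumed run picks
up the failing row at its first non-successful step.  Any step failure stops
the whole run; a grid-scan skip marks the sample's daq as skipped and the
run continues with the next sample.

All per-row randomness is derived from ``(run_seed, row_index, step_index)``
so that a resumed step reproduces the original outcome bit-for-bit.
"""
from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import centering as _centering
from . import gridscan as _gridscan
from .config import BeamlineConfig
from .errors import (
    AcquisitionFailure,
    AutomationStopped,
    CorruptJournal,
    Interrupted,
    LoopAlignError,
    MountFailure,
    UnknownMethod,
)
from .spreadsheet import SampleRow
from .virtual_beamline import LoopScene, VirtualBeamline, random_scene


class StepName(str, Enum):
    safety_check = "safety_check"
    mount = "mount"
    optical_center = "optical_center"
    diff_center = "diff_center"
    daq = "daq"


STEP_ORDER = [s.value for s in StepName]

_STACKS = {
    "standard": ["safety_check", "mount", "optical_center", "diff_center", "daq"],
    "multi_orientation": ["safety_check", "mount", "optical_center", "diff_center", "daq"],
    "serial": ["safety_check", "mount", "optical_center", "daq"],
    "robot_test": ["safety_check", "mount"],
    "alc_test": ["safety_check", "mount", "optical_center"],
}

TERMINAL = ("success", "skipped", "failed")


def build_stack(method: str) -> List[str]:
    """Ordered step names for a collection method.  The serial method omits
    diffraction centering; the robot and ALC test methods truncate the stack
    for hardware commissioning runs."""
    try:
        return list(_STACKS[method])
    except KeyError:
        raise UnknownMethod(f"unknown collection method {method!r}") from None


@dataclass
class StepStatus:
    status: str = "unknown"   # unknown | in_progress | success | skipped | failed
    timestamp: Optional[float] = None
    message: str = ""


@dataclass
class ExecutionRecord:
    row: int
    sample: str
    method: str
    steps: Dict[str, StepStatus] = field(default_factory=dict)
    manifests: List[dict] = field(default_factory=list)
    artifacts: Dict[str, str] = field(default_factory=dict)
    decision: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "sample": self.sample,
            "method": self.method,
            "steps": {
                k: {"status": v.status, "timestamp": v.timestamp, "message": v.message}
                for k, v in self.steps.items()
            },
            "manifests": self.manifests,
            "artifacts": self.artifacts,
            "decision": self.decision,
        }

    def signature(self) -> dict:
        """Timestamp-free view used to compare runs for equivalence."""
        d = self.to_dict()
        for st in d["steps"].values():
            st.pop("timestamp")
        return d

    def complete(self) -> bool:
        stack = build_stack(self.method)
        return all(
            self.steps.get(s, StepStatus()).status in ("success", "skipped")
            for s in stack
        )


@dataclass
class RunState:
    status: str = "ready"     # ready | running | paused | failed | done
    current_row: int = -1


class Journal:
    """Append-only JSON-lines journal of run events."""

    def __init__(self, path):
        self.path = Path(path)
        self._fh = None

    def open(self):
        self._fh = open(self.path, "a", encoding="utf-8")
        return self

    def append(self, event: dict) -> None:
        if self._fh is None:
            raise RuntimeError("journal not open")
        self._fh.write(json.dumps(event, sort_keys=True) + "\n")
        self._fh.flush()
        os.fsync(self._fh.fileno())

    def close(self):
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    @staticmethod
    def read_events(path) -> List[dict]:
        path = Path(path)
        if not path.exists():
            raise CorruptJournal(f"journal {path} does not exist")
        events = []
        with open(path, "r", encoding="utf-8") as fh:
            raw = fh.read()
        if raw and not raw.endswith("\n"):
            raise CorruptJournal("journal ends with a truncated record")
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                events.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorruptJournal(f"malformed journal line {lineno}") from exc
        if not events or events[0].get("type") != "run_start":
            raise CorruptJournal("journal missing run_start event")
        return events


def replay_journal(path) -> Tuple[List[ExecutionRecord], dict]:
    """Reconstruct execution records from a journal.  Returns the records in
    row order plus the run_start metadata (seed etc.)."""
    events = Journal.read_events(path)
    meta = events[0]
    records: Dict[int, ExecutionRecord] = {}
    for ev in events[1:]:
        t = ev.get("type")
        if t == "step":
            row = ev["row"]
            rec = records.setdefault(
                row, ExecutionRecord(row=row, sample=ev["sample"], method=ev["method"])
            )
            rec.steps[ev["step"]] = StepStatus(
                status=ev["status"], timestamp=ev["ts"], message=ev.get("message", "")
            )
        elif t == "manifest":
            records[ev["row"]].manifests.append(ev["manifest"])
        elif t == "artifact":
            records[ev["row"]].artifacts[ev["kind"]] = ev["path"]
        elif t == "decision":
            records[ev["row"]].decision = ev["decision"]
    return [records[r] for r in sorted(records)], meta


# --------------------------------------------------------------------------

SceneSource = Callable[[int, SampleRow, np.random.Generator], LoopScene]


def default_scene_source(row_index: int, row: SampleRow, rng: np.random.Generator) -> LoopScene:
    """Random crystal-bearing scene per sample (the virtual 'puck')."""
    return random_scene(rng, with_crystal=True)


def _step_rng(seed: int, row_index: int, step_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(row_index, step_index))
    )


class _StepFailed(LoopAlignError):
    pass


@dataclass
class _RowContext:
    scene: Optional[LoopScene] = None
    centering: Optional[_centering.CenteringResult] = None
    plan: Optional[_centering.GridPlan] = None
    decision: Optional[_gridscan.CenterDecision] = None


class Executor:
    """Shared machinery behind :func:`run` and :func:`resume`."""

    def __init__(
        self,
        rows: Sequence[SampleRow],
        bl: VirtualBeamline,
        journal: Journal,
        seed: int,
        out_dir,
        scene_source: Optional[SceneSource] = None,
        interrupter: Optional[Callable[[int, str], bool]] = None,
        pause_check: Optional[Callable[[], bool]] = None,
        force_mount_failure_rows: Sequence[int] = (),
        notification_sink: Optional[Callable[[dict], None]] = None,
    ):
        self.rows = list(rows)
        self.bl = bl
        self.journal = journal
        self.seed = seed
        self.out_dir = Path(out_dir)
        self.scene_source = scene_source or default_scene_source
        self.interrupter = interrupter
        self.pause_check = pause_check
        self.force_mount_failure_rows = set(force_mount_failure_rows)
        self.notification_sink = notification_sink
        self.run_state = RunState()
        (self.out_dir / "assets").mkdir(parents=True, exist_ok=True)
        (self.out_dir / "datasets").mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------------- events

    def _journal_step(self, row: int, rec: ExecutionRecord, step: str, status: str, message: str = ""):
        ts = time.time()
        rec.steps[step] = StepStatus(status=status, timestamp=ts, message=message)
        self.journal.append({
            "type": "step", "row": row, "sample": rec.sample, "method": rec.method,
            "step": step, "status": status, "ts": ts, "message": message,
        })

    def _notify(self, event: dict):
        self.journal.append({"type": "notification", **event})
        if self.notification_sink is not None:
            self.notification_sink(event)

    # ----------------------------------------------------------------- steps

    def _do_safety_check(self, row_index: int, row: SampleRow, ctx: _RowContext, rng):
        st = self.bl.state
        if st.mode not in ("idle", "sample_exchange"):
            raise _StepFailed(f"beamline in mode {st.mode!r}, expected idle")
        if st.sample_mounted:
            raise _StepFailed("previous sample still mounted")
        t = self.bl.config.limits.translation_mm
        if any(abs(v) > t for v in (st.x, st.y, st.z)):
            raise _StepFailed("motors outside soft limits")

    def _do_mount(self, row_index: int, row: SampleRow, ctx: _RowContext, rng):
        if row_index in self.force_mount_failure_rows:
            raise MountFailure("injected mount failure")
        scene_rng = _step_rng(self.seed, row_index, 100)  # scene independent of retries
        ctx.scene = self.scene_source(row_index, row, scene_rng)
        self.bl.mount_sample(ctx.scene, rng)

    def _do_optical_center(self, row_index: int, row: SampleRow, ctx: _RowContext, rng):
        if row.no_centering:
            ctx.centering = _centering.CenteringResult(status="disabled")
            return
        _centering.prelocate(self.bl)
        result = _centering.center_to_flat(self.bl, rng=rng)
        ctx.centering = result
        if result.status != "centered":
            raise _StepFailed(f"optical centering ended with status {result.status!r}")
        frame = self.bl.render("microscope")
        path = self.out_dir / "assets" / f"row{row_index}_alc.png"
        frame.save_png(path)
        return {"alc_image": str(path.relative_to(self.out_dir))}

    def _do_diff_center(self, row_index: int, row: SampleRow, ctx: _RowContext, rng):
        if ctx.centering is None or ctx.centering.status != "centered":
            raise _StepFailed("no optical centering result available")
        # icy pin bases settle between optical and diffraction centering
        self.bl.apply_ice_jitter(rng)
        plan = _centering.grid_from_result(self.bl, ctx.centering)
        ctx.plan = plan
        policy = _gridscan.ThresholdPolicy.from_config(
            row.threshold_mode, self.bl.config.thresholds
        )
        (x1, y1), (x2, y2) = ctx.centering.bbox
        h_mm = (y2 - y1 + 1) / self.bl.config.microscope_camera.px_per_mm
        decision = _gridscan.decide(self.bl, plan, policy, rng, h_mm)
        ctx.decision = decision

        artifacts = {}
        frame2d = self.bl.render("microscope")
        if decision.result_2d is not None:
            p = self.out_dir / "assets" / f"row{row_index}_grid2d.png"
            _gridscan.save_heat_map(p, frame2d, decision.result_2d)
            artifacts["grid_2d"] = str(p.relative_to(self.out_dir))
        if decision.result_line is not None:
            self.bl.move_to(omega=decision.result_line.plan.omega)
            frameln = self.bl.render("microscope")
            p = self.out_dir / "assets" / f"row{row_index}_gridline.png"
            _gridscan.save_heat_map(p, frameln, decision.result_line)
            artifacts["grid_line"] = str(p.relative_to(self.out_dir))
            self.bl.move_to(omega=plan.omega)
        return artifacts

    def _do_daq(self, row_index: int, row: SampleRow, ctx: _RowContext, rng):
        if rng.random() < self.bl.config.simulator.acquisition_failure_prob:
            raise AcquisitionFailure("simulated detector/disk fault")
        if ctx.decision is not None and ctx.decision.outcome == "collect":
            pos = ctx.decision.position
            self.bl.move_to(x=pos["x"], y=pos["y"], z=pos["z"], omega=pos["omega"])
        pairs = row.orientation_pairs if row.method == "multi_orientation" else [(0.0, 0.0)]
        manifests = []
        for i, (chi, phi) in enumerate(pairs):
            # multi-orientation sets are collected without re-centering
            self.bl.move_to(chi=chi, phi=phi)
            folder = f"datasets/{row.sample}_set{i}"
            manifest = {
                "sample": row.sample,
                "row": row_index,
                "folder": folder,
                "exposure_time_s": row.exposure_time_s,
                "oscillation_deg": row.oscillation_deg,
                "total_range_deg": row.total_range_deg,
                "transmission": row.transmission,
                "resolution_a": row.resolution_a,
                "omega_start": self.bl.state.omega,
                "chi": chi,
                "phi": phi,
                "provenance": self._provenance(ctx),
            }
            path = self.out_dir / "datasets" / f"{row.sample}_set{i}.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, sort_keys=True, indent=1)
            with open(path, "r", encoding="utf-8") as fh:  # verify the write completed
                json.load(fh)
            manifests.append(manifest)
        return manifests

    @staticmethod
    def _provenance(ctx: _RowContext) -> Optional[dict]:
        d = ctx.decision
        if d is None:
            return None
        return {
            "outcome": d.outcome,
            "best_2d_index": list(d.best_2d_index) if d.best_2d_index else None,
            "best_line_index": d.best_line_index,
            "peak_2d": d.peak_2d,
            "peak_line": d.peak_line,
        }

    _STEP_FNS = {
        "safety_check": _do_safety_check,
        "mount": _do_mount,
        "optical_center": _do_optical_center,
        "diff_center": _do_diff_center,
        "daq": _do_daq,
    }

    # ------------------------------------------------------------------ rows

    def _run_step(self, row_index: int, row: SampleRow, rec: ExecutionRecord,
                  ctx: _RowContext, step: str, replay: bool):
        """Execute one step.  In replay mode (resume of an already-successful
        step) the side effects are re-applied deterministically but no new
        journal events are emitted and the journaled status is kept."""
        rng = _step_rng(self.seed, row_index, STEP_ORDER.index(step))
        fn = self._STEP_FNS[step]
        if not replay:
            self._journal_step(row_index, rec, step, "in_progress")
        try:
            out = fn(self, row_index, row, ctx, rng)
        except (LoopAlignError, _StepFailed) as exc:
            self._journal_step(row_index, rec, step, "failed", str(exc))
            self._notify({
                "severity": "error", "row": row_index, "step": step, "message": str(exc),
            })
            self.journal.append({"type": "run_end", "status": "failed"})
            self.run_state.status = "failed"
            raise AutomationStopped(row_index, step, str(exc)) from exc
        self._journal_step(row_index, rec, step, "success")
        if step == "optical_center" and isinstance(out, dict):
            for kind, path in out.items():
                rec.artifacts[kind] = path
                self.journal.append({"type": "artifact", "row": row_index, "kind": kind, "path": path})
        elif step == "diff_center":
            if isinstance(out, dict):
                for kind, path in out.items():
                    rec.artifacts[kind] = path
                    self.journal.append({"type": "artifact", "row": row_index, "kind": kind, "path": path})
            rec.decision = self._provenance(ctx)
            self.journal.append({"type": "decision", "row": row_index, "decision": rec.decision})
        elif step == "daq" and isinstance(out, list):
            for m in out:
                rec.manifests.append(m)
                self.journal.append({"type": "manifest", "row": row_index, "manifest": m})

    def execute(self, start_row: int = 0,
                prior_records: Optional[List[ExecutionRecord]] = None,
                partial_row_statuses: Optional[Dict[str, str]] = None) -> List[ExecutionRecord]:
        records: List[ExecutionRecord] = list(prior_records or [])
        self.run_state.status = "running"
        for row_index in range(start_row, len(self.rows)):
            row = self.rows[row_index]
            self.run_state.current_row = row_index
            stack = build_stack(row.method)
            rec = ExecutionRecord(row=row_index, sample=row.sample, method=row.method)
            for s in stack:
                rec.steps[s] = StepStatus()
            replayed: Dict[str, str] = {}
            if row_index == start_row and partial_row_statuses:
                replayed = partial_row_statuses
            ctx = _RowContext()
            skip_daq = False
            for step in stack:
                prior = replayed.get(step)
                if prior == "success":
                    # resume: re-apply effects deterministically under the
                    # original seeds; outputs and statuses end up identical
                    # to the uninterrupted run
                    self._run_step(row_index, row, rec, ctx, step, replay=True)
                    continue
                if self.pause_check is not None and self.pause_check():
                    self.journal.append({"type": "run_end", "status": "paused"})
                    self.run_state.status = "paused"
                    return records
                if self.interrupter is not None and self.interrupter(row_index, step):
                    raise Interrupted(f"simulated crash before row {row_index} step {step}")
                if (step == "diff_center" and ctx.centering is not None
                        and ctx.centering.status == "disabled"):
                    self._journal_step(row_index, rec, step, "skipped",
                                       "centering disabled for this sample")
                    continue
                if step == "daq" and ctx.decision is not None and ctx.decision.outcome == "skip":
                    self._journal_step(row_index, rec, step, "skipped",
                                       "no grid box above spot threshold")
                    skip_daq = True
                    continue
                self._run_step(row_index, row, rec, ctx, step, replay=False)
            records.append(rec)
            if self.bl.state.sample_mounted:
                self.bl.dismount()
        self.journal.append({"type": "run_end", "status": "done"})
        self.run_state.status = "done"
        return records


def run(
    rows: Sequence[SampleRow],
    bl: VirtualBeamline,
    journal_path,
    seed: int,
    out_dir,
    **kwargs,
) -> List[ExecutionRecord]:
    """Run automation over all rows, journaling every transition.

    Raises :class:`AutomationStopped` on the first failed step (records up to
    the failure stay in the journal); a grid-scan skip only skips that
    sample's daq.
    """
    journal = Journal(journal_path).open()
    journal.append({
        "type": "run_start", "seed": int(seed), "n_rows": len(rows),
        "samples": [r.sample for r in rows], "version": 1,
    })
    ex = Executor(rows, bl, journal, int(seed), out_dir, **kwargs)
    try:
        return ex.execute()
    finally:
        journal.close()


def resume(
    journal_path,
    rows: Sequence[SampleRow],
    bl: VirtualBeamline,
    out_dir,
    **kwargs,
) -> List[ExecutionRecord]:
    """Continue a run from its journal.

    Rows whose steps are all terminal success/skipped are not re-executed;
    the first incomplete row restarts from its first non-successful step
    (already-successful steps are replayed for their side effects under the
    original seeds, so outcomes are identical).  Resuming a completed run is
    a no-op.
    """
    prior, meta = replay_journal(journal_path)
    seed = int(meta["seed"])
    done: List[ExecutionRecord] = []
    partial: Optional[ExecutionRecord] = None
    for rec in prior:
        if rec.complete():
            done.append(rec)
        else:
            partial = rec
            break
    if partial is None and len(done) == len(rows):
        return done
    start_row = partial.row if partial is not None else len(done)
    partial_statuses = (
        {s: st.status for s, st in partial.steps.items() if st.status == "success"}
        if partial is not None
        else None
    )
    journal = Journal(journal_path).open()
    journal.append({"type": "resume", "seed": seed, "start_row": start_row})
    ex = Executor(rows, bl, journal, seed, out_dir, **kwargs)
    try:
        return ex.execute(
            start_row=start_row,
            prior_records=done,
            partial_row_statuses=partial_statuses,
        )
    finally:
        journal.close()
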