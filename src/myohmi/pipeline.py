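"""End-to-end orchestration and the trajectory-following evaluation.

``run_pipeline`` chains every stage on one recording: spectrum-tuned
low-pass filtering, burst segmentation, MLP classification, the Mealy
machine, and PD+ regulation of the manipulator to each emitted set-point.

The evaluation harness mirrors the point-to-point trajectory protocol
used to assess the interface: a task is an ordered list of machine states
to visit; every visited state that is not the next expected waypoint
counts as a penalty, and a task is repeated until a zero-penalty
completion.  Response times for scripted sessions are the durations
implied by the EMG timeline (contraction + rest), so results are
hardware-independent.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .dsp import apply_lowpass, compute_spectrum, lowpass_coefficients, tune_cutoff
from .mlp import MlpModel, predict_class
from .recording import EmgRecording
from .robot import ControlGains, Manipulator, RobotParams
from .segmentation import Segment, label_segments, segment_bursts
from .statemachine import MachineState, MealyMachine, load_transition_table
from .synthetic import (ContractionClass, SessionPlan, balanced_plan,
                        generate_session)

VOLUNTARY = (ContractionClass.SMP, ContractionClass.SMP3, ContractionClass.SMP5)


# ---------------------------------------------------------------------------
# benchmark dataset


def make_benchmark_segments(
    n_per_class: int = 40,
    seed: int = 42,
    fc_hz: float = 450.0,
    **plan_kwargs,
) -> list[Segment]:
    """Labeled segments from a balanced synthetic session, one per event.

    The session is low-pass filtered and segmented exactly as at inference
    time; each planned voluntary event contributes the detected burst that
    best overlaps its ground-truth interval (falling back to the interval
    itself when detection finds nothing).  Rest/involuntary events use
    their full ground-truth slot, so the NIM class is trained on both its
    quiet and its erratic face.
    """
    plan = balanced_plan(n_per_class, seed, **plan_kwargs)
    rec, truth = generate_session(plan)
    cfg = lowpass_coefficients(fc_hz, rec.sample_rate_hz)
    filt = apply_lowpass(rec, cfg)
    detected = [s for s in segment_bursts(filt) if s.kind == "burst"]
    out: list[Segment] = []
    for iv in truth:
        best, best_ov = None, 0.0
        if iv.cls is not ContractionClass.NIM:
            for seg in detected:
                ov = min(seg.end_s, iv.end_s) - max(seg.start_s, iv.start_s)
                if ov > best_ov:
                    best, best_ov = seg, ov
        if best is not None and best_ov >= 0.5 * min(best.duration_s, iv.duration_s):
            out.append(Segment(best.recording, best.start_s, best.end_s, iv.cls))
        else:
            out.append(Segment(filt.slice_seconds(iv.start_s, iv.end_s),
                               iv.start_s, iv.end_s, iv.cls,
                               kind="burst" if iv.cls.is_voluntary else "rest"))
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineEvent:
    """One classified event and what the machine/robot did with it."""

    start_s: float
    end_s: float
    predicted: ContractionClass
    state: MachineState
    setpoint: tuple
    active: bool
    cartesian_error_m: float | None = None


@dataclass
class PipelineTrace:
    events: list[PipelineEvent]
    cutoff_hz: float
    response_time_s: float

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps({
                    "start_s": ev.start_s, "end_s": ev.end_s,
                    "event": ev.predicted.name, "state": ev.state.name,
                    "px": ev.setpoint[0], "py": ev.setpoint[1],
                    "pz": ev.setpoint[2], "active": ev.active,
                    "cartesian_error_m": ev.cartesian_error_m,
                }) + "\n")

    @property
    def states(self) -> list[MachineState]:
        return [ev.state for ev in self.events]


def run_pipeline(
    rec: EmgRecording,
    model: MlpModel,
    machine: MealyMachine | None = None,
    robot: Manipulator | None = None,
    simulate_robot: bool = True,
    sim_duration_s: float = 5.0,
    dt: float = 1e-3,
) -> PipelineTrace:
    """Filter -> segment -> classify -> state machine -> PD+ regulation.

    Only detected burst segments carry command intent and step the
    machine — sustained rest leaves the robot where it is, while a burst
    classified NIM (involuntary movement) deactivates everything after
    it, mirroring the safety rule.  Response time is the duration of the
    EMG timeline itself.
    """
    machine = machine if machine is not None else MealyMachine()
    robot = robot if robot is not None else Manipulator()

    spec = compute_spectrum(rec)
    with warnings.catch_warnings():
        # a contraction-dominated spectrum legitimately peaks in-band
        warnings.simplefilter("ignore")
        cfg = tune_cutoff(spec)
    filt = apply_lowpass(rec, cfg)
    segments = sorted(segment_bursts(filt), key=lambda s: s.start_s)

    machine.reset()
    q = robot.inverse_kinematics(np.asarray(machine.state.output))
    events: list[PipelineEvent] = []
    for seg in segments:
        cls, _pulse = predict_class(model, seg)
        if not machine.active:
            break
        prev_state = machine.state
        if seg.kind != "burst":
            events.append(PipelineEvent(seg.start_s, seg.end_s, cls,
                                        machine.state, machine.state.output,
                                        machine.active))
            continue
        state, point = machine.step(cls)
        err = None
        if simulate_robot and machine.active and state is not prev_state:
            qd = robot.inverse_kinematics(np.asarray(point))
            sim = robot.simulate(q, qd, dt=dt, duration=sim_duration_s)
            q = sim.q[-1]
            err = float(np.linalg.norm(
                robot.forward_kinematics(q) - np.asarray(point)))
        events.append(PipelineEvent(seg.start_s, seg.end_s, cls, state,
                                    tuple(point), machine.active, err))
    return PipelineTrace(events, cfg.fc_hz, rec.duration_s)


# ---------------------------------------------------------------------------
# trajectory tasks, scoring, learning-curve harness


@dataclass
class TrajectoryTask:
    """Ordered waypoints (state names): start, path dots, end point."""

    waypoints: list

    def __post_init__(self):
        self.waypoints = [MachineState[w] if isinstance(w, str) else w
                          for w in self.waypoints]
        if len(self.waypoints) < 2:
            raise ValueError("a task needs at least a start and an end waypoint")

    @classmethod
    def from_json(cls, path) -> "TrajectoryTask":
        with open(path) as fh:
            return cls(json.load(fh)["waypoints"])


@dataclass
class TrialLog:
    trial_index: int
    elapsed_s: float
    penalties: int
    completed: bool


def score_trial(task: TrajectoryTask, states: list[MachineState],
                elapsed_s: float, trial_index: int = 0) -> TrialLog:
    """Score a visited-state trace against the task waypoints.

    Every visited state that is not the next expected waypoint is a
    penalty; the trial is complete once the final waypoint is reached.
    """
    expected = task.waypoints
    ptr = 1  # waypoint 0 is the starting state, not a state the user must produce
    penalties = 0
    for st in states:
        if ptr < len(expected) and st == expected[ptr]:
            ptr += 1
        else:
            penalties += 1
    return TrialLog(trial_index, elapsed_s, penalties, ptr >= len(expected))


def command_path(start: MachineState, goal: MachineState,
                 table: dict | None = None) -> list[ContractionClass]:
    """Shortest voluntary-command sequence from one state to another (BFS)."""
    table = table if table is not None else load_transition_table()
    if start == goal:
        return []
    seen = {start}
    queue = deque([(start, [])])
    while queue:
        state, path = queue.popleft()
        for cls in VOLUNTARY:
            nxt = MachineState[table[state.name][cls.name]]
            if nxt == goal:
                return path + [cls]
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, path + [cls]))
    raise ValueError(f"no voluntary path from {start.name} to {goal.name}")


def _command_cost_s(cls: ContractionClass, rest_s: float = 5.0) -> float:
    return (cls.nominal_duration_s or 0.0) + rest_s


def run_scripted_trial(
    task: TrajectoryTask,
    mistake_probability: float,
    rng: np.random.Generator,
    table: dict | None = None,
    rest_s: float = 5.0,
    max_commands: int = 200,
) -> TrialLog:
    """One trial by a scripted user who errs with a fixed probability.

    The user always knows the shortest command path to the next waypoint
    but occasionally issues a wrong voluntary command; the trial timeline
    charges each command its contraction plus rest duration.
    """
    table = table if table is not None else load_transition_table()
    machine = MealyMachine(table)
    visited: list[MachineState] = []
    elapsed = 0.0
    ptr = 1
    n_cmd = 0
    while ptr < len(task.waypoints) and n_cmd < max_commands:
        plan = command_path(machine.state, task.waypoints[ptr], table)
        if not plan:
            ptr += 1
            continue
        intended = plan[0]
        cls = intended
        if rng.random() < mistake_probability:
            wrong = [c for c in VOLUNTARY if c is not intended]
            cls = wrong[rng.integers(len(wrong))]
        state, _ = machine.step(cls)
        visited.append(state)
        elapsed += _command_cost_s(cls, rest_s)
        n_cmd += 1
        if state == task.waypoints[ptr]:
            ptr += 1
    log = score_trial(task, visited, elapsed)
    return log


def run_learning_session(
    task: TrajectoryTask,
    seed: int = 0,
    initial_mistake_probability: float = 0.35,
    decay: float = 0.65,
    max_trials: int = 50,
    rest_s: float = 5.0,
) -> list[TrialLog]:
    """Repeat the task with a decaying error rate until zero penalties.

    Emulates a user learning the interface: the mistake probability decays
    geometrically with each repetition, and the session ends at the first
    zero-penalty completion (or at the repetition cap).
    """
    rng = np.random.default_rng(seed)
    logs: list[TrialLog] = []
    p = initial_mistake_probability
    for i in range(max_trials):
        log = run_scripted_trial(task, p, rng, rest_s=rest_s)
        log.trial_index = i
        logs.append(log)
        if log.completed and log.penalties == 0:
            break
        p *= decay
    return logs


def percent_decrease(t_first: float, t_last: float) -> float:
    """Relative decrease 100 (t_first - t_last) / t_first, to two decimals."""
    if t_first <= 0:
        raise ValueError("t_first must be positive")
    return round(100.0 * (t_first - t_last) / t_first, 2)
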