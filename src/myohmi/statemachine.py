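"""Eight-state Mealy machine mapping contraction classes to set-points.

Classified contraction events arrive as 4-bit one-hot words, ordered
[NIM, SMP3, SMP5, SMP] from most to least significant bit.  The machine
has eight motion states, each bound to a fixed Cartesian set-point for the
manipulator's end effector, plus a deactivated HOME state:

    state   (px, py, pz) m          motion
    S1      ( 0.00, -0.34, 0.38)    stop
    S2      ( 0.00, -0.11, 0.46)    up
    S3      ( 0.34, -0.34, 0.38)    right
    S4      (-0.34, -0.34, 0.38)    left
    DUL     (-0.34, -0.11, 0.46)    diagonal up-left
    DUR     ( 0.34, -0.11, 0.46)    diagonal up-right
    DDL     (-0.34, -0.34, 0.28)    diagonal down-left
    DDR     ( 0.34, -0.34, 0.28)    diagonal down-right

A NIM word from any state deactivates the machine (safety rule: noise or
involuntary movement must never drive the robot); only an explicit reset
re-arms it.  The transition table ships as a versioned JSON asset next to
this module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np

from .synthetic import ContractionClass

#: bit order of the input word, MSB first
BIT_ORDER = (
    ContractionClass.NIM,
    ContractionClass.SMP3,
    ContractionClass.SMP5,
    ContractionClass.SMP,
)

#: symbolic input code of each motion state's Table row; the NIM word is IN9
STATE_INPUT_CODE = {
    "S1": "IN1", "S2": "IN2", "S3": "IN4", "S4": "IN7",
    "DUL": "IN8", "DUR": "IN3", "DDL": "IN6", "DDR": "IN5",
}
DEACTIVATE_CODE = "IN9"


class MachineState(Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    DUL = "DUL"
    DUR = "DUR"
    DDL = "DDL"
    DDR = "DDR"
    HOME = "HOME"  # deactivated

    @property
    def output(self) -> tuple[float, float, float]:
        """The state's Cartesian set-point (px, py, pz) in meters."""
        return STATE_OUTPUTS[self]

    @property
    def is_motion_state(self) -> bool:
        return self is not MachineState.HOME


#: Cartesian set-point of each state, meters; HOME parks at the stop point
STATE_OUTPUTS = {
    MachineState.S1: (0.0, -0.34, 0.38),
    MachineState.S2: (0.0, -0.11, 0.46),
    MachineState.S3: (0.34, -0.34, 0.38),
    MachineState.S4: (-0.34, -0.34, 0.38),
    MachineState.DUL: (-0.34, -0.11, 0.46),
    MachineState.DUR: (0.34, -0.11, 0.46),
    MachineState.DDL: (-0.34, -0.34, 0.28),
    MachineState.DDR: (0.34, -0.34, 0.28),
    MachineState.HOME: (0.0, -0.34, 0.38),
}

MOTION_STATES = tuple(s for s in MachineState if s.is_motion_state)


@dataclass(frozen=True)
class InputWord:
    """One-hot 4-bit word [NIM, SMP3, SMP5, SMP], or all-zero (no event)."""

    bits: tuple[int, int, int, int]

    def __post_init__(self):
        if len(self.bits) != 4 or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be four 0/1 values, got {self.bits}")
        if sum(self.bits) > 1:
            raise ValueError(f"input word must be one-hot or zero, got {self.bits}")

    @property
    def cls(self) -> ContractionClass | None:
        for bit, c in zip(self.bits, BIT_ORDER):
            if bit:
                return c
        return None

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


def encode_inputs(cls: ContractionClass) -> InputWord:
    """Contraction class -> one-hot word: NIM=1000, SMP3=0100, SMP5=0010, SMP=0001."""
    return InputWord(tuple(int(c is cls) for c in BIT_ORDER))


def load_transition_table(path=None) -> dict:
    """Load {state: {class_name: next_state}} from JSON (packaged default)."""
    if path is None:
        text = (resources.files("myohmi") / "data/transition_table.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = json.loads(text)["transitions"]
    for state, row in table.items():
        MachineState[state]
        for cls_name, nxt in row.items():
            ContractionClass[cls_name]
            MachineState[nxt]
    return table


class MealyMachine:
    """The command automaton; starts at S1 (stop), active."""

    def __init__(self, table: dict | None = None):
        self.table = table if table is not None else load_transition_table()
        self.state = MachineState.S1
        self.active = True

    def reset(self) -> None:
        """Re-arm after deactivation and return to the stop state."""
        self.state = MachineState.S1
        self.active = True

    def step(self, word: InputWord | ContractionClass) -> tuple["MachineState", tuple]:
        """Advance on one input word; returns (new state, emitted set-point).

        NIM deactivates from any state; an all-zero word is a no-op; steps
        while deactivated are ignored with a warning.
        """
        if isinstance(word, ContractionClass):
            word = encode_inputs(word)
        cls = word.cls
        if not self.active:
            warnings.warn("state machine is deactivated; input ignored until reset",
                          stacklevel=2)
            return self.state, self.state.output
        if cls is None:
            return self.state, self.state.output
        if cls is ContractionClass.NIM:
            self.state = MachineState.HOME
            self.active = False
            return self.state, self.state.output
        self.state = MachineState[self.table[self.state.name][cls.name]]
        return self.state, self.state.output

    def run_sequence(
        self, events: list[ContractionClass]
    ) -> list[tuple[MachineState, tuple]]:
        """Fold ``step`` over a list of classified events from a fresh start."""
        self.reset()
        return [self.step(ev) for ev in events]


def reachable_states(table: dict | None = None) -> set[MachineState]:
    """BFS over the transition table from S1 under voluntary inputs."""
    table = table if table is not None else load_transition_table()
    seen = {MachineState.S1}
    frontier = [MachineState.S1]
    while frontier:
        state = frontier.pop()
        for cls in (ContractionClass.SMP, ContractionClass.SMP3, ContractionClass.SMP5):
            nxt = MachineState[table[state.name][cls.name]]
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen
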