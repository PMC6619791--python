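"""State space and transition graph of the ED patient-flow process.

The model is a seven-state, six-transition acyclic multistate process on a
single forward clock (hours since registration):

    1 Registration ──► 2 Left (without being seen)
                  ──► 3 Redirect
                  ──► 4 Exam Room ──► 5 First Contact ──► 6 Disposition ──► 7 Departure

States 2, 3 and 7 are absorbing; competing risks act only out of state 1,
after which the path is sequential.
"""

from __future__ import annotations

from dataclasses import dataclass, field


STATE_LABELS: dict[int, str] = {
    1: "Registration",
    2: "Left",
    3: "Redirect",
    4: "ExamRoom",
    5: "FirstContact",
    6: "Disposition",
    7: "Departure",
}

#: transition_id -> (from_state, to_state)
TRANSITIONS: dict[int, tuple[int, int]] = {
    1: (1, 2),
    2: (1, 3),
    3: (1, 4),
    4: (4, 5),
    5: (5, 6),
    6: (6, 7),
}


@dataclass(frozen=True)
class TransitionStructure:
    """Directed multistate graph with labelled states and numbered transitions.

    The default construction is the ED flow graph above; alternative graphs
    (used by reduction tests, e.g. a single 1->2 edge recovering Kaplan-Meier)
    can be built by passing an explicit transition list.
    """

    states: tuple[int, ...] = tuple(STATE_LABELS)
    transitions: tuple[tuple[int, int], ...] = tuple(
        TRANSITIONS[k] for k in sorted(TRANSITIONS)
    )
    labels: dict[int, str] = field(default_factory=lambda: dict(STATE_LABELS))

    def __post_init__(self) -> None:
        for q, r in self.transitions:
            if q not in self.states or r not in self.states:
                raise ValueError(f"transition ({q},{r}) references unknown state")
        if self._has_cycle():
            raise ValueError("transition graph must be acyclic")

    def _has_cycle(self) -> bool:
        adj: dict[int, list[int]] = {s: [] for s in self.states}
        for q, r in self.transitions:
            adj[q].append(r)
        seen: dict[int, int] = {}  # 0 = in progress, 1 = done

        def visit(u: int) -> bool:
            if seen.get(u) == 0:
                return True
            if seen.get(u) == 1:
                return False
            seen[u] = 0
            if any(visit(v) for v in adj[u]):
                return True
            seen[u] = 1
            return False

        return any(visit(s) for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def transition_id(self, q: int, r: int) -> int:
        """1-based id of the q->r transition (ordering of the transition list)."""
        try:
            return self.transitions.index((q, r)) + 1
        except ValueError:
            raise KeyError(f"no transition {q}->{r}") from None

    def from_to(self, transition_id: int) -> tuple[int, int]:
        return self.transitions[transition_id - 1]

    def successors(self, state: int) -> list[int]:
        return [r for q, r in self.transitions if q == state]

    def terminal_states(self) -> list[int]:
        out = {q for q, _ in self.transitions}
        return [s for s in self.states if s not in out]

    def initial_states(self) -> list[int]:
        inc = {r for _, r in self.transitions}
        return [s for s in self.states if s not in inc]


def ed_structure() -> TransitionStructure:
    """The canonical 7-state, 6-transition ED flow structure."""
    return TransitionStructure()
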