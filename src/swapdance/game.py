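"""Core state space and transition model of the two-agent exchange game.

Two agents, A and B, each start in possession of one object (A holds a, B
holds b) and each values the *other* agent's object more highly than its own.
The only physical primitive is a *hold*: a binary relation by which an agent
prevents an object (or the other agent) from being removed.  Each agent can
hold up to three things -- object a, object b, and the other agent -- so the
joint state is a sextuple of bits written in the canonical label form
``"xyz:uvw"``:

    bit 1  A holds object a        bit 4  B holds object a
    bit 2  A holds agent B         bit 5  B holds agent A
    bit 3  A holds object b        bit 6  B holds object b

The start state is ``"100:001"`` and the mutually desired final state is
``"001:100"``.  An interaction ends when one agent successfully exits, at
which point both agents are paid the value of the objects they solely hold.

Four *hold variants* restrict which configurations are admissible, giving
state spaces of 64, 36, 16 and 9 non-terminal states.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Agent",
    "Action",
    "ACTIONS",
    "HoldVariant",
    "JointState",
    "GameConfig",
    "TransitionOutcome",
    "Transition",
    "CompiledGame",
    "START_LABEL",
    "GOAL_LABEL",
    "encode_state",
    "decode_state",
    "enumerate_states",
    "legal_actions",
    "transition",
    "reachable_graph",
    "graph_to_dot",
    "state_table",
]

START_LABEL = "100:001"
GOAL_LABEL = "001:100"


class Agent(enum.IntEnum):
    """The two players. ``other()`` gives the opponent."""

    A = 0
    B = 1

    def other(self) -> "Agent":
        return Agent.B if self is Agent.A else Agent.A


class Action(enum.IntEnum):
    """The five actions available to an actor.

    Toggling takes a hold if none is currently held, and releases it
    otherwise; toggles act only on the actor's own hold bits.
    """

    TOGGLE_OBJECT_A = 0
    TOGGLE_AGENT = 1
    TOGGLE_OBJECT_B = 2
    PASS = 3
    EXIT = 4


#: Canonical action ordering used for table columns.
ACTIONS: tuple[Action, ...] = tuple(Action)

N_ACTIONS = len(ACTIONS)


class HoldVariant(enum.Enum):
    """Which holds are permitted; determines the admissible state set.

    * ``ALL_HOLDS`` -- no restriction; 64 non-terminal states.
    * ``EXCLUSIVE_OBJECT_HOLDS`` -- at most one agent may hold a given
      object at a time; 36 states.
    * ``NO_AGENT_HOLDS`` -- agents cannot hold each other; 16 states.
    * ``EXCLUSIVE_AND_NO_AGENT_HOLDS`` -- both restrictions; 9 hold
      configurations (10 states counting the absorbing terminal marker).
    """

    ALL_HOLDS = "all_holds"
    EXCLUSIVE_OBJECT_HOLDS = "exclusive_object_holds"
    NO_AGENT_HOLDS = "no_agent_holds"
    EXCLUSIVE_AND_NO_AGENT_HOLDS = "exclusive_and_no_agent_holds"

    @property
    def allows_agent_holds(self) -> bool:
        return self in (HoldVariant.ALL_HOLDS, HoldVariant.EXCLUSIVE_OBJECT_HOLDS)

    @property
    def allows_shared_object_holds(self) -> bool:
        return self in (HoldVariant.ALL_HOLDS, HoldVariant.NO_AGENT_HOLDS)


# Bit indices within the sextuple.
A_HOLDS_A, A_HOLDS_AGENT, A_HOLDS_B, B_HOLDS_A, B_HOLDS_AGENT, B_HOLDS_B = range(6)

#: Per-agent (object-a bit, agent bit, object-b bit).
_AGENT_BITS = {
    Agent.A: (A_HOLDS_A, A_HOLDS_AGENT, A_HOLDS_B),
    Agent.B: (B_HOLDS_A, B_HOLDS_AGENT, B_HOLDS_B),
}


@dataclass(frozen=True)
class JointState:
    """A joint hold configuration, possibly marked terminal after an exit.

    ``bits`` keeps the holds at the moment of exit when ``terminal`` is set,
    and ``exiter`` records which agent left.
    """

    bits: tuple[bool, bool, bool, bool, bool, bool]
    terminal: bool = False
    exiter: Optional[Agent] = None

    def __post_init__(self) -> None:
        if self.terminal and self.exiter is None:
            raise ValueError("terminal states must record the exiting agent")
        if not self.terminal and self.exiter is not None:
            raise ValueError("only terminal states have an exiter")

    @property
    def label(self) -> str:
        b = "".join("1" if x else "0" for x in self.bits)
        return f"{b[:3]}:{b[3:]}"

    @property
    def index(self) -> int:
        """Canonical integer: bit 1 most significant."""
        i = 0
        for b in self.bits:
            i = (i << 1) | int(b)
        return i

    def holds(self, agent: Agent) -> tuple[bool, bool, bool]:
        """(holds object a, holds other agent, holds object b) for ``agent``."""
        ia, ig, ib = _AGENT_BITS[agent]
        return self.bits[ia], self.bits[ig], self.bits[ib]

    def n_holds(self, agent: Agent) -> int:
        return sum(self.holds(agent))

    def held_by_other(self, agent: Agent) -> bool:
        """True if the opponent currently holds ``agent``."""
        return self.bits[_AGENT_BITS[agent.other()][1]]

    def sole_object_holds(self, agent: Agent) -> tuple[bool, bool]:
        """(solely holds a, solely holds b)."""
        oa, _, ob = self.holds(agent)
        other_a, _, other_b = self.holds(agent.other())
        return oa and not other_a, ob and not other_b

    def with_bit(self, bit: int, value: bool) -> "JointState":
        bits = list(self.bits)
        bits[bit] = value
        return JointState(tuple(bits))

    def admissible(self, variant: HoldVariant) -> bool:
        b = self.bits
        if not variant.allows_agent_holds and (b[A_HOLDS_AGENT] or b[B_HOLDS_AGENT]):
            return False
        if not variant.allows_shared_object_holds and (
            (b[A_HOLDS_A] and b[B_HOLDS_A]) or (b[A_HOLDS_B] and b[B_HOLDS_B])
        ):
            return False
        return True

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        if self.terminal:
            return f"<exit:{self.exiter.name} {self.label}>"
        return self.label


def encode_state(label: str) -> JointState:
    """Parse a canonical ``"xyz:uvw"`` label into a :class:`JointState`.

    Raises ``ValueError`` naming the offending character position on a
    malformed label.
    """
    if len(label) != 7 or label[3] != ":":
        raise ValueError(
            f"malformed state label {label!r}: expected six binary digits as 'xyz:uvw'"
        )
    digits = label[:3] + label[4:]
    bits = []
    for pos, ch in enumerate(digits):
        if ch not in "01":
            col = pos if pos < 3 else pos + 1  # position within the label string
            raise ValueError(
                f"malformed state label {label!r}: character {ch!r} at position {col}"
            )
        bits.append(ch == "1")
    return JointState(tuple(bits))


def decode_state(state: JointState) -> str:
    """Inverse of :func:`encode_state` for non-terminal states."""
    return state.label


START = encode_state(START_LABEL)
GOAL = encode_state(GOAL_LABEL)


@dataclass(frozen=True)
class GameConfig:
    """Payoff structure and rules of a single exchange game.

    Values are positive payoffs received at exit for solely-held objects;
    ``value_own`` prices the object an agent starts with and ``value_other``
    the object the opponent starts with (the prisoner's-dilemma-style 1 vs 4
    by default).  The four cost classes are charged per step: ``cost_grab``
    for establishing a hold, ``cost_maintain`` per hold currently maintained,
    ``cost_illegal`` for attempting a forbidden action, and ``cost_step``
    simply for being in the game.  ``p_exit`` < 1 gives a "slow exit": the
    exit attempt succeeds only with that probability, which leaves the other
    agent time to react.
    """

    value_own: float = 1.0
    value_other: float = 4.0
    cost_grab: float = 0.02
    cost_maintain: float = 0.002
    cost_illegal: float = 0.5
    cost_step: float = 0.002
    p_exit: float = 1.0
    variant: HoldVariant = HoldVariant.ALL_HOLDS
    asymmetric_values: Optional[tuple[float, float]] = None  # (A's, B's) value_other

    def __post_init__(self) -> None:
        if self.value_own <= 0 or self.value_other <= 0:
            raise ValueError("object values must be positive")
        for name in ("cost_grab", "cost_maintain", "cost_illegal", "cost_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.p_exit <= 1.0):
            raise ValueError("p_exit must lie in (0, 1]")
        if self.asymmetric_values is not None and any(
            v <= 0 for v in self.asymmetric_values
        ):
            raise ValueError("asymmetric values must be positive")

    def value_of(self, agent: Agent, obj: str) -> float:
        """Value of object ``'a'`` or ``'b'`` to ``agent``."""
        own = (agent is Agent.A and obj == "a") or (agent is Agent.B and obj == "b")
        if own:
            return self.value_own
        if self.asymmetric_values is not None:
            return self.asymmetric_values[int(agent)]
        return self.value_other

    def exit_payout(self, state: JointState, agent: Agent) -> float:
        """Object reward paid to ``agent`` when the game ends in ``state``."""
        sole_a, sole_b = state.sole_object_holds(agent)
        pay = 0.0
        if sole_a:
            pay += self.value_of(agent, "a")
        if sole_b:
            pay += self.value_of(agent, "b")
        return pay


@dataclass(frozen=True)
class TransitionOutcome:
    probability: float
    state: JointState
    reward_to_A: float
    reward_to_B: float

    def reward_to(self, agent: Agent) -> float:
        return self.reward_to_A if agent is Agent.A else self.reward_to_B


@dataclass(frozen=True)
class Transition:
    """Stochastic outcome bundle of one (state, actor, action) triple."""

    state: JointState
    actor: Agent
    action: Action
    outcomes: tuple[TransitionOutcome, ...]

    @property
    def reward_to_A(self) -> float:
        return sum(o.probability * o.reward_to_A for o in self.outcomes)

    @property
    def reward_to_B(self) -> float:
        return sum(o.probability * o.reward_to_B for o in self.outcomes)

    def sample(self, rng: np.random.Generator) -> TransitionOutcome:
        u = rng.random()
        acc = 0.0
        for o in self.outcomes:
            acc += o.probability
            if u < acc:
                return o
        return self.outcomes[-1]


def enumerate_states(
    variant: HoldVariant, include_terminal: bool = False
) -> list[JointState]:
    """All admissible non-terminal states in canonical ascending-bit order.

    Bit 1 (A holds a) is most significant.  With ``include_terminal`` a
    single absorbing marker (attributed to agent A, holds as-at-exit all
    clear) is appended; per-trajectory terminal states carry the actual
    holds and exiter.
    """
    states = []
    for i in range(64):
        bits = tuple(bool((i >> (5 - k)) & 1) for k in range(6))
        s = JointState(bits)
        if s.admissible(variant):
            states.append(s)
    if include_terminal:
        states.append(JointState(tuple([False] * 6), terminal=True, exiter=Agent.A))
    return states


def _toggle_target(action: Action, actor: Agent) -> int:
    ia, ig, ib = _AGENT_BITS[actor]
    return {Action.TOGGLE_OBJECT_A: ia, Action.TOGGLE_AGENT: ig, Action.TOGGLE_OBJECT_B: ib}[
        action
    ]


def is_legal(state: JointState, actor: Agent, action: Action, config: GameConfig) -> bool:
    """Whether ``action`` by ``actor`` is allowed in ``state``.

    PASS is always allowed.  A toggle that would *establish* a hold is
    forbidden when the variant forbids that hold (agent holds disallowed, or
    a grab of an object the opponent already holds under exclusive object
    holds).  EXIT is forbidden while the actor is held by the opponent or
    while any object the actor holds is also held by the opponent (leaving
    would require breaking a hold).
    """
    if state.terminal:
        raise ValueError("terminal states afford no actions")
    variant = config.variant
    if action is Action.PASS:
        return True
    if action is Action.EXIT:
        if state.held_by_other(actor):
            return False
        oa, _, ob = state.holds(actor)
        other_a, _, other_b = state.holds(actor.other())
        return not ((oa and other_a) or (ob and other_b))
    # toggles
    bit = _toggle_target(action, actor)
    establishing = not state.bits[bit]
    if action is Action.TOGGLE_AGENT:
        return variant.allows_agent_holds
    if establishing and not variant.allows_shared_object_holds:
        # grabbing an object the opponent already holds would create a shared hold
        other_bit = _toggle_target(action, actor.other())
        if state.bits[other_bit]:
            return False
    return True


def legal_actions(state: JointState, actor: Agent, config: GameConfig) -> list[Action]:
    """The subset of the five actions legal for ``actor`` in ``state``."""
    return [a for a in ACTIONS if is_legal(state, actor, a, config)]


def _step_rewards(state: JointState, actor: Agent, action: Action, legal: bool,
                  config: GameConfig) -> tuple[float, float]:
    """Per-step costs (exit payouts excluded), as (to A, to B)."""
    r = [-config.cost_step, -config.cost_step]
    for ag in Agent:
        r[int(ag)] -= config.cost_maintain * state.n_holds(ag)
    if not legal:
        r[int(actor)] -= config.cost_illegal
    elif action in (Action.TOGGLE_OBJECT_A, Action.TOGGLE_AGENT, Action.TOGGLE_OBJECT_B):
        if not state.bits[_toggle_target(action, actor)]:  # establishing a hold
            r[int(actor)] -= config.cost_grab
    return r[0], r[1]


def transition(
    state: JointState, actor: Agent, action: Action, config: GameConfig
) -> Transition:
    """The stochastic transition for ``actor`` taking ``action`` in ``state``.

    Illegal attempts are modelled: they leave the state unchanged and charge
    the actor ``cost_illegal``.  A legal EXIT succeeds with probability
    ``p_exit`` (absorbing, with object payouts) and otherwise consumes the
    turn; all other legal actions are deterministic.
    """
    if state.terminal:
        raise ValueError("cannot act in a terminal state")
    legal = is_legal(state, actor, action, config)
    ra, rb = _step_rewards(state, actor, action, legal, config)
    if not legal or action is Action.PASS:
        return Transition(state, actor, action, (TransitionOutcome(1.0, state, ra, rb),))
    if action is Action.EXIT:
        final = JointState(state.bits, terminal=True, exiter=actor)
        pay_a = config.exit_payout(state, Agent.A)
        pay_b = config.exit_payout(state, Agent.B)
        outs = [TransitionOutcome(config.p_exit, final, ra + pay_a, rb + pay_b)]
        if config.p_exit < 1.0:
            outs.append(TransitionOutcome(1.0 - config.p_exit, state, ra, rb))
        return Transition(state, actor, action, tuple(outs))
    bit = _toggle_target(action, actor)
    nxt = state.with_bit(bit, not state.bits[bit])
    return Transition(state, actor, action, (TransitionOutcome(1.0, nxt, ra, rb),))


class CompiledGame:
    """Array form of one configured game, shared by the learner.

    States are indexed in canonical order; a single absorbing terminal slot
    occupies index ``n_states``.  For every (actor, state, action) the
    two-outcome transition (successor indices, probabilities, rewards to each
    agent) and the legality mask are precomputed, so that Bellman sweeps are
    pure vectorised array expressions.
    """

    def __init__(self, config: GameConfig):
        self.config = config
        self.states: list[JointState] = enumerate_states(config.variant)
        self.n_states = len(self.states)
        self.labels = [s.label for s in self.states]
        self.index = {s.bits: i for i, s in enumerate(self.states)}
        self.terminal_index = self.n_states

        S, A = self.n_states, N_ACTIONS
        self.legal = np.zeros((2, S, A), dtype=bool)
        self.succ = np.full((2, S, A, 2), self.terminal_index, dtype=np.int64)
        self.prob = np.zeros((2, S, A, 2))
        self.reward = np.zeros((2, S, A, 2, 2))  # [actor, s, d, outcome, beneficiary]

        for x in Agent:
            for i, s in enumerate(self.states):
                for d in ACTIONS:
                    t = transition(s, x, d, config)
                    self.legal[x, i, d] = is_legal(s, x, d, config)
                    for k, o in enumerate(t.outcomes):
                        j = self.terminal_index if o.state.terminal else self.index[o.state.bits]
                        self.succ[x, i, d, k] = j
                        self.prob[x, i, d, k] = o.probability
                        self.reward[x, i, d, k, 0] = o.reward_to_A
                        self.reward[x, i, d, k, 1] = o.reward_to_B

        self.start_index = self.index[START.bits]

    def state_at(self, i: int) -> JointState:
        return self.states[i]

    def legal_indices(self, i: int, actor: Agent) -> np.ndarray:
        return np.flatnonzero(self.legal[actor, i])


def reachable_graph(config: GameConfig, start: JointState = START) -> nx.MultiDiGraph:
    """Directed multigraph of states reachable from ``start`` by legal play.

    Edges carry ``actor``, ``action`` and ``probability``; the absorbing
    terminal marker is the node ``"EXIT"``.
    """
    g = nx.MultiDiGraph()
    g.add_node(start.label)
    frontier = [start]
    seen = {start.bits}
    while frontier:
        s = frontier.pop()
        for actor in Agent:
            for action in legal_actions(s, actor, config):
                for o in transition(s, actor, action, config).outcomes:
                    target = "EXIT" if o.state.terminal else o.state.label
                    g.add_edge(
                        s.label,
                        target,
                        actor=actor.name,
                        action=action.name,
                        probability=o.probability,
                    )
                    if not o.state.terminal and o.state.bits not in seen:
                        seen.add(o.state.bits)
                        frontier.append(o.state)
    return g


def graph_to_dot(g: nx.MultiDiGraph) -> str:
    """Render a reachability (or dance) graph in DOT format."""
    out = io.StringIO()
    out.write("digraph exchange {\n  rankdir=LR;\n")
    for node in g.nodes:
        shape = "doublecircle" if node == "EXIT" else "circle"
        out.write(f'  "{node}" [shape={shape}];\n')
    for u, v, data in g.edges(data=True):
        bits = [str(data[k]) for k in ("actor", "action", "probability") if k in data]
        label = " ".join(bits)
        out.write(f'  "{u}" -> "{v}" [label="{label}"];\n')
    out.write("}\n")
    return out.getvalue()


def state_table(config: GameConfig) -> "pandas.DataFrame":  # noqa: F821
    """Per-state admissibility/reachability table for all 64 configurations."""
    import pandas as pd

    reach = set(reachable_graph(config).nodes) - {"EXIT"}
    rows = []
    for s in enumerate_states(HoldVariant.ALL_HOLDS):
        rows.append(
            {
                "state_label": s.label,
                "variant": config.variant.value,
                "admissible": s.admissible(config.variant),
                "reachable": s.label in reach,
            }
        )
    return pd.DataFrame(rows)
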