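"""Extraction, classification and safety certification of swap dances.

A *dance* is the joint trajectory through state space that two converged
agents play out greedily from the start state ``"100:001"`` until one of
them exits.  Dances fall into a small taxonomy:

* ``SAFE_MULTIHOLD_SWAP`` -- the objects end up swapped and at some point an
  object was held by both agents at once (the shared hold is what makes
  defection impossible).
* ``AGENT_HOLD_SWAP`` -- the objects end up swapped and at some point one
  agent held the other (the grip substitutes for the shared object hold).
* ``IMPLICIT_SWAP`` -- the objects end up swapped with neither protection:
  fast, but formally unsafe, relying on the threat that a defector could be
  grabbed before a slow exit completes.
* ``EXIT_NO_SWAP`` -- each agent leaves with its original object.
* ``OTHER`` -- anything else, including one agent leaving with both objects
  and trajectories that hit the step cap.

Safety is certified independently of the learned tables: a dance is safe iff
no visited state lets either agent, acting alone against a passive partner,
reach an exit holding both objects (the hypothetical defector is given a
certain exit, the worst case for the victim).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .game import (
    Action,
    Agent,
    GameConfig,
    JointState,
    START,
    is_legal,
    legal_actions,
    transition,
)
from .learning import LearnerConfig, QTables, greedy_action

__all__ = [
    "DanceLabel",
    "DanceStep",
    "Dance",
    "ActorMode",
    "extract_dance",
    "classify_dance",
    "is_safe",
    "convergence_step",
    "dance_to_json",
    "dance_to_dot",
]


class DanceLabel(enum.Enum):
    SAFE_MULTIHOLD_SWAP = "safe_multihold_swap"
    AGENT_HOLD_SWAP = "agent_hold_swap"
    IMPLICIT_SWAP = "implicit_swap"
    EXIT_NO_SWAP = "exit_no_swap"
    OTHER = "other"


SWAP_LABELS = frozenset(
    {DanceLabel.SAFE_MULTIHOLD_SWAP, DanceLabel.AGENT_HOLD_SWAP, DanceLabel.IMPLICIT_SWAP}
)


class ActorMode(enum.Enum):
    """How the acting agent is sequenced during extraction.

    ``SEEDED_RANDOM`` draws the actor i.i.d. Bernoulli(beta) per step, as in
    the learning protocol; the alternating modes produce deterministic
    canonical dances for inspection and testing.
    """

    SEEDED_RANDOM = "seeded-random-actor"
    A_FIRST_ALTERNATING = "A-first-alternating"
    B_FIRST_ALTERNATING = "B-first-alternating"


@dataclass(frozen=True)
class DanceStep:
    actor: Agent
    action: Action
    state: JointState  # state resulting from the action


@dataclass
class Dance:
    steps: list[DanceStep]
    start: JointState
    payoffs: tuple[float, float]
    non_terminating: bool = False
    label: Optional[DanceLabel] = None

    @property
    def terminated(self) -> bool:
        return bool(self.steps) and self.steps[-1].state.terminal

    def visited_states(self, include_terminal: bool = False) -> list[JointState]:
        """Start state plus every resulting state, in order."""
        out = [self.start]
        for st in self.steps:
            if st.state.terminal and not include_terminal:
                continue
            out.append(st.state)
        return out

    @property
    def final_state(self) -> Optional[JointState]:
        return self.steps[-1].state if self.steps else None

    def signature(self) -> list[DanceStep]:
        """Steps with cosmetic PASSes and failed exits dropped."""
        return [
            st
            for st in self.steps
            if st.action is not Action.PASS
            and not (st.action is Action.EXIT and not st.state.terminal)
        ]


def extract_dance(
    q: QTables,
    game_config: GameConfig,
    mode: ActorMode | str = ActorMode.SEEDED_RANDOM,
    seed: Optional[int] = None,
    beta: float = 0.5,
    step_cap: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Dance:
    """Simulate greedy play (no action noise) from the start state.

    Greedy ties are broken uniformly with the seeded generator, as are the
    actor draws (in ``SEEDED_RANDOM`` mode) and slow-exit outcomes.  If the
    step cap is reached the dance is flagged non-terminating and labelled
    ``OTHER``.
    """
    mode = ActorMode(mode)
    if rng is None:
        rng = np.random.default_rng(seed)
    state = START
    steps: list[DanceStep] = []
    payoff = [0.0, 0.0]
    for k in range(step_cap):
        if mode is ActorMode.SEEDED_RANDOM:
            actor = Agent.A if rng.random() < beta else Agent.B
        elif mode is ActorMode.A_FIRST_ALTERNATING:
            actor = Agent.A if k % 2 == 0 else Agent.B
        else:
            actor = Agent.B if k % 2 == 0 else Agent.A
        action = greedy_action(q, state, actor, action_noise_p=0.0, rng=rng)
        outcome = transition(state, actor, action, game_config).sample(rng)
        payoff[0] += outcome.reward_to_A
        payoff[1] += outcome.reward_to_B
        steps.append(DanceStep(actor, action, outcome.state))
        state = outcome.state
        if state.terminal:
            break
    dance = Dance(
        steps=steps,
        start=START,
        payoffs=(payoff[0], payoff[1]),
        non_terminating=not (steps and steps[-1].state.terminal),
    )
    dance.label = DanceLabel.OTHER if dance.non_terminating else classify_dance(dance)
    return dance


def classify_dance(dance: Dance) -> DanceLabel:
    """Assign the taxonomy label from the realised trajectory.

    Classification looks only at the holds, never at the learned tables:
    the ending decides swap / no-swap / other, and the intermediate states
    decide which protection (shared object hold, agent hold, or none) the
    swap relied on.
    """
    if dance.non_terminating or not dance.terminated:
        raise ValueError("cannot classify a non-terminating dance")
    final = dance.steps[-1].state
    a_sole_a, a_sole_b = final.sole_object_holds(Agent.A)
    b_sole_a, b_sole_b = final.sole_object_holds(Agent.B)
    swapped = a_sole_b and b_sole_a and not a_sole_a and not b_sole_b
    original = a_sole_a and b_sole_b and not a_sole_b and not b_sole_a
    if swapped:
        shared = any(
            (s.bits[0] and s.bits[3]) or (s.bits[2] and s.bits[5])
            for s in dance.visited_states()
        )
        if shared:
            return DanceLabel.SAFE_MULTIHOLD_SWAP
        agent_hold = any(
            s.bits[1] or s.bits[4] for s in dance.visited_states()
        )
        if agent_hold:
            return DanceLabel.AGENT_HOLD_SWAP
        return DanceLabel.IMPLICIT_SWAP
    if original:
        return DanceLabel.EXIT_NO_SWAP
    return DanceLabel.OTHER


def _defection_reachable(
    state: JointState, defector: Agent, config: GameConfig
) -> bool:
    """Can ``defector``, with the partner only passing, reach an exit in
    sole possession of both objects?  Exit success is taken as certain
    (worst case for the victim)."""
    seen = {state.bits}
    frontier = [state]
    while frontier:
        s = frontier.pop()
        sole_a, sole_b = s.sole_object_holds(defector)
        if sole_a and sole_b and is_legal(s, defector, Action.EXIT, config):
            return True
        for action in legal_actions(s, defector, config):
            if action in (Action.PASS, Action.EXIT):
                continue
            for o in transition(s, defector, action, config).outcomes:
                if not o.state.terminal and o.state.bits not in seen:
                    seen.add(o.state.bits)
                    frontier.append(o.state)
    return False


def is_safe(
    dance: Dance, game_config: GameConfig
) -> tuple[bool, Optional[JointState]]:
    """Certify a dance against unilateral defection.

    Returns ``(False, witness)`` where ``witness`` is the earliest visited
    non-terminal state from which either agent alone could leave with both
    objects while the partner passes; ``(True, None)`` otherwise.
    """
    if dance.non_terminating or not dance.terminated:
        raise ValueError("cannot certify a non-terminating dance")
    for s in dance.visited_states():
        for defector in Agent:
            if _defection_reachable(s, defector, game_config):
                return False, s
    return True, None


def convergence_step(policy_history: Sequence[np.ndarray]) -> int:
    """First iteration index from which the greedy joint policy never
    changes again; the history length if it never stabilises."""
    if len(policy_history) == 0:
        raise ValueError("empty policy history")
    last = len(policy_history) - 1
    for i in range(last, 0, -1):
        if not np.array_equal(policy_history[i], policy_history[i - 1]):
            return i
    return 0


def dance_to_json(dance: Dance) -> str:
    payload = {
        "start": dance.start.label,
        "label": dance.label.value if dance.label else None,
        "non_terminating": dance.non_terminating,
        "payoff_A": dance.payoffs[0],
        "payoff_B": dance.payoffs[1],
        "steps": [
            {
                "actor": st.actor.name,
                "action": st.action.name,
                "state": "EXIT:" + st.state.label if st.state.terminal else st.state.label,
            }
            for st in dance.steps
        ],
    }
    return json.dumps(payload, indent=1)


def dance_to_dot(dance: Dance) -> str:
    """Render the dance as a left-to-right DOT chain of states."""
    from .game import graph_to_dot

    g = nx.MultiDiGraph()
    prev = dance.start.label
    g.add_node(prev)
    for st in dance.steps:
        node = "EXIT" if st.state.terminal else st.state.label
        g.add_edge(prev, node, actor=st.actor.name, action=st.action.name)
        prev = node
    return graph_to_dot(g)
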