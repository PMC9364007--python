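"""Interleaved value-iteration learning of the exchange game.

Each agent maintains expected-return tables for (state, action) pairs --
four Q tables in all, Q[X][Y] holding the return *to* agent Y when agent X
acts -- plus one value function per agent.  Every iteration performs a full
synchronous Bellman sweep over all legal (state, action) pairs,

    Q_X^Y(s, d) = sum_{s'} P_X(s' | s, d) (R_X^Y(s, d, s') + gamma V^Y(s')),

then recomputes the values as the beta-weighted mixture of an agent's own
best action and the opponent's best response,

    V^A(s) = beta * max_d Q_A^A(s, d) + (1 - beta) * Q_B^A(s, e*),
    e* = argmax_e Q_B^B(s, e),

(and symmetrically for B with weights 1-beta, beta), with argmax ties broken
uniformly at random.  Zero-mean Gaussian noise may be added to the Q entries
each iteration; the noisy copy decides *which* actions d* and e* enter the
value mixture (breaking ties and exploring off-greedy responses) while the
mixture itself is evaluated on the clean tables, and the tables returned to
the caller are always the clean post-sweep Q of the final iteration.

The two processes are competing general-sum MDPs, so convergence is
detected on the greedy joint policy rather than on a contraction argument:
the run is declared converged once the greedy policy (its per-state mode,
when noise is active) has not changed for a window of iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .game import (
    ACTIONS,
    Action,
    Agent,
    CompiledGame,
    GameConfig,
    JointState,
    N_ACTIONS,
)

__all__ = [
    "LearnerConfig",
    "QTables",
    "ValueTables",
    "LearningResult",
    "init_tables",
    "bellman_update",
    "value_update",
    "add_q_noise",
    "bellman_residual",
    "greedy_policy",
    "greedy_action",
    "run_learning",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Learning hyper-parameters.

    ``gamma`` discounts future rewards per elementary action; ``beta`` is
    the probability that agent A is the one chosen to act next, entering
    learning only through the value mixture.  ``q_noise_sd`` is the standard
    deviation of the per-iteration Gaussian perturbation of the Q entries;
    ``action_noise_p`` is the probability a *simulated* actor plays a random
    legal action instead of its greedy one (it never enters the Bellman
    expectation).  Tables are initialised N(0, ``init_sd``).
    """

    gamma: float = 0.99
    beta: float = 0.5
    q_noise_sd: float = 0.05
    action_noise_p: float = 0.0
    init_sd: float = 0.05
    max_iterations: int = 1000
    convergence_window: int = 20
    residual_tol: float = 1e-9
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        for name in ("q_noise_sd", "action_noise_p", "init_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


IMPOSSIBLE = np.nan  # sentinel for illegal (state, action) entries


class QTables:
    """The four expected-return tables, as a (2, 2, |S|, 5) array.

    ``q[x, y, s, d]`` is the expected return to agent ``y`` when agent ``x``
    takes action ``d`` in state ``s``; illegal pairs hold NaN ("impossible",
    the crosses of the published matrices).
    """

    def __init__(self, game: CompiledGame, q: np.ndarray):
        if q.shape != (2, 2, game.n_states, N_ACTIONS):
            raise ValueError("Q array shape must be (2, 2, |S|, 5)")
        self.game = game
        self.q = q

    def copy(self) -> "QTables":
        return QTables(self.game, self.q.copy())

    def table(self, actor: Agent, beneficiary: Agent) -> np.ndarray:
        return self.q[actor, beneficiary]

    def lookup(self, actor: Agent, beneficiary: Agent, state: JointState,
               action: Action) -> float:
        return float(self.q[actor, beneficiary, self.game.index[state.bits], action])

    def to_json(self) -> str:
        """Serialise as state label -> action -> value, with an explicit
        "impossible" sentinel for illegal entries."""
        out = {}
        for x in Agent:
            for y in Agent:
                key = f"Q_{x.name}^{y.name}"
                tab = {}
                for i, label in enumerate(self.game.labels):
                    row = {}
                    for d in ACTIONS:
                        v = self.q[x, y, i, d]
                        row[d.name] = "impossible" if np.isnan(v) else float(v)
                    tab[label] = row
                out[key] = tab
        return json.dumps(out, indent=1)

    @classmethod
    def from_json(cls, game: CompiledGame, payload: str) -> "QTables":
        """Inverse of :meth:`to_json` over the same configured game."""
        data = json.loads(payload)
        q = np.full((2, 2, game.n_states, N_ACTIONS), IMPOSSIBLE)
        label_index = {label: i for i, label in enumerate(game.labels)}
        for x in Agent:
            for y in Agent:
                tab = data[f"Q_{x.name}^{y.name}"]
                for label, row in tab.items():
                    i = label_index[label]
                    for name, v in row.items():
                        if v != "impossible":
                            q[x, y, i, Action[name]] = float(v)
        return cls(game, q)

    def to_csv(self, actor: Agent, beneficiary: Agent) -> str:
        """One table as a CSV matrix: rows = states in canonical order,
        columns = the five actions."""
        import pandas as pd

        df = pd.DataFrame(
            self.q[actor, beneficiary],
            index=self.game.labels,
            columns=[a.name for a in ACTIONS],
        )
        df.index.name = "state"
        return df.to_csv()


class ValueTables:
    """Per-agent state values as a (2, |S|+1) array; the trailing slot is
    the absorbing terminal state and is pinned to exactly 0."""

    def __init__(self, game: CompiledGame, v: np.ndarray):
        if v.shape != (2, game.n_states + 1):
            raise ValueError("V array shape must be (2, |S|+1)")
        self.game = game
        self.v = v
        self.v[:, game.terminal_index] = 0.0

    def copy(self) -> "ValueTables":
        return ValueTables(self.game, self.v.copy())

    def value(self, agent: Agent, state: JointState) -> float:
        if state.terminal:
            return 0.0
        return float(self.v[agent, self.game.index[state.bits]])

    def to_json(self) -> str:
        out = {
            f"V^{y.name}": {
                label: float(self.v[y, i]) for i, label in enumerate(self.game.labels)
            }
            for y in Agent
        }
        return json.dumps(out, indent=1)


def init_tables(
    game: CompiledGame, config: LearnerConfig, rng: Optional[np.random.Generator] = None
) -> tuple[QTables, ValueTables]:
    """Gaussian N(0, init_sd) initialisation of all legal Q entries and all
    non-terminal values; illegal entries are marked impossible."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q = rng.normal(0.0, config.init_sd, size=(2, 2, game.n_states, N_ACTIONS))
    mask = np.broadcast_to(game.legal[:, None, :, :], q.shape)
    q[~mask] = IMPOSSIBLE
    v = rng.normal(0.0, config.init_sd, size=(2, game.n_states + 1))
    return QTables(game, q), ValueTables(game, v)


def bellman_update(
    q: QTables, v: ValueTables, game: CompiledGame, config: LearnerConfig
) -> QTables:
    """One synchronous sweep of the Bellman expectation over all four tables."""
    if q.game is not game or v.game is not game:
        raise ValueError("tables and game must share the same state space")
    new = np.empty_like(q.q)
    for y in Agent:
        vy = v.v[y]  # (S+1,), terminal slot 0
        # expectation over the (at most two) outcomes
        exp = np.sum(
            game.prob * (game.reward[..., y] + config.gamma * vy[game.succ]), axis=-1
        )
        new[:, y, :, :] = exp
    new[~np.broadcast_to(game.legal[:, None, :, :], new.shape)] = IMPOSSIBLE
    return QTables(game, new)


def _tiebreak_argmax(table: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax over a (S, 5) table with NaN-illegal entries, ties
    broken uniformly at random."""
    filled = np.where(np.isnan(table), -np.inf, table)
    mx = filled.max(axis=1, keepdims=True)
    ties = filled == mx
    keys = rng.random(table.shape)
    keys[~ties] = -1.0
    return keys.argmax(axis=1)


def value_update(
    q: QTables,
    config: LearnerConfig,
    rng: Optional[np.random.Generator] = None,
    selector: Optional[QTables] = None,
) -> ValueTables:
    """Recompute both value functions from the current Q tables.

    V^A mixes A's own best return (weight beta) with A's return under B's
    best response e* (weight 1-beta); V^B symmetrically.  Ties in every
    argmax are re-drawn uniformly at random each call.

    When ``selector`` is given (normally the noise-perturbed copy of ``q``),
    the argmaxes d* and e* are read from it while the mixture is evaluated
    on ``q`` itself.  Perturbing the *choice* rather than the stored value
    is what lets per-iteration Gaussian noise break ties and explore
    off-greedy responses without the unbounded upward bias that a max over
    persistently noisy values feeds back through the discount factor.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    game = q.game
    if selector is None:
        selector = q
    if not game.legal.any(axis=2).all():
        raise ValueError("every non-terminal state must afford a legal action")
    v = np.zeros((2, game.n_states + 1))
    best = {}
    for x in Agent:
        best[x] = _tiebreak_argmax(selector.q[x, x], rng)  # (S,) best own action of x
    rows = np.arange(game.n_states)
    for y in Agent:
        own_w = config.beta if y is Agent.A else 1.0 - config.beta
        other = Agent.B if y is Agent.A else Agent.A
        own_best = q.q[y, y][rows, best[y]]
        response = q.q[other, y][rows, best[other]]
        v[y, :-1] = own_w * own_best + (1.0 - own_w) * response
    return ValueTables(game, v)


def add_q_noise(
    q: QTables, config: LearnerConfig, rng: Optional[np.random.Generator] = None
) -> QTables:
    """Independent N(0, q_noise_sd) perturbation of every legal entry."""
    if config.q_noise_sd == 0.0:
        return q
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noisy = q.q + rng.normal(0.0, config.q_noise_sd, size=q.q.shape)
    # NaN + noise stays NaN, so impossibility markers are untouched
    return QTables(q.game, noisy)


def bellman_residual(
    q: QTables, v: ValueTables, game: CompiledGame, config: LearnerConfig
) -> float:
    """max |Q - Bellman RHS| over all legal entries."""
    rhs = bellman_update(q, v, game, config)
    diff = np.abs(rhs.q - q.q)
    return float(np.nanmax(diff))


def greedy_policy(q: QTables) -> np.ndarray:
    """Deterministic (first-index) greedy action of each agent per state,
    as a (2, |S|) integer array; used for convergence detection."""
    filled = np.where(np.isnan(q.q), -np.inf, q.q)
    return np.stack([filled[x, x].argmax(axis=1) for x in Agent])


def greedy_action(
    q: QTables,
    state: JointState,
    actor: Agent,
    action_noise_p: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Action:
    """The actor's greedy legal action (ties uniform), replaced with a
    uniformly random legal action with probability ``action_noise_p``."""
    if rng is None:
        rng = np.random.default_rng()
    if state.terminal:
        raise ValueError("terminal states afford no actions")
    game = q.game
    i = game.index[state.bits]
    legal = game.legal_indices(i, actor)
    if legal.size == 0:
        raise ValueError(f"no legal actions in state {state.label}")
    if action_noise_p > 0.0 and rng.random() < action_noise_p:
        return Action(int(rng.choice(legal)))
    row = q.q[actor, actor, i]
    vals = row[legal]
    mx = np.nanmax(vals)
    ties = legal[vals == mx]
    return Action(int(ties[rng.integers(ties.size)] if ties.size > 1 else ties[0]))


@dataclass
class LearningResult:
    q: QTables
    v: ValueTables
    iterations_to_convergence: int
    converged: bool
    n_iterations: int
    residual: float
    policy: np.ndarray
    policy_history: Optional[list[np.ndarray]] = None


def _greedy_support(game: CompiledGame, pol: np.ndarray) -> tuple[int, ...]:
    """States reachable from the start when both agents follow ``pol``."""
    seen = {game.start_index}
    frontier = [game.start_index]
    while frontier:
        i = frontier.pop()
        for x in Agent:
            d = pol[x, i]
            for k in range(2):
                if game.prob[x, i, d, k] > 0.0:
                    j = int(game.succ[x, i, d, k])
                    if j != game.terminal_index and j not in seen:
                        seen.add(j)
                        frontier.append(j)
    return tuple(sorted(seen))


def _window_mode(buffer: np.ndarray) -> np.ndarray:
    """Per-entry modal policy over a (W, 2, S) stack of policy snapshots."""
    w = buffer.shape[0]
    flat = buffer.reshape(w, -1)
    out = np.empty(flat.shape[1], dtype=np.int64)
    for j in range(flat.shape[1]):
        out[j] = np.bincount(flat[:, j], minlength=N_ACTIONS).argmax()
    return out.reshape(buffer.shape[1:])


def run_learning(
    game_config: GameConfig,
    learner_config: LearnerConfig,
    game: Optional[CompiledGame] = None,
    rng: Optional[np.random.Generator] = None,
    record_history: bool = False,
) -> LearningResult:
    """Iterate {Bellman sweep; Q noise; value update} to a stable joint policy.

    Noise-free runs stop once the greedy joint policy has been unchanged for
    ``convergence_window`` iterations *and* the sweep-to-sweep residual has
    dropped below ``residual_tol``; noisy runs stop once the per-state modal
    policy over the trailing window has been unchanged for a full window.
    ``iterations_to_convergence`` is the first iteration from which the
    (modal) policy never changed again.  Hitting ``max_iterations`` without
    policy stability returns ``converged=False`` with the tables as they
    stand.  The returned Q is the clean post-sweep table (noise excluded) --
    averaged over the trailing window in noisy runs, where the instantaneous
    sweeps jitter around the solution -- and V is recomputed from it.
    """
    if game is None:
        game = CompiledGame(game_config)
    if rng is None:
        rng = np.random.default_rng(learner_config.seed)
    cfg = learner_config
    noisy = cfg.q_noise_sd > 0.0
    w = cfg.convergence_window

    q, v = init_tables(game, cfg, rng)
    prev_q = q.q.copy()
    residual = np.inf
    history: list[np.ndarray] = []
    prev_pol: Optional[np.ndarray] = None
    stable_since = 0
    buffer: list[np.ndarray] = []
    q_buffer: list[np.ndarray] = []  # trailing clean sweeps, noisy mode only
    prev_mode: Optional[np.ndarray] = None
    mode_stable_since = 0
    converged = False
    it = 0

    for it in range(cfg.max_iterations):
        q = bellman_update(q, v, game, cfg)
        residual = float(np.nanmax(np.abs(q.q - prev_q)))
        prev_q = q.q.copy()

        pol = greedy_policy(q)
        if record_history:
            history.append(pol)
        if not noisy:
            if prev_pol is None or not np.array_equal(pol, prev_pol):
                stable_since = it
            prev_pol = pol
            if it - stable_since + 1 >= w and residual <= cfg.residual_tol:
                converged = True
                break
        else:
            buffer.append(pol)
            q_buffer.append(q.q)
            if len(buffer) > w:
                buffer.pop(0)
                q_buffer.pop(0)
            if len(buffer) == w:
                # Persistent noise keeps off-path near-ties flickering forever,
                # so stability is judged on the window-averaged greedy policy
                # restricted to the states that policy actually visits.
                avg = greedy_policy(QTables(game, np.mean(q_buffer, axis=0)))
                support = _greedy_support(game, avg)
                mode = (support, avg[:, support])
                if (
                    prev_mode is None
                    or prev_mode[0] != mode[0]
                    or not np.array_equal(mode[1], prev_mode[1])
                ):
                    mode_stable_since = it
                prev_mode = mode
                if it - mode_stable_since + 1 >= w:
                    converged = True
                    break

        noisy_q = add_q_noise(q, cfg, rng)
        v = value_update(q, cfg, rng, selector=noisy_q)

    if noisy and q_buffer:
        # Under persistent noise the clean sweeps jitter around the solution;
        # the time-average over the trailing window is the stable read-out.
        q = QTables(game, np.mean(q_buffer, axis=0))
    v = value_update(q, cfg, rng)
    first_stable = stable_since if not noisy else mode_stable_since
    return LearningResult(
        q=q,
        v=v,
        iterations_to_convergence=first_stable,
        converged=converged,
        n_iterations=it + 1,
        residual=residual,
        policy=greedy_policy(q),
        policy_history=history if record_history else None,
    )
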