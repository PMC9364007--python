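# Methods

## The game

Two agents, A and B, start holding one object each (A holds a, B holds b)
and each values the other's object more highly. The joint state is the
sextuple of hold bits (A-holds-a, A-holds-B, A-holds-b, B-holds-a,
B-holds-A, B-holds-b), rendered as `"xyz:uvw"`; a single absorbing terminal
state marks the end of the interaction. Five actions are available to the
acting agent: toggle each of its three holds, pass, or attempt to exit.
Toggles act only on the actor's own hold bits — no agent can release a hold
the other maintains. An exit is legal only when leaving would break no
hold: the actor must not be held by its partner and must share no object
hold with it. A legal exit succeeds with probability `p_exit`; on success
both agents are paid the value of each object they solely hold (an object
held by neither is forfeited, paid to nobody), so a completed swap pays
each agent its preferred good and a unilateral defection pays 5 against 0
at the default values (1, 4).

Costs are charged per elementary step: `cost_step` to both agents for being
in the game, `cost_maintain` per hold an agent currently maintains,
`cost_grab` to the actor when a toggle establishes a new hold, and
`cost_illegal` to the actor of a forbidden attempt (which is otherwise a
no-op). Illegal (state, action) pairs are marked impossible in the learned
tables, so a greedy agent never plays them; `cost_illegal` matters only for
the transition model itself.

Four hold variants restrict the admissible states and the toggles that
remain legal: `ALL_HOLDS` (64 states), `EXCLUSIVE_OBJECT_HOLDS` (an object
may be held by at most one agent; 36), `NO_AGENT_HOLDS` (16), and their
conjunction (9 hold configurations; 10 states counting the terminal
marker — both counts are exposed by `enumerate_states`).

## Learning

Learning is exact and tabular: interleaved value iteration on the four
expected-return tables Q_X^Y over all legal (state, action) pairs, fully
synchronous per iteration, followed by the β-weighted value mixture
(an agent's value mixes its own best action, probability β of acting next,
with the opponent's best response e*). Terminal value is pinned to zero.
The expectation runs over transition stochasticity only (the two-outcome
slow exit); it is decoupled from trajectory simulation, which is used only
to extract dances after convergence.

Per-iteration Gaussian Q noise is implemented as *selection* noise: the
noisy copy of the tables decides which actions enter the value mixture as
d* and e*, while the mixture evaluates the clean values at those selections.
This gives noise its two intended functions — uniform tie-breaking and
exploration of off-greedy responses — without the divergence that afflicts
value-level noise under a max operator: adding N(0, σ) into the maximised
values inflates every state value by ≈ 1.16 σ per sweep, which the discount
factor compounds into a bias of order σ/(1 − γ); at γ = 0.99 agents then
learn to pass forever to harvest the phantom reward, and no run converges.
Action noise (`action_noise_p`) affects only simulated play, never the
Bellman expectation, and greedy dance extraction runs without it; with the
full-sweep learner it is therefore a pure play-time parameter.

Convergence is detected on the greedy joint policy, not on a contraction
argument (the two coupled processes form a general-sum game). Noise-free
runs stop once the policy has been unchanged for `convergence_window`
(default 20) iterations *and* the sweep-to-sweep residual has fallen below
`residual_tol` (default 1e-9); the reported iterations-to-convergence is
the first iteration from which the policy never changed again. Under
noise, off-path near-ties flicker indefinitely, so stability is judged on
the window-averaged greedy policy restricted to the states that policy
actually visits from the start state, and the tables returned are the
clean post-sweep tables averaged over the trailing window — the stable
read-out of a solution that jitters around its fixed point. Runs are
capped at `max_iterations` (default 1000) and report `converged=False`
beyond it, with tables returned rather than raised.

## Dances, classification, safety

A dance is extracted by greedy play from `100:001` (actor drawn
Bernoulli(β) per step, as during learning; deterministic alternating modes
exist for inspection), sampling slow-exit outcomes, up to a step cap of 50
(the learned dances need ≤ ~10; a capped trajectory is labelled OTHER).
Classification looks only at the realised holds: the final state decides
swapped / original / other, and the intermediate states decide which
protection the swap relied on — a shared object hold (safe multihold), an
agent hold, or neither (implicit). Cosmetic passes and failed exit
attempts are dropped from the step signature. Safety is certified
independently of the learned tables by brute-force search: a dance is
unsafe iff some visited state lets either agent alone, against a passive
partner and with a certain exit (the worst case for the victim), reach an
exit in sole possession of both objects; the earliest such state is
returned as witness.

## Default parameters and how they were chosen

The cost magnitudes, discount factor, noise scale and exit probability are
free parameters of the model; the defaults below were calibrated once so
that the simulator operates in the regime where the documented phenomena
occur, and then frozen. What matters is their existence and order of
magnitude, not their exact values.

| parameter | default | rationale |
|---|---|---|
| value_own / value_other | 1 / 4 | classic linear prisoner's-dilemma-style payoffs; defection pays 5 |
| γ (discount) | 0.99 | a swap needs ~5 elementary actions, so the swap-vs-exit margin at value ratio r is ≈ r·γ⁴ − 1; γ ≥ ~0.98 is required for exchange to survive down to r = 1.2 |
| β | 0.5 | symmetric reaction times |
| q_noise_sd, init_sd | 0.05 | tables are initialised with the same sd as the per-iteration noise; 1.25% of the high value — enough to break ties and explore, far below the decision margins |
| cost_grab | 0.02 | establishing a hold must cost something for hold-free solutions to be distinguishable |
| cost_maintain, cost_step | 0.002 | keep dances short and passes non-free without distorting payoffs |
| cost_illegal | 0.5 | deterrent priced above any single-step gain |
| p_exit | 1.0 | exits are immediate unless the slow-exit mechanism is being studied |

The **implicit-hold setting** (`implicit_hold_config`) is the combination
under which the fast, hold-free swap emerges as the learned optimum:
exclusive object holds (so the shared-hold dance is unavailable), slow exit
`p_exit = 0.1`, `cost_grab = 0.1`, `cost_maintain = 0.05`. Each piece is
load-bearing. The slow exit makes the implicit threat credible: a defector
grabbing both objects is almost surely grabbed by its victim before an exit
succeeds. At `p_exit` = 0.5 deterrence fails arithmetically — defection
from a hold-both state then wins ≈ 0.5·5 + 0.5·(punished ≈ 4 − delay) > 4,
because being caught merely forces the swap anyway — and the learned
behaviour collapses to exit-without-exchange or punished defections.
Maintaining holds must be costly so that capture is a real punishment, and
grabbing must be costly enough that the explicit agent-hold choreography
(three grabs) loses to the implicit one (two).

With these defaults the four taxonomy branches are produced by four
settings: unrestricted holds → safe multihold swap (modal in ≈100% of
runs); exclusive object holds with fast exit → agent-hold swap (≈70%);
the implicit setting → implicit swap (≈90%); both restrictions together →
exit without exchange (≈100%).

## The discount threshold

Scanning γ over {0.95, 0.9, 0.85, 0.8, 0.7, 0.6}: under the unrestricted
default variant exchange persists at γ = 0.8 and collapses to mutual exit
below it (the safe multihold dance advances at every step regardless of
which agent is drawn, so its per-action discount is the full γ and the
break-even sits near 4γ⁴ ≈ 1). Under the exclusive-variant settings the
cooperative routes contain states where only one agent has a useful move;
the idle draw acts as a pass, capping the per-step factor at γ/(2 − γ),
and those dances are already unprofitable at γ = 0.8. The largest
no-exchange γ on the grid is therefore 0.7 for the default variant and 0.8
for the implicit setting; both readings are computed by
`find_gamma_threshold`, and the acceptance script reports the
implicit-setting value per its stated setup.

## What the simulator does and does not capture

All inputs are generated by the model itself; there is no external data.
The simulator explores the full (≤ 64-state) joint space exactly, so its
results are properties of the game, not of sampling. It does not model
spatial structure, more than two agents, repeated interactions or
reputation, asymmetric action repertoires, or any evolutionary dynamics;
"hold" is the only physical primitive. Learned equilibria are local optima
reached by greedy interleaved value iteration from random initialisation —
no claim of uniqueness is made, and run-to-run variability (the batch
frequencies) reflects genuine multistability, not measurement error.

## Numerical choices and problem sizes

Argmax ties are broken uniformly at random, re-drawn per iteration;
convergence snapshots use a deterministic first-index argmax so that
tie-flicker does not mask stability. The Bellman sweep is fully vectorised
over precompiled two-outcome transition arrays, so a run is a few
milliseconds and the standard batch — one hundred seeded runs per parameter
point, the scale used throughout the tests and the acceptance script —
takes seconds per point on one CPU. Batches are reproducible end to end:
run r of a batch uses seed `base_seed + r` for initialisation, tie-breaks,
noise, actor draws and exit outcomes alike, and identical specs produce
byte-identical CSV output.
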