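# swapdance

Two strangers each hold an object the other wants more. Neither trusts the
other, there is no third party, and whoever ends up holding both objects is
free to walk away with them. Under what physical rules can such a one-shot
exchange happen at all — and happen *safely*?

`swapdance` implements this question as a small competitive stochastic game
between two independently learning agents, and reproduces the emergent
choreographies ("swap dances") by which selfish agents settle on exchange as
a local optimum.

## The model

The joint state is six bits, written `"xyz:uvw"`: what agent A holds
(object a, agent B, object b) and what agent B holds (object a, agent A,
object b). The start state is `100:001` — each agent holds its own,
lower-valued good — and the mutually desired final state is `001:100`. Each
turn a random agent acts with one of five actions: toggle its hold on either
object, toggle its hold on the other agent, pass, or attempt to exit. An
exit ends the game and pays each agent the value of the objects it solely
holds (by default 1 for its own good, 4 for the other's). Establishing a
hold, maintaining a hold, attempting a forbidden action, and simply being in
the game all carry small configurable costs; an exit attempt succeeds only
with probability `p_exit` (a "slow exit" gives the partner time to react).

Each agent X maintains expected-return tables Q_X^Y(s, d) — the return *to*
agent Y when X takes action d in state s, four tables in all — updated by
synchronous Bellman sweeps

    Q_X^Y(s, d) = Σ_s' P_X(s' | s, d) [ R_X^Y(s, d, s') + γ V^Y(s') ],

with the value of a state mixing an agent's own best action and the
opponent's best response e* (β is the probability that A acts next):

    V^A(s) = β max_d Q_A^A(s, d) + (1 − β) Q_B^A(s, e*),
    e* = argmax_e Q_B^B(s, e).

Zero-mean Gaussian noise perturbs which actions are selected each iteration,
breaking ties and driving exploration. Four *hold variants* restrict the
admissible states: all holds (64 states), exclusive object holds (36), no
agent holds (16), and both restrictions (9 hold configurations, 10 states
counting the terminal marker).

Converged runs are rolled out greedily from `100:001` and the resulting
trajectory is classified: a **safe multihold swap** (some object is held by
both agents at once, which makes defection impossible), an **agent-hold
swap** (one agent grips the other instead), an **implicit swap** (no
protective hold at all — fast but formally unsafe, relying on the threat
that a defector could be grabbed before a slow exit completes), an **exit
without swapping**, or anything else. A separate brute-force certifier
checks safety: could either agent, from any visited state, have walked off
with both objects against a passive partner?

## A worked example

```
$ swapdance run --seed 3
converged: True (policy stable from iteration 19, 39 sweeps)
dance: safe_multihold_swap
  B TOGGLE_OBJECT_A  -> 100:101
  A TOGGLE_OBJECT_B  -> 101:101
  B TOGGLE_OBJECT_B  -> 101:100
  A TOGGLE_OBJECT_A  -> 001:100
  B EXIT             -> EXIT
payoffs: A=3.956 B=3.956
safe: True
```

The agents learned the canonical safe exchange: B grabs a (now shared), A
grabs b (now shared), then each releases its own good and either agent
leaves. At no intermediate state could either agent have defected with both
objects — each good is pinned by a shared hold until its new owner has sole
possession — and each agent nets its preferred good (value 4) minus the
small grab/maintain/step costs. With `--implicit` the exclusive-variant,
slow-exit, costly-grab setting is applied instead and the agents learn the
fast hold-free swap that human exchanges resemble:

```
$ swapdance run --implicit --seed 3
dance: implicit_swap
  B TOGGLE_OBJECT_B  -> 100:000
  ...
  A TOGGLE_OBJECT_A  -> 000:000
  B TOGGLE_OBJECT_A  -> 000:100
  A TOGGLE_OBJECT_B  -> 001:100
  ...
  A EXIT             -> EXIT
```

Both agents simply drop their goods and cross-collect; the repeated failed
`EXIT` attempts are the slow exit at work — precisely what makes defection
unprofitable along the way. `swapdance batch`, `swapdance sweep` and
`swapdance report` run the hundred-seed batches and parameter grids and
write `sweep.csv` summaries.

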