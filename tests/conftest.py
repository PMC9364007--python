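"""Shared fixtures: compiled games and converged learning runs.

Learning runs are session-scoped -- they are deterministic for a fixed seed,
and several test modules probe different aspects of the same converged
solution.
"""

from __future__ import annotations

import numpy as np
import pytest

from swapdance import (
    BatchSpec,
    CompiledGame,
    GameConfig,
    HoldVariant,
    LearnerConfig,
    implicit_hold_config,
    run_batch,
    run_learning,
)


@pytest.fixture(scope="session")
def default_game() -> GameConfig:
    return GameConfig()


@pytest.fixture(scope="session")
def compiled_default(default_game) -> CompiledGame:
    return CompiledGame(default_game)


@pytest.fixture(scope="session")
def noise_free_learner() -> LearnerConfig:
    return LearnerConfig(q_noise_sd=0.0, init_sd=0.01, seed=11)


@pytest.fixture(scope="session")
def converged_default(default_game, compiled_default, noise_free_learner):
    """A converged noise-free run on the unrestricted variant."""
    res = run_learning(default_game, noise_free_learner, game=compiled_default)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def implicit_game() -> GameConfig:
    return implicit_hold_config()


@pytest.fixture(scope="session")
def converged_implicit(implicit_game):
    res = run_learning(implicit_game, LearnerConfig(seed=3))
    assert res.converged
    return res


@pytest.fixture(scope="session")
def agent_hold_game() -> GameConfig:
    return GameConfig(variant=HoldVariant.EXCLUSIVE_OBJECT_HOLDS)


@pytest.fixture(scope="session")
def converged_agent_hold(agent_hold_game):
    """A run in the exclusive-object-holds variant that learned the
    agent-hold choreography (seed chosen among the ~70% that do)."""
    from swapdance import DanceLabel, extract_dance

    for seed in range(20):
        res = run_learning(agent_hold_game, LearnerConfig(seed=seed))
        dance = extract_dance(res.q, agent_hold_game, seed=seed)
        if dance.label is DanceLabel.AGENT_HOLD_SWAP:
            return res
    pytest.fail("no agent-hold run found in 20 seeds")
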