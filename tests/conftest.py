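"""Shared fixtures: models and trajectories reused across test modules.

Long stochastic integrations are expensive, so trajectories are
session-scoped; tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import growthnoise as gn


@pytest.fixture(scope="session")
def toy_model() -> gn.CellModel:
    return gn.make_two_protein_toy()


@pytest.fixture(scope="session")
def toy_lnm(toy_model) -> gn.LinearNoiseModel:
    return gn.linearize(toy_model)


@pytest.fixture(scope="session")
def toy_traj(toy_model) -> gn.Trajectory:
    """A 400 h toy trajectory for distributional checks (not the long
    acceptance run)."""
    return gn.simulate(toy_model, duration=400.0, dt=1e-3, seed=11)


@pytest.fixture(scope="session")
def small_built_model() -> gn.CellModel:
    """A reduced many-protein model (60 background species) for cheap
    structural checks."""
    return gn.build("intermediate", seed=5, n_background=60)


@pytest.fixture(scope="session")
def built_models() -> dict[str, gn.CellModel]:
    """Full-size models for the three growth conditions (fast to build;
    no trajectory simulation is run on them)."""
    return {name: gn.build(name, seed=1) for name in ("slow", "intermediate", "fast")}
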