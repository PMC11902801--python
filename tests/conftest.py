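"""Shared fixtures.

The expensive self-assembly runs (scaled-down capsule boxes) are
session-scoped so structural tests share a single set of trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest

from mesocapsule.builder import BoxSpec, SimulationState, build_system
from mesocapsule.engine import EngineParams, run_simulation
from mesocapsule.parameters import default_interactions
from mesocapsule.presets import desk_scale, load_recipes
from mesocapsule.topology import standard_templates

STRUCTURE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def interactions():
    return default_interactions()


@pytest.fixture(scope="session")
def templates():
    return standard_templates()


@pytest.fixture(scope="session")
def recipes():
    return load_recipes()


def make_state(
    positions: np.ndarray,
    L: float,
    species: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    bonds: np.ndarray | None = None,
    seed: int = 0,
) -> SimulationState:
    """Hand-built state for unit tests (density inferred from bead count)."""
    n = len(positions)
    return SimulationState(
        positions=np.asarray(positions, dtype=float) % L,
        velocities=np.zeros((n, 3)) if velocities is None else np.asarray(velocities, float),
        species=np.array(["W"] * n) if species is None else np.asarray(species),
        bonds=np.empty((0, 2), dtype=np.int64) if bonds is None else np.asarray(bonds),
        box=BoxSpec(side_length=L, number_density=n / L**3),
        rng_seed=seed,
    )


def _capsule_run(label: str, n_steps: int, seed: int):
    recipes = load_recipes()
    manifest = desk_scale(label, L=12.0, n_steps=n_steps, seed=seed)
    state = build_system(recipes[label], manifest.box(), seed)
    return run_simulation(state, manifest.engine_params())


@pytest.fixture(scope="session")
def cts_citral_runs():
    """Scaled-down chitosan-citral self-assembly, three seeds (L=12)."""
    return [_capsule_run("Cts-Citral (5)", 40_000, s) for s in STRUCTURE_SEEDS]


@pytest.fixture(scope="session")
def alg_citral_runs():
    """Scaled-down alginate-citral self-assembly, three seeds (L=12)."""
    return [_capsule_run("Alg-Citral (3)", 20_000, s) for s in STRUCTURE_SEEDS]


@pytest.fixture(scope="session")
def pure_water_equilibrated():
    """3000-bead pure-solvent box after 10,000 thermostatted steps."""
    from mesocapsule.builder import CompositionRecipe

    state = build_system(CompositionRecipe("pure", {"H2O": 100.0}), BoxSpec(10.0), seed=11)
    params = EngineParams(n_steps=10_000, frame_interval=500)
    traj = run_simulation(state, params)
    return state, traj
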