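"""DPD time integration.

The equations of motion follow the standard soft-sphere DPD force field:
a linear conservative repulsion ``F_C = a_ij (1 - r) e_ij`` inside the
cut-off, a pairwise dissipative force ``F_D = -gamma (1-r)^2 (e.v) e`` and
a pairwise random force ``F_R = sigma (1-r) theta dt^{-1/2} e`` that
together thermostat the system (fluctuation-dissipation fixes
``sigma^2 = 2 gamma k_BT``), plus zero-rest-length harmonic bonds along
the polymer chains.  Integration uses the modified velocity-Verlet scheme
with predictor weight lambda.

All forces are pairwise antisymmetric, so total momentum is conserved to
floating-point accumulation error at every step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .builder import SimulationState
from .parameters import ALL_SPECIES, InteractionMatrix, default_interactions

__all__ = [
    "EngineParams",
    "Trajectory",
    "conservative_force",
    "dissipative_random_forces",
    "bond_force",
    "neighbor_pairs",
    "integrate_step",
    "run_simulation",
    "kinetic_temperature",
    "EngineInstability",
]

_SPECIES_INDEX = {s: i for i, s in enumerate(ALL_SPECIES)}


class EngineInstability(RuntimeError):
    """A bead moved more than half the box in one step (or NaN appeared)."""


@dataclass(frozen=True)
class EngineParams:
    """Integration parameters, reduced units.

    sigma is always derived from gamma and kBT through the
    fluctuation-dissipation relation sigma^2 = 2 gamma kBT.
    """

    dt: float = 0.05
    gamma: float = 4.5
    kBT: float = 1.0
    lambda_vv: float = 0.65
    bond_k: float = 4.0
    r_c: float = 1.0
    n_steps: int = 250_000
    frame_interval: int = 5_000
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0 or self.kBT <= 0:
            raise ValueError("gamma must be >= 0 and kBT > 0")
        if self.n_steps % self.frame_interval and self.n_steps > 0:
            raise ValueError(
                f"frame_interval {self.frame_interval} does not divide n_steps {self.n_steps}"
            )
        object.__setattr__(self, "sigma", math.sqrt(2.0 * self.gamma * self.kBT))

    @property
    def n_frames(self) -> int:
        """Saved frames including the initial one."""
        return self.n_steps // self.frame_interval + 1


@dataclass
class Trajectory:
    """Periodic snapshots of one run (wrapped + unwrapped coordinates)."""

    steps: np.ndarray  # (F,)
    wrapped: np.ndarray  # (F, N, 3)
    unwrapped: np.ndarray  # (F, N, 3)
    species: np.ndarray  # (N,)
    bonds: np.ndarray  # (B, 2)
    box_length: float
    seed: int
    dt: float

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def n_beads(self) -> int:
        return self.wrapped.shape[1]

    def times(self) -> np.ndarray:
        return self.steps * self.dt

    def frame_state(self, f: int):
        """(step, wrapped positions, unwrapped positions) of frame f."""
        return self.steps[f], self.wrapped[f], self.unwrapped[f]


def conservative_force(r_vec: np.ndarray, a_ij: float, r_c: float = 1.0) -> np.ndarray:
    """Soft repulsion a_ij (1 - r/r_c) along the pair axis, zero beyond r_c.

    `r_vec` points from bead j to bead i; the returned force acts on i.
    """
    r = float(np.linalg.norm(r_vec))
    if r >= r_c:
        return np.zeros(3)
    if r == 0.0:
        rng = np.random.default_rng(0)
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        return a_ij * e  # capped degenerate case
    return a_ij * (1.0 - r / r_c) * (np.asarray(r_vec) / r)


def dissipative_random_forces(
    r_vec: np.ndarray,
    v_rel: np.ndarray,
    gamma: float,
    sigma: float,
    dt: float,
    noise: float,
    r_c: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissipative and random pair forces on bead i (Groot-Warren weights).

    w_D = (1-r)^2, w_R = (1-r); `noise` is a zero-mean unit-variance
    symmetric variate shared by the pair; both vanish beyond the cut-off.
    """
    r = float(np.linalg.norm(r_vec))
    if r >= r_c or r == 0.0:
        return np.zeros(3), np.zeros(3)
    e = np.asarray(r_vec) / r
    w = 1.0 - r / r_c
    f_d = -gamma * w * w * float(np.dot(e, v_rel)) * e
    f_r = sigma * w * noise / math.sqrt(dt) * e
    return f_d, f_r


def bond_force(r_vec: np.ndarray, bond_k: float) -> np.ndarray:
    """Harmonic restoring force -k r (zero rest length) on bead i."""
    return -bond_k * np.asarray(r_vec, dtype=float)


def _pack(state: SimulationState, interactions: InteractionMatrix | None):
    interactions = interactions or default_interactions()
    sidx = np.array([_SPECIES_INDEX[s] for s in state.species], dtype=np.int64)
    A = interactions.as_array(ALL_SPECIES)
    L = state.box.side_length
    ncell = int(L)  # cell edge >= r_c = 1
    if ncell < 3:
        ncell = 0  # brute-force fallback inside the kernel
    n = state.n_beads
    nbr = _kernels.build_neighbor_table(max(ncell, 1))
    order = np.empty(n, dtype=np.int64)
    start = np.zeros(max(ncell, 1) ** 3 + 1, dtype=np.int64)
    return sidx, A, L, ncell, nbr, order, start


def neighbor_pairs(state: SimulationState) -> np.ndarray:
    """All periodic minimum-image pairs with r < r_c, as a (P, 2) array."""
    L = state.box.side_length
    ncell = int(L)
    if ncell < 3:
        warnings.warn("box too small for a cell decomposition; using all pairs", stacklevel=2)
        d = state.positions[:, None, :] - state.positions[None, :, :]
        d -= L * np.rint(d / L)
        r2 = (d**2).sum(axis=-1)
        ii, jj = np.where(np.triu(r2 < 1.0, k=1))
        return np.column_stack([ii, jj]).astype(np.int64)
    nbr = _kernels.build_neighbor_table(ncell)
    pairs = _kernels.cell_list_pairs(np.ascontiguousarray(state.positions), L, ncell, nbr)
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.array(pairs, dtype=np.int64)
    return arr[np.lexsort((arr[:, 1], arr[:, 0]))]


def _ensure_forces(state, params, sidx, A, L, ncell, nbr, order, start):
    if state.forces is None or state.forces.shape != state.positions.shape:
        state.forces = np.zeros_like(state.positions)
        _kernels.compute_forces(
            state.positions, state.velocities, sidx, A, state.bonds,
            params.bond_k, L, params.gamma, params.sigma, params.dt,
            state.step, state.rng_seed % 2**31, state.forces, ncell, nbr, order, start,
        )


def integrate_step(
    state: SimulationState,
    params: EngineParams,
    interactions: InteractionMatrix | None = None,
    n_steps: int = 1,
) -> SimulationState:
    """Advance the state in place by `n_steps` modified velocity-Verlet steps."""
    sidx, A, L, ncell, nbr, order, start = _pack(state, interactions)
    _ensure_forces(state, params, sidx, A, L, ncell, nbr, order, start)
    vtilde = np.empty_like(state.velocities)
    newf = np.empty_like(state.forces)
    status = _kernels.run_steps(
        state.positions, state.unwrapped, state.velocities, state.forces,
        sidx, A, state.bonds, params.bond_k, L,
        params.gamma, params.sigma, params.dt, params.lambda_vv,
        state.rng_seed % 2**31, state.step, n_steps,
        ncell, nbr, order, start, vtilde, newf,
    )
    if status == _kernels.UNSTABLE:
        raise EngineInstability(
            f"displacement exceeded half the box at step ~{state.step}; reduce dt"
        )
    if status == _kernels.NAN or not np.all(np.isfinite(state.positions)):
        raise EngineInstability(f"non-finite positions at step ~{state.step}")
    state.step += n_steps
    return state


def run_simulation(
    state: SimulationState,
    params: EngineParams,
    interactions: InteractionMatrix | None = None,
) -> Trajectory:
    """Run the full simulation, saving a frame every `frame_interval` steps.

    The initial configuration is frame 0, so n_steps / frame_interval + 1
    frames are returned.  Bit-deterministic for a given (state, seed).
    """
    n_frames = params.n_frames
    n = state.n_beads
    steps = np.empty(n_frames, dtype=np.int64)
    wrapped = np.empty((n_frames, n, 3))
    unwrapped = np.empty((n_frames, n, 3))
    steps[0] = state.step
    wrapped[0] = state.positions
    unwrapped[0] = state.unwrapped
    for f in range(1, n_frames):
        integrate_step(state, params, interactions, n_steps=params.frame_interval)
        steps[f] = state.step
        wrapped[f] = state.positions
        unwrapped[f] = state.unwrapped
    return Trajectory(
        steps=steps,
        wrapped=wrapped,
        unwrapped=unwrapped,
        species=state.species.copy(),
        bonds=state.bonds.copy(),
        box_length=state.box.side_length,
        seed=state.rng_seed,
        dt=params.dt,
    )


def kinetic_temperature(state_or_vel) -> float:
    """Instantaneous kinetic temperature m<v^2>/3 (unit bead mass)."""
    vel = getattr(state_or_vel, "velocities", state_or_vel)
    return float((vel**2).sum() / (3.0 * len(vel)))
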