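"""System builder: composition recipe -> randomized initial configuration.

A recipe gives the volume fraction of each component (water, wall
polymers, citral).  Because every bead occupies the same coarse-grained
volume, volume fractions equal bead-number fractions; the builder turns
them into whole-molecule counts for a periodic cubic box at number density
rho and places the molecules at random, polymers as random walks with the
bond length near its equilibrium value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .topology import MoleculeTemplate, expand_template, standard_templates

__all__ = [
    "CompositionRecipe",
    "BoxSpec",
    "SimulationState",
    "recipe_to_counts",
    "init_configuration",
    "build_system",
    "dehydrated_composition",
]

#: initial bond length for chain placement; balance point of the default
#: harmonic spring (k=4, zero rest length) against a_ii(1-r) soft repulsion.
INIT_BOND_LENGTH = 0.86

COMPONENTS = ("H2O", "Cts", "Alg", "MC", "Citral")


@dataclass(frozen=True)
class CompositionRecipe:
    """Volume fractions (percent) of one simulated system."""

    label: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if "H2O" not in self.fractions:
            raise ValueError(f"{self.label}: recipe must include H2O")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError(f"{self.label}: fractions must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 0.15:
            raise ValueError(f"{self.label}: fractions sum to {total:.2f}, not 100 +- 0.15")

    def nonzero(self) -> dict[str, float]:
        return {k: v for k, v in self.fractions.items() if v > 0}


@dataclass(frozen=True)
class BoxSpec:
    """Cubic periodic box in reduced units."""

    side_length: float
    number_density: float = 3.0

    def __post_init__(self) -> None:
        if self.side_length <= 2:
            raise ValueError("box side must exceed 2 r_c for minimum-image validity")
        if self.number_density <= 0:
            raise ValueError("number density must be positive")

    @property
    def n_beads(self) -> int:
        return round(self.number_density * self.side_length**3)

    @property
    def volume(self) -> float:
        return self.side_length**3


@dataclass
class SimulationState:
    """Complete per-bead state of one DPD system."""

    positions: np.ndarray  # (N, 3) wrapped into [0, L)
    velocities: np.ndarray  # (N, 3)
    species: np.ndarray  # (N,) unicode labels
    bonds: np.ndarray  # (B, 2) int
    box: BoxSpec
    step: int = 0
    rng_seed: int = 0
    molecule_id: np.ndarray | None = None  # (N,) which molecule each bead belongs to
    unwrapped: np.ndarray | None = None  # (N, 3) trajectory-continuous coordinates
    forces: np.ndarray = field(default=None)  # filled by the engine

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.unwrapped is None:
            self.unwrapped = self.positions.copy()
        if n != self.box.n_beads:
            raise ValueError(f"bead count {n} != round(rho L^3) = {self.box.n_beads}")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def total_momentum(self) -> np.ndarray:
        return self.velocities.sum(axis=0)


def recipe_to_counts(
    recipe: CompositionRecipe,
    box: BoxSpec,
    templates: dict[str, MoleculeTemplate] | None = None,
) -> dict[str, int]:
    """Whole-molecule counts realizing a recipe in a given box.

    Each non-water component gets ``floor(fraction * N_total / beads_per_
    molecule)`` molecules; water absorbs the remaining beads so the total
    is exactly ``round(rho L^3)``.  A nonzero fraction that rounds to zero
    molecules raises a warning (box too small for that component).
    """
    templates = templates or standard_templates()
    total = box.n_beads
    counts: dict[str, int] = {}
    used = 0
    for comp, frac in recipe.nonzero().items():
        if comp == "H2O":
            continue
        beads_per = templates[comp].n_beads
        n_mol = math.floor(frac / 100.0 * total / beads_per)
        if n_mol == 0:
            warnings.warn(
                f"{recipe.label}: component {comp} at {frac}% yields 0 molecules "
                f"in a {total}-bead box ({beads_per} beads/molecule); increase the box",
                stacklevel=2,
            )
        counts[comp] = n_mol
        used += n_mol * beads_per
    if used > total:
        raise ValueError(f"{recipe.label}: non-water beads ({used}) exceed box budget ({total})")
    counts["H2O"] = total - used  # 1 bead per water molecule
    return counts


def dehydrated_composition(recipe: CompositionRecipe) -> dict[str, float]:
    """Renormalize the non-water fractions to percent of dry matter."""
    dry = {k: v for k, v in recipe.nonzero().items() if k != "H2O"}
    if not dry:
        raise ValueError(f"{recipe.label}: water-only recipe has no dry composition")
    total = sum(dry.values())
    return {k: 100.0 * v / total for k, v in dry.items()}


def _place_chain(
    rng: np.ndarray, n_beads: int, bonds: list[tuple[int, int]], L: float
) -> np.ndarray:
    """Random-walk placement of one molecule; bonded neighbors at
    INIT_BOND_LENGTH, free wrapping across the periodic boundary."""
    pos = np.empty((n_beads, 3))
    pos[0] = rng.uniform(0.0, L, 3)
    placed = np.zeros(n_beads, dtype=bool)
    placed[0] = True
    # breadth-first over the bond tree so every bead is set from a placed neighbor
    adj: dict[int, list[int]] = {i: [] for i in range(n_beads)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    stack = [0]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if not placed[j]:
                step = rng.normal(size=3)
                step *= INIT_BOND_LENGTH / np.linalg.norm(step)
                pos[j] = pos[i] + step
                placed[j] = True
                stack.append(j)
    return pos


def init_configuration(
    counts: dict[str, int],
    box: BoxSpec,
    seed: int,
    templates: dict[str, MoleculeTemplate] | None = None,
    kBT: float = 1.0,
) -> SimulationState:
    """Random initial configuration: molecules placed with random positions
    and orientations, Maxwell velocities at temperature kBT shifted to zero
    total momentum.  Deterministic for a given seed."""
    templates = templates or standard_templates()
    rng = np.random.default_rng(seed)
    total = box.n_beads
    budget = sum(counts.get(c, 0) * templates[c].n_beads for c in counts)
    if budget > total:
        raise ValueError(f"counts need {budget} beads but the box holds {total}")

    species: list[str] = []
    positions: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    mol_id: list[int] = []
    offset = 0
    mol = 0
    # deterministic component order: polymers first, then citral, then water
    for comp in COMPONENTS[1:] + COMPONENTS[:1]:
        n_mol = counts.get(comp, 0)
        if n_mol == 0:
            continue
        beads, mol_bonds = expand_template(templates[comp])
        for _ in range(n_mol):
            pos = _place_chain(rng, len(beads), mol_bonds, box.side_length)
            positions.append(pos)
            species.extend(beads)
            bonds.extend((offset + i, offset + j) for i, j in mol_bonds)
            mol_id.extend([mol] * len(beads))
            offset += len(beads)
            mol += 1

    pos = np.vstack(positions) % box.side_length
    vel = rng.normal(scale=math.sqrt(kBT), size=pos.shape)
    vel -= vel.mean(axis=0)  # exact zero total momentum (unit bead mass)
    return SimulationState(
        positions=pos,
        velocities=vel,
        species=np.array(species),
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        box=box,
        rng_seed=seed,
        molecule_id=np.array(mol_id, dtype=np.int64),
    )


def build_system(
    recipe: CompositionRecipe,
    box: BoxSpec,
    seed: int,
    templates: dict[str, MoleculeTemplate] | None = None,
) -> SimulationState:
    """Convenience: recipe -> counts -> randomized initial state."""
    templates = templates or standard_templates()
    counts = recipe_to_counts(recipe, box, templates)
    return init_configuration(counts, box, seed, templates)
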