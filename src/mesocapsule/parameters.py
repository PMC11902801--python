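"""DPD interaction parameterization.

The conservative force between two beads of species *i* and *j* is a soft
repulsion of strength ``a_ij`` (reduced units, r_c = k_BT = 1).  Like-bead
repulsion follows from matching the compressibility of water at number
density rho, ``a_ii = 75 k_BT / rho``, and unlike-bead repulsion maps
linearly onto the Flory-Huggins parameter, ``a_ij = a_ii + 3.27 chi_ij``.

The packaged parameter set covers eight canonical species; three further
names (N3, O3, O4) are aliases that exist only to distinguish chemically
identical groups sitting on different wall polymers (sodium alginate,
methylcellulose, chitosan).  Alias resolution happens at lookup time so the
canonical table remains the single source of truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "BeadSpecies",
    "SpeciesTable",
    "InteractionMatrix",
    "ReducedUnitSystem",
    "like_repulsion",
    "chi_to_aij",
    "aij_to_chi",
    "build_interaction_matrix",
    "load_interaction_table",
    "default_interactions",
    "default_species",
]

#: canonical bead alphabet (8 species carrying parameters, 3 aliases)
CANONICAL_SPECIES = ("N1", "N2", "O1", "O2", "C1", "C2", "S", "W")
ALIASES = {"N3": "N2", "O3": "O2", "O4": "O2"}
ALL_SPECIES = ("N1", "N2", "N3", "O1", "O2", "O3", "O4", "C1", "C2", "S", "W")

_ROLES = {
    "N1": "chitosan six-membered-ring backbone unit (lipophilic)",
    "N2": "methylcellulose ring backbone unit (lipophilic)",
    "N3": "sodium alginate ring backbone unit (lipophilic)",
    "O1": "methylcellulose -OR side group",
    "O2": "hydrophilic hydroxyl pair on methylcellulose",
    "O3": "hydrophilic hydroxyl pair on sodium alginate",
    "O4": "hydrophilic hydroxyl pair on chitosan",
    "C1": "citral aldehyde-end fragment",
    "C2": "citral isoprenoid-end fragment",
    "S": "sodium carboxylate group of alginate",
    "W": "water = 3 H2O molecules",
}


@dataclass(frozen=True)
class BeadSpecies:
    """One entry of the bead alphabet."""

    name: str
    alias_of: str | None = None
    role: str = ""

    def __post_init__(self) -> None:
        if self.alias_of is not None and self.alias_of in ALIASES:
            raise ValueError(
                f"alias chain too deep: {self.name} -> {self.alias_of} is itself an alias"
            )


@dataclass(frozen=True)
class SpeciesTable:
    """The full 11-name bead alphabet with alias resolution."""

    species: tuple[BeadSpecies, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if sorted(names) != sorted(ALL_SPECIES):
            raise ValueError(f"species table must contain exactly {ALL_SPECIES}, got {names}")

    def canonical(self, name: str) -> str:
        """Resolve an alias to its canonical species name."""
        for s in self.species:
            if s.name == name:
                return s.alias_of if s.alias_of is not None else s.name
        raise KeyError(f"unknown bead species {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)


def default_species() -> SpeciesTable:
    """Bead alphabet of the microcapsule model (8 canonical + 3 aliased)."""
    return SpeciesTable(
        tuple(
            BeadSpecies(name, alias_of=ALIASES.get(name), role=_ROLES[name])
            for name in ALL_SPECIES
        )
    )


def like_repulsion(rho: float, kBT: float = 1.0) -> float:
    """Like-bead repulsion a_ii = 75 kBT / rho from water compressibility.

    Parameters
    ----------
    rho : bead number density per r_c^3 (3 in this model).
    kBT : thermal energy in reduced units (1 in this model).
    """
    if rho <= 0 or kBT <= 0:
        raise ValueError(f"rho and kBT must be positive, got rho={rho}, kBT={kBT}")
    return 75.0 * kBT / rho


def chi_to_aij(chi: float, a_like: float) -> float:
    """Map a Flory-Huggins parameter to an unlike repulsion, a_ij = a_ii + 3.27 chi."""
    if a_like <= 0:
        raise ValueError(f"a_like must be positive, got {a_like}")
    return a_like + 3.27 * chi


def aij_to_chi(a_ij: float, a_like: float) -> float:
    """Inverse of :func:`chi_to_aij`: chi = (a_ij - a_ii) / 3.27."""
    if a_like <= 0:
        raise ValueError(f"a_like must be positive, got {a_like}")
    return (a_ij - a_like) / 3.27


@dataclass
class InteractionMatrix:
    """Symmetric repulsion-parameter lookup with alias resolution.

    ``entries`` maps frozensets of canonical names (singleton for the
    diagonal) to a_ij values in reduced units.
    """

    entries: dict[frozenset, float]
    a_like: float
    species: SpeciesTable = field(default_factory=default_species)

    def __post_init__(self) -> None:
        for pair, value in self.entries.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"repulsion for {set(pair)} must be finite and positive")

    def get(self, i: str, j: str) -> float:
        """a_ij for any species pair, resolving aliases to canonical names."""
        ci, cj = self.species.canonical(i), self.species.canonical(j)
        if ci == cj:
            return self.a_like
        key = frozenset((ci, cj))
        if key not in self.entries:
            raise KeyError(f"no interaction parameter for pair ({i}, {j})")
        return self.entries[key]

    def chi(self, i: str, j: str) -> float:
        """Implied Flory-Huggins parameter for the pair (consistency check)."""
        return aij_to_chi(self.get(i, j), self.a_like)

    def as_array(self, order: tuple[str, ...] = ALL_SPECIES) -> np.ndarray:
        """Dense symmetric matrix over `order` (aliases expanded), for the engine."""
        n = len(order)
        a = np.empty((n, n))
        for ii, si in enumerate(order):
            for jj, sj in enumerate(order):
                a[ii, jj] = self.get(si, sj)
        return a


def build_interaction_matrix(
    table: dict[tuple[str, str], float] | np.ndarray,
    species: SpeciesTable | None = None,
    canonical_order: tuple[str, ...] = CANONICAL_SPECIES,
) -> InteractionMatrix:
    """Build the symmetric lookup from a pairwise table over canonical species.

    Accepts either a {(i, j): a_ij} mapping (triangular or full; symmetric
    duplicates must agree) or a dense array in `canonical_order`.
    """
    species = species or default_species()
    pairs: dict[frozenset, float] = {}
    diag: dict[str, float] = {}

    if isinstance(table, np.ndarray):
        if table.shape != (len(canonical_order),) * 2:
            raise ValueError("dense table shape does not match canonical order")
        it = (
            ((canonical_order[i], canonical_order[j]), table[i, j])
            for i in range(len(canonical_order))
            for j in range(i + 1)
            if np.isfinite(table[i, j])
        )
    else:
        it = iter(table.items())

    for (i, j), value in it:
        if i == j:
            diag[i] = float(value)
            continue
        key = frozenset((i, j))
        if key in pairs and not np.isclose(pairs[key], value):
            raise ValueError(f"conflicting symmetric entries for ({i}, {j})")
        pairs[key] = float(value)

    missing = [s for s in canonical_order if s not in diag]
    if missing:
        raise ValueError(f"table lacks diagonal entries for {missing}")
    a_like = diag[canonical_order[0]]
    if any(not np.isclose(v, a_like) for v in diag.values()):
        raise ValueError("all diagonal entries must equal the like-bead repulsion")
    for i in range(len(canonical_order)):
        for j in range(i):
            if frozenset((canonical_order[i], canonical_order[j])) not in pairs:
                raise ValueError(
                    f"missing canonical pair ({canonical_order[i]}, {canonical_order[j]})"
                )
    return InteractionMatrix(entries=pairs, a_like=a_like, species=species)


def load_interaction_table(path=None) -> InteractionMatrix:
    """Read a repulsion table from delimited text (packaged Table by default).

    Layout: header row of canonical species names, one row per species,
    lower-triangular or full symmetric; units are DPD reduced units.
    """
    if path is None:
        source = resources.files("mesocapsule.data").joinpath("interactions.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = list(csv.reader(text.splitlines()))
    header = tuple(h.strip() for h in rows[0][1:])
    table: dict[tuple[str, str], float] = {}
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        name = row[0].strip()
        for col, cell in zip(header, row[1:]):
            cell = cell.strip()
            if cell:
                table[(name, col)] = float(cell)
    return build_interaction_matrix(table, canonical_order=header)


def default_interactions() -> InteractionMatrix:
    """The packaged microcapsule parameter set."""
    return load_interaction_table()


@dataclass(frozen=True)
class ReducedUnitSystem:
    """Mapping between reduced units and physical ones, for reporting.

    One bead stands for 111.03 A^3 / 54 amu of matter; at number density
    rho r_c^3 = 3 this fixes the cut-off at 6.93 A.
    """

    r_c_physical: float = 6.93  # Angstrom
    bead_mass: float = 54.0  # amu
    bead_volume: float = 111.03  # Angstrom^3
    k_B_T: float = 1.0
    rho: float = 3.0

    def __post_init__(self) -> None:
        # one grid cell of volume r_c^3 holds rho beads of volume bead_volume
        lhs = self.r_c_physical**3
        rhs = self.rho * self.bead_volume
        if abs(lhs - rhs) / rhs > 0.005:
            raise ValueError(
                f"inconsistent unit system: r_c^3 = {lhs:.2f} but rho*V_bead = {rhs:.2f}"
            )

    @property
    def grid_volume(self) -> float:
        """Volume (A^3) of one density grid cell holding rho beads."""
        return self.rho * self.bead_volume

    def to_angstrom(self, r_reduced) -> np.ndarray | float:
        return r_reduced * self.r_c_physical

    def to_reduced(self, r_angstrom) -> np.ndarray | float:
        return r_angstrom / self.r_c_physical
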