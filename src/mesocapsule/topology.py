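"""Coarse-grained molecule templates.

Five molecules make up the model: three wall polysaccharides (chitosan Cts,
sodium alginate Alg, methylcellulose MC) at polymerization degree 20, the
citral payload (two beads), and water (one bead for three H2O molecules).
Each template carries the per-repeat bead species, the intra-repeat bond
wiring, and the bond that links consecutive repeats; expansion yields the
full bead list and bond graph, which is always a tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["MoleculeTemplate", "standard_templates", "expand_template", "load_templates"]


@dataclass(frozen=True)
class MoleculeTemplate:
    name: str
    repeat_beads: tuple[str, ...]
    repeat_bonds: tuple[tuple[int, int], ...]
    linker_bond: tuple[int, int] | None  # (bead of repeat k, bead of repeat k+1)
    degree: int = 1

    def __post_init__(self) -> None:
        n = len(self.repeat_beads)
        for i, j in self.repeat_bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"{self.name}: bond ({i},{j}) invalid for {n}-bead repeat")
        if self.linker_bond is not None:
            i, j = self.linker_bond
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.name}: linker ({i},{j}) invalid")
        if self.degree < 1:
            raise ValueError(f"{self.name}: degree must be >= 1")
        if self.degree > 1 and self.linker_bond is None:
            raise ValueError(f"{self.name}: polymers need a linker bond")

    @property
    def n_beads(self) -> int:
        return len(self.repeat_beads) * self.degree

    @property
    def n_bonds(self) -> int:
        per_repeat = len(self.repeat_bonds) * self.degree
        linkers = (self.degree - 1) if self.linker_bond is not None else 0
        return per_repeat + linkers


def expand_template(t: MoleculeTemplate) -> tuple[list[str], list[tuple[int, int]]]:
    """Expand a template into a flat bead list and bond list.

    Bead ``r * len(repeat) + k`` is bead *k* of repeat *r*.  The result is
    validated to be a connected acyclic graph (or an isolated bead).
    """
    nr = len(t.repeat_beads)
    beads: list[str] = []
    bonds: list[tuple[int, int]] = []
    for r in range(t.degree):
        off = r * nr
        beads.extend(t.repeat_beads)
        bonds.extend((off + i, off + j) for i, j in t.repeat_bonds)
        if r > 0 and t.linker_bond is not None:
            i, j = t.linker_bond
            bonds.append(((r - 1) * nr + i, off + j))
    _check_tree(t.name, len(beads), bonds)
    return beads, bonds


def _check_tree(name: str, n: int, bonds: list[tuple[int, int]]) -> None:
    if n == 1 and not bonds:
        return
    if len(bonds) != n - 1:
        raise ValueError(f"{name}: expanded graph is not a tree ({n} beads, {len(bonds)} bonds)")
    # connectivity by union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bonds:
        parent[find(i)] = find(j)
    if len({find(i) for i in range(n)}) != 1:
        raise ValueError(f"{name}: expanded bond graph is disconnected")


def load_templates(path=None) -> dict[str, MoleculeTemplate]:
    """Load molecule templates from a YAML file (packaged defaults if None)."""
    if path is None:
        text = resources.files("mesocapsule.data").joinpath("templates.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, MoleculeTemplate] = {}
    for name, spec in raw.items():
        out[name] = MoleculeTemplate(
            name=name,
            repeat_beads=tuple(spec["repeat_beads"]),
            repeat_bonds=tuple((int(i), int(j)) for i, j in spec["repeat_bonds"]),
            linker_bond=tuple(spec["linker_bond"]) if spec.get("linker_bond") else None,
            degree=int(spec.get("degree", 1)),
        )
    return out


def standard_templates() -> dict[str, MoleculeTemplate]:
    """The five packaged templates: Cts, Alg, MC, Citral, H2O."""
    return load_templates()
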