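"""Packaged composition presets and reproducible run manifests.

Forty named recipes cover the four experiment families: chitosan and
sodium alginate single-wall systems, and the Alg-Cts and Alg-MC
double-wall systems, each with and without the citral payload at five
wall-material loadings.  A preset pairs a recipe with production-scale engine
defaults (box 28.86 r_c ~ 200 A, 250,000 steps, frames every 5000 steps);
``desk_scale`` shrinks that to a box that runs in minutes while keeping
the composition.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .builder import BoxSpec, CompositionRecipe, build_system, recipe_to_counts
from .engine import EngineParams, run_simulation
from .io import write_bonds, write_table, write_xyz
from .topology import standard_templates

__all__ = [
    "PRODUCTION_BOX_L",
    "load_recipes",
    "preset",
    "desk_scale",
    "production_scale",
    "RunManifest",
    "execute_manifest",
]

#: production-scale box side: 200 A at r_c = 6.93 A
PRODUCTION_BOX_L = 28.86

_COMPONENTS = ("H2O", "Cts", "Alg", "MC", "Citral")


def _normalize(label: str) -> str:
    return label.replace("–", "-").replace("—", "-").strip()


def load_recipes(path=None) -> dict[str, CompositionRecipe]:
    """All packaged composition rows, keyed by label."""
    if path is None:
        text = resources.files("mesocapsule.data").joinpath("recipes.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out: dict[str, CompositionRecipe] = {}
    for row in csv.DictReader(text.splitlines()):
        label = _normalize(row["label"])
        fractions = {
            c: float(row[c]) for c in _COMPONENTS if row.get(c) and float(row[c]) > 0
        }
        fractions.setdefault("H2O", 0.0)
        out[label] = CompositionRecipe(label=label, fractions=fractions)
    return out


def preset(label: str) -> tuple[CompositionRecipe, EngineParams, BoxSpec]:
    """Look up a packaged recipe with production-scale defaults.

    Raises KeyError listing the known labels when the label is unknown.
    """
    recipes = load_recipes()
    key = _normalize(label)
    if key not in recipes:
        known = ", ".join(sorted(recipes))
        raise KeyError(f"unknown preset {label!r}; known labels: {known}")
    return recipes[key], EngineParams(), BoxSpec(side_length=PRODUCTION_BOX_L)


@dataclass
class RunManifest:
    """Everything needed to reproduce one run bit-identically."""

    recipe_label: str
    box_side: float
    number_density: float
    dt: float
    gamma: float
    lambda_vv: float
    bond_k: float
    n_steps: int
    frame_interval: int
    seed: int
    production_scale: bool
    version: str = __version__

    def engine_params(self) -> EngineParams:
        return EngineParams(
            dt=self.dt,
            gamma=self.gamma,
            lambda_vv=self.lambda_vv,
            bond_k=self.bond_k,
            n_steps=self.n_steps,
            frame_interval=self.frame_interval,
        )

    def box(self) -> BoxSpec:
        return BoxSpec(side_length=self.box_side, number_density=self.number_density)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def desk_scale(label: str, L: float = 12.0, n_steps: int = 30_000, seed: int = 0) -> RunManifest:
    """A scaled-down manifest for a packaged recipe.

    Keeps the composition but shrinks the box and the run length so a
    single core finishes in minutes; the manifest is flagged as
    production-scale only when L reaches the 28.86 r_c box.
    """
    recipe, params, _ = preset(label)
    if L < 10.0:
        raise ValueError(
            f"L = {L} r_c cannot accommodate a degree-20 wall polymer; use L >= 10"
        )
    frame_interval = max(n_steps // 50, 1) if n_steps else 1
    while n_steps % frame_interval:
        frame_interval -= 1
    return RunManifest(
        recipe_label=recipe.label,
        box_side=L,
        number_density=3.0,
        dt=params.dt,
        gamma=params.gamma,
        lambda_vv=params.lambda_vv,
        bond_k=params.bond_k,
        n_steps=n_steps,
        frame_interval=frame_interval,
        seed=seed,
        production_scale=L >= PRODUCTION_BOX_L - 1e-9,
    )


def production_scale(label: str, seed: int = 0) -> RunManifest:
    """The full-size manifest (~72,000 beads, 250,000 steps)."""
    recipe, params, box = preset(label)
    return RunManifest(
        recipe_label=recipe.label,
        box_side=box.side_length,
        number_density=box.number_density,
        dt=params.dt,
        gamma=params.gamma,
        lambda_vv=params.lambda_vv,
        bond_k=params.bond_k,
        n_steps=params.n_steps,
        frame_interval=params.frame_interval,
        seed=seed,
        production_scale=True,
    )


def execute_manifest(manifest: RunManifest, outdir) -> Path:
    """Build, run, and analyze one manifest; returns the run directory.

    The directory always contains the manifest, the trajectory (extended
    XYZ + bond sidecar), and per-species radial observable tables, so the
    run is fully regenerable from the manifest alone.
    """
    from .analysis import radial_profile, shell_order

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recipes = load_recipes()
    recipe = recipes[_normalize(manifest.recipe_label)]
    box = manifest.box()
    params = manifest.engine_params()
    state = build_system(recipe, box, manifest.seed)
    traj = run_simulation(state, params)

    manifest.save(outdir / "manifest.yaml")
    write_xyz(traj, outdir / "trajectory.xyz")
    write_bonds(traj.bonds, outdir / "bonds.tsv")

    non_water = [s for s in dict.fromkeys(traj.species.tolist()) if s != "W"]
    if non_water:
        prof = radial_profile(traj.wrapped[-1], traj.species, box.side_length, non_water)
        cols = {"r_lo": prof.bin_edges[:-1], "r_hi": prof.bin_edges[1:]}
        cols.update({f"conc_{s}": prof.concentration[s] for s in non_water})
        write_table(
            outdir / "radial_profile.tsv",
            cols,
            {"recipe": recipe.label, "seed": manifest.seed, "frame": int(traj.steps[-1])},
        )
        order = shell_order(traj.wrapped[-1], traj.species, box.side_length, non_water)
        write_table(
            outdir / "shell_order.tsv",
            {"mean_radius": np.array([order[s] for s in non_water])},
            {"species": ",".join(non_water), "recipe": recipe.label, "seed": manifest.seed},
        )
    return outdir
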