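"""From a composition recipe to a simulation-ready box.

Takes the highest-loading chitosan-citral recipe, converts volume
fractions to whole-molecule counts in a desk-scale box, and builds the
randomized initial configuration.  Also shows the dehydrated (dry-matter)
composition used to compare wall formulations.
"""

from mesocapsule import BoxSpec, build_system, dehydrated_composition, recipe_to_counts
from mesocapsule.presets import load_recipes

recipes = load_recipes()
recipe = recipes["Cts-Citral (5)"]
box = BoxSpec(side_length=12.0)  # 12 r_c ~ 83 Angstrom, 5184 beads at rho=3

counts = recipe_to_counts(recipe, box)
print(f"recipe {recipe.label}: {recipe.fractions}")
print(f"box {box.side_length} r_c -> {box.n_beads} beads")
print("molecule counts:", counts)
# Each chitosan chain is 60 beads (20 repeats of N1-N1-O4), citral is 2
# beads, water 1; water absorbs the rounding so the bead total is exact.

state = build_system(recipe, box, seed=42)
print("beads placed:", state.n_beads, "| bonds:", len(state.bonds))
print("total momentum (exactly zeroed):", state.total_momentum())

best = recipes["Alg-Cts-Citral (4)"]
print()
print(f"dry-matter composition of {best.label}:")
for comp, pct in dehydrated_composition(best).items():
    print(f"  {comp}: {pct:.1f}%")
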