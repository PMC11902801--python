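# Default coarse-grained molecule templates.
#
# Each repeat unit lists its bead species in order; `repeat_bonds` are
# index pairs within one repeat; `linker_bond` joins bead (i of repeat k)
# to bead (j of repeat k+1).  Degree 20 for the three wall polymers,
# 1 for citral and water.
#
# The intra-repeat wiring follows the ring-backbone-plus-substituent
# picture: the two N beads of each repeat form the backbone, side groups
# (hydroxyl pairs, the carboxylate/sodium group) hang off it, and
# consecutive repeats join N-to-N.
Cts:
  repeat_beads: [N1, N1, O4]
  repeat_bonds: [[0, 1], [1, 2]]
  linker_bond: [1, 0]
  degree: 20
Alg:
  repeat_beads: [N3, N3, S, O3]
  repeat_bonds: [[0, 1], [0, 2], [1, 3]]
  linker_bond: [1, 0]
  degree: 20
MC:
  repeat_beads: [N2, N2, O1, O2]
  repeat_bonds: [[0, 1], [0, 2], [1, 3]]
  linker_bond: [1, 0]
  degree: 20
Citral:
  repeat_beads: [C1, C2]
  repeat_bonds: [[0, 1]]
  linker_bond: null
  degree: 1
H2O:
  repeat_beads: [W]
  repeat_bonds: []
  linker_bond: null
  degree: 1
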