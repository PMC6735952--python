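# Topology of the hybrid right-/left-handed G-quadruplex TBA-TT-Block2
# (28-nt construct; NMR solution structure). Tetrads are listed in layer
# order from the solvent-exposed 3' tetrad of the right-handed TBA block
# down to the solvent-exposed 5' tetrad of the left-handed Block2, each in
# cyclic donor→acceptor order. All core guanines are anti.
name: TBA-TT-Block2
default_chain: A
tetrads:
  - [G2, G6, G11, G15]
  - [G1, G5, G10, G14]
  - [G18, G21, G24, G27]
  - [G20, G23, G26, G29]
positions: [outer, inner, inner, outer]
all_anti: true
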