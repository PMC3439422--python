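# Reduced nearest-neighbour energy model for single-hairpin MFE folding.
#
# The model keeps the structure of the classical nearest-neighbour scheme
# (negative stacking terms, positive size-dependent loop penalties) but
# collapses the stacking table to pair classes (GU < AU < GC) so that the
# whole model fits one page and the -18 kcal/mol precursor cutoff is
# meaningful: canonical miRNA-like stems (>=14 mixed pairs) score well below
# -18, random sequence rarely does.  All energies in kcal/mol.
pair_classes:
  GU: 0
  UG: 0
  AU: 1
  UA: 1
  GC: 2
  CG: 2
# stack[c1][c2]: pair (i,j) of class c1 stacked on directly-nested pair of
# class c2.  Symmetric; orientation effects of the full Turner table are
# averaged out.
stack:
  - [-0.5, -1.0, -1.5]
  - [-1.0, -1.1, -2.1]
  - [-1.5, -2.1, -3.3]
# loop penalties: base + slope * ln(size / ref), size >= ref
hairpin: {base: 5.6, slope: 1.6, ref: 3}
bulge: {base: 3.6, slope: 1.6, ref: 1}
internal: {base: 1.7, slope: 1.6, ref: 2}
# multiloops are legal but strongly discouraged: closing penalty plus a
# per-branch term (single-hairpin candidates should not branch).
multiloop: {close: 7.0, branch: 0.9}
min_hairpin_loop: 3
# interior loops (bulge + internal combined unpaired count) larger than this
# are disallowed, as in standard folding implementations.
max_interior: 30
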