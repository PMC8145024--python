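# RNA/RNA duplex nearest-neighbor energy parameters, version 1.
#
# Stacking free energies (kcal/mol, 37 C) for two adjacent base pairs in an
# intermolecular duplex.  Key "P.Q" names the 5'-side pair P and 3'-side pair Q
# along strand 1 (the miRNA): pair "XY" means strand-1 base X paired with
# strand-2 base Y.  So "AU.CG" scores the step  5'-A C-3' / 3'-U G-5'.
#
# Watson-Crick x Watson-Crick entries are the standard RNA nearest-neighbor
# stack values; entries involving a G:U wobble are curated approximations on
# the same scale (published wobble parameters are sparser and context
# dependent; only their magnitude ordering matters to this scanner).
# Strand-flip symmetry E[P.Q] == E[rev(Q).rev(P)] (rev swaps the two bases of
# a pair) is asserted when the model is loaded.
version: 1
duplex_init: 4.09
wobble_in_helix: true
stacks:
  # Watson-Crick / Watson-Crick
  AU.AU: -0.93
  UA.UA: -0.93
  AU.UA: -1.10
  UA.AU: -1.33
  AU.CG: -2.24
  GC.UA: -2.24
  AU.GC: -2.08
  CG.UA: -2.08
  UA.CG: -2.35
  GC.AU: -2.35
  UA.GC: -2.11
  CG.AU: -2.11
  CG.CG: -3.26
  GC.GC: -3.26
  CG.GC: -2.36
  GC.CG: -3.42
  # involving one or two G:U wobbles
  AU.GU: -0.55
  UG.UA: -0.55
  AU.UG: -1.36
  GU.UA: -1.36
  UA.GU: -1.27
  UG.AU: -1.27
  UA.UG: -1.00
  GU.AU: -1.00
  CG.GU: -1.41
  UG.GC: -1.41
  CG.UG: -2.11
  GU.GC: -2.11
  GC.GU: -1.53
  UG.CG: -1.53
  GC.UG: -2.51
  GU.CG: -2.51
  GU.GU: -0.50
  UG.UG: -0.50
  GU.UG: 0.47
  UG.GU: -0.30
# Bulge loop penalties (kcal/mol) by bulge length 1..max; longer bulges are
# disallowed (treated as +inf).  Nondecreasing in length.
bulge:
  1: 3.8
  2: 4.0
  3: 4.2
  4: 4.4
  5: 4.6
  6: 4.8
  7: 5.0
  8: 5.2
# Internal loop penalties by total unpaired length (both sides together),
# 2..max; nondecreasing.
internal:
  2: 1.6
  3: 2.1
  4: 2.5
  5: 2.9
  6: 3.3
  7: 3.6
  8: 3.9
  9: 4.2
  10: 4.5
  11: 4.8
  12: 5.0
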