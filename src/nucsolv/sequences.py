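"""Synthetic stand-in sequences for the model kissing-complex constructs.

These are *synthetic* sequences, reconstructed from the published construct
description rather than copied from a deposited table: DIS_C is a 29-nt
GC-rich hairpin whose apical palindrome (residues 13-18) is mutated to all
cytosines; DIS_GK is a 65-nt hairpin with the complementary all-guanine loop
(residues 32-37), a UCU bulge and a 16-bp elongation that breaks the size
degeneracy of the two hairpins.  Their sequence molecular weights (9.2, 20.9
and 30.1 kDa for the two monomers and the 1:1 complex) match the published
constructs to within 0.1 kDa, which is the property the contrast and mass
calculations actually depend on.
"""

DIS_C = "GGCGGCUGGCGCCCCCCCGCGCCAGCCGC"
"""29-nt all-C-loop hairpin (synthetic stand-in), ~9.2 kDa."""

DIS_GK = "GCGGCUGGCGUCUAUGCAAUUGCAAUUGCAGGGGGGGCUGCAAUUGCAAUUGCAUCGCCAGCCGC"
"""65-nt all-G-loop kinked-elongation hairpin (synthetic stand-in), ~20.9 kDa."""
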