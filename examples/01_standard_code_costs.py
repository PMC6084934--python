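"""Polarity costs of the standard genetic code, per codon position.

Builds the 263 single-nucleotide neighbor pairs among the 61 sense
codons and sums squared polar-requirement differences for each codon
position.  Position 2 dominates the total (every change there replaces
the amino acid), position 3 is nearly silent (high degeneracy).
"""

import codonopt as co

sgc = co.standard_code()
scale = co.WOESE_POLAR_REQUIREMENT

pairs = co.build_pairs()
print(f"neighbor pairs |D| = {len(pairs)} "
      f"({', '.join(str(len(co.build_pairs(position=p))) for p in (1, 2, 3))} "
      "at positions 1, 2, 3)")

v = co.objective_vector(sgc, scale)
print(f"F1 = {v.f1:8.2f}   (first-position substitutions)")
print(f"F2 = {v.f2:8.2f}   (second-position substitutions)")
print(f"F3 = {v.f3:8.2f}   (third-position substitutions)")
print(f"FT = {v.ft:8.2f}   (total; exactly F1 + F2 + F3)")
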