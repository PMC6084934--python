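"""Exact sizes of the four code spaces, and of the unconstrained space.

Each structural model admits a closed-form count: factorials within
degeneracy classes (DEG), 20! block permutations (BLO), a multinomial
over the SGC codon counts (NUM) and surjection counting by
inclusion-exclusion (GEN).  All arithmetic is exact big-integer.
"""

import codonopt as co

for model in co.MODEL_NAMES:
    n = co.space_size(model)
    print(f"{model}: {co.sci_notation(n)}  ({n})")

total = co.total_space_size()
print(f"all codes with 3 fixed-position stops: {co.sci_notation(total, 3)}")
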