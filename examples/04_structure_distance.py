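"""Structure distance SD between codes: how many assignments differ.

SD is the Hamming distance between 1220-bit codon/amino-acid indicator
vectors, normalized by the maximum of 122 (all 61 codons reassigned).
The single Met<->Trp codon swap is the classic near-SGC example at 3.3%.
"""

import numpy as np

import codonopt as co

sgc = co.standard_code()

swapped = co.swap_amino_acids(sgc, "M", "W")
r = co.structure_distance(sgc, swapped)
print(f"SGC vs Met<->Trp swap: Hamming {r.hamming}/122, SD = {r.sd_rounded}%")

rng = np.random.default_rng(0)
for model in co.MODEL_NAMES:
    sds = [co.structure_distance(sgc, co.random_code(model, rng)).sd
           for _ in range(200)]
    print(f"random {model} codes: mean SD to SGC = {np.mean(sds):.1f}%")
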