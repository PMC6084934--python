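"""Where do random codes sit between the best and worst codes?

Replaces the SGC's cost by the mean cost of model-constrained random
codes in the GD formula.  Unbiased sampling would give ~50%; random
codes under the general (GEN) model land well below — surjective random
assignments are nearly uniform in codons per amino acid, which already
buys part of the cost minimization.
"""

import numpy as np

import codonopt as co
from codonopt.costfn import population_costs
from codonopt.models import get_model

scale = co.WOESE_POLAR_REQUIREMENT
rng = np.random.default_rng(0)

for model in ("BLO", "GEN"):
    m = get_model(model)
    costs = population_costs(m.decode(m.random_genomes(50_000, rng)),
                             scale.as_array(), "sum")
    # stand-in extremes: the random sample's own range (fast, not EA-derived)
    b = co.random_baseline(model, "sum", 20_000, np.random.default_rng(1),
                           float(costs.min()), float(costs.max()))
    print(f"{model}: mean F = {b.mean_f:9.1f}  GD^rand = {b.gd_rand:5.1f}% "
          f"(2 SD of F: {b.sd2_f:.1f})")
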