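"""Relatedness calibration on pedigrees of known kinship.

The product-moment estimator (r = 2 * coancestry) should average 0 for
unrelated pairs, 0.5 for parent-offspring and 1.0 for self-pairs.
"""

import numpy as np

from allokin import pairwise_relatedness, simulate_pedigree_pairs

rng = np.random.default_rng(3)
p = rng.uniform(0.05, 0.95, 5000)  # panel allele frequencies

for relationship, expected in [("unrelated", 0.0),
                               ("parent_offspring", 0.5),
                               ("full_sib", 0.5),
                               ("self", 1.0)]:
    dm = simulate_pedigree_pairs(p, n_pairs=20, relationship=relationship,
                                 seed=4)
    rm = pairwise_relatedness(dm, p, l_min=100)
    vals = [rm.get(dm.samples[2 * k], dm.samples[2 * k + 1])
            for k in range(20)]
    print(f"{relationship:17s} mean r = {np.mean(vals):+.3f} "
          f"(expected {expected:+.1f})")
# values within Monte-Carlo noise of the pedigree expectations confirm
# the ploidy-scale conversion is calibrated
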