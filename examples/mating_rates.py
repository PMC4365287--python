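"""Pairwise mating rates and their row-sum identities.

Builds a six-individual population and prints the total mating rate of one
individual under each mating model: semi-random rates sum to the individual's
capability p(x); female-referenced and normalized assortative rates sum to 1.
"""

import numpy as np

import hermesim as hs

traits = np.array([0.1, 0.4, 0.5, 1.2, 2.0, 3.3])

semi = hs.MatingModel(variant="semi_random", p=lambda x: 1.0 + x, selfing=True)
female = hs.MatingModel(variant="assortative_female", a=hs.gaussian_pref(1.0))
normalized = hs.MatingModel(variant="assortative_normalized",
                            a=hs.gaussian_pref(1.0))

print("trait of focal individual:", traits[2])
print("semi-random row sum      :", hs.rate_row_sum(2, traits, semi),
      " (equals p(x) =", 1.0 + traits[2], ")")
print("female-referenced row sum:", hs.rate_row_sum(2, traits, female),
      " (every female mates at unit rate)")
print("normalized row sum       :", hs.rate_row_sum(2, traits, normalized),
      " (symmetric rate, still unit rows)")

coeffs = hs.solve_normalization(traits, hs.gaussian_pref(1.0))
print("normalization coefficients c_i:", np.round(coeffs.values, 4))
print("linear-system residual        :", coeffs.residual)
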