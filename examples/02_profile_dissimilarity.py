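"""Compare two oligotype profiles with the read-randomization null.

Builds two groups whose planted oligotype frequency vectors differ by a
total-variation distance of 0.30, then tests the observed dissimilarity
against the null in which every read joins either group with probability
1/2. A significant p means the profile difference cannot be explained by
random assortment of the pooled reads.
"""

import numpy as np

from oligopipe import permutation_test

rng = np.random.default_rng(7)
freqs = {"cheetah": [0.55, 0.30, 0.15], "jackal": [0.25, 0.30, 0.45]}
oligotypes = ["AGT", "ACC", "GCT"]
reads = []
for group, p in freqs.items():
    for olig in rng.choice(oligotypes, size=3000, p=p):
        reads.append((olig, group))

res = permutation_test(reads, n_perm=1000, seed=11)
print(f"observed dissimilarity : {res.observed * 100:.1f}%  (planted: 30%)")
print(f"null 95% quantile      : {res.null_quantile_95 * 100:.1f}%")
print(f"permutation p-value    : {res.permutation_p:.4f}  "
      f"({res.n_permutations} replicates)")
print("\nThe observed value far exceeds the null quantile: the two groups'")
print("oligotype profiles differ more than chance read assortment allows.")
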