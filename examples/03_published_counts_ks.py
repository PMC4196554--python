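"""Bootstrap K-S test on the published carnivore oligotype counts.

The bundled table lists, for 22 gut bacterial taxa shared by cheetahs and
black-backed jackals, how many oligotypes each host species carried. The
bootstrap two-sample Kolmogorov-Smirnov test (resampling from the pooled
counts, which is valid under the heavy ties of small integer data) asks
whether the two species differ in their distribution of oligotype
richness per taxon.
"""

from oligopipe import ks_boot
from oligopipe.datasets import carnivore_oligotype_counts, \
    carnivore_oligotype_table

table = carnivore_oligotype_table()
print(table[["taxon", "ot_cheetah", "ot_jackal", "shared_ot"]].to_string(
    index=False))

cheetah, jackal = carnivore_oligotype_counts()
res = ks_boot(cheetah, jackal, n_boot=1000, seed=1)
print(f"\nK-S D = {res.D:.2f}  (exact {res.D:.4f} = 4/22)")
print(f"bootstrap p = {res.p_boot:.2f}  ({res.n_boot} bootstraps)")
print("\nD rounds to 0.18 with p well above 0.05: the number of oligotypes")
print("per shared taxon is distributed alike in the two host species, even")
print("though the oligotypes themselves differ.")
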