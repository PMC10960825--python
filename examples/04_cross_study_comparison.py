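"""Compare modules across datasets.

Module overlap significance uses Fisher's exact test on the features
measured in both datasets (pairs sharing >= 2 features, BH-FDR < 0.1);
the genus co-occurrence test asks whether module species appear with
congeneric species more often than size-matched random modules would.
"""

import numpy as np

from crossomic.crossstudy import genus_cooccurrence_test, module_overlap_test, overlap_fdr

species = [f"T:Bacteroides sp{i}" for i in range(6)] + [
    f"T:Genus{i} sp" for i in range(44)
]

# two studies measuring (mostly) the same species
universe_a = species[:45]
universe_b = species[:30] + species[40:]

module_a = ["T:Bacteroides sp0", "T:Bacteroides sp1", "T:Bacteroides sp2",
            "T:Genus1 sp", "T:Genus2 sp"]
module_b = ["T:Bacteroides sp0", "T:Bacteroides sp1", "T:Bacteroides sp2",
            "T:Genus7 sp"]

test = module_overlap_test(module_a, module_b, universe_a, universe_b,
                           module_a_id="cohortA/m0", module_b_id="cohortB/m0")
(test,) = overlap_fdr([test])
print(f"overlap {test.overlap} of |A|={test.n_a}, |B|={test.n_b} on a "
      f"{test.universe}-feature shared universe: OR={test.odds_ratio:.1f}, "
      f"p={test.p:.2e}, q={test.q:.2e}, significant={test.significant}")

out = genus_cooccurrence_test(
    {"cohortA": [module_a], "cohortB": [module_b]},
    {"cohortA": universe_a, "cohortB": universe_b},
    n_perm=2000,
    rng=np.random.default_rng(0),
)
print(f"species sharing a genus within their module: {out['observed_pct']:.1f}% "
      f"observed vs {out['null_mean_pct']:.1f}% "
      f"[{out['null_ci'][0]:.1f}-{out['null_ci'][1]:.1f}%] in random modules, "
      f"p={out['p']:.4g}")

# A significant excess means taxonomically related species co-occur in
# modules more than chance — consistent with congeneric species competing
# for, or sharing, a niche.
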