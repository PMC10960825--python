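"""Cross-dataset module comparison.

Two modules from different datasets overlap significantly when, after
restricting both to the features measured in both datasets, a two-sided
Fisher's exact test on the 2x2 membership table is significant (BH-FDR
< 0.1 across all tested pairs; only pairs sharing >= 2 features are
tested). A separate permutation test asks whether species in modules
co-occur with congeneric species more often than random same-size
modules would.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapTest",
    "module_overlap_test",
    "overlap_fdr",
    "genus_cooccurrence_test",
]


@dataclasses.dataclass
class OverlapTest:
    module_a: str
    module_b: str
    universe: int
    n_a: int
    n_b: int
    overlap: int
    odds_ratio: float
    p: float
    q: float = float("nan")
    significant: bool = False
    tested: bool = True


def module_overlap_test(
    module_a: Sequence[str],
    module_b: Sequence[str],
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    module_a_id: str = "A",
    module_b_id: str = "B",
    alternative: str = "two-sided",
) -> OverlapTest:
    """Fisher's exact test of module overlap on the shared feature universe.

    Both modules are first narrowed to features present in both datasets'
    universes. Pairs with overlap < 2 are recorded but not tested.
    """
    universe = set(universe_a) & set(universe_b)
    if not universe:
        raise ValueError("the two datasets share no features")
    a = set(module_a) & universe
    b = set(module_b) & universe
    overlap = len(a & b)
    n = len(universe)
    table = np.array(
        [
            [overlap, len(a) - overlap],
            [len(b) - overlap, n - len(a) - len(b) + overlap],
        ]
    )
    if overlap < 2:
        return OverlapTest(
            module_a=module_a_id, module_b=module_b_id, universe=n,
            n_a=len(a), n_b=len(b), overlap=overlap,
            odds_ratio=float("nan"), p=float("nan"), tested=False,
        )
    odds, p = fisher_exact(table, alternative=alternative)
    return OverlapTest(
        module_a=module_a_id, module_b=module_b_id, universe=n,
        n_a=len(a), n_b=len(b), overlap=overlap,
        odds_ratio=float(odds), p=float(p),
    )


def overlap_fdr(tests: Sequence[OverlapTest], fdr: float = 0.1) -> list[OverlapTest]:
    """BH-correct the tested pairs; flag significance at q < fdr."""
    out = [dataclasses.replace(t) for t in tests]
    tested = [t for t in out if t.tested]
    if tested:
        qs = multipletests([t.p for t in tested], method="fdr_bh")[1]
        for t, q in zip(tested, qs):
            t.q = float(q)
            t.significant = bool(q < fdr)
    return out


def _genus_of(feature: str, genus_map: Optional[Mapping[str, str]]) -> str:
    if genus_map is not None and feature in genus_map:
        return genus_map[feature]
    name = feature.split(":", 1)[-1]
    return name.split(" ")[0].split("_")[0]


def _shared_genus_fraction(
    modules_species: Sequence[Sequence[str]], genus_map: Optional[Mapping[str, str]]
) -> float:
    """% of species occurrences sharing a genus with another module member."""
    total = 0
    shared = 0
    for species in modules_species:
        genera = [_genus_of(s, genus_map) for s in species]
        counts: dict[str, int] = {}
        for g in genera:
            counts[g] = counts.get(g, 0) + 1
        for g in genera:
            total += 1
            if counts[g] >= 2:
                shared += 1
    if total == 0:
        return float("nan")
    return 100.0 * shared / total


def genus_cooccurrence_test(
    modules_by_dataset: Mapping[str, Sequence[Sequence[str]]],
    species_universe: Mapping[str, Sequence[str]],
    genus_map: Optional[Mapping[str, str]] = None,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Do module species co-occur with congeneric species more than chance?

    ``modules_by_dataset`` maps dataset id -> list of modules, each a list
    of species feature ids; ``species_universe`` maps dataset id -> all
    species available in that dataset. The genus is the first token of
    the species name unless ``genus_map`` overrides it. The statistic is
    the percentage of species occurrences (across all modules and
    datasets) sharing a genus with >= 1 other species in their module.
    The null redraws each module's species uniformly (same size, same
    dataset universe); p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    all_modules = [
        (ds, list(mod))
        for ds, mods in modules_by_dataset.items()
        for mod in mods
        if len(mod) >= 1
    ]
    if not any(len(mod) >= 2 for _, mod in all_modules):
        return {
            "observed_pct": 0.0, "null_mean_pct": float("nan"),
            "null_ci": (float("nan"), float("nan")), "p": float("nan"),
            "degenerate": True, "n_perm": n_perm,
        }
    observed = _shared_genus_fraction([m for _, m in all_modules], genus_map)
    null_vals = np.empty(n_perm)
    universes = {ds: list(u) for ds, u in species_universe.items()}
    for i in range(n_perm):
        drawn = []
        for ds, mod in all_modules:
            uni = universes[ds]
            if len(mod) > len(uni):
                raise ValueError(f"dataset {ds!r}: module larger than species universe")
            idx = rng.choice(len(uni), size=len(mod), replace=False)
            drawn.append([uni[j] for j in idx])
        null_vals[i] = _shared_genus_fraction(drawn, genus_map)
    p = (1 + int(np.sum(null_vals >= observed))) / (n_perm + 1)
    lo, hi = np.quantile(null_vals, [0.025, 0.975])
    return {
        "observed_pct": float(observed),
        "null_mean_pct": float(np.mean(null_vals)),
        "null_ci": (float(lo), float(hi)),
        "p": float(p),
        "degenerate": False,
        "n_perm": n_perm,
    }
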