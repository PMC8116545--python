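"""Cross-dataset DMG set algebra: shared universe, common and exclusive sets.

Datasets measured by different assays cover different genes, so cross-dataset
comparison is restricted to the *shared universe* — genes measured in every
dataset.  Within that universe the report tallies per-dataset DMG counts and
directions, all pairwise and higher-order intersections, exclusive sets
(DMGs found in exactly one dataset), the common set across all datasets, and
the sign concordance of the common set (fraction whose hypo/hyper direction
agrees everywhere).  Overlap significance uses the hypergeometric upper tail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmptyUniverseError",
    "ConsistencyReport",
    "shared_universe",
    "build_report",
    "overlap_significance",
]


class EmptyUniverseError(ValueError):
    """The datasets share no measured genes."""


def shared_universe(gene_sets_measured: list[set]) -> frozenset:
    """Exact intersection of the per-dataset measured-gene sets (>= 2 sets)."""
    if len(gene_sets_measured) < 2:
        raise ValueError("need at least two datasets")
    out = frozenset(gene_sets_measured[0])
    for s in gene_sets_measured[1:]:
        out &= frozenset(s)
    if not out:
        raise EmptyUniverseError("no genes are measured in all datasets")
    return out


def overlap_significance(set_a: set, set_b: set, universe: set) -> float:
    """Hypergeometric upper-tail p of observing >= |A ∩ B| genes in common.

    Models B as a uniform draw of size |B| from the universe and asks how
    often it would hit A at least as many times as observed.
    """
    universe = frozenset(universe)
    a = frozenset(set_a) & universe
    b = frozenset(set_b) & universe
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    if N == 0:
        raise EmptyUniverseError("empty universe")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class ConsistencyReport:
    """Cross-dataset DMG consistency summary (all sets within the universe)."""

    datasets: list[str]
    universe: frozenset
    dmg_sets: dict[str, frozenset]
    directions: dict[str, dict[str, str]]
    n_dmg: dict[str, int]
    n_hypo: dict[str, int]
    n_hyper: dict[str, int]
    intersections: dict[tuple[str, ...], frozenset]
    exclusive: dict[str, frozenset]
    common: frozenset
    sign_concordance: float

    def to_frame(self) -> pd.DataFrame:
        """Per-dataset summary table (one row per dataset)."""
        rows = []
        for d in self.datasets:
            rows.append(
                {
                    "dataset": d,
                    "n_universe": len(self.universe),
                    "n_dmg": self.n_dmg[d],
                    "n_hypo": self.n_hypo[d],
                    "n_hyper": self.n_hyper[d],
                    "n_exclusive": len(self.exclusive[d]),
                    "n_common_all": len(self.common),
                    "sign_concordance": self.sign_concordance,
                }
            )
        return pd.DataFrame(rows)

    def intersection_counts(self) -> pd.DataFrame:
        """Venn-style table: one row per dataset combination with its count."""
        rows = [
            {"datasets": "&".join(combo), "k": len(combo), "n_genes": len(s)}
            for combo, s in sorted(self.intersections.items())
        ]
        return pd.DataFrame(rows)


def build_report(
    dmg_tables: dict[str, pd.DataFrame], universe: set
) -> ConsistencyReport:
    """Assemble a :class:`ConsistencyReport` from per-dataset DMG tables.

    Each table is a :func:`~methconsist.differential.call_dmg` output; rows
    outside the universe are ignored.  A dataset with zero DMGs is valid and
    simply empties the intersections it participates in.
    """
    universe = frozenset(universe)
    if not universe:
        raise EmptyUniverseError("empty universe")
    datasets = list(dmg_tables)
    dmg_sets: dict[str, frozenset] = {}
    directions: dict[str, dict[str, str]] = {}
    for d, tab in dmg_tables.items():
        tab = tab[tab.index.isin(universe)]
        called = tab[tab["is_dmg"].astype(bool)]
        dmg_sets[d] = frozenset(called.index)
        directions[d] = {g: str(v) for g, v in called["direction"].items()}

    n_dmg = {d: len(s) for d, s in dmg_sets.items()}
    n_hypo = {d: sum(1 for v in directions[d].values() if v == "hypo") for d in datasets}
    n_hyper = {d: sum(1 for v in directions[d].values() if v == "hyper") for d in datasets}

    intersections: dict[tuple[str, ...], frozenset] = {}
    for r in range(2, len(datasets) + 1):
        for combo in itertools.combinations(datasets, r):
            s = dmg_sets[combo[0]]
            for d in combo[1:]:
                s = s & dmg_sets[d]
            intersections[combo] = s
    common = intersections[tuple(datasets)] if len(datasets) >= 2 else dmg_sets[datasets[0]]

    union_others = {
        d: frozenset().union(*(dmg_sets[o] for o in datasets if o != d))
        for d in datasets
    }
    exclusive = {d: dmg_sets[d] - union_others[d] for d in datasets}

    if common:
        concordant = sum(
            1 for g in common if len({directions[d][g] for d in datasets}) == 1
        )
        sign_concordance = concordant / len(common)
    else:
        sign_concordance = float("nan")

    return ConsistencyReport(
        datasets=datasets,
        universe=universe,
        dmg_sets=dmg_sets,
        directions=directions,
        n_dmg=n_dmg,
        n_hypo=n_hypo,
        n_hyper=n_hyper,
        intersections=intersections,
        exclusive=exclusive,
        common=common,
        sign_concordance=sign_concordance,
    )
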