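"""Synergistic-system lncRNA counting and tolerance-phenotype partitioning.

Storage (stress granules, P-bodies-adjacent storage, de-ubiquitination
regulation) and degradation (P-bodies, proteasome, poly-ubiquitination
regulation) systems act synergistically under ethanol stress.  A relevant
lncRNA "connects" a synergistic category when its propagation subnetwork
touches at least two distinct systems of that category; the per-strain
percentage of such lncRNAs among the top-N most relevant ones is related
(negatively, in stressed yeast) to the strain's maximum tolerated ethanol
concentration.  Strains themselves are partitioned into higher- (HT) and
lower-tolerant (LT) phenotypes by a median split of their maximum
tolerated concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffusion import HeatVector
from .io import ToleranceTable

#: default synergistic-system groupings: stress granules (SG), protein
#: storage granules (PSG) and protein de-ubiquitination regulation (PDNR)
#: store molecules; P-bodies (PB), the proteasome and protein
#: poly-ubiquitination regulation (PPPR) degrade them.
DEFAULT_CATEGORIES: dict[str, set[str]] = {
    "storage": {"SG", "PSG", "PDNR"},
    "degradation": {"PB", "proteasome", "PPPR"},
}


@dataclass
class SynergyCategories:
    categories: dict[str, set[str]] = field(
        default_factory=lambda: {k: set(v) for k, v in DEFAULT_CATEGORIES.items()})

    def __post_init__(self) -> None:
        for name, systems in self.categories.items():
            if len(systems) < 2:
                raise ValueError(f"category {name!r} needs >=2 distinct systems")

    @property
    def known_systems(self) -> set[str]:
        return set().union(*self.categories.values())


def rank_lncrnas(heats: Mapping[str, HeatVector], n: int = 30) -> list[str]:
    """Top-N lncRNAs by total heat delivered outside their seed set.

    Ties break lexicographically by id, so the ranking is deterministic.
    """
    order = sorted(heats, key=lambda l: (-heats[l].delivered(), l))
    return order[:n]


def synergy_percentage(top_lncrnas: list[str],
                       subnetwork_proteins: Mapping[str, set[str]],
                       membership: Mapping[str, set[str] | str],
                       categories: SynergyCategories | None = None
                       ) -> dict[str, float]:
    """Percent of top lncRNAs whose subnetwork spans >=2 systems of a category.

    ``membership`` maps protein -> system label(s) (e.g. SG, PB, proteasome).
    Unknown system labels raise, to catch typos in the membership map.
    """
    cats = categories or SynergyCategories()
    known = cats.known_systems
    protein_systems: dict[str, set[str]] = {}
    for protein, systems in membership.items():
        s = {systems} if isinstance(systems, str) else set(systems)
        if unknown := s - known:
            raise ValueError(f"unknown system labels {sorted(unknown)} for {protein!r}")
        protein_systems[protein] = s

    out = {}
    for name, systems in cats.categories.items():
        count = 0
        for lnc in top_lncrnas:
            hit = set()
            for p in subnetwork_proteins.get(lnc, ()):
                hit |= protein_systems.get(p, set()) & systems
            if len(hit) >= 2:
                count += 1
        out[name] = 100.0 * count / len(top_lncrnas) if top_lncrnas else 0.0
    return out


def tolerance_association(percentages: Mapping[str, float],
                          tolerance: ToleranceTable) -> tuple[float, int]:
    """Spearman rank correlation of connecting-percentage vs max EtOH tolerance.

    Returns (rho, sign); rho is NaN (sign 0) when either vector is constant.
    Tolerance is ordinal by design, hence the rank correlation.
    """
    tol = tolerance.as_series()
    strains = [s for s in tol.index if s in percentages]
    if len(strains) < 4:
        raise ValueError("need at least 4 strains")
    x = np.array([percentages[s] for s in strains], dtype=float)
    y = tol[strains].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), 0
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, int(np.sign(rho))


@dataclass
class PhenotypePartition:
    labels: dict[str, str]   # strain -> HT / LT
    split_value: float       # the median used for the split

    def strains(self, phenotype: str) -> list[str]:
        return sorted(s for s, p in self.labels.items() if p == phenotype)


def partition_phenotypes(tolerance: ToleranceTable, method: str = "median") -> PhenotypePartition:
    """Split strains into HT/LT tolerance phenotypes.

    ``median``: strains strictly above the median tolerance (midpoint of the
    middle order statistics for even n) are HT, the rest LT.  ``kmeans``:
    1-d 2-means on the tolerances, the higher-centered cluster is HT.  Both
    are deterministic and guarantee every HT tolerance exceeds every LT one.
    """
    tol = tolerance.as_series()
    if len(tol) < 2:
        raise ValueError("need at least 2 strains")
    values = tol.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError("all tolerances equal: no phenotype split exists")

    if method == "median":
        split = float(np.median(values))
        labels = {s: ("HT" if tol[s] > split else "LT") for s in tol.index}
    elif method == "kmeans":
        # exact 1-d 2-means: best contiguous split of the sorted values
        order = np.sort(values)
        best = None
        for cut in range(1, len(order)):
            lo, hi = order[:cut], order[cut:]
            cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if best is None or cost < best[0]:
                best = (cost, order[cut - 1])
        split = float(best[1])
        labels = {s: ("HT" if tol[s] > split else "LT") for s in tol.index}
    else:
        raise ValueError(f"unknown method {method!r}")

    if not any(v == "HT" for v in labels.values()):
        raise ValueError("degenerate split: no HT strains")
    return PhenotypePartition(labels, split)
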