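"""Assembly of bipartite interaction networks and community summaries.

Surveys are pooled per (site, site class): all transects and all survey
rounds of the edge transects of one island form one quantitative network,
and likewise for the interior transects.  Cell weights are summed visit
counts.  Flowering-plant-only records (``visit_count == 0``) contribute to
floral resources and plant richness but never create a network row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BipartiteNetwork:
    """Weighted plant x pollinator interaction matrix for one site class."""

    site_id: str
    site_class: str
    weights: np.ndarray                      # plants x pollinators, int
    plant_names: list[str]
    pollinator_names: list[str]
    plant_floral_area: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)
        if self.weights.shape != (len(self.plant_names), len(self.pollinator_names)):
            raise ValueError("weight matrix shape does not match name lists")
        if (self.weights < 0).any():
            raise ValueError("negative interaction weight")

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    @property
    def n_links(self) -> int:
        return int((self.weights > 0).sum())

    def links(self) -> set[tuple[str, str]]:
        """Distinct realised (plant, pollinator) species pairs."""
        rows, cols = np.nonzero(self.weights)
        return {(self.plant_names[i], self.pollinator_names[j]) for i, j in zip(rows, cols)}


@dataclass(frozen=True)
class CommunityMetrics:
    """Community-structure summary of one (site, class) group.

    Fields mirror the four community responses of the path model: floral
    resources (FR), plant richness (PL), pollinator abundance (AB) and
    pollinator richness (PO).
    """

    floral_resources: float
    plant_richness: int
    pollinator_abundance: int
    pollinator_richness: int


def assemble_networks(records: pd.DataFrame) -> list[BipartiteNetwork]:
    """Pool surveys and build one network per (site_id, site_class).

    Cell weight = summed ``visit_count`` over every transect and survey round
    of that class on that site.  Species with zero total visits appear only in
    the floral-area totals, not as matrix rows or columns.  Groups with no
    records emit no network.  Plants and pollinators are ordered
    lexicographically for determinism.
    """
    networks: list[BipartiteNetwork] = []
    for (site_id, site_class), grp in records.groupby(["site_id", "site_class"], sort=True):
        floral = grp.groupby("plant_species")["floral_area"].sum().to_dict()
        visited = grp[grp["visit_count"] > 0]
        cell = (visited.groupby(["plant_species", "pollinator_species"])["visit_count"]
                .sum())
        plants = sorted({p for p, _ in cell.index})
        polls = sorted({a for _, a in cell.index})
        weights = np.zeros((len(plants), len(polls)), dtype=int)
        p_idx = {p: i for i, p in enumerate(plants)}
        a_idx = {a: j for j, a in enumerate(polls)}
        for (p, a), w in cell.items():
            weights[p_idx[p], a_idx[a]] = int(w)
        networks.append(BipartiteNetwork(str(site_id), str(site_class), weights,
                                         plants, polls, floral))
    return networks


def community_summaries(records: pd.DataFrame) -> dict[tuple[str, str], CommunityMetrics]:
    """Compute community metrics for every (site_id, site_class) group.

    Plant richness counts any flowering record; pollinator richness and
    abundance count only actual visits.
    """
    out: dict[tuple[str, str], CommunityMetrics] = {}
    for (site_id, site_class), grp in records.groupby(["site_id", "site_class"], sort=True):
        out[(str(site_id), str(site_class))] = summarise_group(grp)
    return out


def summarise_group(grp: pd.DataFrame) -> CommunityMetrics:
    """Community metrics of one already-grouped record set."""
    visited = grp[grp["visit_count"] > 0]
    return CommunityMetrics(
        floral_resources=float(grp["floral_area"].sum()),
        plant_richness=int(grp["plant_species"].nunique()),
        pollinator_abundance=int(grp["visit_count"].sum()),
        pollinator_richness=int(visited["pollinator_species"].nunique()),
    )


def global_link_map(records: pd.DataFrame) -> set[tuple[str, str]]:
    """All distinct (plant, pollinator) links realised anywhere in the study.

    This is the reference universe for relative connectance: a link counts if
    the pair was observed interacting on any site, any class, any round.
    """
    visited = records[records["visit_count"] > 0]
    return set(zip(visited["plant_species"], visited["pollinator_species"]))
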