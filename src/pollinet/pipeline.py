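"""High-level pipeline steps shared by the CLI, examples and scripts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as net_metrics
from .io import IslandAttributes
from .networks import assemble_networks, community_summaries, global_link_map
from .sem import prepare_design


def metrics_tables(records: pd.DataFrame, n_restarts: int = 20,
                   seed: int = 0) -> tuple[pd.DataFrame, dict, dict]:
    """Community and network metrics for every (site, class) group.

    Returns a tidy ``site_id, site_class, metric, value`` frame plus the raw
    community- and network-metric mappings (keyed by (site_id, site_class))
    for further analysis.  Networks too sparse for a metric are skipped.
    """
    community = community_summaries(records)
    links = global_link_map(records)
    networks = assemble_networks(records)
    nm: dict[tuple[str, str], net_metrics.NetworkMetrics] = {}
    rows = []
    for key, cm in community.items():
        for name in ("floral_resources", "plant_richness", "pollinator_abundance",
                     "pollinator_richness"):
            rows.append({"site_id": key[0], "site_class": key[1],
                         "metric": name, "value": getattr(cm, name)})
    for net in networks:
        if net.n_links == 0:
            continue
        key = (net.site_id, net.site_class)
        m = net_metrics.compute_network_metrics(net, links, n_restarts=n_restarts,
                                                seed=seed)
        nm[key] = m
        for name in ("relative_connectance", "nodf", "modularity", "robustness"):
            rows.append({"site_id": key[0], "site_class": key[1],
                         "metric": name, "value": getattr(m, name)})
    return pd.DataFrame(rows), community, nm


def build_design(records: pd.DataFrame, attributes: dict[str, IslandAttributes],
                 n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Analysis table over islands only (mainland rows carry no attributes)."""
    islands = records[~records["is_mainland"]]
    _, community, nm = metrics_tables(islands, n_restarts=n_restarts, seed=seed)
    # full-study link map for RC, not the island-only one
    links = global_link_map(records)
    networks = assemble_networks(islands)
    for net in networks:
        key = (net.site_id, net.site_class)
        if key in nm:
            nm[key] = net_metrics.NetworkMetrics(
                relative_connectance=net_metrics.relative_connectance(net, links),
                nodf=nm[key].nodf, modularity=nm[key].modularity,
                robustness=nm[key].robustness)
    table = prepare_design(attributes, community, nm)
    return table.dropna().reset_index(drop=True)
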