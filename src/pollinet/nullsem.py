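"""Null-model SEM: refitting the final path structure on null draws.

Each replicate replaces the community columns (FR, PL, AB, PO) with Null
model I draws and the architecture columns (RC, NE, MO, RO) with metrics of
Null model II networks, island attributes untouched, then refits the *same*
path structure — no re-selection — and records the standardized
coefficients.  An observed path "deviates" from passive-sampling expectation
when it falls outside the empirical 95% envelope of its null coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import FitError
from .networks import BipartiteNetwork
from .nullmodels import ReferencePool, null_draw_network, null_draw_transects
from .sem import FittedSem, PathStructure, SemFitter, _std_map
from . import metrics as net_metrics

COMMUNITY_VARS = ("FR", "PL", "AB", "PO")
NETWORK_VARS = ("RC", "NE", "MO", "RO")


@dataclass(frozen=True)
class PathNullComparison:
    """Envelope of one path's null coefficients vs the observed value."""

    path_id: int
    source: str
    target: str
    observed: float
    null_mean: float
    ci_low: float
    ci_high: float
    deviates: bool
    n_reps: int


@dataclass(frozen=True)
class IslandConstraints:
    """Per-(island, class) quantities that the null draws must match."""

    n_transects: int
    n_interactions: int
    n_plants: int
    n_pollinators: int


def island_constraints(records: pd.DataFrame,
                       networks: dict[tuple[str, str], BipartiteNetwork]
                       ) -> dict[tuple[str, str], IslandConstraints]:
    """Observed transect counts and network sizes for each island group."""
    out: dict[tuple[str, str], IslandConstraints] = {}
    islands = records[~records["is_mainland"]]
    for (site_id, site_class), grp in islands.groupby(["site_id", "site_class"],
                                                      sort=True):
        key = (str(site_id), str(site_class))
        net = networks.get(key)
        out[key] = IslandConstraints(
            n_transects=int(grp["transect_id"].nunique()),
            n_interactions=net.total_weight if net else 0,
            n_plants=len(net.plant_names) if net else 0,
            n_pollinators=len(net.pollinator_names) if net else 0,
        )
    return out


def feasible_constraints(constraints: dict[tuple[str, str], IslandConstraints],
                         pool: ReferencePool
                         ) -> dict[tuple[str, str], IslandConstraints]:
    """Island groups whose Null model II targets the pool can satisfy.

    A group is excluded when it recorded no interactions, or when its
    observed plant or pollinator richness exceeds the matching mainland
    pool's richness (the constrained draw is then impossible by
    definition).  Use the returned subset to drive replicate loops.
    """
    out = {}
    for (site_id, site_class), cons in constraints.items():
        if cons.n_interactions == 0:
            continue
        cl = pool._links(site_class)
        if cons.n_plants > len(cl.plants) or cons.n_pollinators > len(cl.polls):
            continue
        out[(site_id, site_class)] = cons
    return out


def _null_row_values(pool: ReferencePool, cons: IslandConstraints, site_class: str,
                     rng: np.random.Generator, modularity_restarts: int,
                     max_tries: int = 200) -> dict[str, float]:
    cm = null_draw_transects(pool, cons.n_transects, site_class, rng)
    values = {
        "FR": cm.floral_resources, "PL": cm.plant_richness,
        "AB": cm.pollinator_abundance, "PO": cm.pollinator_richness,
    }
    draw = null_draw_network(pool, cons.n_interactions, cons.n_plants,
                             cons.n_pollinators, site_class, rng,
                             max_tries=max_tries)
    net = draw.network
    floral = pool.species_floral_area[site_class]
    order = sorted(net.plant_names, key=lambda p: (floral.get(p, 0.0), p))
    values["RC"] = net_metrics.relative_connectance(net, pool._rc_index())
    values["NE"] = net_metrics.nodf(net.weights)
    values["MO"] = net_metrics.optimize_modules(
        net.weights, n_restarts=modularity_restarts,
        seed=int(rng.integers(2**31))).q
    values["RO"] = net_metrics.robustness(net, order)
    return values


def null_design_table(design: pd.DataFrame, pool: ReferencePool,
                      constraints: dict[tuple[str, str], IslandConstraints],
                      rng_seed: tuple, modularity_restarts: int = 4) -> pd.DataFrame:
    """One null replicate of the analysis table (attributes bit-identical).

    Design rows without an entry in ``constraints`` are dropped from the
    replicate — pass :func:`feasible_constraints` to exclude island groups
    whose observed richness the mainland pool cannot match.
    """
    keep = [idx for idx, row in design.iterrows()
            if (row["island"], row["site_class"]) in constraints]
    table = design.loc[keep].copy()
    drawn = {var: np.empty(len(keep)) for var in COMMUNITY_VARS + NETWORK_VARS}
    for pos, (idx, row) in enumerate(table.iterrows()):
        cons = constraints[(row["island"], row["site_class"])]
        rng = np.random.default_rng((*rng_seed, idx))
        values = _null_row_values(pool, cons, row["site_class"], rng,
                                  modularity_restarts)
        for var in COMMUNITY_VARS + NETWORK_VARS:
            drawn[var][pos] = values[var]
    for var in COMMUNITY_VARS + NETWORK_VARS:
        table[var] = drawn[var]
    return table.reset_index(drop=True)


def run_null_sem(final: PathStructure, design: pd.DataFrame, pool: ReferencePool,
                 constraints: dict[tuple[str, str], IslandConstraints],
                 observed: FittedSem, n_reps: int = 1000, seed: int = 0,
                 modularity_restarts: int = 4,
                 max_failed_frac: float = 0.20) -> list[PathNullComparison]:
    """Fit the final structure on ``n_reps`` null datasets and build envelopes.

    Replicates whose component models fail to converge are dropped (and
    counted); more than ``max_failed_frac`` failures aborts.  Two runs with
    the same seed produce identical envelopes.
    """
    observed_std = _std_map(observed)
    draws: dict[int, list[float]] = {p.path_id: [] for p in final.paths}
    n_ok = 0
    n_failed = 0
    for rep in range(n_reps):
        table = null_design_table(design, pool, constraints, (seed, rep),
                                  modularity_restarts)
        try:
            fit = SemFitter(table, final.families).fit_sem(final, compute_dsep=False)
        except FitError:
            n_failed += 1
            continue
        std = _std_map(fit)
        for p in final.paths:
            draws[p.path_id].append(std[(p.source, p.target)])
        n_ok += 1
    if n_reps and n_failed > max_failed_frac * n_reps:
        raise FitError(f"{n_failed}/{n_reps} null SEM replicates failed to fit")

    out = []
    for p in final.paths:
        null = np.asarray(draws[p.path_id])
        lo, hi = np.percentile(null, [2.5, 97.5])
        obs = observed_std[(p.source, p.target)]
        out.append(PathNullComparison(
            path_id=p.path_id, source=p.source, target=p.target, observed=obs,
            null_mean=float(null.mean()), ci_low=float(lo), ci_high=float(hi),
            deviates=bool(obs < lo or obs > hi), n_reps=n_ok,
        ))
    return out


def comparisons_frame(comparisons: list[PathNullComparison], seed: int) -> pd.DataFrame:
    rows = [{
        "path_id": c.path_id, "source": c.source, "target": c.target,
        "observed": c.observed, "null_mean": c.null_mean,
        "ci_low": c.ci_low, "ci_high": c.ci_high, "deviates": c.deviates,
        "n_reps": c.n_reps, "seed": seed,
    } for c in comparisons]
    return pd.DataFrame(rows)
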