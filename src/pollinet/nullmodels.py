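"""Constrained null models against the mainland reference pool.

Two randomisations ask whether island communities and networks differ from
what a passive sampling effect from the unfragmented mainland would produce:

* **Null model I** — draw, with replacement, the same number of transects
  from the mainland pool of the matching site class as were sampled on the
  island, and recompute the four community metrics;
* **Null model II** — draw, with replacement, the same number of pairwise
  interaction *events* (proportional to mainland visit counts) while
  requiring exactly the island's observed numbers of plant and pollinator
  species; draws are rejection-sampled and, past a cap, repaired by single
  event swaps (flagged in the draw metadata).

Observed values are compared to the null distribution through the
standardized effect size SES = (obs - mean_null) / sd_null with two-tailed
significance read off the empirical 2.5-97.5 percentile interval.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import (BipartiteNetwork, CommunityMetrics, assemble_networks,
                       global_link_map)
from . import metrics as net_metrics

SITE_CLASSES = ("edge", "interior")


@dataclass(frozen=True)
class TransectSummary:
    """Precomputed totals of one mainland transect (all rounds pooled)."""

    transect_id: str
    site_class: str
    floral_total: float
    visit_total: int
    plant_species: frozenset
    pollinator_species: frozenset


@dataclass
class ReferencePool:
    """Mainland edge and interior reference pools for all null draws."""

    edge_transects: list[TransectSummary]
    interior_transects: list[TransectSummary]
    link_weights: dict[str, dict[tuple[str, str], int]]     # per class
    species_floral_area: dict[str, dict[str, float]]        # per class
    global_links: set[tuple[str, str]]

    def transects(self, site_class: str) -> list[TransectSummary]:
        if site_class == "edge":
            return self.edge_transects
        if site_class == "interior":
            return self.interior_transects
        raise ValueError(f"unknown site class {site_class!r}")

    def _links(self, site_class: str) -> "_ClassLinks":
        cache = getattr(self, "_link_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_link_cache", cache)
        if site_class not in cache:
            cache[site_class] = _ClassLinks(self.link_weights[site_class])
        return cache[site_class]

    def _rc_index(self) -> dict[str, set]:
        idx = getattr(self, "_rc_index_cache", None)
        if idx is None:
            idx = {}
            for p, a in self.global_links:
                idx.setdefault(p, set()).add(a)
            object.__setattr__(self, "_rc_index_cache", idx)
        return idx


@dataclass(frozen=True)
class NullEnvelope:
    """Null distribution summary and SES of one observed quantity."""

    quantity: str
    observed: float
    null_mean: float
    null_sd: float
    ci_low: float
    ci_high: float
    ses: float
    significant: bool
    n_draws: int
    degenerate: bool = False


@dataclass
class NullNetworkDraw:
    """One accepted Null model II network plus draw metadata."""

    network: BipartiteNetwork
    repaired: bool
    n_tries: int


def build_reference_pool(records: pd.DataFrame) -> ReferencePool:
    """Compile the mainland reference pools from the full record table.

    Mainland rows build the per-class transect summaries, pooled link weights
    and per-plant floral totals; the study-wide link map (for relative
    connectance) pools every site, island or mainland.
    """
    mainland = records[records["is_mainland"]]
    pools: dict[str, list[TransectSummary]] = {"edge": [], "interior": []}
    link_weights: dict[str, dict[tuple[str, str], int]] = {}
    floral: dict[str, dict[str, float]] = {}
    for site_class in SITE_CLASSES:
        cls = mainland[mainland["site_class"] == site_class]
        if cls.empty:
            raise ValueError(f"no mainland records for site class {site_class!r}")
        for tid, grp in cls.groupby("transect_id", sort=True):
            visited = grp[grp["visit_count"] > 0]
            pools[site_class].append(TransectSummary(
                transect_id=str(tid),
                site_class=site_class,
                floral_total=float(grp["floral_area"].sum()),
                visit_total=int(grp["visit_count"].sum()),
                plant_species=frozenset(grp["plant_species"]),
                pollinator_species=frozenset(visited["pollinator_species"]),
            ))
        visited = cls[cls["visit_count"] > 0]
        link_weights[site_class] = {
            (p, a): int(w) for (p, a), w in
            visited.groupby(["plant_species", "pollinator_species"])["visit_count"]
            .sum().items()
        }
        floral[site_class] = cls.groupby("plant_species")["floral_area"].sum().to_dict()
    return ReferencePool(pools["edge"], pools["interior"], link_weights, floral,
                         global_link_map(records))


# ---------------------------------------------------------------------------
# Null model I
# ---------------------------------------------------------------------------

def null_draw_transects(pool: ReferencePool, n_transects: int, site_class: str,
                        rng: np.random.Generator) -> CommunityMetrics:
    """One Null model I draw: community metrics of n resampled transects.

    Transects are sampled uniformly with replacement from the matching class;
    floral resources and abundance sum over the sampled multiset, richness is
    counted over the union of species.
    """
    if n_transects < 1:
        raise ValueError("n_transects must be >= 1")
    transects = pool.transects(site_class)
    picks = rng.integers(0, len(transects), size=n_transects)
    chosen = [transects[i] for i in picks]
    plants: set = set()
    polls: set = set()
    for t in chosen:
        plants |= t.plant_species
        polls |= t.pollinator_species
    return CommunityMetrics(
        floral_resources=float(sum(t.floral_total for t in chosen)),
        plant_richness=len(plants),
        pollinator_abundance=int(sum(t.visit_total for t in chosen)),
        pollinator_richness=len(polls),
    )


# ---------------------------------------------------------------------------
# Null model II
# ---------------------------------------------------------------------------

def _network_from_counts(counts: np.ndarray, links: list[tuple[str, str]],
                         pool: ReferencePool, site_class: str) -> BipartiteNetwork:
    nz = np.flatnonzero(counts)
    plants = sorted({links[i][0] for i in nz})
    polls = sorted({links[i][1] for i in nz})
    p_idx = {p: i for i, p in enumerate(plants)}
    a_idx = {a: j for j, a in enumerate(polls)}
    weights = np.zeros((len(plants), len(polls)), dtype=int)
    for i in nz:
        p, a = links[i]
        weights[p_idx[p], a_idx[a]] += int(counts[i])
    floral = pool.species_floral_area[site_class]
    return BipartiteNetwork("null", site_class, weights, plants, polls,
                            {p: floral.get(p, 0.0) for p in plants})


def _distinct(counts: np.ndarray, links: list[tuple[str, str]]) -> tuple[set, set]:
    nz = np.flatnonzero(counts)
    return {links[i][0] for i in nz}, {links[i][1] for i in nz}


class _ClassLinks:
    """Precomputed arrays over one class's pooled links (sorted by pair)."""

    def __init__(self, link_weights: dict[tuple[str, str], int]):
        self.links = sorted(link_weights)
        w = np.array([link_weights[l] for l in self.links], dtype=float)
        self.prob = w / w.sum()
        plant_side = np.asarray([p for p, _ in self.links])
        poll_side = np.asarray([a for _, a in self.links])
        self.p_codes, self.plants = pd.factorize(plant_side, sort=True)
        self.a_codes, self.polls = pd.factorize(poll_side, sort=True)
        self.p_perm = np.argsort(self.p_codes, kind="stable")
        self.p_starts = np.flatnonzero(np.diff(self.p_codes[self.p_perm], prepend=-1))
        self.a_perm = np.argsort(self.a_codes, kind="stable")
        self.a_starts = np.flatnonzero(np.diff(self.a_codes[self.a_perm], prepend=-1))


def null_draw_network(pool: ReferencePool, n_interactions: int, n_plants: int,
                      n_pollinators: int, site_class: str,
                      rng: np.random.Generator, max_tries: int = 10_000,
                      allow_repair: bool = True) -> NullNetworkDraw:
    """One Null model II draw under the three constraints.

    Events are sampled with replacement proportional to pooled mainland visit
    counts; a draw is accepted when the induced network has exactly the
    requested species richness on both sides.  After ``max_tries`` rejections
    a repair pass swaps single events toward the richness targets (the
    returned draw is flagged ``repaired``); with ``allow_repair=False`` the
    exhausted cap raises instead.
    """
    cl = pool._links(site_class)
    if n_plants > len(cl.plants) or n_pollinators > len(cl.polls):
        raise ValueError("requested richness exceeds the reference pool's richness")
    if n_interactions < max(n_plants, n_pollinators):
        raise ValueError("n_interactions must be >= max(n_plants, n_pollinators)")

    counts = None
    tries = 0
    batch = 128
    while tries < max_tries:
        size = min(batch, max_tries - tries)
        cand = rng.multinomial(n_interactions, cl.prob, size=size)
        nz = (cand > 0).astype(np.int32)
        n_p = (np.add.reduceat(nz[:, cl.p_perm], cl.p_starts, axis=1) > 0).sum(axis=1)
        n_a = (np.add.reduceat(nz[:, cl.a_perm], cl.a_starts, axis=1) > 0).sum(axis=1)
        hits = np.flatnonzero((n_p == n_plants) & (n_a == n_pollinators))
        if hits.size:
            tries += int(hits[0]) + 1
            return NullNetworkDraw(
                _network_from_counts(cand[hits[0]], cl.links, pool, site_class),
                repaired=False, n_tries=tries)
        tries += size
        counts = cand[-1]
    if not allow_repair:
        raise RuntimeError(f"Null model II: no accepted draw in {max_tries} tries")

    try:
        counts = _repair(counts, cl, n_plants, n_pollinators, rng)
    except RuntimeError:
        # swap repair can stall on extreme targets (e.g. one plant, several
        # pollinators); build a feasible draw constructively instead
        counts = _constructive_draw(cl, n_interactions, n_plants,
                                    n_pollinators, rng)
    return NullNetworkDraw(_network_from_counts(counts, cl.links, pool, site_class),
                           repaired=True, n_tries=tries)


def _repair(counts: np.ndarray, cl: "_ClassLinks", n_plants: int,
            n_pollinators: int, rng: np.random.Generator,
            max_passes: int = 5000) -> np.ndarray:
    """Swap events until both species-richness targets hold exactly.

    Surplus species are dissolved into the kept set (their events re-sampled
    weight-proportionally among remaining links); missing species receive one
    event taken from a multi-event donor.  The event total never changes.
    Raises if the targets cannot be reached within ``max_passes``.
    """
    counts = np.asarray(counts).copy()
    n_pc, n_ac = len(cl.plants), len(cl.polls)

    for _ in range(max_passes):
        p_tot = np.bincount(cl.p_codes, weights=counts, minlength=n_pc)
        a_tot = np.bincount(cl.a_codes, weights=counts, minlength=n_ac)
        np_now, na_now = int((p_tot > 0).sum()), int((a_tot > 0).sum())
        if np_now == n_plants and na_now == n_pollinators:
            return counts
        for codes, tot, now, target in ((cl.p_codes, p_tot, np_now, n_plants),
                                        (cl.a_codes, a_tot, na_now, n_pollinators)):
            if now > target:
                # dissolve the poorest surplus species into the kept set;
                # destinations stay within currently-present species so the
                # move never introduces new ones
                present = np.flatnonzero(tot > 0)
                drop = present[np.argmin(tot[present])]
                drop_mask = codes == drop
                moved = int(counts[drop_mask].sum())
                counts[drop_mask] = 0
                keep = ((p_tot[cl.p_codes] > 0) & (a_tot[cl.a_codes] > 0)
                        & ~drop_mask)
                dest = cl.prob * keep
                if dest.sum() == 0:
                    dest = cl.prob * ~drop_mask
                counts += rng.multinomial(moved, dest / dest.sum())
                break
            if now < target:
                # one event from a multi-event donor to an absent species,
                # preferring links whose other side is already present so
                # the move cannot break the other constraint
                other_codes = cl.a_codes if codes is cl.p_codes else cl.p_codes
                other_tot = a_tot if codes is cl.p_codes else p_tot
                safe = np.flatnonzero((tot[codes] == 0)
                                      & (other_tot[other_codes] > 0))
                cand_links = safe if safe.size else \
                    np.flatnonzero(tot[codes] == 0)
                add = cand_links[int(rng.choice(
                    len(cand_links),
                    p=cl.prob[cand_links] / cl.prob[cand_links].sum()))]
                # a donor event is safe when removing it leaves both of its
                # species represented
                donors = np.flatnonzero(
                    (counts > 0) & (tot[codes] >= 2)
                    & ((counts >= 2) | (other_tot[other_codes] >= 2)))
                if donors.size == 0:
                    donors = np.flatnonzero((counts > 0) & (tot[codes] >= 2))
                if donors.size == 0:
                    raise RuntimeError("Null model II repair: no donor event available")
                take = donors[int(rng.integers(donors.size))]
                counts[take] -= 1
                counts[add] += 1
                break
    p_ok = int((np.bincount(cl.p_codes, weights=counts, minlength=n_pc) > 0).sum())
    a_ok = int((np.bincount(cl.a_codes, weights=counts, minlength=n_ac) > 0).sum())
    if p_ok == n_plants and a_ok == n_pollinators:
        return counts
    raise RuntimeError("Null model II repair failed to reach the richness targets")


def _constructive_draw(cl: "_ClassLinks", n_interactions: int, n_plants: int,
                       n_pollinators: int, rng: np.random.Generator,
                       max_tries: int = 500) -> np.ndarray:
    """Assemble a constraint-satisfying draw directly.

    Grows a connected species set link by link (weight-proportional), covers
    every chosen species with one event via a greedy edge cover, and spreads
    the remaining events weight-proportionally over the induced links.  Used
    only when swap repair stalls; raises if no feasible assembly is found.
    """
    n_links = len(cl.links)
    for _ in range(max_tries):
        seed = int(rng.choice(n_links, p=cl.prob))
        plants = {int(cl.p_codes[seed])}
        polls = {int(cl.a_codes[seed])}
        ok = True
        while ok and (len(plants) < n_plants or len(polls) < n_pollinators):
            grew = False
            if len(plants) < n_plants:
                cand = np.flatnonzero(np.isin(cl.a_codes, list(polls))
                                      & ~np.isin(cl.p_codes, list(plants)))
                if cand.size:
                    pick = int(rng.choice(cand.size,
                                          p=cl.prob[cand] / cl.prob[cand].sum()))
                    plants.add(int(cl.p_codes[cand[pick]]))
                    grew = True
            if len(polls) < n_pollinators:
                cand = np.flatnonzero(np.isin(cl.p_codes, list(plants))
                                      & ~np.isin(cl.a_codes, list(polls)))
                if cand.size:
                    pick = int(rng.choice(cand.size,
                                          p=cl.prob[cand] / cl.prob[cand].sum()))
                    polls.add(int(cl.a_codes[cand[pick]]))
                    grew = True
            ok = grew
        if not ok:
            continue
        induced = np.flatnonzero(np.isin(cl.p_codes, list(plants))
                                 & np.isin(cl.a_codes, list(polls)))
        # greedy edge cover: heavy matching first, then cover leftovers
        order = induced[np.argsort(-cl.prob[induced], kind="stable")]
        covered_p: set = set()
        covered_a: set = set()
        cover: list[int] = []
        for i in order:
            if cl.p_codes[i] not in covered_p and cl.a_codes[i] not in covered_a:
                cover.append(int(i))
                covered_p.add(int(cl.p_codes[i]))
                covered_a.add(int(cl.a_codes[i]))
        for i in order:
            p_new = cl.p_codes[i] not in covered_p
            a_new = cl.a_codes[i] not in covered_a
            if p_new or a_new:
                cover.append(int(i))
                covered_p.add(int(cl.p_codes[i]))
                covered_a.add(int(cl.a_codes[i]))
        if len(cover) > n_interactions:
            continue
        counts = np.zeros(n_links, dtype=int)
        counts[cover] = 1
        rest = n_interactions - len(cover)
        if rest:
            counts += rng.multinomial(rest, cl.prob[induced] / cl.prob[induced].sum()
                                      ) @ _scatter(induced, n_links)
        return counts
    raise RuntimeError("Null model II: no feasible constrained draw found")


def _scatter(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(idx), n), dtype=int)
    out[np.arange(len(idx)), idx] = 1
    return out


# ---------------------------------------------------------------------------
# SES
# ---------------------------------------------------------------------------

def ses_compare(observed: float, null_values, quantity: str = "") -> NullEnvelope:
    """Standardized effect size and two-tailed empirical 95% test.

    SES = (observed - mean(null)) / sd(null); the observation is significant
    when it falls strictly outside the empirical 2.5-97.5 percentile
    interval.  A degenerate null (zero s.d.) yields an undefined (NaN) SES
    with significance decided by exact inequality.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null values")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    lo, hi = (float(v) for v in np.percentile(null, [2.5, 97.5]))
    if sd == 0.0:
        return NullEnvelope(quantity, float(observed), mean, 0.0, lo, hi,
                            float("nan"), observed != mean, null.size, degenerate=True)
    ses = (float(observed) - mean) / sd
    significant = bool(observed < lo or observed > hi)
    return NullEnvelope(quantity, float(observed), mean, sd, lo, hi, ses,
                        significant, null.size)


# ---------------------------------------------------------------------------
# per-island null analysis
# ---------------------------------------------------------------------------

COMMUNITY_QUANTITIES = ("floral_resources", "plant_richness",
                        "pollinator_abundance", "pollinator_richness")
NETWORK_QUANTITIES = ("relative_connectance", "nodf", "modularity", "robustness")


def null_analysis(records: pd.DataFrame, pool: ReferencePool, n_draws: int = 1000,
                  seed: int = 0, modularity_restarts: int = 4,
                  max_tries: int = 200) -> pd.DataFrame:
    """SES envelopes for every island x class, community and network metrics.

    For each island group, Null model I resamples the island's own transect
    count and Null model II its observed interaction total and species
    richness.  Null networks use the mainland rarity order (per-class floral
    totals) for robustness.  Returns the tidy envelope table.
    """
    islands = records[~records["is_mainland"]]
    networks = {(n.site_id, n.site_class): n for n in assemble_networks(islands)}
    rows = []
    for (site_id, site_class), grp in islands.groupby(["site_id", "site_class"],
                                                      sort=True):
        n_transects = grp["transect_id"].nunique()
        obs_cm = _group_metrics(grp)
        net = networks.get((site_id, site_class))

        draws_cm = {q: np.empty(n_draws) for q in COMMUNITY_QUANTITIES}
        draws_net = {q: [] for q in NETWORK_QUANTITIES}
        site_key = zlib.crc32(f"{site_id}/{site_class}".encode()) % (2**31)
        for d in range(n_draws):
            rng = np.random.default_rng((seed, site_key, d))
            cm = null_draw_transects(pool, n_transects, site_class, rng)
            for q in COMMUNITY_QUANTITIES:
                draws_cm[q][d] = getattr(cm, q)
            if net is not None and net.n_links > 0:
                draw = null_draw_network(pool, net.total_weight,
                                         len(net.plant_names),
                                         len(net.pollinator_names),
                                         site_class, rng, max_tries=max_tries)
                m = _null_network_metrics(draw.network, pool, site_class,
                                          modularity_restarts,
                                          int(rng.integers(2**31)))
                for q in NETWORK_QUANTITIES:
                    draws_net[q].append(m[q])

        obs_net = None
        if net is not None and net.n_links > 0:
            obs_net = _null_network_metrics(net, pool, site_class,
                                            modularity_restarts, seed,
                                            observed=True)
        for q in COMMUNITY_QUANTITIES:
            env = ses_compare(getattr(obs_cm, q), draws_cm[q], q)
            rows.append(_env_row(site_id, site_class, env, seed))
        if obs_net is not None:
            for q in NETWORK_QUANTITIES:
                env = ses_compare(obs_net[q], np.asarray(draws_net[q]), q)
                rows.append(_env_row(site_id, site_class, env, seed))
    return pd.DataFrame(rows)


def _group_metrics(grp: pd.DataFrame) -> CommunityMetrics:
    from .networks import summarise_group
    return summarise_group(grp)


def _null_network_metrics(net: BipartiteNetwork, pool: ReferencePool,
                          site_class: str, restarts: int, seed: int,
                          observed: bool = False) -> dict[str, float]:
    floral = pool.species_floral_area[site_class]
    if observed:
        order = net_metrics.extinction_order_by_rarity(net)
    else:
        order = sorted(net.plant_names, key=lambda p: (floral.get(p, 0.0), p))
    return {
        "relative_connectance": net_metrics.relative_connectance(net, pool.global_links),
        "nodf": net_metrics.nodf(net.weights),
        "modularity": net_metrics.optimize_modules(net.weights, n_restarts=restarts,
                                                   seed=seed).q,
        "robustness": net_metrics.robustness(net, order),
    }


def _env_row(site_id: str, site_class: str, env: NullEnvelope, seed: int) -> dict:
    return {
        "site_id": site_id, "site_class": site_class, "quantity": env.quantity,
        "observed": env.observed, "null_mean": env.null_mean, "null_sd": env.null_sd,
        "ci_low": env.ci_low, "ci_high": env.ci_high, "ses": env.ses,
        "significant": env.significant, "n_draws": env.n_draws, "seed": seed,
    }
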